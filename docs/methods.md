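# Methods

## Measurement model

A time-of-flight depth sensor reports, per pixel, the distance to the first
reflecting surface.  For a pinhole camera with field of view 62° (vertical,
224 rows) × 45° (horizontal, 171 columns), a pixel's footprint on a frontal
surface at distance d is

    S(d) = (2 d tan 31° / 224) · (2 d tan 22.5° / 171)  mm²,

independent of the pixel position under the uniform-pinhole approximation
and quadratic in d (S(350 mm) ≈ 3.184 mm²).  When the chest surface under
pixel (i, j) moves by ΔZ along the ray, it sweeps S·ΔZ of volume.  The
anterior-thorax volume curve is the cumulative sum of

    ΔV(t) = Σ_(i,j)∈ROI  S(d̄_ij(t)) · (d_ij(t−1) − d_ij(t)),

with d̄ the midpoint of the two distances.  Sign convention: decreasing
distance (chest approaching the sensor) is inspiration and counts positive;
this matches the physical deformation of the thorax and makes the forced
expiration a falling curve.  The midpoint-area convention is symmetric and
second-order accurate in the step size; at 45 Hz the per-frame excursion is
a few mm, so the residual error is negligible (the rigid-piston test bounds
it below 0.5%).

Assumptions: the subject faces the sensor squarely and does not translate;
only the anterior surface is visible, so the curve understates lung volume
change (hence the regression below); frame-to-frame surface correspondence
is per-pixel (no lateral motion tracking).

## Region of interest

Foreground is everything valid and strictly closer than the seating
distance plus 150 mm (the background cut).  The chest is the largest
4-connected foreground component; components under 100 px are rejected as
noise.  Head and neck are removed by a silhouette-width heuristic: scanning
upward from the widest row, the first row whose foreground width falls
below 60% of the maximum marks the neck line, and the box starts one row
below it.  The ROI — foreground ∩ box, computed once from the per-pixel
median of the first second of frames — is held fixed for the whole record,
because the swept-volume integral treats the ROI as a constant indicator;
a per-frame ROI would alias mask churn into apparent volume.

The neck heuristic always fires eventually on a convex silhouette (any
blob's width tapers near its top), so for a subject without a visible head
it trims only the last few rows of the chest taper; with the torso model
below this costs under 0.2% of the swept volume.

## Smoothing

Each frame is smoothed with a normalized 7×7 Gaussian, σ = 1.5 px (the 7×7
support then carries >99% of the kernel mass), reflect padding.  Pixels
with no sensor return are excluded from the weighted sum and the remaining
weights renormalized.  Inside the volume integral the same mechanism also
excludes pixels outside the ROI: background depths differ from chest depths
by hundreds of mm, and letting them bleed into the rim would inflate the
(distance-dependent) pixel areas there.  With ROI-restricted smoothing the
volume curve is exactly invariant to the background geometry.  Smoothing is
spatial only; no temporal filter is applied to the depth data.

## Spirometric indices

The forced maneuver is located as the global volume maximum (rejected if it
falls within 0.5 s of either end — a truncated maneuver) followed by the
minimum over the next 3 s.  FVC is the peak-to-peak amplitude over that
window, never over the whole record, so tidal breaths cannot inflate it.

Time zero of the forced expiration uses the standard back-extrapolation
convention: on the expired-volume curve E(t) = V(peak) − V(t), the tangent
at the point of maximum slope (central differences on a lightly smoothed
copy, temporal Gaussian σ = 1 sample; ties broken by earliest time) is
intersected with E = 0.  FEV1 is E(time zero + 1 s), linearly interpolated
between samples — at 22.2 ms sampling, nearest-sample rounding alone could
cost ~1% of FEV1 on a steep curve — and clipped to FVC.  On sampled
exponential expirations E = FVC·(1 − e^(−t/τ)) the recovered FEV1 is within
1% of the closed form for τ ∈ [0.3, 2] s.

The curve-to-prediction rescaling multiplies the whole volume axis by
FVC_pred/FVC_anterior.  Because a single ratio rescales the curve, FEV1%
is mathematically invariant under it: the predicted FEV1% always equals the
anterior-thorax FEV1%.  This is a property of the single-ratio design, not
an implementation artifact, and the tests assert it to machine precision.

## Calibration and cross-validation

FVC_pred = a·FVC_anterior + b·Height + c·BMI + d, fitted by plain ordinary
least squares (no regularization) with units mL / cm / kg·m⁻²; only this
unit reading makes the published coefficients (0.55, 46.41, 0.29, −5690.56)
produce physiologic volumes.  Fitting requires ≥5 rows and a full-rank
design; rank deficiency (e.g., a constant covariate) is an error, not a
silent pseudo-inverse.  The estimator follows the scikit-learn API
(`FvcCalibrator`), so model selection utilities compose with it;
leave-one-out prediction uses `sklearn.model_selection.LeaveOneOut`, and a
mutation test verifies that a subject's own spirometry never influences
their fold.

## Screening evaluation

Airflow limitation is called when FEV1% < 70 (strictly; 70.0 is negative).
The reference label is the same spirometric rule applied to the reference
instrument, not the clinical group tag, which is retained for reporting
only.  ROC analysis orients scores as "lower FEV1% = more positive" and
integrates by trapezoid (tied scores contribute ½, the Mann–Whitney
convention).  Pearson r carries the two-sided t-test p-value on n−2 df.
Bland–Altman limits of agreement are mean ± 1.96·SD (sample SD, n−1) of
first-minus-second differences.

## Synthetic scenes

The simulated chest is a superellipse |x/rx|⁴ + |y/ry|⁴ ≤ 1 (default
rx = 120 mm, ry = 130 mm, centred 70 mm below the optical axis at 350 mm)
carrying a bump g = 1 − s² (s the superelliptic radial coordinate to the
4th power): smooth, 1 at the centre, 0 at the rim.  The quartic footprint
keeps the silhouette width above 60% of maximum until ~97% of the
half-height, so the neck heuristic behaves on headless scenes the way it
does on real torsos.  An optional static head/neck protrusion exercises the
neck cut; a flat wall at 700 mm provides background.

Displacement is applied along the optical axis (no perspective
re-projection: chest excursion ≪ distance).  For bump amplitude a, the
exactly swept volume under the pinhole model is

    V(a) = a·G1 − a²·G2/d0 + a³·G3/(3·d0²),   Gk = ∬ g^k dx dy,

because the pixel footprint scales as (d/d0)² along each ray; the Gk have
closed forms via Dirichlet integrals (gamma functions).  The renderer
inverts V (dense monotone grid, 8192 points) so the prescribed volume
waveform is realized exactly in volume space.  A first-order scaling
through G1 alone was rejected: a 3 L vital capacity inside this field of
view forces ~75 mm excursions, where the linearization errs by ~10% — far
larger than the 1% the pipeline itself achieves.  Keeping the cubic makes
the oracle exact at any excursion while remaining fully analytic.

The breathing waveform is built in volume space: n sinusoidal tidal breaths
(default 3 × 3 s, 500 mL peak-to-peak, around a resting level of 30% FVC),
a 1.5 s half-cosine ramp to maximal inspiration (the peak lands exactly on
a sample), a forced expiration with exhaled volume FVC·(1 − e^(−t/τ))
sampled for 8τ, then rest at the end-expiratory level; default record 30 s
at 45 Hz, FVC 3000 mL, τ = 0.5 s, so the true FEV1 is
3000·(1 − e⁻²) ≈ 2594 mL.  Tidal periods use an even sample count so the
sampled peak-to-peak equals the prescribed tidal volume.

Sensor imperfections: optional i.i.d. Gaussian depth noise (mm) per pixel
per frame, then optional quantization to the 2 mm depth quantum.  All
randomness flows from one seed; a fixed seed reproduces the scene
bit-for-bit.

What the simulator does not emulate: two-compartment ribcage/abdomen
mechanics, clothing, posture sway, lateral motion, multi-path ToF
artifacts, or perspective distortion of the deforming surface.  Passing
recovery tests therefore demonstrates the correctness of the geometry and
integration chain, not robustness to every clinical artifact.

## Synthetic cohorts

Per group (healthy / airflow-limited), height, weight, vital capacity and
FEV1% are drawn from truncated normals matching the study-population
summaries (healthy: height 163.8 ± 10.0 cm, weight 57.0 ± 8.7 kg, VC
3.5 ± 0.9 L, FEV1% 81.5 ± 9.4; AFL: 161.8 ± 8.5 cm, 60.1 ± 14.3 kg,
2.5 ± 0.7 L, 54.9 ± 15.0).  Truncation bounds keep values physiologic at
these SDs.  Only group summaries are available, so the correlation
structure is this package's choice: FVC is correlated with height at
45 mL/cm (taller subjects have larger lungs), with the remaining spread as
an independent residual; draws whose implied anterior FVC would be
non-physical (≤200 mL) are rejected and redrawn.

The anterior-thorax FVC is obtained by inverting the calibration equation
from the (stored, rounded) covariates, plus optional Gaussian error — so at
zero noise the forward prediction reproduces the spirometer FVC to machine
precision, which the calibration-recovery and LOOCV tests exploit as an
exact oracle.  The anterior FEV1 is set so the anterior FEV1% equals the
spirometer FEV1% plus optional classification noise; at zero noise the two
groups are perfectly separable at the 70% rule by construction.

## Problem sizes and tolerances

The acceptance checks run the full-resolution configuration: 1350 frames of
224×171 px (30 s at 45 Hz), twice (noiseless and noisy/quantized), about
15 s each end to end.  Unit and property tests use a reduced sensor
(56×43 px, same optics and frame rate, 12 s records) where a full render
costs well under a second; at that pixel pitch the end-to-end recovery is
asserted at 2% rather than the 1% achieved at full resolution.  Key
tolerances: piston oracle 0.5%; noiseless FVC 1%, FEV1 2%; noisy/quantized
5%; noiseless coefficient recovery 1e-6 relative; FEV1% scaling invariance
1e-9 relative.

## Known limitations

- Per-pixel correspondence ignores lateral chest motion; gross body
  movement corrupts the curve and is not detected beyond the
  skipped-pixel warning.
- The ROI is frozen at baseline; a subject who shifts after the first
  second degrades silently.
- The FEV1% of the rescaled curve equals the anterior ratio by
  construction, so regression quality affects FVC/FEV1 in mL but not the
  screening statistic itself.
- The published calibration coefficients are population-specific; applying
  them to a different population requires refitting.
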