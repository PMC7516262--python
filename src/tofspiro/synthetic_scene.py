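"""Synthetic breathing-torso depth scenes with analytic ground truth.

The simulated subject is a superelliptic chest plate carrying a smooth bump
whose amplitude follows a prescribed breathing waveform; an optional static
head-and-neck protrusion sits above it and a flat wall behind.  Because the
bump is applied along the optical axis and its profile has closed-form
plane integrals, the volume swept by the surface between any two instants
is known exactly, giving the whole measurement pipeline an independent
oracle with no hardware involved.

For a bump of profile ``g`` and amplitude ``a`` (mm), the swept volume seen
by a pinhole sensor at base distance ``d0`` is exactly

    V(a) = a*G1 - a^2*G2/d0 + a^3*G3/(3*d0^2),   Gk = double-integral of g^k,

because the pixel footprint scales as (d/d0)^2 along each ray.  The
renderer inverts this map so that the prescribed waveform is realized in
volume space exactly, not just to first order in the excursion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
from scipy.optimize import brentq
from scipy.special import gamma

from .calibration import CalibrationModel, published_model
from .depth_io import DepthFrame, DepthSequence, SensorGeometry, SubjectRecord

__all__ = [
    "TorsoModel",
    "BreathWaveform",
    "GroundTruth",
    "make_breath_waveform",
    "render_depth_sequence",
    "generate_cohort",
]

_AMP_GRID_POINTS = 8192


def _superellipse_moment(m: int, p: int) -> float:
    """Exact ∬ (|u|^p + |v|^p)^m du dv over the region |u|^p + |v|^p <= 1.

    Binomial expansion plus the Dirichlet integral
    ∬_{u,v>=0} u^(a-1) v^(b-1) du dv = Γ(a/p)Γ(b/p) / (p² Γ((a+b)/p + 1)).
    """
    total = 0.0
    for jj in range(m + 1):
        a = p * jj + 1
        b = p * (m - jj) + 1
        total += (
            math.comb(m, jj)
            * gamma(a / p) * gamma(b / p) / (p * p * gamma((a + b) / p + 1))
        )
    return 4.0 * total  # four quadrants


@dataclass(frozen=True)
class TorsoModel:
    """Parametric anterior-thorax scene.

    The chest footprint is the superellipse |x/rx|^p + |y/ry|^p <= 1 in the
    image plane at ``base_distance`` (x lateral, y vertical, +y downward,
    both mm, origin on the optical axis); the bump profile is
    g = 1 - s^(q/p) with s the superelliptic radius to the p-th power, so g
    is 1 at the centre and 0 at the rim.  p = 4 keeps the silhouette width
    nearly constant over most of the height, as a torso's is.
    """

    rx: float = 120.0                 # lateral half-width, mm
    ry: float = 130.0                 # vertical half-height, mm
    center_y: float = 70.0            # chest centre below the optical axis, mm
    footprint_exponent: int = 4
    bump_exponent: int = 8
    base_distance: float = 350.0      # chest rim plane, mm from sensor
    background_distance: float = 700.0
    head_neck: bool = False
    head_rx: float = 55.0
    head_ry: float = 45.0
    head_center_y: float = -150.0
    head_protrusion: float = 25.0     # static, mm toward the sensor
    neck_half_width: float = 20.0
    neck_protrusion: float = 10.0

    def __post_init__(self) -> None:
        if min(self.rx, self.ry, self.base_distance) <= 0:
            raise ValueError("torso dimensions must be positive")
        if self.background_distance - self.base_distance <= 150.0:
            raise ValueError(
                "background must sit more than 150 mm behind the torso rim "
                "so the background cut applies"
            )
        if self.bump_exponent % self.footprint_exponent != 0:
            raise ValueError("bump_exponent must be a multiple of footprint_exponent")

    # -- closed-form plane integrals of the bump profile -------------------
    def profile_moments(self) -> tuple[float, float, float]:
        """(G1, G2, G3) = ∬ g^k dx dy in mm², exact.

        With r = q/p, g = 1 - s^r and ∬ s^(r k) reduces to superellipse
        moments, e.g. G1 = rx*ry*(M0 - Mr) with Mm = ∬ s^m du dv.
        """
        p = self.footprint_exponent
        r = self.bump_exponent // p
        M = {m: _superellipse_moment(m, p) for m in range(0, 3 * r + 1, r)}
        M[0] = _superellipse_moment(0, p)
        g1 = M[0] - M[r]
        g2 = M[0] - 2 * M[r] + M[2 * r]
        g3 = M[0] - 3 * M[r] + 3 * M[2 * r] - M[3 * r]
        scale = self.rx * self.ry
        return g1 * scale, g2 * scale, g3 * scale

    def swept_volume_mm3(self, amplitude_mm: float | np.ndarray) -> float | np.ndarray:
        """Exact volume (mm³) swept between bump amplitude 0 and ``a``."""
        g1, g2, g3 = self.profile_moments()
        a = np.asarray(amplitude_mm, dtype=float)
        d0 = self.base_distance
        v = a * g1 - a**2 * g2 / d0 + a**3 * g3 / (3 * d0 * d0)
        return float(v) if v.ndim == 0 else v

    def amplitude_for_volume(self, volume_mm3: float) -> float:
        """Invert the swept-volume map: amplitude (mm) realizing a volume."""
        if volume_mm3 == 0:
            return 0.0
        hi = self.base_distance * 0.9
        if self.swept_volume_mm3(hi) < volume_mm3:
            raise ValueError("requested volume exceeds what the torso can sweep")
        return float(brentq(
            lambda a: self.swept_volume_mm3(a) - volume_mm3, 0.0, hi, xtol=1e-10
        ))


@dataclass
class BreathWaveform:
    """Normalized breathing waveform a(t) in [0, 1] (fraction of FVC in
    volume space; 0 = full expiration, 1 = maximal inspiration)."""

    samples: np.ndarray
    frame_rate_hz: float
    segments: dict[str, tuple[int, int]]
    tidal_volume: float
    fvc: float
    tau: float
    n_tidal: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if np.any(self.samples < -1e-12) or np.any(self.samples > 1 + 1e-12):
            raise ValueError("waveform samples must lie in [0, 1]")

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.frame_rate_hz

    def volume_ml(self) -> np.ndarray:
        """Prescribed lung-volume trajectory above full expiration, mL."""
        return self.samples * self.fvc


@dataclass(frozen=True)
class GroundTruth:
    """Analytic truth for a rendered scene: the exact volume trajectory and
    the spirometric indices it implies."""

    volume_true: np.ndarray       # mL, zero-referenced at the first sample
    fvc_true: float
    fev1_true: float

    def __post_init__(self) -> None:
        if self.fev1_true > self.fvc_true + 1e-9:
            raise ValueError("true FEV1 cannot exceed true FVC")


def make_breath_waveform(
    tidal_volume: float = 500.0,
    fvc: float = 3000.0,
    tau: float = 0.5,
    n_tidal: int = 3,
    frame_rate: float = 45.0,
    duration_s: float = 30.0,
    tidal_period_s: float = 3.0,
    inspiration_s: float = 1.5,
    resting_level: float = 0.3,
    seed: int | None = None,
) -> tuple[BreathWaveform, GroundTruth]:
    """Tidal breathing, maximal inspiration, then forced expiration.

    ``n_tidal`` sinusoidal breaths of peak-to-peak ``tidal_volume`` around a
    resting level (default 30% of FVC above full expiration), a half-cosine
    ramp to maximal inspiration, then the forced expiration
    ``V_exhaled(t) = fvc*(1 - exp(-t/tau))`` sampled for 8*tau, then rest at
    the end-expiratory level.  Ground-truth FEV1 is ``fvc*(1 - exp(-1/tau))``.

    ``seed`` is accepted for interface uniformity; the waveform itself is
    deterministic.
    """
    if not fvc > tidal_volume > 0:
        raise ValueError("need fvc > tidal_volume > 0")
    if tau <= 0 or frame_rate <= 0 or n_tidal < 0:
        raise ValueError("tau and frame_rate must be positive, n_tidal >= 0")
    v0 = resting_level * fvc
    if v0 + tidal_volume >= fvc:
        raise ValueError("tidal range must stay below maximal inspiration")

    n_total = round(duration_s * frame_rate)
    # an even number of samples per period puts the tidal extremes exactly
    # on samples, so the sampled peak-to-peak equals the prescribed volume
    n_period = 2 * max(1, round(tidal_period_s * frame_rate / 2))
    n_tidal_seg = n_tidal * n_period
    n_ramp = max(2, round(inspiration_s * frame_rate))
    n_exh = max(2, round(8 * tau * frame_rate))
    n_core = n_tidal_seg + n_ramp + n_exh
    if n_core + round(frame_rate) > n_total:
        raise ValueError("duration too short for the requested maneuver")

    v = np.empty(n_total)
    k = np.arange(n_tidal_seg)
    v[:n_tidal_seg] = v0 + 0.5 * tidal_volume * (1 - np.cos(2 * np.pi * k / n_period))
    m = np.arange(1, n_ramp + 1)
    v[n_tidal_seg:n_tidal_seg + n_ramp] = (
        v0 + (fvc - v0) * 0.5 * (1 - np.cos(np.pi * m / n_ramp))
    )
    peak = n_tidal_seg + n_ramp - 1          # single sample exactly at fvc
    m = np.arange(1, n_exh + 1)
    v[peak + 1 : peak + 1 + n_exh] = fvc * np.exp(-m / (frame_rate * tau))
    v[peak + 1 + n_exh :] = v[peak + n_exh]

    segments = {
        "tidal": (0, n_tidal_seg),
        "max_inspiration": (n_tidal_seg, peak + 1),
        "forced_expiration": (peak + 1, peak + 1 + n_exh),
        "rest": (peak + 1 + n_exh, n_total),
    }
    waveform = BreathWaveform(
        samples=v / fvc,
        frame_rate_hz=frame_rate,
        segments=segments,
        tidal_volume=tidal_volume,
        fvc=fvc,
        tau=tau,
        n_tidal=n_tidal,
    )
    truth = GroundTruth(
        volume_true=v - v[0],
        fvc_true=float(v.max() - v.min()),
        fev1_true=fvc * (1.0 - math.exp(-1.0 / tau)),
    )
    return waveform, truth


def _pixel_plane_coords(
    geometry: SensorGeometry, distance: float
) -> tuple[np.ndarray, np.ndarray]:
    """(y, x) mm coordinates of pixel centres on a plane at ``distance``."""
    pv, ph = geometry.pixel_pitch_mm(distance)
    rows = (np.arange(geometry.n_rows) - (geometry.n_rows - 1) / 2.0) * pv
    cols = (np.arange(geometry.n_cols) - (geometry.n_cols - 1) / 2.0) * ph
    return rows[:, None], cols[None, :]


def render_depth_sequence(
    torso: TorsoModel,
    waveform: BreathWaveform,
    geometry: SensorGeometry | None = None,
    noise_sd: float = 0.0,
    quantize: bool = False,
    seed: int = 0,
) -> DepthSequence:
    """Render the breathing torso into a depth sequence.

    Inside the chest footprint the surface sits at
    ``base_distance - a(t)*g(x, y)`` with the amplitude trajectory chosen so
    the exact swept volume follows the waveform's prescribed volumes;
    inhalation moves the surface toward the sensor.  Outside the subject the
    flat background wall is visible.  Optional i.i.d. Gaussian depth noise
    (``noise_sd`` mm) is added before optional quantization to the sensor's
    depth quantum.  Fixing ``seed`` makes the output bit-identical.
    """
    geometry = geometry or SensorGeometry()
    d0 = torso.base_distance
    y, x = _pixel_plane_coords(geometry, d0)
    half_h = abs(y[0, 0])
    half_w = abs(x[0, -1])
    if torso.rx > half_w or abs(torso.center_y) + torso.ry > half_h:
        raise ValueError("torso footprint exceeds the field of view")

    p = torso.footprint_exponent
    s = (np.abs(x) / torso.rx) ** p + (np.abs(y - torso.center_y) / torso.ry) ** p
    inside = s < 1.0
    g = np.where(inside, 1.0 - np.clip(s, 0.0, 1.0) ** (torso.bump_exponent / p), 0.0)

    # amplitude trajectory realizing the prescribed volumes exactly
    vol_mm3 = waveform.volume_ml() * 1000.0
    a_max = torso.amplitude_for_volume(float(vol_mm3.max()))
    grid_a = np.linspace(0.0, a_max, _AMP_GRID_POINTS)
    grid_v = torso.swept_volume_mm3(grid_a)
    amplitude = np.interp(vol_mm3, grid_v, grid_a)
    if a_max >= d0:
        raise ValueError("bump excursion reaches the sensor; depth would go negative")

    static = np.full(geometry.shape, torso.background_distance)
    if torso.head_neck:
        sh = (
            (np.abs(x) / torso.head_rx) ** 2
            + (np.abs(y - torso.head_center_y) / torso.head_ry) ** 2
        )
        head = sh < 1.0
        static = np.where(
            head, d0 - torso.head_protrusion * (1.0 - sh), static
        )
        chest_top = torso.center_y - torso.ry
        neck = (
            (np.abs(x) <= torso.neck_half_width)
            & (y >= torso.head_center_y)
            & (y <= chest_top + 5.0)
        )
        static = np.where(neck, np.minimum(static, d0 - torso.neck_protrusion), static)

    rng = np.random.default_rng(seed)
    frames = []
    dt = 1.0 / waveform.frame_rate_hz
    for k, a in enumerate(amplitude):
        chest = d0 - a * g
        depth = np.where(inside, np.minimum(chest, static), static)
        if noise_sd > 0:
            depth = depth + rng.normal(0.0, noise_sd, size=depth.shape)
        if quantize:
            q = geometry.depth_quantum_mm
            depth = np.round(depth / q) * q
        if np.any(depth <= 0):
            raise ValueError("rendered depth is non-positive")
        frames.append(DepthFrame(depth=depth, timestamp=k * dt))
    return DepthSequence(frames=frames, geometry=geometry)


# ---------------------------------------------------------------------------
# cohort generation

_GROUP_STATS = {
    # mean/sd from the study population summaries: height cm, weight kg,
    # vital capacity mL, FEV1% of FVC
    "healthy": {"height": (163.8, 10.0), "weight": (57.0, 8.7),
                "fvc": (3500.0, 900.0), "fev1_pct": (81.5, 9.4)},
    "AFL": {"height": (161.8, 8.5), "weight": (60.1, 14.3),
            "fvc": (2500.0, 700.0), "fev1_pct": (54.9, 15.0)},
}
# share of the FVC spread attributed to stature (taller subjects have
# larger lungs); the remainder is an independent residual
_FVC_HEIGHT_SLOPE = 45.0  # mL per cm


def _truncated_normal(rng, mean, sd, low, high):
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if low < x < high:
            return x
    raise RuntimeError("truncated-normal rejection loop failed")


def generate_cohort(
    n_healthy: int,
    n_afl: int,
    model: CalibrationModel | None = None,
    noise_fvc_anterior: float = 0.0,
    classification_noise_pct: float = 0.0,
    seed: int = 0,
) -> list[SubjectRecord]:
    """Draw a synthetic cohort with anterior-thorax indices.

    Anthropometrics and spirometry are sampled per group from truncated
    normals matching the study-population summaries; the anterior-thorax FVC
    is obtained by inverting the calibration regression (plus optional
    Gaussian error, ``noise_fvc_anterior`` mL), so with zero noise the
    forward prediction reproduces the spirometer FVC exactly.  The anterior
    FEV1 is set so the anterior FEV1% equals the spirometer FEV1% plus
    optional classification noise (``classification_noise_pct`` points).
    """
    if n_healthy < 0 or n_afl < 0:
        raise ValueError("cohort counts must be non-negative")
    model = model or published_model()
    if model.a == 0:
        raise ValueError("degenerate calibration model: a = 0")
    rng = np.random.default_rng(seed)

    records: list[SubjectRecord] = []
    plan = [("healthy", n_healthy, "h"), ("AFL", n_afl, "a")]
    for group, count, prefix in plan:
        stats = _GROUP_STATS[group]
        made = 0
        while made < count:
            height = _truncated_normal(rng, *stats["height"], 135.0, 205.0)
            weight = _truncated_normal(rng, *stats["weight"], 33.0, 130.0)
            bmi = float(np.clip(weight / (height / 100.0) ** 2, 12.0, 55.0))
            fvc_mean = stats["fvc"][0] + _FVC_HEIGHT_SLOPE * (
                height - stats["height"][0]
            )
            resid_sd = math.sqrt(
                max(stats["fvc"][1] ** 2 - (_FVC_HEIGHT_SLOPE * stats["height"][1]) ** 2,
                    200.0**2)
            )
            fvc_spiro = _truncated_normal(rng, fvc_mean, resid_sd, 800.0, 7500.0)
            fev1_pct = _truncated_normal(rng, *stats["fev1_pct"], 10.0, 100.0)

            # round the stored covariates first, then invert the regression
            # from the rounded values, so the noiseless forward prediction
            # reproduces the stored spirometer FVC to machine precision
            height = round(height, 2)
            bmi = round(bmi, 3)
            fvc_spiro = round(fvc_spiro, 2)
            fev1_spiro = round(fev1_pct * fvc_spiro / 100.0, 2)

            fvc_anterior = (
                fvc_spiro - model.b * height - model.c * bmi - model.d
            ) / model.a
            if noise_fvc_anterior > 0:
                fvc_anterior += rng.normal(0.0, noise_fvc_anterior)
            if fvc_anterior <= 200.0:
                continue  # redraw physically impossible combinations
            pct_anterior = 100.0 * fev1_spiro / fvc_spiro
            if classification_noise_pct > 0:
                pct_anterior = float(np.clip(
                    pct_anterior + rng.normal(0.0, classification_noise_pct),
                    5.0, 100.0,
                ))
            fev1_anterior = fvc_anterior * pct_anterior / 100.0

            made += 1
            records.append(SubjectRecord(
                subject_id=f"{prefix}{made:03d}",
                height=height,
                bmi=bmi,
                fvc_spirometer=fvc_spiro,
                fev1_spirometer=fev1_spiro,
                group=group,
                fvc_anterior=round(fvc_anterior, 6),
                fev1_anterior=round(fev1_anterior, 6),
            ))
    return records
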