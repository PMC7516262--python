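"""Anterior-thorax volume curve from a depth sequence.

The chest surface visible to the sensor sweeps a volume as it moves.  Each
pixel's footprint on a surface at distance ``d`` is

    S(d) = (2 d tan(FOVv/2) / n_rows) * (2 d tan(FOVh/2) / n_cols)   [mm²]

so a per-pixel distance change ΔZ contributes S·ΔZ of swept volume.  Summing
over the region of interest and accumulating over frames yields the volume
curve; motion toward the sensor (inspiration) counts positive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .depth_io import DepthFrame, DepthSequence, SensorGeometry
from .thorax_roi import RoiMask

__all__ = [
    "VolumeCurve",
    "pixel_area",
    "smooth_frame",
    "volume_curve",
    "anterior_fvc",
    "scale_curve",
    "GAUSSIAN_SIGMA_PX",
    "GAUSSIAN_KERNEL_SIZE",
]

# 7x7 spatial kernel; sigma chosen so the support holds >99% of the mass.
GAUSSIAN_KERNEL_SIZE = 7
GAUSSIAN_SIGMA_PX = 1.5
_TRUNCATE = (GAUSSIAN_KERNEL_SIZE // 2) / GAUSSIAN_SIGMA_PX  # radius 3 -> 7 taps


@dataclass
class VolumeCurve:
    """Sampled volume-vs-time signal in mL, zero-referenced at sample 0."""

    time: np.ndarray
    volume: np.ndarray
    kind: str = "anterior_thorax"  # or "eafl_scaled"
    frame_rate_hz: float = 45.0
    skipped_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        if self.time.shape != self.volume.shape or self.time.ndim != 1:
            raise ValueError("time and volume must be 1-D arrays of equal length")
        if self.time.size and not np.all(np.isfinite(self.volume)):
            raise ValueError("volume curve contains non-finite samples")

    def __len__(self) -> int:
        return self.time.size


def pixel_area(
    d: float | np.ndarray,
    i: int | np.ndarray | None = None,
    j: int | np.ndarray | None = None,
    geometry: SensorGeometry | None = None,
) -> float | np.ndarray:
    """Pixel footprint area (mm²) on a surface at distance ``d`` mm.

    Under the pinhole-uniform model the area depends only on distance, not on
    the pixel position (i, j); the indices are accepted for interface
    symmetry.  Scales quadratically: ``pixel_area(2d) == 4*pixel_area(d)``.
    """
    geometry = geometry or SensorGeometry()
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("distance must be positive")
    tv = math.tan(math.radians(geometry.fov_vertical_deg) / 2)
    th = math.tan(math.radians(geometry.fov_horizontal_deg) / 2)
    area = (2.0 * d * tv / geometry.n_rows) * (2.0 * d * th / geometry.n_cols)
    return float(area) if area.ndim == 0 else area


def _masked_gaussian(depth: np.ndarray, validity: np.ndarray) -> np.ndarray:
    """7x7 Gaussian smoothing with invalid pixels excluded and weights
    renormalized; reflect padding at the borders."""
    if validity.all():
        return ndimage.gaussian_filter(
            depth, sigma=GAUSSIAN_SIGMA_PX, truncate=_TRUNCATE, mode="reflect"
        )
    v = validity.astype(float)
    num = ndimage.gaussian_filter(
        np.where(validity, depth, 0.0), sigma=GAUSSIAN_SIGMA_PX,
        truncate=_TRUNCATE, mode="reflect",
    )
    den = ndimage.gaussian_filter(
        v, sigma=GAUSSIAN_SIGMA_PX, truncate=_TRUNCATE, mode="reflect"
    )
    out = np.zeros_like(depth)
    np.divide(num, den, out=out, where=den > 0)
    return out


def smooth_frame(frame: DepthFrame) -> DepthFrame:
    """Apply the 7x7 spatial Gaussian (sigma 1.5 px) to one frame.

    Invalid pixels are dropped from the weighted sum and the remaining
    weights renormalized, so valid depths never bleed into the sentinel.
    """
    smoothed = _masked_gaussian(frame.depth, frame.validity)
    return DepthFrame(
        depth=np.where(frame.validity, smoothed, 0.0),
        timestamp=frame.timestamp,
        validity=frame.validity.copy(),
    )


def volume_curve(
    seq: DepthSequence,
    roi: RoiMask | np.ndarray,
    smooth: bool = True,
) -> VolumeCurve:
    """Integrate per-pixel swept volume over the ROI into a volume curve.

    For each consecutive frame pair and ROI pixel the contribution is
    ``S(d̄) * (d_prev − d_curr)`` with the area evaluated at the midpoint
    distance d̄; decreasing distance (chest approaching the sensor) is
    inspiration and increases volume.  Output in mL, zero at the first
    sample.  ROI pixels invalid in either frame of a pair are skipped; if
    more than 20% of pixel-steps are skipped a warning is issued and the
    fraction recorded on the curve.

    The spatial Gaussian is applied within the ROI (pixels outside it are
    excluded and the kernel renormalized, exactly as for invalid pixels):
    depths beyond the chest silhouette belong to the background and would
    otherwise bleed into the rim, biasing the pixel-area weights.
    """
    mask = roi.mask if isinstance(roi, RoiMask) else np.asarray(roi, dtype=bool)
    if len(seq) < 2:
        raise ValueError("need at least 2 frames to integrate volume")
    if mask.shape != seq.geometry.shape:
        raise ValueError("ROI shape does not match sensor geometry")
    if not mask.any():
        raise ValueError("ROI is empty")

    geometry = seq.geometry
    tv = math.tan(math.radians(geometry.fov_vertical_deg) / 2)
    th = math.tan(math.radians(geometry.fov_horizontal_deg) / 2)
    area_coeff = 4.0 * tv * th / (geometry.n_rows * geometry.n_cols)

    n_roi = int(mask.sum())
    increments = np.empty(len(seq) - 1)
    skipped = 0

    def roi_depth(frame: DepthFrame) -> np.ndarray:
        if not smooth:
            return frame.depth[mask]
        return _masked_gaussian(frame.depth, frame.validity & mask)[mask]

    prev = seq[0]
    prev_depth = roi_depth(prev)
    prev_valid = prev.validity[mask]
    for k in range(1, len(seq)):
        curr = seq[k]
        curr_depth = roi_depth(curr)
        curr_valid = curr.validity[mask]
        ok = prev_valid & curr_valid
        skipped += n_roi - int(ok.sum())
        dz = prev_depth[ok] - curr_depth[ok]          # + toward sensor
        dbar = 0.5 * (prev_depth[ok] + curr_depth[ok])
        increments[k - 1] = np.sum(area_coeff * dbar * dbar * dz)
        prev_depth, prev_valid = curr_depth, curr_valid

    skipped_fraction = skipped / (n_roi * (len(seq) - 1))
    if skipped_fraction > 0.20:
        warnings.warn(
            f"{skipped_fraction:.0%} of ROI pixel-steps skipped as invalid; "
            "the volume curve may be unreliable",
            stacklevel=2,
        )
    volume_ml = np.concatenate([[0.0], np.cumsum(increments)]) / 1000.0
    return VolumeCurve(
        time=seq.timestamps - seq[0].timestamp,
        volume=volume_ml,
        kind="anterior_thorax",
        frame_rate_hz=geometry.frame_rate_hz,
        skipped_fraction=skipped_fraction,
    )


def anterior_fvc(curve: VolumeCurve, use_maneuver_window: bool = True) -> float:
    """Peak-to-peak amplitude (mL) of the volume curve.

    By default the amplitude is taken over the detected forced-maneuver
    window so tidal breaths never inflate it; pass
    ``use_maneuver_window=False`` to use the whole record.  Falls back to the
    whole record when no maneuver is detectable.
    """
    if len(curve) == 0:
        raise ValueError("empty volume curve")
    if use_maneuver_window:
        from .spiro_indices import detect_forced_maneuver
        from .errors import ManeuverError

        try:
            m = detect_forced_maneuver(curve)
        except ManeuverError:
            pass
        else:
            window = curve.volume[m.peak_inspiration_index : m.exhalation_end_index + 1]
            return float(window.max() - window.min())
    return float(curve.volume.max() - curve.volume.min())


def scale_curve(curve: VolumeCurve, fvc_predicted: float) -> VolumeCurve:
    """Rescale the anterior-thorax curve to the regression-predicted FVC.

    Multiplies every sample by ``fvc_predicted / anterior_fvc(curve)``; the
    time axis is untouched, so ratios such as FEV1% are invariant.
    """
    ref = anterior_fvc(curve)
    if ref <= 0:
        raise ValueError("anterior FVC must be positive to rescale")
    return VolumeCurve(
        time=curve.time.copy(),
        volume=curve.volume * (fvc_predicted / ref),
        kind="eafl_scaled",
        frame_rate_hz=curve.frame_rate_hz,
        skipped_fraction=curve.skipped_fraction,
    )
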