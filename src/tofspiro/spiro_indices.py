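"""Forced-maneuver detection and spirometric indices on a volume curve.

FVC is the peak-to-peak amplitude over the forced maneuver; FEV1 is the
expired volume one second after the back-extrapolated time zero, the
standard convention locating the start of forced expiration at the
intersection of the steepest-slope tangent of the expired-volume curve with
zero expired volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ManeuverError
from .volumetry import VolumeCurve

__all__ = [
    "ForcedManeuver",
    "RespiratoryIndices",
    "detect_forced_maneuver",
    "back_extrapolate_time_zero",
    "compute_indices",
    "analyze_curve",
]

# samples of temporal Gaussian used only for slope estimation; keeps the
# max-slope search robust to depth-quantization ripple
SLOPE_SMOOTH_SIGMA = 1.0
_EDGE_GUARD_S = 0.5        # peak this close to either end = truncated maneuver
_EXHALE_WINDOW_S = 3.0     # search window for end of exhalation after the peak


@dataclass(frozen=True)
class ForcedManeuver:
    """Sample indices bracketing the forced expiration on a volume curve."""

    peak_inspiration_index: int
    exhalation_end_index: int

    def __post_init__(self) -> None:
        if self.peak_inspiration_index >= self.exhalation_end_index:
            raise ValueError("peak must precede end of exhalation")


@dataclass(frozen=True)
class RespiratoryIndices:
    """FVC, FEV1 (mL) and their ratio FEV1% = 100*FEV1/FVC."""

    fvc: float
    fev1: float
    fev1_percent: float
    time_zero_s: float

    def __post_init__(self) -> None:
        if not 0 < self.fev1 <= self.fvc:
            raise ValueError("need 0 < FEV1 <= FVC")


def detect_forced_maneuver(curve: VolumeCurve) -> ForcedManeuver:
    """Locate the forced expiration: global volume maximum, then the minimum
    over the following 3 s (or to the curve end).

    Raises :class:`ManeuverError` when the curve is shorter than 3 s or the
    peak sits within 0.5 s of either end (truncated maneuver).
    """
    if len(curve) < 2 or curve.time[-1] - curve.time[0] < 3.0:
        raise ManeuverError("volume curve shorter than 3 s")
    peak = int(np.argmax(curve.volume))
    t_peak = curve.time[peak]
    if t_peak - curve.time[0] < _EDGE_GUARD_S or curve.time[-1] - t_peak < _EDGE_GUARD_S:
        raise ManeuverError(
            "inspiratory peak within 0.5 s of the record edge; maneuver truncated"
        )
    in_window = np.flatnonzero(
        (curve.time > t_peak) & (curve.time <= t_peak + _EXHALE_WINDOW_S)
    )
    end = int(in_window[np.argmin(curve.volume[in_window])])
    return ForcedManeuver(peak_inspiration_index=peak, exhalation_end_index=end)


def _expired_volume(curve: VolumeCurve, maneuver: ForcedManeuver) -> tuple[np.ndarray, np.ndarray]:
    """(t, E) from the inspiratory peak to the curve end; E(t) is volume
    expired since the peak, estimated on a lightly smoothed curve."""
    v = ndimage.gaussian_filter1d(curve.volume, sigma=SLOPE_SMOOTH_SIGMA, mode="nearest")
    p = maneuver.peak_inspiration_index
    return curve.time[p:], v[p] - v[p:]


def back_extrapolate_time_zero(curve: VolumeCurve, maneuver: ForcedManeuver) -> float:
    """Back-extrapolated start of forced expiration, in seconds.

    Finds the maximum expiratory slope dE/dt by central differences on the
    smoothed expired-volume curve (ties broken by earliest time) and
    intersects that tangent with E = 0.
    """
    t, e = _expired_volume(curve, maneuver)
    if len(t) < 3:
        raise ManeuverError("too few samples after the peak")
    slope = np.gradient(e, t)  # central differences, one-sided at the ends
    k = int(np.argmax(slope))
    if slope[k] <= 0:
        raise ManeuverError("expired-volume curve is flat; no expiration found")
    t0 = t[k] - e[k] / slope[k]
    return float(max(t0, t[0]))


def compute_indices(curve: VolumeCurve, maneuver: ForcedManeuver) -> RespiratoryIndices:
    """FVC, FEV1 and FEV1% for a detected forced maneuver.

    FVC is max − min of the volume over the maneuver window; FEV1 is the
    expired volume at time_zero + 1 s with linear interpolation between
    samples.  Raises when the record ends before time_zero + 1 s.
    """
    t0 = back_extrapolate_time_zero(curve, maneuver)
    if t0 + 1.0 > curve.time[-1] + 1e-9:
        raise ManeuverError("curve ends before time_zero + 1 s; FEV1 undefined")
    window = curve.volume[
        maneuver.peak_inspiration_index : maneuver.exhalation_end_index + 1
    ]
    fvc = float(window.max() - window.min())
    p = maneuver.peak_inspiration_index
    t_exp = curve.time[p:]
    e_exp = curve.volume[p] - curve.volume[p:]
    fev1 = float(np.interp(t0 + 1.0, t_exp, e_exp))
    # expired volume cannot exceed the maneuver amplitude
    fev1 = min(fev1, fvc)
    return RespiratoryIndices(
        fvc=fvc, fev1=fev1, fev1_percent=100.0 * fev1 / fvc, time_zero_s=t0
    )


def analyze_curve(curve: VolumeCurve) -> RespiratoryIndices:
    """Detect the forced maneuver and compute the indices in one step."""
    return compute_indices(curve, detect_forced_maneuver(curve))
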