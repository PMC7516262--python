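"""Anterior-thorax region-of-interest extraction.

Background removal keeps only points within 15 cm of the seating distance;
the chest bounding box is the largest connected foreground blob with the
head and neck cut off where the silhouette narrows.  The ROI is computed
once from a baseline frame (median of the first second) and held fixed for
the whole sequence, so the swept-volume integral sees a constant indicator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .depth_io import DepthFrame, DepthSequence
from .errors import RoiError, SubjectAbsentError

__all__ = [
    "RoiMask",
    "ChestBox",
    "background_mask",
    "chest_bounding_box",
    "extract_roi",
    "check_position",
    "BACKGROUND_CUTOFF_MM",
    "NECK_WIDTH_FRACTION",
    "MIN_COMPONENT_PIXELS",
]

BACKGROUND_CUTOFF_MM = 150.0   # "more than 15 cm away" is background
NECK_WIDTH_FRACTION = 0.6      # silhouette narrower than this is neck/head
MIN_COMPONENT_PIXELS = 100     # smaller blobs cannot be a thorax


@dataclass
class RoiMask:
    """Fixed per-pixel indicator of the anterior-thorax region."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2-D")
        if not self.mask.any():
            raise RoiError("ROI mask has no pixels")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class ChestBox:
    """Inclusive pixel bounds of the chest region."""

    row_min: int
    row_max: int
    col_min: int
    col_max: int

    def __post_init__(self) -> None:
        if self.row_min > self.row_max or self.col_min > self.col_max:
            raise ValueError("degenerate chest box")
        if min(self.row_min, self.col_min) < 0:
            raise ValueError("chest box outside frame")

    def to_dict(self) -> dict:
        return {
            "row_min": self.row_min,
            "row_max": self.row_max,
            "col_min": self.col_min,
            "col_max": self.col_max,
        }

    def contains_mask(self, shape: tuple[int, int]) -> np.ndarray:
        box = np.zeros(shape, dtype=bool)
        box[self.row_min : self.row_max + 1, self.col_min : self.col_max + 1] = True
        return box


def background_mask(
    frame: DepthFrame,
    reference_distance: float,
    cutoff: float = BACKGROUND_CUTOFF_MM,
) -> np.ndarray:
    """Foreground indicator: valid and strictly closer than reference+cutoff.

    Raises :class:`SubjectAbsentError` when nothing survives the cut.
    """
    if reference_distance <= 0:
        raise ValueError("reference distance must be positive")
    fg = frame.validity & (frame.depth < reference_distance + cutoff)
    if not fg.any():
        raise SubjectAbsentError(
            f"no foreground within {cutoff:.0f} mm of the "
            f"{reference_distance:.0f} mm seating distance"
        )
    return fg


def _row_widths(component: np.ndarray) -> np.ndarray:
    return component.sum(axis=1)


def chest_bounding_box(
    foreground: np.ndarray,
    neck_fraction: float = NECK_WIDTH_FRACTION,
) -> ChestBox:
    """Bound the chest: largest 4-connected blob, neck and head trimmed.

    Scanning upward (toward row 0) from the blob's widest row, the first row
    whose silhouette width drops below 60% of the maximum marks the neck
    line; the box starts one row below it.  Blobs under 100 pixels are
    rejected as too small to be a thorax.
    """
    foreground = np.asarray(foreground, dtype=bool)
    if not foreground.any():
        raise RoiError("no foreground pixels")
    labels, n = ndimage.label(foreground)  # default structure = 4-connected
    sizes = ndimage.sum_labels(foreground, labels, index=np.arange(1, n + 1))
    component = labels == (int(np.argmax(sizes)) + 1)
    if sizes.max() < MIN_COMPONENT_PIXELS:
        raise RoiError(
            f"largest component has {int(sizes.max())} px "
            f"(< {MIN_COMPONENT_PIXELS}); too small to be a thorax"
        )

    rows = np.flatnonzero(component.any(axis=1))
    cols = np.flatnonzero(component.any(axis=0))
    row_min, row_max = int(rows[0]), int(rows[-1])

    widths = _row_widths(component)
    widest = int(np.argmax(widths))
    threshold = neck_fraction * widths[widest]
    for r in range(widest, row_min - 1, -1):
        if widths[r] < threshold:
            row_min = r + 1
            break
    return ChestBox(row_min=row_min, row_max=row_max,
                    col_min=int(cols[0]), col_max=int(cols[-1]))


def baseline_frame(seq: DepthSequence) -> DepthFrame:
    """Per-pixel median of the first second of frames.

    A pixel is valid in the baseline when valid in at least half of those
    frames; its depth is the median over its valid samples.
    """
    if len(seq) == 0:
        raise RoiError("empty sequence")
    n = min(len(seq), max(1, round(seq.geometry.frame_rate_hz)))
    depth = np.stack([seq[k].depth for k in range(n)])
    valid = np.stack([seq[k].validity for k in range(n)])
    validity = valid.sum(axis=0) >= (n + 1) // 2
    with np.errstate(invalid="ignore"):
        med = np.nanmedian(np.where(valid, depth, np.nan), axis=0)
    return DepthFrame(
        depth=np.where(validity & np.isfinite(med), med, 0.0),
        timestamp=seq[0].timestamp,
        validity=validity & np.isfinite(med),
    )


def extract_roi(
    seq: DepthSequence,
    reference_distance: float | None = None,
    cutoff: float = BACKGROUND_CUTOFF_MM,
    neck_fraction: float = NECK_WIDTH_FRACTION,
) -> tuple[RoiMask, ChestBox]:
    """Extract the fixed anterior-thorax ROI from a sequence.

    The baseline frame is the median of the first second; the ROI is its
    foreground intersected with the chest bounding box.  The reference
    distance defaults to the sensor's nominal seating distance.
    """
    base = baseline_frame(seq)
    if reference_distance is None:
        reference_distance = seq.geometry.nominal_distance_mm
    fg = background_mask(base, reference_distance, cutoff)
    box = chest_bounding_box(fg, neck_fraction)
    mask = fg & box.contains_mask(fg.shape)
    return RoiMask(mask=mask), box


def check_position(
    seq: DepthSequence,
    tolerance: float = 50.0,
) -> tuple[bool, float]:
    """Verify the subject sits at the nominal distance.

    Returns ``(ok, median_distance_mm)`` where ``ok`` is True when the
    median ROI depth of the baseline frame lies within
    ``nominal_distance ± tolerance``.  Never raises for an out-of-range or
    absent subject: that is reported as ``(False, nan)``.
    """
    try:
        roi, _ = extract_roi(seq)
    except (SubjectAbsentError, RoiError):
        return False, float("nan")
    base = baseline_frame(seq)
    sel = roi.mask & base.validity
    median = float(np.median(base.depth[sel]))
    nominal = seq.geometry.nominal_distance_mm
    return abs(median - nominal) <= tolerance, median
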