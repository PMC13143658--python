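"""Gray-histogram segmentation of the cardiac region of interest.

The segmenter thresholds the image at the *least max value* (LMV): the
smallest gray level that is a dominant local maximum of the 256-bin intensity
histogram.  Pixels darker than the LMV form the region-of-interest cluster C1
(cardiac structures are imaged dark on a brighter background here); the rest
form the background cluster C2.  An optional post-processing step keeps only
the largest 4-connected RoI component, demoting isolated dark specks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InvalidInputError

__all__ = ["SegmentationResult", "gray_histogram", "least_max_value", "segment_image", "segment"]


@dataclass
class SegmentationResult:
    """Per-pixel RoI labels plus the threshold that produced them."""

    labels: np.ndarray  # bool, True = RoI (cluster C1)
    lmv: int
    roi_pixel_count: int = field(default=0)

    def __post_init__(self):
        self.roi_pixel_count = int(np.count_nonzero(self.labels))


def gray_histogram(img: np.ndarray) -> np.ndarray:
    """256-bin intensity histogram; bin g counts pixels equal to g."""
    arr = np.asarray(img)
    if arr.ndim != 2 or arr.size == 0:
        raise InvalidInputError("expected a non-empty 2-D grayscale image")
    if arr.min() < 0 or arr.max() > 255:
        raise InvalidInputError("image intensities must lie in [0, 255]")
    return np.bincount(arr.ravel().astype(np.int64), minlength=256)[:256]


def least_max_value(
    hist: np.ndarray,
    count_thresh: int = 20,
    value_floor: int = 220,
    require_above_floor: bool = False,
) -> int:
    """Smallest dominant local maximum of the gray histogram.

    A gray level g qualifies when ``hist[g] >= hist[g-1]`` and
    ``hist[g] >= hist[g+1]`` (edges compared one-sided) and
    ``hist[g] > count_thresh``.  When no level qualifies, ``value_floor`` is
    returned as a fallback threshold.  ``require_above_floor`` additionally
    restricts candidates to gray levels above ``value_floor`` (the literal
    reading of the printed pseudocode, off by default).
    """
    h = np.asarray(hist, dtype=np.int64)
    if h.ndim != 1 or h.size != 256:
        raise InvalidInputError("histogram must have 256 bins")
    if h.sum() == 0:
        raise InvalidInputError("histogram is empty (all-zero counts)")

    left = np.empty(256, dtype=np.int64)
    right = np.empty(256, dtype=np.int64)
    left[0], left[1:] = -1, h[:-1]
    right[-1], right[:-1] = -1, h[1:]
    is_max = (h >= left) & (h >= right) & (h > count_thresh)
    if require_above_floor:
        is_max &= np.arange(256) > value_floor
    candidates = np.nonzero(is_max)[0]
    return int(candidates[0]) if candidates.size else int(value_floor)


def segment_image(img: np.ndarray, lmv: int, keep_largest: bool = True) -> SegmentationResult:
    """Split pixels into RoI (value < lmv) and background clusters.

    With ``keep_largest`` the RoI is reduced to its largest 4-connected
    component; demoted pixels rejoin the background.
    """
    arr = np.asarray(img)
    if not 0 <= lmv <= 255:
        raise InvalidInputError(f"lmv must lie in [0, 255], got {lmv}")
    if lmv == 0:
        warnings.warn("degenerate threshold lmv=0: result contains no RoI pixels")
    roi = arr < lmv
    if keep_largest and roi.any():
        labelled, n = ndimage.label(roi)  # default structure = 4-connectivity
        if n > 1:
            sizes = ndimage.sum_labels(roi, labelled, index=np.arange(1, n + 1))
            roi = labelled == (int(np.argmax(sizes)) + 1)
    return SegmentationResult(labels=roi, lmv=int(lmv))


def segment(
    img: np.ndarray,
    count_thresh: int = 20,
    value_floor: int = 220,
    keep_largest: bool = True,
    require_above_floor: bool = False,
) -> SegmentationResult:
    """Convenience wrapper: histogram -> LMV threshold -> segmentation."""
    lmv = least_max_value(
        gray_histogram(img),
        count_thresh=count_thresh,
        value_floor=value_floor,
        require_above_floor=require_above_floor,
    )
    return segment_image(img, lmv, keep_largest=keep_largest)
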