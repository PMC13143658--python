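"""Deformation descriptors from segmented images, ECG descriptors from beat
waveforms, and their feature-level fusion.

Four shape/intensity descriptors summarise the segmented region of interest:

* NAD  — normalized area of the deformation: RoI area / image area.
* ACAD — average curvature: mean absolute turning angle per step (radians)
  along the traced 8-connected outer boundary of the largest RoI component.
* NVD  — normalized volume: RoI intensity mass / (255 * image area).
* ACVD — average curvature of volume: mean |4-neighbour Laplacian| / 255 over
  interior RoI pixels.

Two descriptors come from a fixed-length ECG beat sampled at 125 Hz: the heart
rate from inter-peak intervals, and an explicitly *surrogate* blood-pressure
value, a documented linear function of peak amplitude and heart rate (no
physiological claim is made; the coefficients are configuration).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import InvalidInputError
from .segmentation import SegmentationResult

__all__ = [
    "FEATURE_NAMES",
    "MRIFeatures",
    "ECGFeatures",
    "FusedFeatureVector",
    "extract_mri_features",
    "extract_ecg_features",
    "fuse_features",
    "trace_boundary",
    "features_to_frame",
    "frame_to_features",
    "write_feature_table",
    "read_feature_table",
    "read_ecg_csv",
]

#: Canonical fused-feature ordering: artery pair, valve pair, ECG pair.
FEATURE_NAMES = ("nad", "acad", "nvd", "acvd", "bp", "hr")


@dataclass(frozen=True)
class MRIFeatures:
    nad: float
    acad: float
    nvd: float
    acvd: float


@dataclass(frozen=True)
class ECGFeatures:
    hr: float
    bp: float


@dataclass(frozen=True)
class FusedFeatureVector:
    """One multimodal sample: (nad, acad, nvd, acvd, bp, hr) + label."""

    values: tuple
    label: object
    sample_id: object = None

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


# 8 king moves in clockwise order starting North; ring neighbours are adjacent.
_DIRS = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
_DIR_INDEX = {d: i for i, d in enumerate(_DIRS)}


def trace_boundary(mask: np.ndarray) -> list[tuple[int, int]]:
    """Ordered outer-boundary walk of a connected foreground region.

    Moore-neighbour tracing, clockwise, starting from the topmost-leftmost
    pixel.  Returns the closed sequence of boundary pixel coordinates (the
    start pixel is not repeated at the end).
    """
    mask = np.asarray(mask, dtype=bool)
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        return []
    start = (int(ys[0]), int(xs[0]))  # nonzero is raster-ordered
    if ys.size == 1:
        return [start]

    h, w = mask.shape

    def fg(p):
        return 0 <= p[0] < h and 0 <= p[1] < w and mask[p]

    path = [start]
    cur = start
    back = (start[0], start[1] - 1)  # west of start is background by choice of start
    first_move = None
    for _ in range(8 * mask.size):  # safety bound
        i = _DIR_INDEX[(back[0] - cur[0], back[1] - cur[1])]
        nxt = None
        last_bg = back
        for k in range(1, 9):
            cand = (cur[0] + _DIRS[(i + k) % 8][0], cur[1] + _DIRS[(i + k) % 8][1])
            if fg(cand):
                nxt = cand
                break
            last_bg = cand
        if nxt is None:  # isolated pixel (cannot happen for size > 1 components)
            break
        if first_move is None:
            first_move = (cur, nxt)
        elif (cur, nxt) == first_move:
            break
        path.append(nxt)
        back, cur = last_bg, nxt
    if len(path) > 1 and path[-1] == start:
        path.pop()
    return path


def _boundary_curvature(mask: np.ndarray) -> float:
    """Mean absolute turning angle per step along the traced boundary."""
    path = trace_boundary(mask)
    if len(path) < 3:
        return 0.0
    pts = np.asarray(path + [path[0]], dtype=float)  # close the walk
    steps = np.diff(pts, axis=0)
    angles = np.arctan2(steps[:, 0], steps[:, 1])
    dtheta = np.diff(np.concatenate([angles, angles[:1]]))
    dtheta = (dtheta + np.pi) % (2 * np.pi) - np.pi
    return float(np.mean(np.abs(dtheta)))


def extract_mri_features(img: np.ndarray, seg: SegmentationResult) -> MRIFeatures:
    """Compute the four deformation descriptors for a segmented image."""
    arr = np.asarray(img, dtype=float)
    roi = np.asarray(seg.labels, dtype=bool)
    if arr.shape != roi.shape:
        raise InvalidInputError("image and segmentation shapes differ")
    h, w = arr.shape
    area = int(roi.sum())
    if area == 0:
        return MRIFeatures(0.0, 0.0, 0.0, 0.0)

    nad = area / (h * w)
    nvd = float(arr[roi].sum()) / (255.0 * h * w)
    acad = _boundary_curvature(roi)

    # interior pixels: RoI pixels whose 4 neighbours are all RoI (and in-bounds)
    interior = np.zeros_like(roi)
    interior[1:-1, 1:-1] = (
        roi[1:-1, 1:-1] & roi[:-2, 1:-1] & roi[2:, 1:-1] & roi[1:-1, :-2] & roi[1:-1, 2:]
    )
    if interior.any():
        lap = np.zeros_like(arr)
        lap[1:-1, 1:-1] = (
            arr[:-2, 1:-1] + arr[2:, 1:-1] + arr[1:-1, :-2] + arr[1:-1, 2:] - 4 * arr[1:-1, 1:-1]
        )
        acvd = float(np.mean(np.abs(lap[interior]))) / 255.0
    else:
        acvd = 0.0
    return MRIFeatures(nad=nad, acad=acad, nvd=nvd, acvd=acvd)


def extract_ecg_features(
    beat: np.ndarray,
    fs: float = 125.0,
    peak_sd_factor: float = 2.0,
    min_peak_distance: int = 25,
    bp_coefs: tuple = (80.0, 30.0, 0.2),
) -> ECGFeatures:
    """Heart rate and surrogate blood pressure from one beat waveform.

    Peaks are samples above mean + ``peak_sd_factor``*sd, at least
    ``min_peak_distance`` samples (0.2 s at 125 Hz) apart.  With >= 2 peaks the
    heart rate is 60 / mean inter-peak interval; otherwise the waveform is
    treated as a single beat spanning its full duration.  The surrogate
    pressure is ``b0 + b1*(max - baseline) + b2*hr`` with the waveform median
    as baseline.
    """
    x = np.asarray(beat, dtype=float).ravel()
    if x.size < 2:
        raise InvalidInputError("waveform must have at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("waveform contains non-finite values")

    duration = x.size / fs
    sd = float(x.std())
    if sd == 0.0:
        warnings.warn("flat waveform: no peaks detectable, single-beat fallback used")
        hr = 60.0 / duration
    else:
        peaks, _ = find_peaks(x, height=x.mean() + peak_sd_factor * sd, distance=min_peak_distance)
        if peaks.size >= 2:
            hr = 60.0 / (float(np.mean(np.diff(peaks))) / fs)
        else:
            hr = 60.0 / duration
    b0, b1, b2 = bp_coefs
    bp = b0 + b1 * (float(x.max()) - float(np.median(x))) + b2 * hr
    return ECGFeatures(hr=hr, bp=bp)


def fuse_features(mri: MRIFeatures, ecg: ECGFeatures, label, sample_id=None) -> FusedFeatureVector:
    """Assemble the fixed-order multimodal record (no scaling here)."""
    return FusedFeatureVector(
        values=(mri.nad, mri.acad, mri.nvd, mri.acvd, ecg.bp, ecg.hr),
        label=label,
        sample_id=sample_id,
    )


def features_to_frame(samples: list[FusedFeatureVector]) -> pd.DataFrame:
    rows = [
        {"id": s.sample_id if s.sample_id is not None else i,
         **dict(zip(FEATURE_NAMES, s.values)), "label": s.label}
        for i, s in enumerate(samples)
    ]
    return pd.DataFrame(rows, columns=["id", *FEATURE_NAMES, "label"])


def frame_to_features(frame: pd.DataFrame) -> list[FusedFeatureVector]:
    return [
        FusedFeatureVector(
            values=tuple(float(row[f]) for f in FEATURE_NAMES),
            label=row["label"],
            sample_id=row["id"],
        )
        for _, row in frame.iterrows()
    ]


def write_feature_table(path, samples_or_frame) -> None:
    frame = (
        samples_or_frame
        if isinstance(samples_or_frame, pd.DataFrame)
        else features_to_frame(samples_or_frame)
    )
    frame.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in ("id", *FEATURE_NAMES, "label") if c not in frame.columns]
    if missing:
        raise InvalidInputError(f"feature table missing columns: {missing}")
    return frame


def read_ecg_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a beat-per-row ECG CSV (last column = integer class label)."""
    frame = pd.read_csv(path, header=None)
    if frame.shape[1] < 3:
        raise InvalidInputError("ECG CSV needs waveform columns plus a label column")
    return frame.iloc[:, :-1].to_numpy(float), frame.iloc[:, -1].to_numpy(int)
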