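"""Seeded synthetic-data generators: cardiac phantoms, ECG beats, and
planted-signal feature tables.

The phantom generator draws a dark elliptical region of interest on a
brighter textured background (matching the segmenter's dark-RoI convention),
clips intensities to [1, 254] *before* impulse corruption so that 0/255
pixels are exactly the planted noise, and returns the clean ellipse as ground
truth.  "Abnormal" phantoms scale the ellipse axes and add a boundary ripple.
ECG beats are 187-sample rows at 125 Hz (the public heartbeat-CSV layout)
with class-conditional QRS amplitude and spacing.  Feature tables plant a
known informative subset with a prescribed class-mean separation, for scoring
feature-selection recovery.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .features import FEATURE_NAMES

__all__ = [
    "PhantomSpec",
    "PlantedTableSpec",
    "ECG_CLASS_PARAMS",
    "generate_phantom_mri",
    "generate_ecg_beats",
    "generate_feature_table",
    "make_fused_benchmark",
    "write_metadata",
]


@dataclass
class PhantomSpec:
    """Parameters of one synthetic cardiac phantom image.

    Default ellipse semi-axes are kept small relative to the histogram
    dominance threshold of the segmenter so that per-gray-level RoI counts
    stay sub-dominant and the least-max-value threshold lands between the
    intensity modes (see the methods note).
    """

    height: int = 128
    width: int = 128
    background_mean: float = 200.0
    background_sd: float = 10.0
    roi_mean: float = 80.0
    roi_sd: float = 10.0
    center: tuple | None = None  # (row, col); image centre when None
    semi_axes: tuple = (8.0, 6.0)  # (row semi-axis, col semi-axis)
    rotation: float = 0.0  # radians
    impulse_rate: float = 0.05
    label: str = "normal"  # "normal" | "abnormal"
    abnormal_scale: float = 1.3
    ripple_amp: float = 1.0  # boundary ripple amplitude, pixels (abnormal only)
    ripple_freq: int = 5
    seed: int = 0


@dataclass
class PlantedTableSpec:
    n: int = 300
    d: int = 20
    k: int = 4
    effect: float = 1.5  # class-mean separation in pooled-sd units
    n_classes: int = 2
    proportions: tuple | None = None
    seed: int = 0


def generate_phantom_mri(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render one phantom; returns ``(image uint8, truth mask bool)``."""
    if not 0.0 <= spec.impulse_rate <= 0.5:
        raise ConfigurationError("impulse rate must lie in [0, 0.5]")
    if spec.label not in ("normal", "abnormal"):
        raise ConfigurationError(f"unknown phantom class {spec.label!r}")
    h, w = spec.height, spec.width
    cy, cx = spec.center if spec.center is not None else ((h - 1) / 2.0, (w - 1) / 2.0)
    a, b = spec.semi_axes
    if spec.label == "abnormal":
        a, b = a * spec.abnormal_scale, b * spec.abnormal_scale
    margin = max(a, b) + (spec.ripple_amp if spec.label == "abnormal" else 0.0)
    if cy - margin < 0 or cy + margin >= h or cx - margin < 0 or cx + margin >= w:
        raise ConfigurationError("ellipse (plus ripple) exceeds image bounds")

    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    cos_t, sin_t = np.cos(spec.rotation), np.sin(spec.rotation)
    ry = dy * cos_t - dx * sin_t
    rx = dy * sin_t + dx * cos_t
    r_norm = np.sqrt((ry / a) ** 2 + (rx / b) ** 2)
    if spec.label == "abnormal" and spec.ripple_amp > 0:
        theta = np.arctan2(ry, rx)
        boundary = 1.0 + (spec.ripple_amp / ((a + b) / 2.0)) * np.sin(spec.ripple_freq * theta)
    else:
        boundary = 1.0
    mask = r_norm <= boundary

    rng = np.random.default_rng(spec.seed)
    img = rng.normal(spec.background_mean, spec.background_sd, size=(h, w))
    img[mask] = rng.normal(spec.roi_mean, spec.roi_sd, size=int(mask.sum()))
    img = np.clip(np.rint(img), 1, 254).astype(np.uint8)  # 0/255 reserved for noise

    if spec.impulse_rate > 0:
        corrupt = rng.random((h, w)) < spec.impulse_rate
        salt = rng.random((h, w)) < 0.5
        img[corrupt & salt] = 255
        img[corrupt & ~salt] = 0
    return img, mask


#: Per-class QRS parameters (amplitude, inter-peak spacing in samples,
#: Gaussian bump width) emulating the five heartbeat categories N/S/V/F/Q.
ECG_CLASS_PARAMS = {
    0: {"amp": 1.0, "spacing": 100, "width": 3.0},  # normal
    1: {"amp": 0.6, "spacing": 62, "width": 2.5},  # supraventricular ectopic
    2: {"amp": 1.4, "spacing": 80, "width": 3.5},  # ventricular ectopic
    3: {"amp": 0.9, "spacing": 55, "width": 3.0},  # fusion
    4: {"amp": 0.5, "spacing": 115, "width": 2.0},  # unknown
}


def generate_ecg_beats(
    label: int,
    n: int,
    seed: int = 0,
    length: int = 187,
    noise_sd: float = 0.05,
    amp_jitter: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-length class-conditional beat rows; returns ``(beats, labels)``."""
    if n < 1:
        raise ConfigurationError("need n >= 1 beats")
    if label not in ECG_CLASS_PARAMS:
        raise ConfigurationError(f"unknown ECG class label {label!r}")
    p = ECG_CLASS_PARAMS[label]
    rng = np.random.default_rng(seed)
    t = np.arange(length)
    beats = np.zeros((n, length))
    for i in range(n):
        amp = p["amp"] * (1.0 + amp_jitter * rng.standard_normal())
        centre = 30
        while centre < length - 5:
            beats[i] += amp * np.exp(-((t - centre) ** 2) / (2.0 * p["width"] ** 2))
            centre += p["spacing"]
        if noise_sd > 0:
            beats[i] += noise_sd * rng.standard_normal(length)
    return beats, np.full(n, label, dtype=int)


def generate_feature_table(spec: PlantedTableSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Planted-signal table; returns ``(frame, informative feature indices)``.

    Informative columns get class means separated by ``effect`` pooled
    standard deviations (unit sd); the rest are standard Gaussian noise.
    """
    if spec.k > spec.d:
        raise ConfigurationError("k informative features cannot exceed d")
    if spec.effect < 0:
        raise ConfigurationError("effect size must be non-negative")
    rng = np.random.default_rng(spec.seed)
    props = (
        np.asarray(spec.proportions, dtype=float)
        if spec.proportions is not None
        else np.full(spec.n_classes, 1.0 / spec.n_classes)
    )
    props = props / props.sum()
    counts = np.floor(props * spec.n).astype(int)
    counts[: spec.n - counts.sum()] += 1
    y = np.repeat(np.arange(spec.n_classes), counts)

    informative = np.sort(rng.choice(spec.d, size=spec.k, replace=False))
    X = rng.standard_normal((spec.n, spec.d))
    offsets = (np.arange(spec.n_classes) - (spec.n_classes - 1) / 2.0) * spec.effect
    for c in range(spec.n_classes):
        X[np.ix_(y == c, informative)] += offsets[c]

    frame = pd.DataFrame(X, columns=[f"f{i}" for i in range(spec.d)])
    frame["label"] = y
    return frame, informative


# affine maps giving the benchmark columns realistic scales (separability is
# unaffected by per-column affine transforms)
_FUSED_SCALES = {
    "nad": (0.015, 0.004),
    "acad": (0.35, 0.08),
    "nvd": (0.006, 0.002),
    "acvd": (0.05, 0.015),
    "bp": (115.0, 12.0),
    "hr": (75.0, 10.0),
}


def make_fused_benchmark(n: int = 400, effect: float = 2.0, seed: int = 0) -> pd.DataFrame:
    """Separable two-class fused-feature benchmark.

    All six canonical features carry class signal at ``effect`` pooled-sd
    separation, then each column is mapped affinely onto a realistic scale.
    Columns: id, nad, acad, nvd, acvd, bp, hr, label.
    """
    frame, _ = generate_feature_table(
        PlantedTableSpec(n=n, d=6, k=6, effect=effect, n_classes=2, seed=seed)
    )
    out = pd.DataFrame({"id": np.arange(n)})
    for name, col in zip(FEATURE_NAMES, [f"f{i}" for i in range(6)]):
        loc, scale = _FUSED_SCALES[name]
        out[name] = loc + scale * frame[col].to_numpy()
    out["label"] = frame["label"].to_numpy()
    return out


def write_metadata(path, spec) -> None:
    """Echo generator parameters to a YAML sidecar for provenance."""
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump({"generator": type(spec).__name__, "params": asdict(spec)}, fh)
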