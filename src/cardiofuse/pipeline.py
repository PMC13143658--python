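"""End-to-end orchestration of the six pipeline stages.

preprocess -> segment -> extract (MRI + ECG) -> fuse -> select -> classify,
driven by a single configuration object, with every intermediate artifact
written to the run directory and all randomness flowing from one master seed
split per stage.  Reruns with the same configuration and seed reproduce every
CSV/JSON output bit-identically (no timestamps enter the outputs).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .efmlnp import ensemble_predict, save_model, train_efmlnp
from .errors import ConfigurationError
from .evaluation import confusion_and_metrics
from .features import (
    FEATURE_NAMES,
    extract_ecg_features,
    extract_mri_features,
    features_to_frame,
    fuse_features,
    read_feature_table,
)
from .imaging import preprocess_image, write_image
from .rsso import run_rsso
from .segmentation import segment
from .synthetic import PhantomSpec, generate_ecg_beats, generate_phantom_mri

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Per-stage parameter blocks; defaults follow the evaluation protocol
    (100 epochs, learning rate 0.001, adaptive-moment optimizer, 70/30
    train/test split)."""

    seed: int = 0
    n_per_class: int = 40  # phantoms (and paired beats) per class in simulate mode
    write_images: bool = True
    features_csv: str | None = None  # skip simulation and load this table instead
    phantom: dict = field(default_factory=dict)  # PhantomSpec overrides
    preprocess: dict = field(default_factory=lambda: {"kernel": 3, "mode": "selective"})
    segmentation: dict = field(
        default_factory=lambda: {"count_thresh": 20, "value_floor": 220, "keep_largest": True}
    )
    ecg: dict = field(default_factory=lambda: {"noise_sd": 0.05})
    selection: dict = field(
        default_factory=lambda: {"enabled": True, "n_spiders": 20, "n_iterations": 50}
    )
    model: dict = field(
        default_factory=lambda: {
            "epochs": 100,
            "learning_rate": 0.001,
            "hidden": [64, 32],
            "input_dims": [128, 144, 156],
            "batch_sizes": [128, 64, 128],
        }
    )
    test_size: float = 0.3

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


# phantom class label <-> ECG heartbeat category used for index pairing
_CLASS_MAP = {"normal": 0, "abnormal": 2}


def _simulate_features(cfg: PipelineConfig, out: Path, log: list) -> "object":
    """Stages 1-4 on synthetic inputs: generate, denoise, segment, extract, fuse."""
    ss = np.random.SeedSequence(cfg.seed)
    phantom_seeds, ecg_seeds = ss.spawn(2)
    img_dir = out / "images"
    if cfg.write_images:
        img_dir.mkdir(exist_ok=True)

    samples = []
    for class_idx, (label, ecg_class) in enumerate(sorted(_CLASS_MAP.items())):
        beats, _ = generate_ecg_beats(
            ecg_class,
            cfg.n_per_class,
            seed=int(ecg_seeds.generate_state(1)[0] + class_idx) % (2**31),
            **cfg.ecg,
        )
        base = int(phantom_seeds.generate_state(1)[0]) % (2**31)
        for i in range(cfg.n_per_class):
            spec = PhantomSpec(
                label=label, seed=(base + 1000 * class_idx + i) % (2**31), **cfg.phantom
            )
            raw, _truth = generate_phantom_mri(spec)
            den = preprocess_image(raw, **cfg.preprocess)
            seg = segment(den, **cfg.segmentation)
            mri = extract_mri_features(den, seg)
            ecg = extract_ecg_features(beats[i])
            sid = f"{label}_{i:03d}"
            samples.append(fuse_features(mri, ecg, label=class_idx, sample_id=sid))
            if cfg.write_images:
                write_image(img_dir / f"{sid}_raw.png", raw)
                write_image(img_dir / f"{sid}_denoised.png", den)
                write_image(img_dir / f"{sid}_roi.png", seg.labels.astype(np.uint8) * 255)
    log.append(f"simulated {len(samples)} fused samples ({cfg.n_per_class} per class)")
    return features_to_frame(samples)


def run_pipeline(cfg: PipelineConfig, out_dir, simulate: bool = True) -> dict:
    """Execute the six stages and write model, reports and logs to ``out_dir``.

    Returns the evaluation report as a dict.  With ``simulate`` the inputs
    are generated by the phantom/beat generators; otherwise ``features_csv``
    must point at an existing fused feature table.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    cfg.to_yaml(out / "config.yaml")
    cfg_hash = hashlib.sha256((out / "config.yaml").read_bytes()).hexdigest()[:16]

    if simulate:
        frame = _simulate_features(cfg, out, log)
    else:
        if not cfg.features_csv or not Path(cfg.features_csv).exists():
            raise ConfigurationError(
                "stage 'features': missing input table "
                f"(features_csv={cfg.features_csv!r}); run with simulate or point "
                "features_csv at an existing CSV"
            )
        frame = read_feature_table(cfg.features_csv)
        log.append(f"loaded features from {cfg.features_csv}")
    frame.to_csv(out / "features.csv", index=False)

    X = frame[list(FEATURE_NAMES)].to_numpy(float)
    y = frame["label"].to_numpy()

    # stratified 70/30 split, seeded from the master seed
    from sklearn.model_selection import train_test_split

    tr, te = train_test_split(
        np.arange(y.size), test_size=cfg.test_size, stratify=y, random_state=cfg.seed % (2**31)
    )

    sel_cfg = dict(cfg.selection)
    use_selection = sel_cfg.pop("enabled", True)
    selected = list(range(X.shape[1]))
    if use_selection:
        sel = run_rsso(X[tr], y[tr], seed=cfg.seed, **sel_cfg)
        sel.to_json(out / "selection.json")
        selected = sel.selected
        log.append(f"selection kept features {selected}")
    else:
        log.append("selection stage disabled (fusion-without-selection configuration)")

    model_cfg = dict(cfg.model)
    model_cfg["hidden"] = tuple(model_cfg.get("hidden", (64, 32)))
    model_cfg["input_dims"] = tuple(model_cfg.get("input_dims", (128, 144, 156)))
    model_cfg["batch_sizes"] = tuple(model_cfg.get("batch_sizes", (128, 64, 128)))
    model = train_efmlnp(
        X[tr][:, selected],
        y[tr],
        seed=cfg.seed,
        feature_names=tuple(np.array(FEATURE_NAMES)[selected]),
        **model_cfg,
    )
    save_model(model, out / "model.npz")

    labels, scores = ensemble_predict(model, X[te][:, selected])
    pred_frame = frame.iloc[te][["id"]].copy()
    pred_frame["label"] = labels
    pred_frame["score"] = scores.max(axis=1)
    pred_frame.to_csv(out / "predictions.csv", index=False)

    report = confusion_and_metrics(y[te], labels, scores=scores, seed=cfg.seed)
    report.config = {
        "selected_features": selected,
        "use_selection": use_selection,
        "config_hash": cfg_hash,
        "n_train": int(len(tr)),
        "n_test": int(len(te)),
    }
    report.to_json(out / "report.json")

    versions = {"cardiofuse": __version__, "numpy": np.__version__}
    (out / "run_log.txt").write_text(
        "\n".join(
            [f"seed={cfg.seed}", f"config_hash={cfg_hash}", f"versions={json.dumps(versions)}"]
            + log
        )
        + "\n"
    )
    return report.to_dict()
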