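"""Ensemble fuzzy multilayer perceptron classifier.

Each selected feature is min-max normalized and *fuzzified*: expanded into a
bank of bell-membership channels centred at evenly spaced prototypes in
[0,1], so that three perceptron members see input widths of exactly 128, 144
and 156 channels (zero-padded when the channel bank does not divide evenly).
The members (two hidden layers, softmax output) are trained with
adaptive-moment gradient descent on a cross-entropy loss weighted per sample
by the fuzzy certainty kappa = mean_f |2 mu_f - 1|, so ambiguous samples
(memberships near 0.5) exert less influence.  Prediction is a majority vote
with summed-score tie-breaking.

Alongside the ensemble, class-conditional fuzzy prototypes support a
distance-ratio classifier: per class, the artery (ACIM), valve (VCIM) and ECG
(ECIM) impact measures are ratios of feature-to-prototype distances, combined
as CECIM = (VCIM/ACIM)*ECIM; the class with maximal CECIM wins.  A type-II
interval extension and a fuzzy dependency diagnostic are exposed as well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, StateError
from .features import FEATURE_NAMES

__all__ = [
    "ClassFuzzyProfile",
    "TypeIIMembership",
    "ImpactMeasures",
    "FuzzyDependency",
    "EnsembleModel",
    "compute_fuzzy_profile",
    "bell_membership",
    "fuzzy_dependency",
    "membership_to_rank",
    "compute_impact_measures",
    "cecim_classify",
    "fuzzify_features",
    "train_efmlnp",
    "ensemble_predict",
    "save_model",
    "load_model",
]

_EPS = 1e-6
_S_CAP = 1e4


@dataclass
class TypeIIMembership:
    """Interval-valued membership degree, 0 <= lower <= upper <= 1."""

    lower: float
    upper: float


@dataclass(frozen=True)
class ImpactMeasures:
    acim: float
    vcim: float
    ecim: float
    cecim: float


@dataclass(frozen=True)
class FuzzyDependency:
    F: float
    F1: float
    FD: float


@dataclass
class ClassFuzzyProfile:
    """Per-class feature prototypes on the min-max normalized scale."""

    classes: list
    feature_names: tuple
    feat_min: np.ndarray
    feat_max: np.ndarray
    prototypes: dict  # class -> (d,) array E(c,f) in [0,1]
    widths: dict  # class -> (d,) array s(c,f) > 0

    def normalize(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        span = np.where(self.feat_max > self.feat_min, self.feat_max - self.feat_min, 1.0)
        return np.clip((X - self.feat_min) / span, 0.0, 1.0)


def compute_fuzzy_profile(
    X: np.ndarray, y: np.ndarray, feature_names: tuple | None = None, eps: float = _EPS
) -> ClassFuzzyProfile:
    """Fit class prototypes E(c,f) and bell widths s(c,f) = 1/(2 var + eps).

    Features are min-max normalized by the training extremes; single-valued
    class features get the width cap 1e4.  Every class needs >= 2 samples.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise InvalidInputError("X must be 2-D with one label per row")
    classes = sorted(np.unique(y).tolist())
    for c in classes:
        if np.count_nonzero(y == c) < 2:
            raise InvalidInputError(f"class {c!r} has fewer than 2 samples")
    names = tuple(feature_names) if feature_names is not None else tuple(
        f"f{i}" for i in range(X.shape[1])
    )
    feat_min, feat_max = X.min(axis=0), X.max(axis=0)
    span = np.where(feat_max > feat_min, feat_max - feat_min, 1.0)
    Xn = np.clip((X - feat_min) / span, 0.0, 1.0)
    prototypes, widths = {}, {}
    for c in classes:
        block = Xn[y == c]
        prototypes[c] = block.mean(axis=0)
        widths[c] = np.minimum(1.0 / (2.0 * block.var(axis=0) + eps), _S_CAP)
    return ClassFuzzyProfile(
        classes=classes,
        feature_names=names,
        feat_min=feat_min,
        feat_max=feat_max,
        prototypes=prototypes,
        widths=widths,
    )


def bell_membership(
    a: float, b: float, s: float, delta2: float = 0.1
) -> tuple[float, float, TypeIIMembership]:
    """Bell fuzzification of a normalized value against a prototype.

    Returns ``(Fl, mu, interval)`` where ``Fl = 1 - 1/(1 + s (a-b)^2)`` (the
    inverted bell, zero at the prototype), ``mu = 1 - Fl`` is the membership
    degree, and the type-II interval is ``[mu - delta2, mu + delta2]`` clipped
    to [0,1].
    """
    if not (np.isfinite(a) and np.isfinite(b) and np.isfinite(s)):
        raise InvalidInputError("bell membership requires finite inputs")
    if s <= 0:
        raise InvalidInputError("bell width s must be positive")
    mu = 1.0 / (1.0 + s * (a - b) ** 2)
    fl = 1.0 - mu
    return fl, mu, TypeIIMembership(max(0.0, mu - delta2), min(1.0, mu + delta2))


def fuzzy_dependency(weights, intervals: list[TypeIIMembership]) -> FuzzyDependency:
    """Aggregate membership F, aggregate uncertainty F1, dependency F/(F1+F).

    A diagnostic of how decisively a feature set supports a class: F sums the
    weighted interval centres, F1 the weighted interval half-widths, and the
    dependency FD shrinks as intervals widen.  FD is defined 0 when F = 0.
    """
    w = np.asarray(weights, dtype=float)
    if w.size != len(intervals) or w.size == 0:
        raise InvalidInputError("weights and intervals must align (m >= 1)")
    if np.any(w < 0):
        raise InvalidInputError("weights must be non-negative")
    lo = np.array([iv.lower for iv in intervals])
    up = np.array([iv.upper for iv in intervals])
    F = float(np.sum(w * (up + lo) / 2.0))
    F1 = float(np.sum(w * (up - lo) / 2.0))
    FD = 0.0 if F == 0.0 else F / (F1 + F)
    return FuzzyDependency(F=F, F1=F1, FD=FD)


def membership_to_rank(mu: float) -> int:
    """Map a membership degree to a rank position via the anchor points
    (0.9 -> 1, 0.1 -> 6, 0 -> 13), piecewise linear, clamped to rank 1 above
    0.9 and rounded half-up to the nearest integer >= 1."""
    if not np.isfinite(mu) or mu < 0.0 or mu > 1.0:
        raise InvalidInputError(f"membership must lie in [0, 1], got {mu}")
    if mu >= 0.9:
        r = 1.0
    elif mu >= 0.1:
        r = 6.0 - 5.0 * (mu - 0.1) / 0.8
    else:
        r = 13.0 - 70.0 * mu
    return max(1, int(np.floor(r + 0.5)))


def _distance(x: float, y: float, eps: float = _EPS) -> float:
    return abs(x - y) + eps


def compute_impact_measures(
    sample, profile: ClassFuzzyProfile, eps: float = _EPS
) -> dict:
    """Per-class ACIM/VCIM/ECIM/CECIM distance-ratio scores (percent scale).

    With D(x,y) = |x-y| + eps on normalized values: ACIM pairs the artery
    features (NAD/ACAD), VCIM the valve features (NVD/ACVD), ECIM the ECG
    features (BP/HR); CECIM = (VCIM/ACIM) * ECIM.
    """
    if profile is None or not profile.prototypes:
        raise StateError("profile must be trained before computing impact measures")
    for f in FEATURE_NAMES:
        if f not in profile.feature_names:
            raise InvalidInputError(
                "impact measures need the canonical fused features "
                f"{FEATURE_NAMES}; profile has {profile.feature_names}"
            )
    values = sample.as_array() if hasattr(sample, "as_array") else np.asarray(sample, float)
    idx = [profile.feature_names.index(f) for f in FEATURE_NAMES]
    xn = profile.normalize(values.reshape(1, -1))[0]
    out = {}
    for c in profile.classes:
        E = profile.prototypes[c]
        d = {f: _distance(xn[i], E[i], eps) for f, i in zip(FEATURE_NAMES, idx)}
        acim = 100.0 * d["nad"] / d["acad"]
        vcim = 100.0 * d["nvd"] / d["acvd"]
        ecim = 100.0 * d["bp"] / d["hr"]
        out[c] = ImpactMeasures(acim=acim, vcim=vcim, ecim=ecim, cecim=(vcim / acim) * ecim)
    return out


def cecim_classify(sample, profile: ClassFuzzyProfile):
    """Pick the class with maximal CECIM; ties go to the lowest class index."""
    measures = compute_impact_measures(sample, profile)
    best, best_val = None, -np.inf
    for c in profile.classes:  # sorted: first maximal class wins ties
        if measures[c].cecim > best_val:
            best, best_val = c, measures[c].cecim
    return best


# ---------------------------------------------------------------------------
# fuzzification + perceptron ensemble
# ---------------------------------------------------------------------------


def fuzzify_features(Xn: np.ndarray, dim: int) -> tuple[np.ndarray, np.ndarray]:
    """Expand normalized features into bell-membership channels.

    Each of the d features is evaluated against G = dim // d evenly spaced
    prototypes in [0,1] with a bell width chosen so that membership is 0.5
    midway between adjacent prototypes; the channel block is zero-padded to
    exactly ``dim`` columns.  Also returns the per-sample fuzzy certainty
    kappa = mean |2 mu - 1| over the real channels.
    """
    Xn = np.atleast_2d(np.asarray(Xn, dtype=float))
    n, d = Xn.shape
    G = max(1, dim // d)
    if G == 1:
        protos = np.array([0.5])
        s = 4.0
    else:
        protos = np.linspace(0.0, 1.0, G)
        spacing = 1.0 / (G - 1)
        s = 4.0 / spacing**2
    mu = 1.0 / (1.0 + s * (Xn[:, :, None] - protos[None, None, :]) ** 2)
    channels = mu.reshape(n, d * G)[:, : min(d * G, dim)]
    kappa = np.mean(np.abs(2.0 * channels - 1.0), axis=1)
    if channels.shape[1] < dim:
        channels = np.pad(channels, ((0, 0), (0, dim - channels.shape[1])))
    return channels, kappa


class _MLP:
    """Two-hidden-layer softmax perceptron trained with Adam on a
    sample-weighted cross-entropy (the delta rule recovered at the output)."""

    def __init__(self, dim_in: int, n_classes: int, hidden=(64, 32), seed=0):
        rng = np.random.default_rng(seed)
        sizes = [dim_in, *hidden, n_classes]
        self.W = [
            rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self.b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]

    def _forward(self, X):
        acts = [X]
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = acts[-1] @ W + b
            acts.append(np.maximum(z, 0.0) if i < len(self.W) - 1 else z)
        logits = acts[-1]
        logits = logits - logits.max(axis=1, keepdims=True)
        probs = np.exp(logits)
        probs /= probs.sum(axis=1, keepdims=True)
        return acts, probs

    def predict_proba(self, X):
        return self._forward(X)[1]

    def fit(self, X, Y, sample_weight, epochs=100, lr=1e-3, batch_size=128, seed=0):
        rng = np.random.default_rng(seed)
        n = X.shape[0]
        batch_size = min(batch_size, n)
        mW = [np.zeros_like(W) for W in self.W]
        vW = [np.zeros_like(W) for W in self.W]
        mb = [np.zeros_like(b) for b in self.b]
        vb = [np.zeros_like(b) for b in self.b]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        for _ in range(epochs):
            perm = rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = perm[start : start + batch_size]
                xb, yb, wb = X[idx], Y[idx], sample_weight[idx]
                acts, probs = self._forward(xb)
                delta = (probs - yb) * wb[:, None] / len(idx)
                grads_W, grads_b = [], []
                for layer in range(len(self.W) - 1, -1, -1):
                    grads_W.append(acts[layer].T @ delta)
                    grads_b.append(delta.sum(axis=0))
                    if layer > 0:
                        delta = (delta @ self.W[layer].T) * (acts[layer] > 0)
                grads_W.reverse()
                grads_b.reverse()
                t += 1
                for layer in range(len(self.W)):
                    for store_m, store_v, grad, param in (
                        (mW, vW, grads_W[layer], self.W),
                        (mb, vb, grads_b[layer], self.b),
                    ):
                        store_m[layer] = beta1 * store_m[layer] + (1 - beta1) * grad
                        store_v[layer] = beta2 * store_v[layer] + (1 - beta2) * grad**2
                        m_hat = store_m[layer] / (1 - beta1**t)
                        v_hat = store_v[layer] / (1 - beta2**t)
                        param[layer] = param[layer] - lr * m_hat / (np.sqrt(v_hat) + eps)
        return self


@dataclass
class EnsembleModel:
    """Three fuzzified perceptrons plus the profile and normalization stats."""

    members: list
    input_dims: tuple
    batch_sizes: tuple
    classes: list
    feat_min: np.ndarray
    feat_max: np.ndarray
    profile: ClassFuzzyProfile | None
    seed: int
    config: dict = field(default_factory=dict)

    def _normalize(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        span = np.where(self.feat_max > self.feat_min, self.feat_max - self.feat_min, 1.0)
        return np.clip((X - self.feat_min) / span, 0.0, 1.0)


def train_efmlnp(
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    epochs: int = 100,
    learning_rate: float = 0.001,
    hidden=(64, 32),
    input_dims=(128, 144, 156),
    batch_sizes=(128, 64, 128),
    feature_names: tuple | None = None,
    fit_profile: bool = True,
) -> EnsembleModel:
    """Train the three-member fuzzy perceptron ensemble.

    All members see the same training set; they differ in fuzzification width
    (input dims 128/144/156) and batch size (128/64/128).  Training runs for
    ``epochs`` epochs at ``learning_rate`` with adaptive-moment updates and a
    per-sample certainty weight kappa.  Reproducible from ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise InvalidInputError("X must be 2-D with one label per row")
    classes = sorted(np.unique(y).tolist())
    if len(classes) < 2:
        raise InvalidInputError("training needs at least 2 classes")
    n = X.shape[0]
    if n < max(batch_sizes):
        warnings.warn(
            f"fewer samples ({n}) than the largest batch ({max(batch_sizes)}); batches clipped"
        )

    feat_min, feat_max = X.min(axis=0), X.max(axis=0)
    span = np.where(feat_max > feat_min, feat_max - feat_min, 1.0)
    Xn = np.clip((X - feat_min) / span, 0.0, 1.0)
    y_idx = np.array([classes.index(v) for v in y])
    Y = np.eye(len(classes))[y_idx]

    members = []
    for m, (dim, batch) in enumerate(zip(input_dims, batch_sizes)):
        channels, kappa = fuzzify_features(Xn, dim)
        member_seed = np.random.SeedSequence([int(seed) % (2**31), m])
        mlp = _MLP(dim, len(classes), hidden=hidden, seed=member_seed)
        mlp.fit(
            channels,
            Y,
            sample_weight=kappa,
            epochs=epochs,
            lr=learning_rate,
            batch_size=batch,
            seed=np.random.SeedSequence([int(seed) % (2**31), 100 + m]),
        )
        members.append(mlp)

    profile = None
    if fit_profile:
        try:
            profile = compute_fuzzy_profile(X, y, feature_names=feature_names)
        except InvalidInputError:
            profile = None
    return EnsembleModel(
        members=members,
        input_dims=tuple(input_dims),
        batch_sizes=tuple(batch_sizes),
        classes=classes,
        feat_min=feat_min,
        feat_max=feat_max,
        profile=profile,
        seed=int(seed),
        config={"epochs": epochs, "learning_rate": learning_rate, "hidden": tuple(hidden)},
    )


def ensemble_predict(model: EnsembleModel, X: np.ndarray):
    """Majority-vote prediction with summed-score tie-breaking.

    Returns ``(labels, scores)`` where ``scores`` is the (n, k) sum of the
    members' softmax outputs.
    """
    if model is None or not model.members:
        raise StateError("model must be trained before prediction")
    Xn = model._normalize(X)
    n = Xn.shape[0]
    k = len(model.classes)
    summed = np.zeros((n, k))
    votes = np.zeros((n, k), dtype=int)
    for mlp, dim in zip(model.members, model.input_dims):
        channels, _ = fuzzify_features(Xn, dim)
        probs = mlp.predict_proba(channels)
        summed += probs
        votes[np.arange(n), probs.argmax(axis=1)] += 1

    labels = []
    for i in range(n):
        top = votes[i].max()
        tied = np.nonzero(votes[i] == top)[0]
        winner = tied[0] if tied.size == 1 else tied[np.argmax(summed[i, tied])]
        labels.append(model.classes[int(winner)])
    return np.asarray(labels), summed


def save_model(model: EnsembleModel, path) -> None:
    """Serialize the ensemble (weights, profile, normalization, config) to .npz."""
    payload = {
        "classes": np.asarray(model.classes),
        "feat_min": model.feat_min,
        "feat_max": model.feat_max,
        "input_dims": np.asarray(model.input_dims),
        "batch_sizes": np.asarray(model.batch_sizes),
        "seed": np.asarray(model.seed),
        "hidden": np.asarray(model.config.get("hidden", (64, 32))),
    }
    for m, mlp in enumerate(model.members):
        for layer, (W, b) in enumerate(zip(mlp.W, mlp.b)):
            payload[f"W_{m}_{layer}"] = W
            payload[f"b_{m}_{layer}"] = b
    if model.profile is not None:
        payload["profile_names"] = np.asarray(model.profile.feature_names)
        payload["profile_min"] = model.profile.feat_min
        payload["profile_max"] = model.profile.feat_max
        for c in model.profile.classes:
            payload[f"profile_E_{c}"] = model.profile.prototypes[c]
            payload[f"profile_s_{c}"] = model.profile.widths[c]
    np.savez(path, **payload)


def load_model(path) -> EnsembleModel:
    data = np.load(path, allow_pickle=True)
    classes = data["classes"].tolist()
    hidden = tuple(int(h) for h in data["hidden"])
    input_dims = tuple(int(v) for v in data["input_dims"])
    members = []
    for m, dim in enumerate(input_dims):
        mlp = _MLP(dim, len(classes), hidden=hidden, seed=0)
        layer = 0
        W, b = [], []
        while f"W_{m}_{layer}" in data:
            W.append(data[f"W_{m}_{layer}"])
            b.append(data[f"b_{m}_{layer}"])
            layer += 1
        mlp.W, mlp.b = W, b
        members.append(mlp)
    profile = None
    if "profile_names" in data:
        names = tuple(str(x) for x in data["profile_names"])
        profile = ClassFuzzyProfile(
            classes=classes,
            feature_names=names,
            feat_min=data["profile_min"],
            feat_max=data["profile_max"],
            prototypes={c: data[f"profile_E_{c}"] for c in classes},
            widths={c: data[f"profile_s_{c}"] for c in classes},
        )
    return EnsembleModel(
        members=members,
        input_dims=input_dims,
        batch_sizes=tuple(int(v) for v in data["batch_sizes"]),
        classes=classes,
        feat_min=data["feat_min"],
        feat_max=data["feat_max"],
        profile=profile,
        seed=int(data["seed"]),
    )
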