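"""Spider-swarm feature selection with recursive elimination.

A social-spider swarm explores the unit hypercube [0,1]^d; thresholding a
spider's position at 0.5 yields a candidate feature mask whose fitness is the
cross-validated accuracy of a linear max-margin classifier minus a small
cardinality penalty.  Females (65-90% of the colony) move under "vibrations"
received from the nearest better spider and the global best; males move toward
the nearest female or the male mean.  After the swarm run, per-feature rank
scores combine magnitude weights, modal-decile value weights, and the
frequency with which each feature appeared in the stronger half of the swarm;
features are then re-examined in ascending rank order and removed whenever
removal does not hurt the fitness oracle.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .errors import ConfigurationError, InvalidInputError, StateError

__all__ = [
    "SpiderPopulation",
    "FeatureWeights",
    "FeatureSelectionResult",
    "init_population",
    "evaluate_fitness",
    "spider_weights",
    "spider_step",
    "compute_feature_weights",
    "recursive_feature_elimination",
    "run_rsso",
]


@dataclass
class SpiderPopulation:
    positions: np.ndarray  # (N, d) in [0,1]
    female: np.ndarray  # (N,) bool
    fitness: np.ndarray | None = None  # (N,)
    weights: np.ndarray | None = None  # (N,) in [0,1]
    iteration: int = 0

    @property
    def n_spiders(self) -> int:
        return self.positions.shape[0]

    @property
    def n_features(self) -> int:
        return self.positions.shape[1]


@dataclass
class FeatureWeights:
    wei: np.ndarray  # per-feature magnitude weight, sums to 1
    w_val: np.ndarray  # modal-decile value weight in (0, 1]
    w_tx: np.ndarray  # combined weight
    inclusion_freq: np.ndarray | None = None
    rank: np.ndarray = field(default=None)  # final score, min-max scaled to [0,1]


@dataclass
class FeatureSelectionResult:
    selected: list[int]
    rank_scores: list[float]
    fitness_trace: list[float]
    elimination_trace: list[dict]
    seed: int
    config: dict

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "selected": self.selected,
                "rank_scores": self.rank_scores,
                "fitness_trace": self.fitness_trace,
                "elimination_trace": self.elimination_trace,
                "seed": self.seed,
                "config": self.config,
            },
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, path) -> "FeatureSelectionResult":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            selected=d["selected"],
            rank_scores=d["rank_scores"],
            fitness_trace=d["fitness_trace"],
            elimination_trace=d["elimination_trace"],
            seed=d["seed"],
            config=d["config"],
        )


def init_population(d: int, n_spiders: int, rng) -> SpiderPopulation:
    """Seeded colony: N_f = floor((0.9 - 0.25 u) N) females, uniform positions."""
    if n_spiders < 4:
        raise ConfigurationError(f"population size must be >= 4, got {n_spiders}")
    if d < 1:
        raise ConfigurationError("need at least one feature dimension")
    rng = np.random.default_rng(rng)
    u = rng.random()
    n_female = int(np.floor((0.9 - 0.25 * u) * n_spiders))
    female = np.zeros(n_spiders, dtype=bool)
    female[:n_female] = True
    return SpiderPopulation(positions=rng.random((n_spiders, d)), female=female)


def _validate_dataset(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise InvalidInputError("X must be 2-D with one label per row")
    if X.shape[0] < 10:
        raise InvalidInputError("fitness oracle needs at least 10 samples")
    if np.unique(y).size < 2:
        raise InvalidInputError("fitness oracle needs at least 2 classes")
    return X, y


def _mask_fitness(mask: np.ndarray, X, y, cv_seed: int, penalty: float) -> float:
    if not mask.any():
        return 0.0
    clf = make_pipeline(StandardScaler(), LinearSVC(random_state=0))
    skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=cv_seed)
    Xm = X[:, mask]
    accs = []
    for tr, te in skf.split(Xm, y):
        clf.fit(Xm[tr], y[tr])
        accs.append(float(np.mean(clf.predict(Xm[te]) == y[te])))
    return float(np.mean(accs)) - penalty * (mask.sum() / mask.size)


def evaluate_fitness(
    position: np.ndarray, X: np.ndarray, y: np.ndarray, cv_seed: int = 0, penalty: float = 0.01
) -> float:
    """Fitness of one spider: 3-fold linear-SVM accuracy of its binarized mask,
    minus ``penalty * |mask|/d``.  Empty masks score 0."""
    X, y = _validate_dataset(X, y)
    mask = np.asarray(position, dtype=float).ravel() >= 0.5
    return _mask_fitness(mask, X, y, cv_seed, penalty)


def spider_weights(fitness: np.ndarray) -> np.ndarray:
    """Min-max normalized fitness; all ones when every spider ties."""
    f = np.asarray(fitness, dtype=float)
    best, worst = f.max(), f.min()
    if best == worst:
        return np.ones_like(f)
    return (f - worst) / (best - worst)


def spider_step(pop: SpiderPopulation, rng, ps: float = 0.7) -> SpiderPopulation:
    """One swarm iteration; returns the moved colony (best spider retained)."""
    if pop.fitness is None:
        raise StateError("spider_step requires evaluated fitness")
    rng = np.random.default_rng(rng)
    pos = pop.positions
    n, d = pos.shape
    w = spider_weights(pop.fitness)
    best_idx = int(np.argmax(pop.fitness))
    s_best = pos[best_idx]
    new_pos = pos.copy()

    sq_dists = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=2)
    degenerate = bool(pop.fitness.max() == pop.fitness.min())

    for i in range(n):
        if i == best_idx:
            continue  # elitist bookkeeping: best position retained
        alpha, beta, delta, u = rng.random(4)
        drift = delta * (u - 0.5)
        if degenerate:  # no information in the colony: random drift only
            new_pos[i] = pos[i] + drift
            continue
        if pop.female[i]:
            better = np.nonzero(w > w[i])[0]
            if better.size:
                c = better[np.argmin(sq_dists[i, better])]
                f_vib = w[c] * np.exp(-sq_dists[i, c])
                attract = alpha * f_vib * (pos[c] - pos[i])
            else:
                attract = np.zeros(d)
            v_vib = w[best_idx] * np.exp(-sq_dists[i, best_idx])
            pull = beta * v_vib * (s_best - pos[i])
            sign = 1.0 if rng.random() < ps else -1.0
            new_pos[i] = pos[i] + sign * (attract + pull) + drift
        else:
            males = np.nonzero(~pop.female)[0]
            females = np.nonzero(pop.female)[0]
            median_w = np.median(w[males]) if males.size else 0.0
            if w[i] > median_w and females.size:
                target = pos[females[np.argmin(sq_dists[i, females])]]
            else:
                target = pos[males].mean(axis=0) if males.size else pos[i]
            new_pos[i] = pos[i] + alpha * (target - pos[i]) + drift

    np.clip(new_pos, 0.0, 1.0, out=new_pos)
    return SpiderPopulation(
        positions=new_pos,
        female=pop.female.copy(),
        fitness=None,
        weights=w,
        iteration=pop.iteration + 1,
    )


def compute_feature_weights(X: np.ndarray, inclusion_freq: np.ndarray | None = None) -> FeatureWeights:
    """Per-feature weights: magnitude share, modal-decile frequency, and rank.

    ``wei`` is each feature's mean absolute value divided by the sum over
    features (sums to 1); ``w_val`` is the fraction of samples falling in the
    modal decile bin of that feature; ``w_tx = wei * w_val``.  The final rank
    score multiplies ``w_tx`` by the swarm inclusion frequency (when supplied)
    and is min-max rescaled to [0,1].
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.size == 0:
        raise InvalidInputError("dataset must be a non-empty 2-D array")
    n, d = X.shape

    mags = np.mean(np.abs(X), axis=0)
    if np.any(mags == 0):
        warnings.warn("all-zero feature column(s): magnitude weight set to 0")
    total = mags.sum()
    if total == 0:
        warnings.warn("all features are identically zero; uniform magnitude weights used")
        wei = np.full(d, 1.0 / d)
    else:
        wei = mags / total

    w_val = np.empty(d)
    for a in range(d):
        counts, _ = np.histogram(X[:, a], bins=10)
        w_val[a] = counts.max() / n

    w_tx = wei * w_val
    rank = w_tx * (inclusion_freq if inclusion_freq is not None else 1.0)
    lo, hi = rank.min(), rank.max()
    rank = np.full(d, 0.5) if hi == lo else (rank - lo) / (hi - lo)
    return FeatureWeights(wei=wei, w_val=w_val, w_tx=w_tx, inclusion_freq=inclusion_freq, rank=rank)


def recursive_feature_elimination(
    X: np.ndarray,
    y: np.ndarray,
    weights: FeatureWeights,
    cv_seed: int = 0,
    penalty: float = 0.01,
    tol: float = 0.005,
    min_features: int = 2,
    raw_branch: bool = False,
    fitness_cache: dict | None = None,
) -> FeatureSelectionResult:
    """Remove features, weakest rank first, whenever removal does not hurt.

    For each candidate (ascending rank score) the oracle scores the current
    set (C1) and the set without the candidate (C2) under a fixed CV seed;
    the removal is accepted when ``C2 >= C1 - tol`` (or strictly ``C2 > C1``
    in ``raw_branch`` mode, the literal printed comparison).  Stops at a floor
    of ``min_features`` features.
    """
    X, y = _validate_dataset(X, y)
    d = X.shape[1]
    cache = fitness_cache if fitness_cache is not None else {}

    def score(idx: list[int]) -> float:
        mask = np.zeros(d, dtype=bool)
        mask[idx] = True
        key = tuple(mask.nonzero()[0])
        if key not in cache:
            cache[key] = _mask_fitness(mask, X, y, cv_seed, penalty)
        return cache[key]

    config = {"tol": tol, "min_features": min_features, "penalty": penalty, "raw_branch": raw_branch}
    if d < 2:
        return FeatureSelectionResult([0], list(map(float, weights.rank)), [], [], cv_seed, config)

    order = list(np.argsort(weights.rank, kind="stable"))
    current = list(range(d))
    trace = []
    # recursive passes: re-attempt removals until a full pass confirms every
    # remaining feature (no removal accepted) or the floor is reached
    while len(current) > min_features:
        removed_any = False
        for f in [f for f in order if f in current]:
            if len(current) <= min_features:
                break
            c1 = score(current)
            reduced = [g for g in current if g != f]
            c2 = score(reduced)
            removed = (c2 > c1) if raw_branch else (c2 >= c1 - tol)
            trace.append({"feature": int(f), "c1": c1, "c2": c2, "removed": bool(removed)})
            if removed:
                current = reduced
                removed_any = True
        if not removed_any:
            break
    return FeatureSelectionResult(
        selected=sorted(int(f) for f in current),
        rank_scores=[float(r) for r in weights.rank],
        fitness_trace=[],
        elimination_trace=trace,
        seed=cv_seed,
        config=config,
    )


def run_rsso(
    X: np.ndarray,
    y: np.ndarray,
    n_spiders: int = 20,
    n_iterations: int = 50,
    seed: int = 0,
    ps: float = 0.7,
    penalty: float = 0.01,
    tol: float = 0.005,
    min_features: int = 2,
    raw_branch: bool = False,
) -> FeatureSelectionResult:
    """Full selection run: swarm search, feature weighting, recursive
    elimination.  Fully reproducible from ``seed``."""
    X, y = _validate_dataset(X, y)
    d = X.shape[1]
    rng = np.random.default_rng(seed)
    cv_seed = int(seed) % (2**31)
    cache: dict = {}

    def fitness_of(position: np.ndarray) -> float:
        mask = position >= 0.5
        key = tuple(np.nonzero(mask)[0])
        if key not in cache:
            cache[key] = _mask_fitness(mask, X, y, cv_seed, penalty)
        return cache[key]

    pop = init_population(d, n_spiders, rng)
    inclusion_counts = np.zeros(d)
    n_top = max(1, n_spiders // 2)
    fitness_trace = []
    for _ in range(n_iterations):
        pop.fitness = np.array([fitness_of(p) for p in pop.positions])
        fitness_trace.append(float(pop.fitness.max()))
        top = np.argsort(pop.fitness, kind="stable")[::-1][:n_top]
        inclusion_counts += (pop.positions[top] >= 0.5).sum(axis=0)
        pop = spider_step(pop, rng, ps=ps)

    denom = max(1, n_iterations) * n_top
    weights = compute_feature_weights(X, inclusion_freq=inclusion_counts / denom)
    result = recursive_feature_elimination(
        X,
        y,
        weights,
        cv_seed=cv_seed,
        penalty=penalty,
        tol=tol,
        min_features=min_features,
        raw_branch=raw_branch,
        fitness_cache=cache,
    )
    result.fitness_trace = fitness_trace
    result.seed = int(seed)
    result.config.update(
        {"n_spiders": n_spiders, "n_iterations": n_iterations, "ps": ps, "seed": int(seed)}
    )
    return result
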