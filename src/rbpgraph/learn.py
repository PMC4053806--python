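"""Model fitting and evaluation.

Classification is a linear model on the explicit kernel features, trained by
minimizing the lambda-regularized hinge loss with Pegasos-style stochastic
gradient descent (learning rate 1/(lambda*(t + t0)), t0 = 1/lambda, seeded
per-epoch shuffling, unregularized bias).  Regression is epsilon-insensitive
support vector regression solved by scikit-learn's LinearSVR; the contract
is the convex optimum, not the algorithm.  Evaluation uses AUROC
(Mann-Whitney, ties counted half) and average precision (mean precision at
each positive's rank); improvements are reported as the relative error
reduction (x' - x) / (1 - x).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVR

from .kernel import KernelParams


@dataclass(frozen=True)
class ClassifierParams:
    lambda_: float = 1e-4
    epochs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_ <= 0:
            raise ValueError("lambda must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass(frozen=True)
class RegressionParams:
    c: float = 1.0
    epsilon: float = 0.1

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("c must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")


class LinearModel:
    """A trained linear predictor over hashed kernel features."""

    def __init__(self, kind: str, weights: np.ndarray, bias: float,
                 kernel_params: KernelParams, mode: str = "sequence",
                 meta: dict | None = None):
        if kind not in ("classification", "regression"):
            raise ValueError("kind must be classification or regression")
        if not np.all(np.isfinite(weights)):
            raise ValueError("non-finite weights")
        self.kind = kind
        self.weights = np.asarray(weights, dtype=np.float64)
        self.bias = float(bias)
        self.kernel_params = kernel_params
        self.mode = mode
        self.meta = meta or {}

    # -- prediction --------------------------------------------------------
    def margin(self, X) -> np.ndarray:
        """Prediction margin(s): weights . x + bias."""
        X = _as_matrix(X, self.kernel_params)
        return np.asarray(X @ self.weights).ravel() + self.bias

    # -- persistence -------------------------------------------------------
    FORMAT = "rbpgraph-model/1"

    def save(self, path) -> None:
        nz = np.flatnonzero(self.weights)
        payload = {
            "format": self.FORMAT,
            "kind": self.kind,
            "mode": self.mode,
            "bias": self.bias.hex(),
            "dim": int(self.weights.size),
            "kernel_params": asdict(self.kernel_params),
            "weights": {int(i): float(self.weights[i]).hex() for i in nz},
            "meta": self.meta,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True, indent=0)

    @classmethod
    def load(cls, path) -> "LinearModel":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != cls.FORMAT:
            raise ValueError("unrecognized model file format")
        w = np.zeros(payload["dim"])
        for i, v in payload["weights"].items():
            w[int(i)] = float.fromhex(v)
        kp = KernelParams(**payload["kernel_params"])
        return cls(payload["kind"], w, float.fromhex(payload["bias"]), kp,
                   payload["mode"], payload.get("meta", {}))


def _as_matrix(X, params: KernelParams | None = None):
    if sparse.issparse(X):
        return X.tocsr()
    from .kernel import SparseFeatureVector, vectors_to_csr
    if isinstance(X, SparseFeatureVector):
        X = [X]
    if isinstance(X, (list, tuple)) and X and isinstance(X[0], SparseFeatureVector):
        return vectors_to_csr(X, params or X[0].params)
    return np.atleast_2d(np.asarray(X, dtype=np.float64))


# ---------------------------------------------------------------------------
# training

def train_classifier(X, labels: Sequence[int], params: ClassifierParams,
                     kernel_params: KernelParams | None = None,
                     mode: str = "sequence") -> LinearModel:
    """Pegasos SGD on the regularized hinge loss; deterministic under seed."""
    kernel_params = kernel_params or _infer_params(X)
    X = _as_matrix(X, kernel_params)
    y = np.asarray(labels, dtype=np.float64)
    if set(np.unique(y)) != {-1.0, 1.0}:
        raise ValueError("need both classes, labeled +1/-1")
    n, dim = X.shape
    rng = np.random.default_rng(params.seed)
    lam = params.lambda_
    w = np.zeros(dim)
    w_scale = 1.0
    b = 0.0
    t0 = 1.0 / lam
    t = 0
    indptr, indices, data = X.indptr, X.indices, X.data
    for _ in range(params.epochs):
        for i in rng.permutation(n):
            t += 1
            eta = 1.0 / (lam * (t + t0))
            w_scale *= max(1e-12, 1.0 - eta * lam)
            lo, hi = indptr[i], indptr[i + 1]
            idx, vals = indices[lo:hi], data[lo:hi]
            m = y[i] * (w_scale * float(w[idx] @ vals) + b)
            if m < 1.0:
                w[idx] += (eta * y[i] / w_scale) * vals
                b += eta * y[i]
            if w_scale < 1e-9:
                w *= w_scale
                w_scale = 1.0
    return LinearModel("classification", w * w_scale, b, kernel_params, mode,
                       meta={"classifier_params": asdict(params)})


def train_regressor(X, affinities: Sequence[float], params: RegressionParams,
                    kernel_params: KernelParams | None = None,
                    mode: str = "sequence") -> LinearModel:
    """Epsilon-insensitive linear SVR at trade-off c (convex optimum)."""
    kernel_params = kernel_params or _infer_params(X)
    X = _as_matrix(X, kernel_params)
    y = np.asarray(affinities, dtype=np.float64)
    if np.unique(y).size < 2:
        raise ValueError("need at least two distinct affinity values")
    svr = LinearSVR(C=params.c, epsilon=params.epsilon, loss="epsilon_insensitive",
                    tol=1e-6, max_iter=50000, random_state=0)
    svr.fit(X, y)
    return LinearModel("regression", svr.coef_.ravel(), float(np.ravel(svr.intercept_)[0]),
                       kernel_params, mode, meta={"regression_params": asdict(params)})


def _infer_params(X) -> KernelParams:
    from .kernel import SparseFeatureVector
    if isinstance(X, (list, tuple)) and X and isinstance(X[0], SparseFeatureVector):
        return X[0].params
    return KernelParams()


def margin(model: LinearModel, vector) -> float | np.ndarray:
    """Margin of one vector (or a matrix of vectors) under a trained model."""
    from .kernel import SparseFeatureVector
    if isinstance(vector, SparseFeatureVector):
        if vector.params != model.kernel_params:
            raise ValueError("vector and model use different kernel parameters")
        return float(model.margin([vector])[0])
    return model.margin(vector)


# ---------------------------------------------------------------------------
# metrics

def auroc(margins: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney AUROC; tied margins contribute one half."""
    y = np.asarray(labels)
    m = np.asarray(margins, dtype=np.float64)
    pos, neg = m[y > 0], m[y < 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUROC requires both classes")
    ranks = rankdata(m)  # average ranks handle ties -> 1/2 contribution
    r_pos = ranks[y > 0].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size))


def average_precision(margins: Sequence[float], labels: Sequence[int]) -> float:
    """Mean precision at each positive's rank, descending margins, stable ties."""
    y = np.asarray(labels)
    m = np.asarray(margins, dtype=np.float64)
    if not np.any(y > 0):
        raise ValueError("average precision requires at least one positive")
    order = np.argsort(-m, kind="stable")
    hits = 0
    precisions = []
    for rank, i in enumerate(order, start=1):
        if y[i] > 0:
            hits += 1
            precisions.append(hits / rank)
    return float(np.mean(precisions))


def relative_error_reduction(x: float, x_prime: float) -> float:
    """(x' - x) / (1 - x): improvement relative to the remaining error."""
    if x >= 1.0:
        raise ValueError("baseline performance must be below 1")
    return (x_prime - x) / (1.0 - x)


# ---------------------------------------------------------------------------
# cross-validation and hyperparameter search

@dataclass
class CVResult:
    fold_scores: list[float]
    margins: np.ndarray
    metric: str = "auroc"

    @property
    def mean_score(self) -> float:
        return float(np.mean(self.fold_scores))


def crossvalidate(X, labels: Sequence[int], params: ClassifierParams,
                  k: int = 10, seed: int = 0,
                  kernel_params: KernelParams | None = None) -> CVResult:
    """Stratified k-fold CV; every example predicted exactly once."""
    kernel_params = kernel_params or _infer_params(X)
    X = _as_matrix(X, kernel_params)
    y = np.asarray(labels)
    counts = [np.sum(y == c) for c in np.unique(y)]
    if len(counts) != 2 or min(counts) < k:
        raise ValueError(f"need >= {k} examples per class for {k}-fold CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_scores = []
    all_margins = np.zeros(len(y))
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        model = train_classifier(X[train_idx], y[train_idx], params, kernel_params)
        m = model.margin(X[test_idx])
        all_margins[test_idx] = m
        fold_scores.append(auroc(m, y[test_idx]))
    return CVResult(fold_scores, all_margins)


def tuning_subset(labels: Sequence[int], seed: int,
                  cap: int = 1000, fraction: float = 0.1) -> np.ndarray:
    """Stratified indices of min(cap, floor(fraction*n)) tuning examples."""
    y = np.asarray(labels)
    n = len(y)
    size = min(cap, int(np.floor(fraction * n)))
    if size < 2:
        raise ValueError("too few examples for a tuning subset")
    rng = np.random.default_rng(seed)
    idx: list[int] = []
    classes = np.unique(y)
    for c in classes:
        members = np.flatnonzero(y == c)
        take = max(1, int(round(size * members.size / n)))
        idx.extend(rng.choice(members, size=min(take, members.size), replace=False))
    out = np.sort(np.asarray(idx[:size]))
    if len(np.unique(y[out])) < len(classes):
        raise ValueError("tuning subset does not contain every class")
    return out


def line_search(score_fn: Callable[[Mapping], float],
                grids: Mapping[str, Sequence],
                start: Mapping | None = None,
                max_rounds: int = 3) -> tuple[dict, float]:
    """Round-robin coordinate search: optimize one parameter at a time over
    its grid, all others fixed, cycling until a full round changes nothing."""
    if not grids or any(len(v) == 0 for v in grids.values()):
        raise ValueError("grids must be nonempty")
    current = {name: vals[0] for name, vals in grids.items()}
    if start:
        current.update({k: v for k, v in start.items() if k in grids})
    best_score = score_fn(current)
    for _ in range(max_rounds):
        changed = False
        for name, values in grids.items():
            for v in values:
                if v == current[name]:
                    continue
                trial = dict(current, **{name: v})
                s = score_fn(trial)
                if s > best_score:
                    best_score, current, changed = s, trial, True
        if not changed:
            break
    return current, best_score


def line_search_classifier(X, labels: Sequence[int],
                           grids: Mapping[str, Sequence],
                           seed: int = 0, cv_k: int = 5,
                           kernel_params: KernelParams | None = None
                           ) -> tuple[ClassifierParams, np.ndarray, float]:
    """Fit classifier hyperparameters on a held-aside tuning subset.

    Returns the chosen parameters, the indices of the examples that remain
    for the performance assessment (the tuning subset is discarded from it),
    and the tuning score.
    """
    kernel_params = kernel_params or _infer_params(X)
    Xm = _as_matrix(X, kernel_params)
    y = np.asarray(labels)
    tune_idx = tuning_subset(y, seed)
    rest = np.setdiff1d(np.arange(len(y)), tune_idx)
    Xt, yt = Xm[tune_idx], y[tune_idx]
    k_eff = min(cv_k, int(min(np.sum(yt > 0), np.sum(yt < 0))))

    def score(cfg: Mapping) -> float:
        p = ClassifierParams(lambda_=cfg.get("lambda_", 1e-4),
                             epochs=int(cfg.get("epochs", 10)), seed=seed)
        return crossvalidate(Xt, yt, p, k=k_eff, seed=seed,
                             kernel_params=kernel_params).mean_score

    best_cfg, best = line_search(score, grids)
    params = ClassifierParams(lambda_=best_cfg.get("lambda_", 1e-4),
                              epochs=int(best_cfg.get("epochs", 10)), seed=seed)
    return params, rest, best
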