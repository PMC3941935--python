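"""From-scratch multilayer perceptron classifier.

Architecture: 9 standardized inputs -> tanh hidden layer (default 10 nodes,
with bias) -> softmax output over the class names.  Training is full-batch
gradient descent on the total cross-entropy with a backtracking line search,
so every accepted iteration strictly reduces the loss; training stops when
no step in the backtracking schedule helps, when the relative improvement
drops below tolerance, or at the iteration cap.

Model selection/validation follows repeated random subsampling: each run
re-partitions the samples independently (Bernoulli assignment to training),
trains from a fresh random initialization, and reports percent correct on
both partitions; the report carries the per-run values and their mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "StandardizationParams",
    "TrainConfig",
    "MLPModel",
    "CVReport",
    "ImportanceTable",
    "round1",
    "softmax",
    "standardize_fit",
    "standardize_apply",
    "mlp_forward",
    "cross_entropy",
    "mlp_train",
    "gradient_check",
    "random_split",
    "split_summary",
    "repeated_cv",
    "per_class_accuracy",
    "variable_importance",
]

_P_CLAMP = 1e-12


def round1(x: float) -> float:
    """Round to one decimal, half up (matches the reported percentages)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StandardizationParams:
    mean: np.ndarray
    sd: np.ndarray  # sample standard deviation (n-1 denominator)


def standardize_fit(X: np.ndarray, feature_names=None) -> StandardizationParams:
    """Per-feature mean/sd from *training* rows only."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(X) < 2:
        raise ValueError("standardization requires a 2-D table with at least 2 rows")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    bad = np.nonzero(sd == 0)[0]
    if len(bad):
        names = (
            [feature_names[i] for i in bad]
            if feature_names is not None
            else [f"column {i}" for i in bad]
        )
        raise ValueError(f"constant feature(s) cannot be standardized: {', '.join(map(str, names))}")
    return StandardizationParams(mean=mean, sd=sd)


def standardize_apply(X: np.ndarray, params: StandardizationParams) -> np.ndarray:
    return (np.asarray(X, dtype=float) - params.mean) / params.sd


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

def softmax(v: np.ndarray) -> np.ndarray:
    """Numerically stable softmax along the last axis."""
    v = np.asarray(v, dtype=float)
    shifted = v - v.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass(frozen=True)
class TrainConfig:
    step0: float = 0.5
    backtrack: float = 0.5
    max_backtracks: int = 30
    tol: float = 1e-8
    max_iter: int = 5000
    init_range: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.step0 <= 0 or not 0 < self.backtrack < 1 or self.tol < 0:
            raise ValueError("invalid training configuration")


@dataclass
class MLPModel:
    """Weights, biases, class names and standardization of one trained net."""

    W1: np.ndarray  # (hidden, n_in)
    b1: np.ndarray  # (hidden,)
    W2: np.ndarray  # (n_classes, hidden)
    b2: np.ndarray  # (n_classes,)
    class_names: tuple[str, ...]
    standardization: StandardizationParams
    seed: int = 0

    def __post_init__(self):
        h, d = self.W1.shape
        k = self.W2.shape[0]
        if self.W2.shape[1] != h or self.b1.shape != (h,) or self.b2.shape != (k,):
            raise ValueError("inconsistent weight shapes")
        if len(set(self.class_names)) != len(self.class_names):
            raise ValueError("class names must be unique")

    @property
    def n_inputs(self) -> int:
        return self.W1.shape[1]

    def predict_proba(self, X_raw: np.ndarray) -> np.ndarray:
        """Probabilities for raw (unstandardized) feature rows."""
        return mlp_forward(self, standardize_apply(np.atleast_2d(X_raw), self.standardization))

    def predict(self, X_raw: np.ndarray) -> list[str]:
        probs = self.predict_proba(X_raw)
        return [self.class_names[i] for i in probs.argmax(axis=1)]

    # -- JSON round trip -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "layer_sizes": [self.n_inputs, self.W1.shape[0], self.W2.shape[0]],
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "W2": self.W2.tolist(),
            "b2": self.b2.tolist(),
            "class_names": list(self.class_names),
            "standardization": {
                "mean": self.standardization.mean.tolist(),
                "sd": self.standardization.sd.tolist(),
            },
            "seed": self.seed,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "MLPModel":
        return cls(
            W1=np.asarray(d["W1"], dtype=float),
            b1=np.asarray(d["b1"], dtype=float),
            W2=np.asarray(d["W2"], dtype=float),
            b2=np.asarray(d["b2"], dtype=float),
            class_names=tuple(d["class_names"]),
            standardization=StandardizationParams(
                mean=np.asarray(d["standardization"]["mean"], dtype=float),
                sd=np.asarray(d["standardization"]["sd"], dtype=float),
            ),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def load(cls, path) -> "MLPModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def mlp_forward(model: MLPModel, X_std: np.ndarray) -> np.ndarray:
    """Forward pass on standardized inputs; returns class probabilities."""
    X = np.atleast_2d(np.asarray(X_std, dtype=float))
    if X.shape[1] != model.n_inputs:
        raise ValueError(f"expected {model.n_inputs} features, got {X.shape[1]}")
    hidden = np.tanh(X @ model.W1.T + model.b1)
    return softmax(hidden @ model.W2.T + model.b2)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Total cross-entropy, sum of -ln p(true class) over the batch.

    Probabilities are clamped to >= 1e-12 so the loss stays finite.
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    labels = np.atleast_1d(np.asarray(labels, dtype=int))
    if labels.min() < 0 or labels.max() >= probs.shape[1]:
        raise ValueError("label index out of range")
    p = np.clip(probs[np.arange(len(labels)), labels], _P_CLAMP, None)
    return float(-np.log(p).sum())


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _loss_and_grads(W1, b1, W2, b2, X, Y):
    """Total cross-entropy and its gradients; Y is one-hot (n, K)."""
    Z1 = X @ W1.T + b1
    H = np.tanh(Z1)
    P = softmax(H @ W2.T + b2)
    idx = Y.argmax(axis=1)
    loss = float(-np.log(np.clip(P[np.arange(len(X)), idx], _P_CLAMP, None)).sum())
    dZ2 = P - Y  # (n, K)
    gW2 = dZ2.T @ H
    gb2 = dZ2.sum(axis=0)
    dH = dZ2 @ W2
    dZ1 = dH * (1 - H**2)
    gW1 = dZ1.T @ X
    gb1 = dZ1.sum(axis=0)
    return loss, (gW1, gb1, gW2, gb2)


def mlp_train(
    X_raw: np.ndarray,
    labels,
    hidden: int = 10,
    cfg: TrainConfig = TrainConfig(),
    class_names=None,
) -> tuple[MLPModel, list[float]]:
    """Train on raw features; standardization is fitted on these rows.

    Returns the model and the loss trajectory (accepted iterations only,
    strictly decreasing by construction).
    """
    X_raw = np.asarray(X_raw, dtype=float)
    labels = [str(v) for v in labels]
    if class_names is None:
        class_names = tuple(sorted(set(labels)))
    else:
        class_names = tuple(class_names)
    missing = [c for c in class_names if c not in set(labels)]
    if missing or not set(labels) <= set(class_names):
        raise ValueError(
            f"every class needs at least one training sample; missing: {missing}, "
            f"unknown labels: {sorted(set(labels) - set(class_names))}"
        )
    y = np.array([class_names.index(v) for v in labels])
    Y = np.eye(len(class_names))[y]

    params = standardize_fit(X_raw)
    X = standardize_apply(X_raw, params)

    rng = np.random.default_rng(cfg.seed)
    r = cfg.init_range
    W1 = rng.uniform(-r, r, size=(hidden, X.shape[1]))
    b1 = rng.uniform(-r, r, size=hidden)
    W2 = rng.uniform(-r, r, size=(len(class_names), hidden))
    b2 = rng.uniform(-r, r, size=len(class_names))

    loss, grads = _loss_and_grads(W1, b1, W2, b2, X, Y)
    trajectory = [loss]
    for _ in range(cfg.max_iter):
        step = cfg.step0
        accepted = None
        for _ in range(cfg.max_backtracks):
            cand = (
                W1 - step * grads[0],
                b1 - step * grads[1],
                W2 - step * grads[2],
                b2 - step * grads[3],
            )
            new_loss, new_grads = _loss_and_grads(*cand, X, Y)
            if new_loss < loss:
                accepted = (cand, new_loss, new_grads)
                break
            step *= cfg.backtrack
        if accepted is None:
            break  # no error reduction possible: stop
        (W1, b1, W2, b2), new_loss, grads = accepted
        trajectory.append(new_loss)
        if (loss - new_loss) <= cfg.tol * max(abs(loss), 1e-30):
            loss = new_loss
            break
        loss = new_loss

    model = MLPModel(
        W1=W1, b1=b1, W2=W2, b2=b2,
        class_names=class_names, standardization=params, seed=cfg.seed,
    )
    return model, trajectory


def gradient_check(model: MLPModel, X_std: np.ndarray, labels: np.ndarray, h: float = 1e-6) -> float:
    """Max relative error between backprop and central finite differences."""
    X = np.atleast_2d(np.asarray(X_std, dtype=float))
    y = np.atleast_1d(np.asarray(labels, dtype=int))
    Y = np.eye(len(model.class_names))[y]
    tensors = [model.W1.copy(), model.b1.copy(), model.W2.copy(), model.b2.copy()]
    _, grads = _loss_and_grads(*tensors, X, Y)
    worst = 0.0
    for t, g in zip(tensors, grads):
        it = np.nditer(t, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = t[idx]
            t[idx] = orig + h
            lp, _ = _loss_and_grads(*tensors, X, Y)
            t[idx] = orig - h
            lm, _ = _loss_and_grads(*tensors, X, Y)
            t[idx] = orig
            fd = (lp - lm) / (2 * h)
            denom = max(abs(fd), abs(g[idx]), 1e-8)
            worst = max(worst, abs(fd - g[idx]) / denom)
    return worst


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def split_summary(n_train: int, n_valid: int) -> dict:
    """Partition bookkeeping: counts plus percentages to one decimal."""
    pct_train = round1(100.0 * n_train / n_valid)
    return {
        "n_train": int(n_train),
        "n_test": int(n_valid - n_train),
        "n_valid": int(n_valid),
        "pct_train": pct_train,
        "pct_test": round1(100.0 - pct_train),
    }


def random_split(n: int, train_probability: float, seed: int) -> tuple[np.ndarray, np.ndarray, dict]:
    """Independent per-sample Bernoulli assignment to the training group.

    If either partition comes out empty, the draw is repeated with the seed
    incremented until both are non-empty.
    """
    if not 0 < train_probability < 1:
        raise ValueError("train_probability must be in (0, 1)")
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    s = seed
    while True:
        take = np.random.default_rng(s).random(n) < train_probability
        if take.any() and not take.all():
            break
        s += 1
    train_idx = np.nonzero(take)[0]
    test_idx = np.nonzero(~take)[0]
    return train_idx, test_idx, split_summary(len(train_idx), n)


@dataclass
class CVReport:
    """Per-run accuracies (%) of repeated random-split cross-validation."""

    training: list[float]
    testing: list[float]
    n_train: list[int] = field(default_factory=list)
    n_test: list[int] = field(default_factory=list)

    def __post_init__(self):
        if len(self.training) != len(self.testing) or not self.testing:
            raise ValueError("training and testing runs must align and be non-empty")
        for v in self.training + self.testing:
            if not 0 <= v <= 100:
                raise ValueError("accuracies must be percentages in [0, 100]")

    @property
    def n_runs(self) -> int:
        return len(self.testing)

    @property
    def mean_training(self) -> float:
        return round1(float(np.mean(self.training)))

    @property
    def mean_testing(self) -> float:
        return round1(float(np.mean(self.testing)))

    @classmethod
    def from_accuracies(cls, testing, training=None) -> "CVReport":
        testing = [float(v) for v in testing]
        training = [float(v) for v in training] if training is not None else [100.0] * len(testing)
        return cls(training=training, testing=testing)


def _accuracy_pct(model: MLPModel, X_raw: np.ndarray, labels) -> float:
    pred = model.predict(X_raw)
    return 100.0 * float(np.mean([p == t for p, t in zip(pred, [str(v) for v in labels])]))


def repeated_cv(
    X_raw: np.ndarray,
    labels,
    n_runs: int = 10,
    train_probability: float = 0.7,
    cfg: TrainConfig = TrainConfig(),
    hidden: int = 10,
) -> CVReport:
    """Repeated random-subsampling cross-validation.

    Run ``r`` uses seed ``cfg.seed + r`` for both the partition draw and the
    weight initialization.  If a draw leaves a training class empty, the
    split is redrawn with an incremented seed (training requires every class
    present).
    """
    X_raw = np.asarray(X_raw, dtype=float)
    labels = [str(v) for v in labels]
    classes = tuple(sorted(set(labels)))
    training, testing, n_trains, n_tests = [], [], [], []
    for run in range(n_runs):
        s = cfg.seed + run
        while True:
            train_idx, test_idx, _ = random_split(len(X_raw), train_probability, s)
            if set(labels[i] for i in train_idx) == set(classes):
                break
            s += 1000003  # redraw; large odd stride to avoid colliding with other runs
        run_cfg = TrainConfig(
            step0=cfg.step0, backtrack=cfg.backtrack, max_backtracks=cfg.max_backtracks,
            tol=cfg.tol, max_iter=cfg.max_iter, init_range=cfg.init_range, seed=cfg.seed + run,
        )
        model, _ = mlp_train(
            X_raw[train_idx], [labels[i] for i in train_idx],
            hidden=hidden, cfg=run_cfg, class_names=classes,
        )
        training.append(round1(_accuracy_pct(model, X_raw[train_idx], [labels[i] for i in train_idx])))
        testing.append(round1(_accuracy_pct(model, X_raw[test_idx], [labels[i] for i in test_idx])))
        n_trains.append(len(train_idx))
        n_tests.append(len(test_idx))
    return CVReport(training=training, testing=testing, n_train=n_trains, n_test=n_tests)


def per_class_accuracy(model: MLPModel, X_raw: np.ndarray, labels) -> dict:
    """Percent correct per class and overall, one decimal."""
    labels = [str(v) for v in labels]
    if any(v in ("", "None") for v in labels):
        raise ValueError("all rows must be labelled")
    pred = model.predict(np.asarray(X_raw, dtype=float))
    per_class = {}
    for cls in model.class_names:
        idx = [i for i, v in enumerate(labels) if v == cls]
        if idx:
            per_class[cls] = round1(100.0 * np.mean([pred[i] == cls for i in idx]))
    overall = round1(100.0 * np.mean([p == t for p, t in zip(pred, labels)]))
    return {"per_class": per_class, "overall": overall}


@dataclass
class ImportanceTable:
    feature_names: tuple[str, ...]
    raw: np.ndarray
    normalized: np.ndarray  # percent of the maximum, max row = 100.0

    def as_rows(self):
        order = np.argsort(self.normalized)[::-1]
        return [
            (self.feature_names[i], float(self.raw[i]), float(self.normalized[i]))
            for i in order
        ]


def variable_importance(
    model: MLPModel,
    X_raw: np.ndarray,
    labels,
    n_permutations: int = 100,
    seed: int = 0,
    feature_names=None,
) -> ImportanceTable:
    """Permutation importance on the total cross-entropy.

    Raw importance of a feature is the mean increase in total cross-entropy
    when that column is shuffled (clipped at 0); normalized importance puts
    the largest at 100%.
    """
    X = np.asarray(X_raw, dtype=float)
    labels = [str(v) for v in labels]
    y = np.array([model.class_names.index(v) for v in labels])
    if feature_names is None:
        feature_names = tuple(f"f{i}" for i in range(X.shape[1]))
    base = cross_entropy(model.predict_proba(X), y)
    rng = np.random.default_rng(seed)
    raw = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        deltas = np.empty(n_permutations)
        for p in range(n_permutations):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(len(X)), j]
            deltas[p] = cross_entropy(model.predict_proba(Xp), y) - base
        raw[j] = max(float(deltas.mean()), 0.0)
    top = raw.max()
    normalized = 100.0 * raw / top if top > 0 else np.zeros_like(raw)
    return ImportanceTable(feature_names=tuple(feature_names), raw=raw, normalized=normalized)
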