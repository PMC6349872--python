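"""Soft-margin kernel SVMs: training, tuning, decision values, calibration.

The binary classifier is the standard soft-margin SVM.  The dual program

    max_a  -1/2 sum_{i,j} a_i a_j y_i y_j K(x_i, x_j) + sum_i a_i
    s.t.   0 <= a_i <= C,  sum_i a_i y_i = 0

is solved by scikit-learn's SVC (libsvm); the fitted state kept in
:class:`SvmModel` is the support vectors, the products ``a_i * y_i``, and the
bias ``b``, from which :func:`decision_value` recomputes

    f(x) = sum_i a_i y_i K(x, x_i) + b

with this module's own kernel implementations.  Four kernels are supported:
linear ``x.y``, polynomial ``(gamma x.y + r)^d``, RBF
``exp(-gamma ||x-y||^2)`` and sigmoid ``tanh(gamma x.y + r)``, with default
bias r = 0, degree d = 3 and gamma = 1/(number of features).

Multi-class classification is one-vs-one: m(m-1)/2 pairwise binary SVMs
combined by majority voting (ties by summed decision-value magnitude, then
class name).  Probabilities come from Platt-calibrated pairwise models
coupled by the iterative pairwise-coupling scheme used in libsvm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "KernelConfig",
    "SvmModel",
    "MulticlassModel",
    "kernel_eval",
    "kernel_matrix",
    "train_binary_svm",
    "decision_value",
    "decision_values",
    "predict_binary",
    "predict_proba_binary",
    "tune_rbf",
    "train_multiclass",
    "predict_multiclass",
    "predict_proba_multiclass",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1

_KERNELS = ("linear", "polynomial", "rbf", "sigmoid")


@dataclass(frozen=True)
class KernelConfig:
    """Kernel family and hyper-parameters.

    ``gamma=None`` means the library default 1/(number of features),
    resolved at fit time against the training matrix.
    """

    kernel: str = "rbf"
    C: float = 1.0
    gamma: float | None = None
    coef0: float = 0.0
    degree: int = 3

    def __post_init__(self) -> None:
        if self.kernel not in _KERNELS:
            raise ValueError(f"unknown kernel {self.kernel!r}; choose from {_KERNELS}")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.degree < 1:
            raise ValueError("degree must be >= 1")

    def resolve_gamma(self, n_features: int) -> float:
        return self.gamma if self.gamma is not None else 1.0 / n_features

    def to_dict(self) -> dict:
        return {
            "kernel": self.kernel,
            "C": self.C,
            "gamma": self.gamma,
            "coef0": self.coef0,
            "degree": self.degree,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KernelConfig":
        return cls(d["kernel"], d["C"], d["gamma"], d["coef0"], d["degree"])


def kernel_matrix(config: KernelConfig, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """K(A_i, B_j) for all pairs; rows of A x rows of B."""
    A = np.atleast_2d(np.asarray(A, float))
    B = np.atleast_2d(np.asarray(B, float))
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"dimension mismatch: {A.shape[1]} vs {B.shape[1]}")
    gamma = config.resolve_gamma(A.shape[1])
    if config.kernel == "linear":
        return A @ B.T
    if config.kernel == "polynomial":
        return (gamma * (A @ B.T) + config.coef0) ** config.degree
    if config.kernel == "rbf":
        return np.exp(-gamma * cdist(A, B, "sqeuclidean"))
    return np.tanh(gamma * (A @ B.T) + config.coef0)


def kernel_eval(config: KernelConfig, x: np.ndarray, y: np.ndarray) -> float:
    """Kernel value K(x, y) for a single pair of feature vectors."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    return float(kernel_matrix(config, x[None, :], y[None, :])[0, 0])


def _fit_platt(decisions: np.ndarray, y_pos: np.ndarray) -> tuple[float, float]:
    """Platt sigmoid P(y=+1|f) = 1/(1+exp(A f + B)) with A <= 0 (monotone).

    Uses Platt's smoothed targets; deterministic (no internal resampling).
    """
    n_pos = int(y_pos.sum())
    n_neg = len(y_pos) - n_pos
    t = np.where(y_pos, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll(params: np.ndarray) -> float:
        a, b = params
        z = a * decisions + b
        # log(1+e^z) and z + log(1+e^-z), stable in both tails
        return float(np.sum(t * np.logaddexp(0.0, z) + (1 - t) * np.logaddexp(0.0, -z)))

    x0 = np.array([-1.0, np.log((n_neg + 1.0) / (n_pos + 1.0))])
    res = minimize(nll, x0, method="L-BFGS-B", bounds=[(-500.0, 0.0), (None, None)])
    return float(res.x[0]), float(res.x[1])


@dataclass
class SvmModel:
    """Fitted binary SVM state sufficient to reproduce decision values.

    ``center``/``scale`` hold the training-column standardization applied
    before the kernel (support vectors are stored already standardized).
    """

    support_vectors: np.ndarray          # (n_sv, n_features), standardized
    dual_coef: np.ndarray                # a_i * y_i per support vector
    intercept: float                     # bias b
    config: KernelConfig
    classes: tuple[str, str]             # (negative label, positive label)
    n_features: int
    calibration: tuple[float, float] | None = None   # Platt (A, B)
    center: np.ndarray | None = None     # per-feature mean, None = identity
    scale: np.ndarray | None = None      # per-feature sd, None = identity

    @property
    def neg_label(self) -> str:
        return self.classes[0]

    @property
    def pos_label(self) -> str:
        return self.classes[1]


def train_binary_svm(
    X: np.ndarray,
    y: Sequence[str],
    config: KernelConfig = KernelConfig(),
    *,
    pos_label: str | None = None,
    calibrate: bool = True,
    standardize: bool = True,
) -> SvmModel:
    """Fit a soft-margin binary SVM by solving the dual QP.

    The positive class defaults to the lexicographically larger label.
    With ``calibrate`` a monotone Platt sigmoid mapping decision values to
    positive-class probabilities is fitted on the training decisions.
    By default each feature column is standardized to zero mean and unit
    variance on the training set (the libsvm-frontend convention, under
    which the default gamma = 1/dimension is meaningful for compositional
    features); the transform is stored in the model and applied to queries.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, dtype=object)
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains non-finite values")
    labels = sorted(set(y))
    if len(labels) != 2:
        raise ValueError(f"binary SVM needs exactly 2 classes, got {labels}")
    if pos_label is None:
        pos_label = labels[1]
    if pos_label not in labels:
        raise ValueError(f"pos_label {pos_label!r} not among {labels}")
    neg_label = labels[0] if labels[1] == pos_label else labels[1]
    y_num = np.where(y == pos_label, 1, -1)

    center = scale = None
    if standardize:
        center = X.mean(axis=0)
        scale = X.std(axis=0, ddof=1)
        scale[scale == 0] = 1.0   # constant columns pass through centered
        X = (X - center) / scale

    gamma = config.resolve_gamma(X.shape[1])
    sk_kernel = {"polynomial": "poly"}.get(config.kernel, config.kernel)
    svc = SVC(
        kernel=sk_kernel,
        C=config.C,
        gamma=gamma,
        coef0=config.coef0,
        degree=config.degree,
    )
    svc.fit(X, y_num)
    model = SvmModel(
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_[0].copy(),
        intercept=float(svc.intercept_[0]),
        config=replace(config, gamma=gamma),
        classes=(neg_label, pos_label),
        n_features=X.shape[1],
        center=center,
        scale=scale,
    )
    if calibrate:
        raw = X * scale + center if standardize else X
        model.calibration = _fit_platt(decision_values(model, raw), y_num == 1)
    return model


def decision_values(model: SvmModel, X: np.ndarray) -> np.ndarray:
    """f(x) = sum_i a_i y_i K(x, x_i) + b for each row of X."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {X.shape[1]}"
        )
    if model.center is not None:
        X = (X - model.center) / model.scale
    K = kernel_matrix(model.config, X, model.support_vectors)
    return K @ model.dual_coef + model.intercept


def decision_value(model: SvmModel, x: np.ndarray) -> float:
    """Decision value for a single query vector."""
    return float(decision_values(model, np.asarray(x, float)[None, :])[0])


def predict_binary(model: SvmModel, X: np.ndarray) -> np.ndarray:
    """Predicted labels; a decision value of exactly 0 goes to the positive class."""
    d = decision_values(model, X)
    return np.where(d >= 0, model.pos_label, model.neg_label).astype(object)


def predict_proba_binary(model: SvmModel, X: np.ndarray) -> np.ndarray:
    """Calibrated P(positive class) per row; requires a calibrated model."""
    if model.calibration is None:
        raise ValueError("model was trained without calibration")
    a, b = model.calibration
    return expit(-(a * decision_values(model, X) + b))


def tune_rbf(
    X: np.ndarray,
    y: Sequence[str],
    C_grid: Sequence[float] | None = None,
    gamma_grid: Sequence[float] | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[tuple[float, float], "pd.DataFrame"]:
    """Grid-search (C, gamma) for the RBF kernel by stratified n-fold CV accuracy.

    Default grids are C in {2^-5 .. 2^15} and gamma in {2^-15 .. 2^-5}, each
    stepped by a factor of 2.  Ties are broken toward smaller C, then smaller
    gamma.  Returns the best pair and the full accuracy table.
    """
    import pandas as pd

    if C_grid is None:
        C_grid = [2.0**e for e in range(-5, 16)]
    if gamma_grid is None:
        gamma_grid = [2.0**e for e in range(-15, -4)]
    C_grid, gamma_grid = list(C_grid), list(gamma_grid)
    if not C_grid or not gamma_grid:
        raise ValueError("C_grid and gamma_grid must be non-empty")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    X = np.asarray(X, float)
    y = np.asarray(y, dtype=object)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y.astype(str)))
    rows = []
    best: tuple[float, tuple[float, float]] | None = None
    for C in sorted(C_grid):
        for gamma in sorted(gamma_grid):
            config = KernelConfig("rbf", C=C, gamma=gamma)
            correct = 0
            for train_idx, test_idx in folds:
                m = train_binary_svm(
                    X[train_idx], y[train_idx], config, calibrate=False
                )
                correct += int(
                    (predict_binary(m, X[test_idx]) == y[test_idx]).sum()
                )
            acc = correct / len(y)
            rows.append({"C": C, "gamma": gamma, "cv_accuracy": acc})
            if best is None or acc > best[0]:
                best = (acc, (C, gamma))
    return best[1], pd.DataFrame(rows)


@dataclass
class MulticlassModel:
    """One-vs-one ensemble: one binary SvmModel per unordered class pair."""

    classes: list[str]
    pairwise: dict[tuple[str, str], SvmModel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = len(self.classes)
        expected = m * (m - 1) // 2
        if self.pairwise and len(self.pairwise) != expected:
            raise ValueError(
                f"{len(self.pairwise)} pairwise models for {m} classes; "
                f"expected {expected}"
            )


def train_multiclass(
    X: np.ndarray,
    y: Sequence[str],
    config: KernelConfig = KernelConfig(),
    *,
    calibrate: bool = True,
) -> MulticlassModel:
    """Fit the one-vs-one ensemble over m >= 3 classes.

    In each pairwise model the lexicographically larger class of the pair is
    the positive class.  Calibration is needed only when coupled class
    probabilities are requested.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, dtype=object)
    classes = sorted(set(y))
    if len(classes) < 3:
        raise ValueError(f"multi-class model needs >= 3 classes, got {classes}")
    small = [c for c in classes if (y == c).sum() < 2]
    if small:
        raise ValueError(f"classes with fewer than 2 members: {small}")
    model = MulticlassModel(classes=classes)
    for a, b in combinations(classes, 2):
        mask = (y == a) | (y == b)
        model.pairwise[(a, b)] = train_binary_svm(
            X[mask], y[mask], config, pos_label=b, calibrate=calibrate
        )
    return model


def _vote_rows(model: MulticlassModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row vote counts and decision-magnitude sums, classes in model order."""
    X = np.atleast_2d(np.asarray(X, float))
    idx = {c: i for i, c in enumerate(model.classes)}
    votes = np.zeros((X.shape[0], len(model.classes)))
    magnitude = np.zeros_like(votes)
    for (a, b), sub in model.pairwise.items():
        d = decision_values(sub, X)
        b_wins = d >= 0
        votes[b_wins, idx[b]] += 1
        votes[~b_wins, idx[a]] += 1
        magnitude[b_wins, idx[b]] += np.abs(d[b_wins])
        magnitude[~b_wins, idx[a]] += np.abs(d[~b_wins])
    return votes, magnitude


def predict_multiclass(model: MulticlassModel, X: np.ndarray) -> np.ndarray:
    """Majority-vote labels; ties by summed decision magnitude, then name."""
    votes, magnitude = _vote_rows(model, X)
    out = []
    for v, m in zip(votes, magnitude):
        # lexicographically smallest among maximal (votes, magnitude)
        order = sorted(
            range(len(model.classes)), key=lambda i: (-v[i], -m[i], model.classes[i])
        )
        out.append(model.classes[order[0]])
    return np.array(out, dtype=object)


def _couple_pairwise(R: np.ndarray, max_iter: int = 200, eps: float = 1e-12) -> np.ndarray:
    """Couple pairwise probabilities into class probabilities (libsvm scheme).

    R[i, j] = P(class i | class i or j, x), R[j, i] = 1 - R[i, j].
    Solves min_p sum_{i<j} (R[j,i] p_i - R[i,j] p_j)^2 s.t. sum p = 1 by the
    fixed-point iteration of Wu, Lin & Weng as implemented in libsvm.
    """
    k = R.shape[0]
    Q = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if i == j:
                Q[i, i] = sum(R[j2, i] ** 2 for j2 in range(k) if j2 != i)
            else:
                Q[i, j] = -R[j, i] * R[i, j]
    p = np.full(k, 1.0 / k)
    for _ in range(max_iter):
        Qp = Q @ p
        pQp = p @ Qp
        if np.max(np.abs(Qp - pQp)) < eps:
            break
        for i in range(k):
            diff = (-Qp[i] + pQp) / Q[i, i]
            p[i] += diff
            pQp = (pQp + diff * (diff * Q[i, i] + 2 * Qp[i])) / (1 + diff) ** 2
            Qp = (Qp + diff * Q[i]) / (1 + diff)
            p /= p.sum()
    return p


def predict_proba_multiclass(model: MulticlassModel, X: np.ndarray) -> np.ndarray:
    """Coupled class probabilities, one row per query, summing to 1.

    Pairwise calibrated probabilities are clipped away from 0/1 (as in
    libsvm) before coupling, for numerical stability.
    """
    X = np.atleast_2d(np.asarray(X, float))
    k = len(model.classes)
    idx = {c: i for i, c in enumerate(model.classes)}
    R = np.full((X.shape[0], k, k), 0.5)
    for (a, b), sub in model.pairwise.items():
        p_b = predict_proba_binary(sub, X)
        p_b = np.clip(p_b, 1e-7, 1 - 1e-7)
        R[:, idx[b], idx[a]] = p_b
        R[:, idx[a], idx[b]] = 1 - p_b
    return np.vstack([_couple_pairwise(R[r]) for r in range(X.shape[0])])


def _model_to_dict(model: SvmModel) -> dict:
    return {
        "support_vectors": model.support_vectors.tolist(),
        "dual_coef": model.dual_coef.tolist(),
        "intercept": model.intercept,
        "config": model.config.to_dict(),
        "classes": list(model.classes),
        "n_features": model.n_features,
        "calibration": list(model.calibration) if model.calibration else None,
        "center": model.center.tolist() if model.center is not None else None,
        "scale": model.scale.tolist() if model.scale is not None else None,
    }


def _model_from_dict(d: dict) -> SvmModel:
    return SvmModel(
        support_vectors=np.asarray(d["support_vectors"], float),
        dual_coef=np.asarray(d["dual_coef"], float),
        intercept=d["intercept"],
        config=KernelConfig.from_dict(d["config"]),
        classes=tuple(d["classes"]),
        n_features=d["n_features"],
        calibration=tuple(d["calibration"]) if d["calibration"] else None,
        center=np.asarray(d["center"], float) if d.get("center") is not None else None,
        scale=np.asarray(d["scale"], float) if d.get("scale") is not None else None,
    )


def _multiclass_to_dict(model: MulticlassModel) -> dict:
    return {
        "classes": model.classes,
        "pairwise": {
            f"{a}\t{b}": _model_to_dict(sub) for (a, b), sub in model.pairwise.items()
        },
    }


def _multiclass_from_dict(d: dict) -> MulticlassModel:
    pairwise = {
        tuple(key.split("\t")): _model_from_dict(sub)
        for key, sub in d["pairwise"].items()
    }
    return MulticlassModel(classes=list(d["classes"]), pairwise=pairwise)


def save_model(model: SvmModel | MulticlassModel, path: str | Path) -> None:
    """Serialize a model to a versioned self-describing JSON file."""
    if isinstance(model, SvmModel):
        payload = {"type": "binary", "model": _model_to_dict(model)}
    else:
        payload = {"type": "multiclass", "model": _multiclass_to_dict(model)}
    payload["format_version"] = MODEL_FORMAT_VERSION
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path: str | Path) -> SvmModel | MulticlassModel:
    """Load a model saved by :func:`save_model`; rejects mismatched versions."""
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format version {payload.get('format_version')!r}; "
            f"expected {MODEL_FORMAT_VERSION}"
        )
    if payload["type"] == "binary":
        return _model_from_dict(payload["model"])
    return _multiclass_from_dict(payload["model"])
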