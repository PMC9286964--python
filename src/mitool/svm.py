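"""Binary soft-margin kernel SVM with cross-validated grid search.

The dual problem max Σα − ½ΣΣ α_i α_j y_i y_j K(x_i, x_j) subject to
Σ α_i y_i = 0 and 0 ≤ α_i ≤ C is solved by libsvm through scikit-learn;
this module owns the kernel definitions, the model contract (box and
equality KKT constraints are validated on every fit) and the (C, g)
selection protocol: K-fold cross-validated accuracy over a grid, highest
accuracy wins, ties broken toward the smallest penalty C (guarding against
over-fitting), remaining ties toward the first g in grid order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

DEFAULT_GRID = [2.0**p for p in range(-10, 11)]


@dataclass
class SvmParams:
    """Kernel choice and penalty for one binary SVM.

    The RBF width is parameterized libsvm-style: K(x, y) = exp(−g‖x−y‖²),
    i.e. g = 1/σ² for the exp(−‖x−y‖²/σ²) form.
    """

    C: float = 1.0
    kernel: str = "rbf"  # linear | polynomial | rbf | sigmoid
    g: float = 1.0  # rbf width
    q: int = 3  # polynomial degree
    beta: float = 1.0  # sigmoid slope
    gamma0: float = 0.0  # sigmoid offset

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.kernel == "rbf" and self.g <= 0:
            raise ValueError("rbf width g must be positive")
        if self.kernel == "polynomial" and self.q <= 0:
            raise ValueError("polynomial degree q must be positive")
        if self.kernel not in ("linear", "polynomial", "rbf", "sigmoid"):
            raise ValueError(f"unknown kernel {self.kernel!r}")


def kernel_eval(params: SvmParams, x: np.ndarray, y: np.ndarray) -> float:
    """Evaluate the kernel K(x, y) for a single vector pair."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    dot = float(x @ y)
    if params.kernel == "linear":
        return dot
    if params.kernel == "polynomial":
        return (dot + 1.0) ** params.q
    if params.kernel == "rbf":
        return float(np.exp(-params.g * np.sum((x - y) ** 2)))
    return float(np.tanh(params.beta * dot + params.gamma0))


def _as_svc(params: SvmParams) -> SVC:
    kernel_map = {"linear": "linear", "polynomial": "poly", "rbf": "rbf", "sigmoid": "sigmoid"}
    kw: dict = {"C": params.C, "kernel": kernel_map[params.kernel], "tol": 1e-8}
    if params.kernel == "polynomial":
        kw.update(degree=params.q, gamma=1.0, coef0=1.0)
    elif params.kernel == "rbf":
        kw.update(gamma=params.g)
    elif params.kernel == "sigmoid":
        kw.update(gamma=params.beta, coef0=params.gamma0)
    return SVC(**kw)


@dataclass
class BinarySvmModel:
    """Trained soft-margin SVM with its (C, g) provenance.

    ``label_pos``/``label_neg`` record which original class ids were mapped
    to +1 and −1; decision values are positive toward ``label_pos``.
    """

    params: SvmParams
    support_vectors: np.ndarray
    dual_coef: np.ndarray  # α_i · y_i per support vector
    bias: float
    label_pos: object
    label_neg: object
    _svc: SVC = field(repr=False, default=None)

    def validate_kkt(self, tol: float = 1e-6) -> None:
        if np.any(np.abs(self.dual_coef) > self.params.C * (1 + 1e-9) + tol):
            raise AssertionError("box constraint 0 <= alpha <= C violated")
        if abs(self.dual_coef.sum()) > tol * max(1.0, np.abs(self.dual_coef).sum()):
            raise AssertionError("equality constraint sum(alpha_i y_i) = 0 violated")

    def dual_objective(self) -> float:
        """Value of the dual objective Σα − ½ (αy)ᵀ K (αy) at the solution."""
        ay = self.dual_coef
        sv = self.support_vectors
        K = np.array([[kernel_eval(self.params, a, b) for b in sv] for a in sv])
        alpha = np.abs(ay)
        return float(alpha.sum() - 0.5 * ay @ K @ ay)


def train_binary(features: np.ndarray, labels: np.ndarray, params: SvmParams) -> BinarySvmModel:
    """Train a binary SVM on ±1-labeled feature vectors."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    present = set(np.unique(y).tolist())
    if present != {-1, 1}:
        raise ValueError(f"labels must contain both +1 and -1, got {sorted(present)}")
    svc = _as_svc(params)
    svc.fit(X, y)
    # sklearn orders classes ascending: classes_=[-1, 1], decision>0 → +1
    model = BinarySvmModel(
        params=params,
        support_vectors=svc.support_vectors_,
        dual_coef=svc.dual_coef_[0],
        bias=float(svc.intercept_[0]),
        label_pos=1,
        label_neg=-1,
        _svc=svc,
    )
    model.validate_kkt()
    return model


def decision_value(model: BinarySvmModel, x: np.ndarray) -> float:
    """Σ α_i y_i K(x_i, x) + b for one feature vector."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.support_vectors.shape[1],):
        raise ValueError(
            f"expected feature vector of length {model.support_vectors.shape[1]}, got {x.shape}"
        )
    k = np.array([kernel_eval(model.params, sv, x) for sv in model.support_vectors])
    return float(model.dual_coef @ k + model.bias)


def predict(model: BinarySvmModel, x: np.ndarray) -> int:
    """Sign of the decision value (+1 on the boundary)."""
    return 1 if decision_value(model, x) >= 0 else -1


@dataclass
class GridSearchResult:
    grid: list[tuple[float, float]]  # (C, g) in evaluation (row-major) order
    cv_accuracy: np.ndarray  # percent, aligned with grid
    best: tuple[float, float]
    K: int

    def to_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["C", "g", "cv_accuracy_percent"])
            for (C, g), acc in zip(self.grid, self.cv_accuracy):
                w.writerow([C, g, acc])


def grid_search_cv(
    features: np.ndarray,
    labels: np.ndarray,
    C_grid: list[float] | None = None,
    g_grid: list[float] | None = None,
    K: int = 5,
    seed: int = 0,
    standardize: bool = True,
) -> GridSearchResult:
    """Select (C, g) for an RBF SVM by stratified K-fold CV over a grid.

    The grid is traversed row-major (C outer, g inner).  The winner is the
    highest mean CV accuracy; among ties, the smallest C; among remaining
    ties, the first g in grid order.  Standardization statistics are fit on
    the training folds only.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if K < 2:
        raise ValueError("K must be >= 2")
    C_grid = list(C_grid) if C_grid is not None else list(DEFAULT_GRID)
    g_grid = list(g_grid) if g_grid is not None else list(DEFAULT_GRID)

    skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    for _, val_idx in folds:
        if np.unique(y[val_idx]).size < 2:
            raise ValueError("a fold contains a single class; need more data per class")

    # Precompute per-fold standardized splits once; reuse across the grid.
    splits = []
    for train_idx, val_idx in folds:
        Xtr, Xva = X[train_idx], X[val_idx]
        if standardize:
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0)
            sd[sd == 0] = 1.0
            Xtr = (Xtr - mu) / sd
            Xva = (Xva - mu) / sd
        splits.append((Xtr, y[train_idx], Xva, y[val_idx]))

    grid = [(C, g) for C in C_grid for g in g_grid]
    acc = np.empty(len(grid))
    for idx, (C, g) in enumerate(grid):
        fold_acc = []
        for Xtr, ytr, Xva, yva in splits:
            svc = SVC(C=C, kernel="rbf", gamma=g)
            svc.fit(Xtr, ytr)
            fold_acc.append(np.mean(svc.predict(Xva) == yva))
        acc[idx] = 100.0 * np.mean(fold_acc)

    best_acc = acc.max()
    tied = [i for i in range(len(grid)) if acc[i] == best_acc]
    min_C = min(grid[i][0] for i in tied)
    tied = [i for i in tied if grid[i][0] == min_C]
    best = grid[tied[0]]  # first g in grid order among remaining ties
    return GridSearchResult(grid=grid, cv_accuracy=acc, best=best, K=K)
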