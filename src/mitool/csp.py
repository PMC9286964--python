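"""Common Spatial Patterns.

CSP learns spatial filters that maximize the variance of one class while
minimizing the variance of another, by whitening the summed class
covariances and simultaneously diagonalizing them.  For a fitted filter
matrix the per-class eigenvalue diagonals are complementary (they sum to the
identity), so the most discriminative filters sit at the two ends of the
eigenvalue ordering: the first m and last m filters are kept and each epoch
is reduced to 2m log-variance-ratio features.

Multi-class extensions: one CSP model per class against the pooled rest
(OVR-CSP) or per unordered class pair (OVO-CSP).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .signal_io import EpochSet


@dataclass
class CspModel:
    """Learned spatial filters for one class pairing.

    ``sf_full`` holds all filters as rows, sorted by descending class-A
    eigenvalue; ``sf_selected`` keeps the first m and last m rows.
    """

    sf_full: np.ndarray  # channels × channels
    sf_selected: np.ndarray  # 2m × channels
    eigvals_A: np.ndarray  # descending, in [0, 1]
    m: int
    class_pair: tuple

    @property
    def eigvals_B(self) -> np.ndarray:
        return 1.0 - self.eigvals_A


def normalized_covariance(epoch: np.ndarray) -> np.ndarray:
    """Trace-normalized spatial covariance R = X·Xᵀ / trace(X·Xᵀ)."""
    X = np.asarray(epoch, dtype=float)
    if X.ndim != 2:
        raise ValueError("epoch must be channels × samples")
    C = X @ X.T
    tr = np.trace(C)
    if tr <= 0:
        raise ValueError("degenerate epoch: zero total power")
    return C / tr


def _class_mean_covariance(data: np.ndarray, reg: float = 0.0) -> np.ndarray:
    covs = [normalized_covariance(ep) for ep in data]
    R = np.mean(covs, axis=0)
    if reg > 0:
        R = R + reg * np.eye(R.shape[0])
    return R


def fit_csp(epochs_A: EpochSet, epochs_B: EpochSet, m: int = 2, reg: float = 0.0) -> CspModel:
    """Fit CSP filters discriminating class A from class B.

    Per-epoch trace-normalized covariances are averaged per class with equal
    weight; the summed covariance is eigendecomposed to build the whitening
    matrix P = Σ^(-1/2)Uᵀ, the whitened class-A covariance is diagonalized,
    and filters are sorted by descending class-A eigenvalue.  Filter signs
    are fixed by making each row's largest-magnitude entry positive.
    """
    if epochs_A.n_epochs == 0 or epochs_B.n_epochs == 0:
        raise ValueError("both classes must be non-empty")
    n_ch = epochs_A.n_channels
    if epochs_B.n_channels != n_ch:
        raise ValueError("class A and B channel counts differ")
    if 2 * m > n_ch:
        raise ValueError(f"2m = {2 * m} exceeds the channel count {n_ch}")

    R_A = _class_mean_covariance(epochs_A.data, reg)
    R_B = _class_mean_covariance(epochs_B.data, reg)
    R = R_A + R_B

    sigma, U = linalg.eigh(R)
    if sigma[0] <= sigma[-1] * 1e-10 or sigma[-1] <= 0:
        raise np.linalg.LinAlgError(
            "singular summed covariance; provide more data or enable regularization"
        )
    P = np.diag(sigma**-0.5) @ U.T  # whitening: P R Pᵀ = I

    S_A = P @ R_A @ P.T
    lam, U_A = linalg.eigh(S_A)
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    U_A = U_A[:, order]

    SF = U_A.T @ P  # rows are spatial filters
    signs = np.sign(SF[np.arange(n_ch), np.argmax(np.abs(SF), axis=1)])
    SF = SF * signs[:, np.newaxis]
    sf_selected = np.vstack([SF[:m], SF[-m:]])
    return CspModel(
        sf_full=SF,
        sf_selected=sf_selected,
        eigvals_A=np.clip(lam, 0.0, 1.0),
        m=m,
        class_pair=(None, None),
    )


def csp_features(model: CspModel, epoch: np.ndarray) -> np.ndarray:
    """2m log-variance-ratio features f_p = log10(var(Z_p) / Σ var(Z_i))."""
    X = np.asarray(epoch, dtype=float)
    if X.ndim != 2 or X.shape[0] != model.sf_full.shape[1]:
        raise ValueError(
            f"epoch must be {model.sf_full.shape[1]} channels × samples, got {X.shape}"
        )
    Z = model.sf_selected @ X
    v = Z.var(axis=1)
    return np.log10(v / v.sum())


def features_for(model: CspModel, epochs: EpochSet) -> np.ndarray:
    """Feature matrix (epochs × 2m) for a whole epoch set."""
    return np.stack([csp_features(model, ep) for ep in epochs.data])


def fit_ovr_csp(epochs: EpochSet, m: int = 2, reg: float = 0.0) -> list[CspModel]:
    """One CSP model per class k, trained class k vs all others pooled."""
    classes = epochs.classes
    if classes.size < 3:
        raise ValueError("OVR-CSP requires at least 3 classes")
    models = []
    for k in classes:
        A = epochs.select(epochs.labels == k)
        B = epochs.select(epochs.labels != k)
        if A.n_epochs == 0 or B.n_epochs == 0:
            raise ValueError(f"class {k} is empty")
        model = fit_csp(A, B, m=m, reg=reg)
        model.class_pair = (int(k), "rest")
        models.append(model)
    return models


def fit_ovo_csp(epochs: EpochSet, m: int = 2, reg: float = 0.0) -> list[CspModel]:
    """One CSP model per unordered class pair, lexicographic pair order."""
    classes = epochs.classes
    if classes.size < 3:
        raise ValueError("OVO-CSP requires at least 3 classes")
    models = []
    for i, a in enumerate(classes):
        for b in classes[i + 1 :]:
            A = epochs.select(epochs.labels == a)
            B = epochs.select(epochs.labels == b)
            if A.n_epochs == 0 or B.n_epochs == 0:
                raise ValueError(f"empty class in pair ({a}, {b})")
            model = fit_csp(A, B, m=m, reg=reg)
            model.class_pair = (int(a), int(b))
            models.append(model)
    return models
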