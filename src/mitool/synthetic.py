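"""Synthetic 4-class motor-imagery EEG generator.

Emulates event-related (de)synchronization as CSP expects to see it: each
class modulates the variance of band-limited (default 8–26 Hz, the µ/β
range) latent sources, which are mixed linearly to channels and topped with
broadband sensor noise.  Sources are stationary within an epoch — the
pipeline operates on whole-epoch variance, so a time-locked transient would
add realism without changing what is being tested.

Train and test sets are drawn independently (the test stream is seeded with
seed + 1) from identical class-conditional distributions, sharing one
mixing matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, signal as sps

from .preprocess import design_bandpass
from .signal_io import EpochSet


@dataclass
class SyntheticSpec:
    """Generation recipe: class-conditional source variances under mixing.

    ``source_variance_table`` is K × channels; row k gives the variance of
    each latent source for class k (µV²).  ``mixing`` is a full-rank
    channels × channels matrix or ``"random-orthogonal"`` (drawn once from
    the seed).  ``noise_sd`` is the broadband sensor-noise σ in µV.
    """

    K: int = 4
    channels: int = 8
    fs: float = 250.0
    epoch_s: float = 4.0
    epochs_per_class: int = 40
    source_variance_table: np.ndarray = None
    mixing: object = "random-orthogonal"
    rhythm_band: tuple[float, float] = (8.0, 26.0)
    noise_sd: float = 0.2
    seed: int = 0
    name: str = field(default="custom")

    def __post_init__(self) -> None:
        if self.source_variance_table is None:
            self.source_variance_table = _contrast_table(self.K, self.channels, 4.0)
        self.source_variance_table = np.asarray(self.source_variance_table, dtype=float)
        if self.source_variance_table.shape != (self.K, self.channels):
            raise ValueError("source_variance_table must be K × channels")
        if np.any(self.source_variance_table <= 0):
            raise ValueError("source variances must be positive")
        for k in range(self.K):
            others = np.delete(self.source_variance_table, k, axis=0)
            if np.any(np.all(np.isclose(others, self.source_variance_table[k]), axis=1)):
                raise ValueError(f"class {k + 1} is indistinguishable from another class")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if isinstance(self.mixing, np.ndarray):
            if np.linalg.matrix_rank(self.mixing) < self.channels:
                raise ValueError("mixing matrix is rank-deficient")


def _contrast_table(K: int, channels: int, contrast: float) -> np.ndarray:
    """Baseline unit-variance sources; class k boosts source k by `contrast`."""
    table = np.ones((K, channels))
    for k in range(K):
        table[k, k % channels] = contrast
    return table


def easy_preset(seed: int = 0) -> SyntheticSpec:
    """Strong 4:1 variance contrast, low noise — every topology should solve it."""
    return SyntheticSpec(
        K=4, channels=8, fs=250.0, epoch_s=4.0, epochs_per_class=40,
        source_variance_table=_contrast_table(4, 8, 4.0),
        noise_sd=0.2, seed=seed, name="easy",
    )


def hard_preset(seed: int = 0) -> SyntheticSpec:
    """Weak 2:1 contrast, high noise — accuracies drop below the easy preset."""
    return SyntheticSpec(
        K=4, channels=8, fs=250.0, epoch_s=4.0, epochs_per_class=40,
        source_variance_table=_contrast_table(4, 8, 2.0),
        noise_sd=3.0, seed=seed, name="hard",
    )


def _mixing_matrix(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    if isinstance(spec.mixing, np.ndarray):
        return spec.mixing
    if spec.mixing == "identity":
        return np.eye(spec.channels)
    if spec.mixing == "random-orthogonal":
        gauss = rng.standard_normal((spec.channels, spec.channels))
        q, r = linalg.qr(gauss)
        return q * np.sign(np.diag(r))
    raise ValueError(f"unknown mixing spec {spec.mixing!r}")


def _draw_epochs(spec: SyntheticSpec, mixing: np.ndarray, rng: np.random.Generator) -> EpochSet:
    n_samp = int(round(spec.epoch_s * spec.fs))
    bp = design_bandpass(*spec.rhythm_band, fs=spec.fs, kind="IIR", order=4)
    data = np.empty((spec.K * spec.epochs_per_class, spec.channels, n_samp))
    labels = np.empty(spec.K * spec.epochs_per_class, dtype=int)
    e = 0
    for k in range(spec.K):
        var_row = spec.source_variance_table[k]
        for _ in range(spec.epochs_per_class):
            white = rng.standard_normal((spec.channels, n_samp))
            sources = sps.filtfilt(bp.numerator, bp.denominator, white, axis=-1)
            # rescale each filtered source to its class-conditional variance
            sources /= sources.std(axis=-1, keepdims=True)
            sources *= np.sqrt(var_row)[:, np.newaxis]
            chans = mixing @ sources
            if spec.noise_sd > 0:
                chans = chans + spec.noise_sd * rng.standard_normal(chans.shape)
            data[e] = chans
            labels[e] = k + 1
            e += 1
    names = [f"SYN{i + 1}" for i in range(spec.channels)]
    return EpochSet(data, labels, spec.fs, names)


def generate(spec: SyntheticSpec) -> tuple[EpochSet, EpochSet]:
    """Draw disjoint train and test epoch sets, deterministic given the seed."""
    rng_train = np.random.default_rng(spec.seed)
    mixing = _mixing_matrix(spec, rng_train)
    train = _draw_epochs(spec, mixing, rng_train)
    rng_test = np.random.default_rng(spec.seed + 1)
    test = _draw_epochs(spec, mixing, rng_test)
    return train, test


def expected_channel_covariance(spec: SyntheticSpec, class_k: int, mixing: np.ndarray) -> np.ndarray:
    """Population channel covariance M·diag(σ²_k)·Mᵀ + noise_sd²·I."""
    D = np.diag(spec.source_variance_table[class_k - 1])
    return mixing @ D @ mixing.T + spec.noise_sd**2 * np.eye(spec.channels)
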