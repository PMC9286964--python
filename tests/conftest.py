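import numpy as np
import pytest

from mitool.signal_io import EpochSet
from mitool.synthetic import SyntheticSpec, _contrast_table


@pytest.fixture
def rng():
    return np.random.default_rng(42)


# Small grid / few folds: keeps multi-node topology tests fast while still
# exercising the full grid-search path.
FAST_SVM = {"C_grid": [1.0, 10.0], "g_grid": [0.5, 1.0], "K": 3, "seed": 0}


def tiny_spec(K: int = 4, seed: int = 0) -> SyntheticSpec:
    """Small, quick-to-generate synthetic problem for structural tests."""
    channels = max(K, 4)
    return SyntheticSpec(
        K=K,
        channels=channels,
        fs=64.0,
        epoch_s=1.0,
        epochs_per_class=12,
        source_variance_table=_contrast_table(K, channels, 4.0),
        rhythm_band=(8.0, 26.0),
        noise_sd=0.1,
        seed=seed,
    )


def two_class_toy(var_a, var_b, n_epochs=60, n_samples=500, seed=0):
    """Independent Gaussian sources with per-class variances, identity mixing."""
    rng = np.random.default_rng(seed)
    n_ch = len(var_a)
    names = [f"ch{i}" for i in range(n_ch)]

    def draw(var):
        sd = np.sqrt(np.asarray(var, dtype=float))[:, None]
        return np.stack([rng.standard_normal((n_ch, n_samples)) * sd for _ in range(n_epochs)])

    A = EpochSet(draw(var_a), np.ones(n_epochs, dtype=int), 100.0, names)
    B = EpochSet(draw(var_b), np.full(n_epochs, 2, dtype=int), 100.0, names)
    return A, B
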