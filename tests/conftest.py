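import numpy as np
import pytest

from stratifs.info import DiscreteMatrix
from stratifs.io import DosageMatrix
from stratifs.simulate import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def fixed_table() -> DiscreteMatrix:
    """A fixed 6-feature, n=64 binary table with planted dependence structure.

    f0 tracks the label closely, f1 duplicates f0 with noise, f2..f4 mix
    label and each other, f5 is noise -- enough structure that relevance,
    redundancy and conditional-redundancy terms are all non-trivial.
    """
    rng = np.random.default_rng(20240917)
    n = 64
    y = rng.integers(0, 2, n)
    f0 = np.where(rng.random(n) < 0.85, y, 1 - y)
    f1 = np.where(rng.random(n) < 0.80, f0, rng.integers(0, 2, n))
    f2 = np.where(rng.random(n) < 0.65, y, rng.integers(0, 2, n))
    f3 = np.where(rng.random(n) < 0.5, f2, rng.integers(0, 2, n))
    f4 = rng.integers(0, 2, n)
    f5 = rng.integers(0, 2, n)
    codes = np.stack([f0, f1, f2, f3, f4, f5], axis=1).astype(np.int16)
    return DiscreteMatrix([f"f{i}" for i in range(6)], codes, [2] * 6, y.astype(np.int16))


@pytest.fixture(scope="session")
def small_cohort() -> tuple:
    """A small default-structure synthetic cohort shared across tests."""
    cfg = SyntheticConfig(n_case=300, n_control=300, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort() -> tuple:
    """One full-size (n=2500) default cohort for the heavier checks."""
    return generate_cohort(SyntheticConfig(seed=5))


def toy_matrix(n=40, p=3, seed=0, labels=None) -> DosageMatrix:
    rng = np.random.default_rng(seed)
    return DosageMatrix(
        sample_ids=[f"S{i}" for i in range(n)],
        feature_names=[f"HLA_X_{j:02d}" for j in range(p)],
        dosages=rng.uniform(0, 2, size=(n, p)),
        aao=rng.uniform(5, 80, n),
        pc1=rng.normal(size=n),
        pc2=rng.normal(size=n),
        label=labels if labels is not None else rng.integers(0, 2, n),
    )
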