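import numpy as np
import pytest

from hetmeta import StudyRecord


@pytest.fixture
def canonical():
    """The two-study instance theta=(0,2), sigma2=(1,1) on which the moment,
    REML and model-error-variance estimators all coincide at 1 while ML
    collapses to 0."""
    return np.array([0.0, 2.0]), np.array([1.0, 1.0])


def random_instances(n, seed=0, k_range=(2, 30)):
    """Random (theta, sigma2, n_totals) meta-analysis instances."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        k = int(rng.integers(k_range[0], k_range[1] + 1))
        theta = rng.normal(0.5, 0.5, size=k)
        sigma2 = rng.uniform(0.01, 0.6, size=k)
        n_tot = rng.integers(50, 501, size=k)
        out.append((theta, sigma2, n_tot))
    return out


@pytest.fixture
def balanced_table():
    return StudyRecord("s1", "dichotomous", events1=5, total1=10,
                       events2=5, total2=10)
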