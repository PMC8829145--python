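import numpy as np
import pytest

import regmixsim as rm


@pytest.fixture(scope="session")
def light_config():
    """Reduced multi-start budget for unit tests on well-separated data."""
    return rm.FitConfig(n_starts=6, n_hard_starts=2, seed=0)


@pytest.fixture(scope="session")
def cond_single_large():
    return rm.make_condition("single_no_intdiff", "large", 500)


@pytest.fixture(scope="session")
def cond_two_large():
    return rm.make_condition("two_no_intdiff", "large", 500)


@pytest.fixture(scope="session")
def small_dataset(cond_single_large):
    return rm.generate_dataset(cond_single_large, seed=11)


def random_dataset(rng: np.random.Generator, n: int = 120, p: int = 1) -> rm.Dataset:
    """Unstructured dataset for oracle checks (not from the study design)."""
    X = rng.standard_normal((n, p))
    y = rng.standard_normal(n) + X.sum(axis=1) * rng.uniform(-1, 1)
    labels = rng.integers(1, 3, size=n)
    return rm.Dataset(X=X, y=y, true_class=labels, seed=0)
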