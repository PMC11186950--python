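import numpy as np
import pytest

from macerisk.catalogue import default_catalogue
from macerisk.profiles import SubjectProfile


@pytest.fixture(scope="session")
def catalogue():
    return default_catalogue()


def make_profile(**kwargs) -> SubjectProfile:
    kwargs.setdefault("subject_id", "p0")
    kwargs.setdefault("age", 50)
    return SubjectProfile(**kwargs)


def competing_fixture_40():
    """40 subjects, distinct times, both event types; matches the frozen
    external-oracle values in test_competing_risks."""
    rng = np.random.default_rng(42)
    n = 40
    x1 = rng.integers(0, 2, n).astype(float)
    x2 = rng.normal(0, 1, n).round(3)
    t = np.round(rng.exponential(100, n) + rng.uniform(0, 1, n), 3)
    ev = rng.choice([0, 1, 2], size=n, p=[0.25, 0.45, 0.30])
    return t, ev, np.column_stack([x1, x2])


def competing_fixture_20():
    """20 subjects, one binary covariate, for the 1-D grid-search oracle."""
    rng = np.random.default_rng(99)
    n = 20
    x = rng.integers(0, 2, n).astype(float)
    t = np.round(rng.exponential(80, n) + rng.uniform(0, 1, n), 3)
    ev = rng.choice([0, 1, 2], size=n, p=[0.2, 0.5, 0.3])
    return t, ev, x
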