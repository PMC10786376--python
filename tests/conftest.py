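import numpy as np
import pytest

import varctrl as vc


@pytest.fixture(scope="session")
def testosterone_table():
    return vc.load_testosterone()


@pytest.fixture(scope="session")
def testosterone_study(testosterone_table):
    return vc.summarize(testosterone_table)


@pytest.fixture(scope="session")
def blood_table():
    return vc.load_blood_counts()


@pytest.fixture(scope="session")
def blood_study(blood_table):
    return vc.summarize(blood_table)


def random_study(rng: np.random.Generator, *, equal_sizes: bool = False,
                 max_k: int = 5, max_n: int = 25) -> vc.StudySummary:
    """Draw a random null study (unit variances) for property tests."""
    k = int(rng.integers(1, max_k + 1))
    n0 = int(rng.integers(3, max_n))
    if equal_sizes:
        m = int(rng.integers(3, max_n))
        sizes = [n0] + [m] * k
    else:
        sizes = [n0] + [int(rng.integers(3, max_n)) for _ in range(k)]
    groups = []
    for i, n in enumerate(sizes):
        x = rng.normal(size=n)
        groups.append(vc.GroupSummary(label=f"g{i}", n=n, s2=float(np.var(x, ddof=1))))
    return vc.StudySummary(control=groups[0], treatments=tuple(groups[1:]))
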