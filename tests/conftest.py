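import numpy as np
import pytest

from entroq import EntropyParams, TimeSeries


@pytest.fixture
def s6():
    """Six-sample worked example with hand-enumerable match structure."""
    return TimeSeries([0.0, 0.1, 0.05, 0.15, 0.5, 0.1])


@pytest.fixture
def s6_params():
    return EntropyParams(m=2, r=0.1, tau=1)


def naive_counts(x, m, r, tau=1):
    """Brute-force triple-loop match counting, independent of the package.

    Returns (C_m, C_m1, B, A) with the same conventions as the
    production counter: C includes the self-match; B and A exclude it
    and restrict both indices to the order-(m+1) template range.
    """
    x = list(map(float, x))
    n = len(x)

    def templates(order):
        cnt = n - (order - 1) * tau
        return [[x[i + k * tau] for k in range(order)] for i in range(cnt)]

    def dist(a, b):
        return max(abs(u - v) for u, v in zip(a, b))

    tm = templates(m)
    tm1 = templates(m + 1)
    n_m, n_m1 = len(tm), len(tm1)
    c_m = [sum(dist(tm[i], tm[j]) <= r for j in range(n_m)) for i in range(n_m)]
    c_m1 = [sum(dist(tm1[i], tm1[j]) <= r for j in range(n_m1)) for i in range(n_m1)]
    b = [
        sum(j != i and dist(tm[i], tm[j]) <= r for j in range(n_m1))
        for i in range(n_m1)
    ]
    a = [c - 1 for c in c_m1]
    return c_m, c_m1, b, a


@pytest.fixture
def oracle_counts():
    return naive_counts


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
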