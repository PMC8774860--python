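"""Approximate and sample entropy with explicit match-count bookkeeping.

Both statistics compare overlapping m-length template vectors under the
Chebyshev (maximum-coordinate) distance with an inclusive threshold r.
ApEn averages log matching probabilities (self-matches included);
SampEn takes the log of ratio-of-sums with self-matches excluded, which
leaves it undefined when no template finds any match.

Index conventions
-----------------
This implementation follows the convention in which the two statistics
use *different* index ranges at order m (written here for tau = 1):

* ApEn order-m counts ``C_i`` run over i, j = 1..N-m+1 (self included);
  its order-(m+1) counts run over i, j = 1..N-m.
* SampEn counts ``B_i`` (order m, self excluded) and ``A_i`` (order m+1)
  both run over i, j = 1..N-m.

Some public implementations instead truncate the ApEn order-m loop to
N-m.  The difference is O(1/N) but visible in small worked examples, so
it is kept exactly as stated above.  Distances are compared with plain
``<=`` and no epsilon slack: a pair at distance exactly r matches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .distributions import TimeSeries

__all__ = [
    "EntropyParams",
    "TemplateSet",
    "MatchCounts",
    "MatchingProbabilities",
    "EntropyEstimate",
    "extract_templates",
    "chebyshev_distance",
    "count_matches",
    "matching_probabilities",
    "apen",
    "sampen",
]


@dataclass(frozen=True)
class EntropyParams:
    """Estimation parameters: template length m, threshold r (SD units), delay tau."""

    m: int = 2
    r: float = 0.2
    tau: int = 1

    def __post_init__(self):
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if not self.r > 0:
            raise ValueError(f"r must be > 0, got {self.r}")
        if self.tau < 1:
            raise ValueError(f"tau must be >= 1, got {self.tau}")

    def n_templates(self, n: int, order: int) -> int:
        """Number of order-``order`` templates in a length-``n`` series."""
        return n - (order - 1) * self.tau


@dataclass(frozen=True)
class TemplateSet:
    """All overlapping order-m templates of a series, as rows of a matrix."""

    templates: np.ndarray  # shape (count, order)
    order: int
    tau: int

    @property
    def count(self) -> int:
        return self.templates.shape[0]


def extract_templates(series: TimeSeries, order: int, tau: int = 1) -> TemplateSet:
    """Build the order-m template vectors x_i, x_{i+tau}, ..., x_{i+(m-1)tau}.

    There are N - (m-1)*tau of them; consecutive templates overlap.
    """
    if order < 1 or tau < 1:
        raise ValueError("order and tau must be >= 1")
    x = series.samples
    count = len(series) - (order - 1) * tau
    if count < 1:
        raise ValueError(
            f"series of length {len(series)} too short for order={order}, tau={tau}"
        )
    idx = np.arange(count)[:, None] + tau * np.arange(order)[None, :]
    return TemplateSet(x[idx], order, tau)


def chebyshev_distance(a, b) -> float:
    """Maximum absolute coordinate difference between two equal-length vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.max(np.abs(a - b)))


@dataclass(frozen=True)
class MatchCounts:
    """Per-template match counts at orders m and m+1.

    ``C_m`` includes the self-match (so every entry is >= 1); ``B`` and
    ``A`` are the self-excluded counts entering SampEn, with
    ``A_i = C_m1_i - 1``.
    """

    C_m: np.ndarray  # order m, self included, length N-(m-1)tau
    C_m1: np.ndarray  # order m+1, self included, length N-m*tau
    B: np.ndarray  # order m, self excluded, i,j <= N-m*tau
    A: np.ndarray  # order m+1, self excluded
    params: EntropyParams
    n: int  # series length


def _match_matrix(x: np.ndarray, order: int, tau: int, r: float) -> np.ndarray:
    """Boolean matrix M[i, j] = (Chebyshev distance of templates i, j) <= r."""
    within = np.abs(x[:, None] - x[None, :]) <= r
    count = x.size - (order - 1) * tau
    m = within[:count, :count].copy()
    for k in range(1, order):
        off = k * tau
        m &= within[off : off + count, off : off + count]
    return m


def count_matches(series: TimeSeries, params: EntropyParams) -> MatchCounts:
    """Count template matches at orders m and m+1 for one series.

    Requires at least one order-(m+1) template, i.e. N - m*tau >= 1.
    The similarity condition is inclusive (distance <= r).
    """
    x = series.samples
    n = x.size
    m, r, tau = params.m, params.r, params.tau
    n_m1 = n - m * tau
    if n_m1 < 1:
        raise ValueError(
            f"series of length {n} too short for m={m}, tau={tau} "
            f"(need N - m*tau >= 1)"
        )
    mm = _match_matrix(x, m, tau, r)
    mm1 = _match_matrix(x, m + 1, tau, r)
    C_m = mm.sum(axis=1).astype(np.int64)
    C_m1 = mm1.sum(axis=1).astype(np.int64)
    B = mm[:n_m1, :n_m1].sum(axis=1).astype(np.int64) - 1
    A = C_m1 - 1
    return MatchCounts(C_m, C_m1, B, A, params, n)


@dataclass(frozen=True)
class MatchingProbabilities:
    """Relative-frequency matching-probability estimates.

    Values live on a lattice: at order m the ApEn estimates are integer
    multiples of 1/(N-m+1) and the SampEn estimates of 1/(N-m) (tau=1).
    """

    pA_m: np.ndarray
    pA_m1: np.ndarray
    pS_m: np.ndarray
    pS_m1: np.ndarray


def matching_probabilities(counts: MatchCounts) -> MatchingProbabilities:
    n, p = counts.n, counts.params
    n_m = p.n_templates(n, p.m)
    n_m1 = p.n_templates(n, p.m + 1)
    return MatchingProbabilities(
        pA_m=counts.C_m / n_m,
        pA_m1=counts.C_m1 / n_m1,
        pS_m=counts.B / n_m1,
        pS_m1=counts.A / n_m1,
    )


@dataclass(frozen=True)
class EntropyEstimate:
    """An ApEn or SampEn value together with its two summands.

    ``defined`` is always true for ApEn; for SampEn it is false when no
    template pair matches at order m or at order m+1 (the log of zero
    would occur), in which case ``value`` is NaN rather than an error so
    that simulation loops can count the incidence.
    """

    kind: str  # "ApEn" | "SampEn"
    value: float
    summand_m: float
    summand_m1: float
    defined: bool
    params: EntropyParams
    n: int


def apen(
    series: TimeSeries, params: EntropyParams, counts: MatchCounts | None = None
) -> EntropyEstimate:
    """Approximate entropy: mean-log matching probabilities, self-matches in.

    Always defined (the self-match guarantees every count >= 1); small-N
    values can be negative.
    """
    c = counts if counts is not None else count_matches(series, params)
    n_m = params.n_templates(c.n, params.m)
    n_m1 = params.n_templates(c.n, params.m + 1)
    phi_m = float(np.mean(np.log(c.C_m / n_m)))
    phi_m1 = float(np.mean(np.log(c.C_m1 / n_m1)))
    return EntropyEstimate(
        "ApEn", phi_m - phi_m1, phi_m, phi_m1, True, params, c.n
    )


def sampen(
    series: TimeSeries, params: EntropyParams, counts: MatchCounts | None = None
) -> EntropyEstimate:
    """Sample entropy: -ln(sum A / sum B), self-matches excluded.

    When defined the value is never negative, since every order-(m+1)
    match implies its embedded order-m match (A_i <= B_i componentwise).
    """
    c = counts if counts is not None else count_matches(series, params)
    n_m1 = params.n_templates(c.n, params.m + 1)
    sum_b = int(c.B.sum())
    sum_a = int(c.A.sum())
    if sum_b == 0 or sum_a == 0:
        return EntropyEstimate(
            "SampEn", math.nan, math.nan, math.nan, False, params, c.n
        )
    psi_m = math.log(sum_b / n_m1**2)
    psi_m1 = math.log(sum_a / n_m1**2)
    return EntropyEstimate(
        "SampEn", psi_m - psi_m1, psi_m, psi_m1, True, params, c.n
    )
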