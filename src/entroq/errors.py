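"""Quantization-error decomposition of ApEn and SampEn estimates.

The relative-frequency matching probabilities that enter ApEn and
SampEn live on a coarse lattice (multiples of 1/(N-m+1) or 1/(N-m) for
tau=1) while the calculated probabilities are continuous, so every
per-template estimate carries a quantization error

    eps_i = p_i (calculated) - p_hat_i (estimated).

SampEn sums probabilities before taking a single logarithm, so for
symmetric source laws the positive and negative eps_i largely cancel
and the estimate is nearly unbiased even at modest N.  ApEn averages
logarithms, which destroys the cancellation and accumulates error.  For
skewed laws (the shifted exponential) the error distribution itself is
asymmetric — calculated probabilities systematically exceed estimated
ones — and neither statistic's error vanishes with N.  This module
computes the per-template errors, the summand and entropy error
identities, the discrete-lattice structure of the error distribution,
and the incidence of zero-matches / undefined SampEn, plus exact
binomial confidence intervals for the matching probability of a fixed
template.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .distributions import DistributionSpec, TimeSeries, generate_series
from .entropy import EntropyParams, count_matches
from .exact import ExactProbabilities, exact_template_prob

__all__ = [
    "ErrorDecomposition",
    "ErrorDistribution",
    "IncidenceReport",
    "ProbabilityCI",
    "decompose_errors",
    "error_distribution",
    "lattice_spacing",
    "cancellation_ratio",
    "zero_match_incidence",
    "undefined_sampen_incidence",
    "matching_prob_ci",
]


@dataclass(frozen=True)
class ErrorDecomposition:
    """Per-template probability errors and the derived summand/entropy errors.

    ``eps_*`` arrays are calculated-minus-estimated per template; the
    summand errors are differences of defined quantities (estimated
    minus calculated Phi / Psi), and the entropy errors satisfy

        eps_apen   = eps_phi_m - eps_phi_m1
        eps_sampen = eps_psi_m - eps_psi_m1

    exactly, by construction.  The Psi-side quantities are NaN when the
    SampEn estimate is undefined (no matches at one of the orders).
    """

    eps_A_m: np.ndarray
    eps_A_m1: np.ndarray
    eps_S_m: np.ndarray
    eps_S_m1: np.ndarray
    eps_phi_m: float
    eps_phi_m1: float
    eps_psi_m: float
    eps_psi_m1: float
    eps_apen: float
    eps_sampen: float
    sampen_defined: bool
    params: EntropyParams


def decompose_errors(
    series: TimeSeries,
    params: EntropyParams,
    dist: DistributionSpec | None = None,
    clip_support: bool = True,
) -> ErrorDecomposition:
    """Compare estimated matching probabilities with calculated ones.

    ``dist`` defaults to the generating law recorded in the series
    metadata; it must be one of the three standardized laws, since the
    calculated probabilities integrate that density.
    ``clip_support=False`` switches the calculated probabilities to the
    unclipped closed forms (see :mod:`entroq.exact`), the convention
    under which skewed-law entropy errors fail to vanish with N.

    The Phi-summand errors are computed as Phi_hat - Phi rather than by
    the per-template log expansion, which is only formal (a per-template
    error can exceed its probability, making the log argument negative).
    """
    if dist is None:
        from .distributions import get_distribution

        name = series.meta.distribution
        if name in (None, "external"):
            raise ValueError(
                "series has no generating distribution in its metadata; "
                "pass dist explicitly"
            )
        dist = get_distribution(name)

    c = count_matches(series, params)
    m, tau = params.m, params.tau
    n = c.n
    n_m = params.n_templates(n, m)
    n_m1 = params.n_templates(n, m + 1)

    ex = ExactProbabilities(series.samples, m, params.r, dist, tau, clip_support)
    p_m = ex.per_template_m  # length n_m
    p_m1 = ex.per_template_m1  # length n_m1

    eps_A_m = p_m - c.C_m / n_m
    eps_A_m1 = p_m1 - c.C_m1 / n_m1
    eps_S_m = p_m[:n_m1] - c.B / n_m1
    eps_S_m1 = p_m1 - c.A / n_m1

    phi_hat_m = float(np.mean(np.log(c.C_m / n_m)))
    phi_hat_m1 = float(np.mean(np.log(c.C_m1 / n_m1)))
    phi_m = float(np.mean(np.log(p_m)))
    phi_m1 = float(np.mean(np.log(p_m1)))
    eps_phi_m = phi_hat_m - phi_m
    eps_phi_m1 = phi_hat_m1 - phi_m1

    sum_b, sum_a = int(c.B.sum()), int(c.A.sum())
    defined = sum_b > 0 and sum_a > 0
    if defined:
        psi_hat_m = float(np.log(sum_b / n_m1**2))
        psi_hat_m1 = float(np.log(sum_a / n_m1**2))
        psi_m = float(np.log(np.mean(p_m[:n_m1])))
        psi_m1 = float(np.log(np.mean(p_m1)))
        eps_psi_m = psi_hat_m - psi_m
        eps_psi_m1 = psi_hat_m1 - psi_m1
        eps_sampen = eps_psi_m - eps_psi_m1
    else:
        eps_psi_m = eps_psi_m1 = eps_sampen = float("nan")

    return ErrorDecomposition(
        eps_A_m=eps_A_m,
        eps_A_m1=eps_A_m1,
        eps_S_m=eps_S_m,
        eps_S_m1=eps_S_m1,
        eps_phi_m=eps_phi_m,
        eps_phi_m1=eps_phi_m1,
        eps_psi_m=eps_psi_m,
        eps_psi_m1=eps_psi_m1,
        eps_apen=eps_phi_m - eps_phi_m1,
        eps_sampen=eps_sampen,
        sampen_defined=defined,
        params=params,
    )


def _merge_close(values: np.ndarray, tol: float = 1e-9):
    """Group sorted values whose neighbours differ by < tol (rounding noise).

    Returns (group means, group multiplicities).
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty error sequence")
    new_group = np.concatenate(([True], np.diff(v) >= tol))
    gid = np.cumsum(new_group) - 1
    count = np.bincount(gid)
    mean = np.bincount(gid, weights=v) / count
    return mean, count


def _modal_gap(points: np.ndarray, rel_tol: float = 1e-6) -> float:
    """Most frequent gap between consecutive sorted points.

    Gaps agreeing to within ``rel_tol`` (relative) count as equal; ties
    resolve to the smallest modal gap.
    """
    gaps = np.diff(np.sort(points))
    gaps = gaps[gaps > 0]
    if gaps.size == 0:
        return float("nan")
    order = np.argsort(gaps)
    g = gaps[order]
    # cluster near-equal gaps
    new_cluster = np.concatenate(([True], np.diff(g) > rel_tol * g[1:]))
    cid = np.cumsum(new_cluster) - 1
    counts = np.bincount(cid)
    best = int(np.argmax(counts))  # argmax -> first (smallest) on ties
    return float(np.mean(g[cid == best]))


def lattice_spacing(errors: Sequence[float], tol: float = 1e-9) -> float:
    """Spacing of the discrete component of an error sample.

    The per-template error is (continuous calculated p) minus (lattice
    estimate), so templates sharing the same calculated probability
    produce exactly repeated error values spaced by the probability
    quantum.  Values repeated at least twice (after merging differences
    below ``tol``) are taken as the discrete atoms; the spacing is the
    modal gap between consecutive atoms.  With fewer than 3 atoms all
    distinct values are used instead.
    """
    centers, mult = _merge_close(np.asarray(errors, dtype=float), tol)
    atoms = centers[mult >= 2]
    pts = atoms if atoms.size >= 3 else centers
    return _modal_gap(pts)


@dataclass(frozen=True)
class ErrorDistribution:
    """Histogram, smoothed density and lattice report of an error sample."""

    bin_edges: np.ndarray
    counts: np.ndarray
    density_x: np.ndarray
    density_y: np.ndarray
    spacing: float
    n_atoms: int


def error_distribution(errors: Sequence[float], n_quant: int = 200) -> ErrorDistribution:
    """Characterize an empirical error distribution.

    Returns a Freedman–Diaconis histogram, a Gaussian-kernel smoothed
    density (Silverman bandwidth) evaluated on ``n_quant`` grid points,
    and the detected lattice spacing of the discrete component.
    """
    e = np.asarray(errors, dtype=float)
    e = e[np.isfinite(e)]
    if e.size == 0:
        raise ValueError("empty error sequence")
    if n_quant < 1:
        raise ValueError("n_quant must be >= 1")
    counts, edges = np.histogram(e, bins="fd")
    grid = np.linspace(e.min(), e.max(), n_quant)
    if e.size > 1 and e.std() > 0:
        kde = stats.gaussian_kde(e, bw_method="silverman")
        dens = kde(grid)
    else:
        dens = np.full_like(grid, np.nan)
    centers, mult = _merge_close(e)
    return ErrorDistribution(
        bin_edges=edges,
        counts=counts,
        density_x=grid,
        density_y=dens,
        spacing=lattice_spacing(e),
        n_atoms=int(np.sum(mult >= 2)),
    )


def cancellation_ratio(errors: Sequence[float]) -> float:
    """|sum of errors| / sum of |errors| — 0 under perfect cancellation."""
    e = np.asarray(errors, dtype=float)
    denom = np.sum(np.abs(e))
    if denom == 0:
        return 0.0
    return float(abs(np.sum(e)) / denom)


@dataclass(frozen=True)
class IncidenceReport:
    """Monte-Carlo incidence of zero-match templates / undefined SampEn."""

    zero_match_pct: float
    undefined_pct: float
    settings: dict


def zero_match_incidence(
    dist: DistributionSpec,
    n: int,
    params: EntropyParams,
    replicates: int,
    seed: int,
) -> IncidenceReport:
    """Mean percentage of templates with no SampEn match (B_i = 0).

    The percentage is computed per series over the N - m*tau SampEn
    templates, then averaged over replicates (replicate j uses
    seed + j).  Undefined-SampEn incidence over the same replicates is
    reported alongside.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    pcts = np.empty(replicates)
    undefined = 0
    for j in range(replicates):
        series = generate_series(dist, n, seed + j)
        c = count_matches(series, params)
        pcts[j] = 100.0 * np.mean(c.B == 0)
        if c.B.sum() == 0 or c.A.sum() == 0:
            undefined += 1
    return IncidenceReport(
        zero_match_pct=float(pcts.mean()),
        undefined_pct=100.0 * undefined / replicates,
        settings={
            "dist": dist.name,
            "n": n,
            "m": params.m,
            "r": params.r,
            "tau": params.tau,
            "replicates": replicates,
            "seed": seed,
        },
    )


def undefined_sampen_incidence(
    dist: DistributionSpec,
    n: int,
    params: EntropyParams,
    replicates: int,
    seed: int,
) -> IncidenceReport:
    """Percentage of replicate series on which SampEn is undefined."""
    return zero_match_incidence(dist, n, params, replicates, seed)


@dataclass(frozen=True)
class ProbabilityCI:
    """Exact binomial CI for the matching probability of a fixed template."""

    template: np.ndarray
    lower: float
    upper: float
    level: float
    calculated: float
    mean_estimate: float
    replicates: int
    n: int
    zero_lower_bound: bool


def matching_prob_ci(
    template,
    dist: DistributionSpec,
    n: int,
    params: EntropyParams,
    replicates: int,
    level: float = 0.95,
    seed: int = 0,
) -> ProbabilityCI:
    """Clopper–Pearson CI for a fixed template's matching probability.

    For each replicate a fresh series is generated and the template is
    matched (Chebyshev distance <= r) against all its order-m templates,
    m being the template's length.  Match counts are pooled over
    replicates and an exact binomial interval computed on the pooled
    proportion; the calculated reference is the product of the per-sample
    probabilities.  A pooled count of zero yields a lower bound of 0,
    flagged via ``zero_lower_bound``.
    """
    t = np.atleast_1d(np.asarray(template, dtype=float))
    if replicates < 2:
        raise ValueError("replicates must be >= 2")
    if not np.all(dist.in_support(t)):
        raise ValueError(f"template component outside the support of {dist.name}")
    m = t.size
    tau = params.tau
    n_templ = n - (m - 1) * tau
    if n_templ < 1:
        raise ValueError("series too short for this template length")
    total_matches = 0
    for j in range(replicates):
        x = generate_series(dist, n, seed + j).samples
        idx = np.arange(n_templ)[:, None] + tau * np.arange(m)[None, :]
        d = np.max(np.abs(x[idx] - t[None, :]), axis=1)
        total_matches += int(np.sum(d <= params.r))
    trials = replicates * n_templ
    lower, upper = proportion_confint(
        total_matches, trials, alpha=1.0 - level, method="beta"
    )
    lower = 0.0 if np.isnan(lower) else float(lower)
    upper = float(upper)
    return ProbabilityCI(
        template=t,
        lower=lower,
        upper=upper,
        level=level,
        calculated=exact_template_prob(t, params.r, dist),
        mean_estimate=total_matches / trials,
        replicates=replicates,
        n=n,
        zero_lower_bound=total_matches == 0,
    )
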