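import numpy as np
import pytest

from entroq import (
    EntropyParams,
    TimeSeries,
    cancellation_ratio,
    decompose_errors,
    error_distribution,
    generate_series,
    get_distribution,
    lattice_spacing,
    matching_prob_ci,
    undefined_sampen_incidence,
    zero_match_incidence,
)


class TestDecomposition:
    def test_identities_hold_exactly(self):
        """Entropy errors equal the differences of their summand errors."""
        params = EntropyParams(m=2, r=0.25)
        for name in ("uniform", "gaussian", "exponential"):
            d = get_distribution(name)
            for seed in range(10):
                dec = decompose_errors(generate_series(d, 150, seed=seed), params, d)
                assert dec.eps_apen == pytest.approx(
                    dec.eps_phi_m - dec.eps_phi_m1, abs=1e-12
                )
                if dec.sampen_defined:
                    assert dec.eps_sampen == pytest.approx(
                        dec.eps_psi_m - dec.eps_psi_m1, abs=1e-12
                    )

    def test_per_template_errors_bounded(self):
        d = get_distribution("gaussian")
        dec = decompose_errors(
            generate_series(d, 200, seed=1), EntropyParams(m=2, r=0.2), d
        )
        for e in (dec.eps_A_m, dec.eps_A_m1, dec.eps_S_m, dec.eps_S_m1):
            assert np.all(e > -1) and np.all(e < 1)

    def test_uniform_errors_symmetric_about_zero(self):
        """For a symmetric law at large N the SampEn error mean is ~0."""
        d = get_distribution("uniform")
        dec = decompose_errors(
            generate_series(d, 3000, seed=3), EntropyParams(m=2, r=0.3), d
        )
        e = dec.eps_S_m
        assert abs(e.mean()) < 3 * e.std() / np.sqrt(e.size)

    def test_exponential_positive_errors_dominate(self):
        """Under the published (unclipped) convention calculated probabilities
        exceed what the template search attains, so errors skew positive."""
        d = get_distribution("exponential")
        pooled = np.concatenate(
            [
                decompose_errors(
                    generate_series(d, 3000, seed=40 + j),
                    EntropyParams(m=2, r=0.2),
                    d,
                    clip_support=False,
                ).eps_S_m
                for j in range(10)
            ]
        )
        assert pooled.mean() > 0
        assert np.mean(pooled > 0) > 0.5

    def test_external_series_requires_explicit_dist(self):
        with pytest.raises(ValueError):
            decompose_errors(
                TimeSeries(np.linspace(-1, 1, 50)), EntropyParams(m=2, r=0.2)
            )

    def test_metadata_distribution_used_when_omitted(self):
        s = generate_series(get_distribution("uniform"), 100, seed=0)
        dec = decompose_errors(s, EntropyParams(m=2, r=0.2))
        assert dec.eps_A_m.shape == (99,)


class TestLattice:
    def test_synthetic_lattice_detected(self):
        # values on a known grid plus unique continuous stragglers
        rng = np.random.default_rng(1)
        grid = 0.004 * np.arange(8)
        errors = np.concatenate([np.repeat(grid, 5), rng.uniform(0, 0.03, 10)])
        assert lattice_spacing(errors) == pytest.approx(0.004, rel=1e-9)

    def test_spacing_matches_probability_quantum(self):
        d = get_distribution("uniform")
        dec = decompose_errors(
            generate_series(d, 300, seed=5), EntropyParams(m=2, r=0.2), d
        )
        assert lattice_spacing(dec.eps_S_m) == pytest.approx(1 / 298, rel=1e-9)

    def test_apen_histogram_shifted_by_one_quantum(self):
        """Self-match inclusion shifts the ApEn error distribution by 1/(N-m)."""
        d = get_distribution("uniform")
        n, m = 300, 3
        shifts = []
        for seed in range(20):
            dec = decompose_errors(
                generate_series(d, n, seed=seed), EntropyParams(m=m, r=0.2), d
            )
            k = len(dec.eps_S_m)
            shifts.append(np.mean(dec.eps_S_m - dec.eps_A_m[:k]))
        assert np.mean(shifts) == pytest.approx(1 / (n - m), rel=0.15)

    def test_error_distribution_report(self):
        d = get_distribution("uniform")
        dec = decompose_errors(
            generate_series(d, 300, seed=7), EntropyParams(m=2, r=0.2), d
        )
        rep = error_distribution(dec.eps_S_m, n_quant=100)
        assert rep.counts.sum() == dec.eps_S_m.size
        assert rep.density_x.shape == (100,)
        assert np.all(rep.density_y >= 0)
        assert rep.spacing == pytest.approx(1 / 298, rel=1e-9)
        assert rep.n_atoms >= 3

    def test_empty_errors_rejected(self):
        with pytest.raises(ValueError):
            error_distribution([])

    def test_cancellation_ratio_limits(self):
        assert cancellation_ratio([0.1, -0.1]) == pytest.approx(0.0)
        assert cancellation_ratio([0.1, 0.2]) == pytest.approx(1.0)
        assert cancellation_ratio([0.0, 0.0]) == 0.0


class TestIncidence:
    def test_full_support_threshold_no_zero_matches(self):
        d = get_distribution("uniform")
        rep = zero_match_incidence(d, 50, EntropyParams(m=2, r=4.0), 20, seed=0)
        assert rep.zero_match_pct == 0.0
        assert rep.undefined_pct == 0.0

    def test_short_low_threshold_series_sometimes_undefined(self):
        for name in ("uniform", "gaussian", "exponential"):
            rep = undefined_sampen_incidence(
                get_distribution(name), 50, EntropyParams(m=2, r=0.1), 200, seed=0
            )
            assert rep.undefined_pct > 0.0

    def test_no_cross_match_series_always_undefined(self, s6):
        """All-zero B on the worked example: single-series incidence is 100%."""
        spread = TimeSeries(np.arange(6, dtype=float) * 10)
        from entroq.entropy import count_matches

        c = count_matches(spread, EntropyParams(m=2, r=0.1))
        assert c.B.sum() == 0

    def test_long_series_never_undefined(self):
        rep = undefined_sampen_incidence(
            get_distribution("gaussian"), 3000, EntropyParams(m=2, r=0.2), 20, seed=0
        )
        assert rep.undefined_pct == 0.0

    def test_replicates_validated(self):
        with pytest.raises(ValueError):
            zero_match_incidence(
                get_distribution("uniform"), 100, EntropyParams(), 0, seed=0
            )


class TestProbabilityCI:
    def test_interval_contains_calculated_value(self):
        """Coverage of the exact binomial interval for a fixed m=2 template."""
        d = get_distribution("uniform")
        params = EntropyParams(m=2, r=0.2)
        hits = 0
        for run in range(100):
            ci = matching_prob_ci(
                [-0.1, 0.1], d, n=100, params=params, replicates=200,
                level=0.95, seed=1000 * run,
            )
            if ci.lower <= ci.calculated <= ci.upper:
                hits += 1
        assert hits >= 93

    def test_rare_template_zero_lower_bound_flagged(self):
        d = get_distribution("uniform")
        ci = matching_prob_ci(
            [-0.1, 0.1, 0.6], d, n=20, params=EntropyParams(m=3, r=0.02),
            replicates=5, seed=3,
        )
        assert ci.zero_lower_bound
        assert ci.lower == 0.0

    def test_interval_tightens_with_replicates(self):
        d = get_distribution("gaussian")
        params = EntropyParams(m=2, r=0.2)
        narrow = matching_prob_ci([0.0, 0.0], d, 200, params, replicates=400, seed=0)
        wide = matching_prob_ci([0.0, 0.0], d, 200, params, replicates=20, seed=0)
        assert narrow.upper - narrow.lower < wide.upper - wide.lower
        assert abs(narrow.mean_estimate - narrow.calculated) < 0.01

    def test_invalid_template_rejected(self):
        with pytest.raises(ValueError):
            matching_prob_ci(
                [0.0, 5.0], get_distribution("uniform"), 100,
                EntropyParams(m=2, r=0.2), replicates=10, seed=0,
            )
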