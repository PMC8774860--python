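# Methods

## Model and scope

The package treats ApEn and SampEn as estimators of functionals of a
matching probability, and studies their error on i.i.d. series drawn
from known standardized laws. The estimated matching probability of a
template is a relative frequency, hence quantized to multiples of
1/(N−m+1) (ApEn, order m) or 1/(N−m) (SampEn and all order-(m+1)
counts, τ = 1). The calculated probability integrates the generating
density and is continuous. Everything the package measures — error
histograms, lattice spacing, cancellation ratios, incidence of
zero-matches, confidence intervals — derives from that contrast.

Per-template errors are defined calculated-minus-estimated,
ε = p − p̂. Summand errors are computed as differences of defined
quantities (Φ̂ − Φ, Ψ̂ − Ψ), never through the per-template logarithmic
expansion, which is only formal: an individual ε can exceed its p,
putting a negative argument under the log. The entropy-error identities
εApEn = εΦ⁽ᵐ⁾ − εΦ⁽ᵐ⁺¹⁾ and εSampEn = εΨ⁽ᵐ⁾ − εΨ⁽ᵐ⁺¹⁾ then hold by
construction and are re-verified to 1e−12 in the tests. When ΣB or ΣA
is zero the Ψ-side quantities are NaN and the series is counted as
"undefined SampEn" rather than contributing to error moments.

## Index conventions

The ApEn order-m loop runs over i, j = 1…N−m+1 with the self-match
included; SampEn restricts both indices to 1…N−m and excludes the
self-match, with Aᵢ = Cᵢ⁽ᵐ⁺¹⁾ − 1. Several public implementations
truncate the ApEn order-m loop to N−m as well; the difference is
O(1/N) but visible in the six-sample worked example, which this
package reproduces exactly (C = [3,3,3,1,1], B = [2,2,2,0],
A = [1,1,0,0], ApEn = 0.08945, SampEn = ln 3). The exact-probability
vector at order m is computed at full length N−m+1; ApEn consumes all
of it, SampEn its first N−m entries. Similarity is inclusive (d ≤ r),
compared with plain `<=` and no epsilon slack; tests that exercise
ties use exactly representable binary fractions. τ > 1 is supported
throughout the counting machinery, but all shipped experiments use
τ = 1, the near-universal choice for beat-to-beat data.

## Source laws and the generator

Three standardized laws are built in: uniform on [−√3, √3], standard
Gaussian, and unit exponential shifted to mean 0 (support [−1, ∞)).
They cover the bounded-symmetric, unbounded-symmetric and skewed cases
while keeping every interval probability in closed form. Synthetic
series are **not** empirically re-standardized: the laws already have
mean 0 and SD 1, and the calculated probabilities assume the
theoretical law, not sample moments. External CSV series are
empirically standardized before entropy estimation (the CLI `entropy`
command does this unless `--no-standardize` is passed), which is also
what makes r interpretable in SD units there.

The generator emulates *amplitude structure only*: i.i.d. draws have no
autocorrelation, no nonstationarity, no measurement artifacts, and no
cardiac dynamics. Passing tests therefore demonstrate the estimators'
sampling behavior under known laws — not that real recordings satisfy
those laws. The interpolation operation reintroduces the one feature of
oversampled physiological signals that matters for entropy, namely
strong serial dependence, by inserting k deterministic samples per gap
(length N + (N−1)k ≈ N(k+1); the ±k end-effect relative to an exact
(k+1)-fold length is accepted). The interpolation kernel is not pinned
down by common practice, so both `cubic_spline` (default, mimicking
smooth resampling of beat-to-beat data) and `linear` are provided.
Interpolated series are fed to the estimators as produced; cubic or
linear smoothing shrinks the sample SD slightly below 1, which at fixed
r makes matches marginally *more* likely and so cannot manufacture the
entropy drop the interpolation study measures — the drop is driven by
the inserted samples' predictability.

## Support clipping and the persistent exponential error

The per-sample calculated probability is ∫ f over [x−r, x+r]. The
default implementation evaluates it as F(x+r) − F(x−r) with F the CDF,
which clips the integration bounds to the support on both sides and
always yields a valid probability. The closed forms that circulate in
print are not always clipped: the two-exponential expression for the
shifted exponential law keeps "integrating density" below the support
edge −1 whenever x − r < −1, which at r = 0.2 affects the lowest ~18%
of samples and overstates their probabilities (at x = −1, r = 0.2:
0.4027 unclipped vs 0.1813 clipped).

This is not a cosmetic discrepancy. With clipped probabilities the mean
exponential SampEn error decays like that of the symmetric laws
(≈ −0.001 at N = 3000 in our runs). Under the unclipped convention the
calculated probabilities systematically exceed anything the template
search can attain, positive errors dominate (mean ε ≈ +0.008
per template), the cancellation ratio |Σε|/Σ|ε| rises to ≈ 0.84, and
the SampEn error plateaus near 0.11 — a persistent, N-independent bias.
That persistent-error regime is the published behavior for skewed data,
so `exact_sample_prob`, `ExactProbabilities` and `decompose_errors`
expose `clip_support` (default `True` = valid probability;
`False` = unclipped convention), and the skewed-law acceptance test
uses `clip_support=False` deliberately. Users comparing against
published skewed-law error curves should do the same; users who want a
correct probability model should keep the default.

## Parameters and defaults

| parameter | default | meaning / rationale |
|---|---|---|
| m | 2 | template length; m = 2 is the standard choice for beat-to-beat series, m = 3 exercises the low-probability regime |
| r | 0.2 | similarity threshold in SD units of the standardized series |
| τ | 1 | template stride; decorrelation delays are supported but unused by the experiments |
| n0 | 75 | interpolation-study base length: one minute of human beat-to-beat data at ~75 bpm |
| k | 1…10 (study), 0…20 supported | interpolated samples per gap |
| CI level | 0.95 | Clopper–Pearson exact binomial on pooled match counts |
| replicates | 50–1000 depending on the quantity | chosen so Monte-Carlo standard errors sit well inside the asserted margins |

Replicate j of any experiment uses seed `base_seed + j`
(`numpy.random.default_rng`), so every table cell is bit-for-bit
reproducible. The i.i.d. control arm of the interpolation study uses a
fixed large seed offset to stay independent of the interpolated arm,
and its series length is the exact interpolated length n0 + (n0−1)k
rather than the approximate (k+1)·n0, making the paired comparison
length-exact.

## Numerical choices

- **Counting** is vectorized over an N×N Boolean within-r matrix with
  shifted AND-reduction across template coordinates — O(N²·m) time and
  O(N²) memory, ample for N ≤ ~10⁴ — and is verified exactly against a
  brute-force triple loop on 200 random small instances.
- **Lattice detection**: per-template errors are sorted; values closer
  than 1e−9 are merged (floating-point noise). Values with multiplicity
  ≥ 2 are taken as the discrete atoms — continuous borderline-template
  errors are almost surely unique, so this projection isolates the
  lattice even when continuous values interleave with it. The reported
  spacing is the modal gap between consecutive atoms (gaps clustered at
  1e−6 relative tolerance; ties resolve to the smallest). With fewer
  than 3 atoms the detector falls back to all distinct values. Errors
  from replicate series of the same law may be pooled: interior
  templates share one calculated probability, so all replicates populate
  the *same* lattice.
- **Histograms** use Freedman–Diaconis binning; the smoothed density is
  a Gaussian KDE with Silverman bandwidth.
- **Probabilities** are computed in linear space (at the m, r ranges of
  interest they stay ≥ ~1e−6); a template probability underflowing
  linear precision triggers a RuntimeWarning rather than silent zero.
- **Zero-match incidence** is defined per template — the percentage of
  order-m SampEn templates with Bᵢ = 0, averaged over replicate
  series — not per series; the per-series reading is a different (much
  larger) quantity and does not cross 10% at the lengths where the
  per-template one does.
- **Confidence intervals** pool match counts over replicates and apply
  the exact (Clopper–Pearson) binomial interval; a pooled count of zero
  is reported with lower bound exactly 0 and flagged. Matches of a
  fixed template against overlapping series templates are weakly
  dependent; the exact interval's conservatism absorbs this at the
  settings tested (coverage ≥ 93/100 in the suite).
- **Uniform closed-form entropy** −ln((4r√3 − r²)/12) is accepted on
  (0, 2√3]; at the right endpoint every pair matches and the value is
  exactly 0. Reference values used in tests: 2.18804 (r = 0.2), 1.79755
  (r = 0.3), 1.31736 (r = 0.5), 0.70519 (r = 1.0) — all evaluated from
  the formula itself.

## Problem sizes in the shipped suite

The test suite and acceptance script run at desk scale: 50 replicates
of N = 3000 for the closed-form comparison; 20 replicates pooled for
each lattice detection; 1000 × N = 250 and 200 × N = 2500 for the
zero-match incidences; 100 replicates of N = 3000 per law for the
cancellation analysis; 200 replicates at N ∈ {100, 300} for the bias
ordering; 50 replicates per k for the interpolation study. All are
package defaults exposed as parameters; larger settings only tighten
the Monte-Carlo standard errors.

## Known limitations

- The error analysis requires a known generating density; there are no
  closed forms for empirical distributions, so user-supplied recordings
  get entropy estimation and the segment-and-average protocol but not
  the ε decomposition.
- i.i.d. surrogates ignore the autocorrelation of real beat-to-beat
  series; conclusions about estimator bias transfer only insofar as the
  matching-probability mechanism, not the signal dynamics, drives them.
- SampEn monotonicity in r is an empirical regularity, not a theorem;
  the suite checks it over seeded replicates and would surface
  violations rather than assume them.
- No analytic sampling distribution of either statistic is provided;
  all distributional statements are Monte-Carlo.
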