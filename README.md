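# entroq

Quantization-error analysis of approximate entropy (ApEn) and sample
entropy (SampEn) for short, standardized time series.

ApEn and SampEn are the workhorse regularity statistics for physiological
recordings — beat-to-beat pulse intervals, heart rate, systolic blood
pressure — yet on short records they are biased, inconsistent, and
occasionally undefined. The root cause is simple to state: both
statistics are built from *matching probabilities* that are estimated as
relative frequencies, so the estimates can only take values on a lattice
with spacing 1/(N−m), while the true probabilities are continuous. This
package implements the estimators, the exact ("calculated") matching
probabilities for three standardized source laws, and the error
decomposition that makes the quantization effect measurable — so that
anyone choosing N, m and r for an entropy study can see the error
structure those choices imply.

## The statistics

Given a series x₁,…,x_N, overlapping template vectors
Xᵢ = [xᵢ, xᵢ₊τ, …, xᵢ₊₍ₘ₋₁₎τ] are compared under the Chebyshev distance
d(Xᵢ,Xⱼ) = maxₖ |xᵢ₊ₖ − xⱼ₊ₖ|, with a match declared when d ≤ r
(inclusive). With Cᵢ the match counts including the self-match and
Bᵢ, Aᵢ the self-excluded counts at orders m and m+1:

    ApEn(m,r,N)   = Φ̂⁽ᵐ⁾ − Φ̂⁽ᵐ⁺¹⁾,   Φ̂⁽ᵐ⁾ = mean ln(Cᵢ/(N−m+1))
    SampEn(m,r,N) = −ln(ΣAᵢ / ΣBᵢ)

Index conventions matter at these sample sizes: the ApEn order-m loop
runs over i, j = 1…N−m+1 while SampEn restricts both indices to N−m.
SampEn is undefined (flagged, not raised) when ΣB = 0 or ΣA = 0.

For i.i.d. data from a known density f, the probability that template
Xᵢ finds a match is exactly ∏ₖ ∫ f over [xᵢ₊ₖ−r, xᵢ₊ₖ+r], and the
per-template error εᵢ = pᵢ − p̂ᵢ decomposes the entropy errors as
εApEn = εΦ⁽ᵐ⁾ − εΦ⁽ᵐ⁺¹⁾ and εSampEn = εΨ⁽ᵐ⁾ − εΨ⁽ᵐ⁺¹⁾. Three
standardized laws (mean 0, SD 1) are built in: uniform on [−√3, √3],
standard Gaussian, and the unit exponential shifted to mean 0. For the
uniform law the entropy itself has the closed form
−ln((4r√3 − r²)/12), identical for ApEn and SampEn.

## Worked example

The six-sample series S₆ = [0, 0.1, 0.05, 0.15, 0.5, 0.1] with m = 2,
r = 0.1 can be enumerated by hand and pins down every convention:

```python
>>> from entroq import TimeSeries, EntropyParams, count_matches, apen, sampen
>>> s6 = TimeSeries([0, 0.1, 0.05, 0.15, 0.5, 0.1])
>>> p = EntropyParams(m=2, r=0.1)
>>> c = count_matches(s6, p)
>>> c.C_m, c.B, c.A
(array([3, 3, 3, 1, 1]), array([2, 2, 2, 0]), array([1, 1, 0, 0]))
>>> apen(s6, p).value
0.08945023160668342
>>> sampen(s6, p).value   # -ln(2/6) = ln 3
1.0986122886681096
```

The counts say: templates 1–3 each match the other two (plus, for C,
themselves) at distance ≤ 0.1, template 4 matches nothing; at order 3
only the first two templates still match each other. At scale, the
Monte-Carlo mean tracks the uniform closed form:

```python
>>> from entroq import ExperimentGrid, run_entropy_vs_length
>>> grid = ExperimentGrid(distributions=("uniform",), N_values=(3000,),
...                       r_values=(0.2,), replicates=50, base_seed=1)
>>> df = run_entropy_vs_length(grid)
>>> df[df.kind == "SampEn"][["mean", "SD", "theory_value"]].round(4)
     mean      SD  theory_value
1  2.1839  0.0140        2.1880
```

i.e. 50 series of N = 3000 give mean SampEn 2.1839 ± 0.0140 (SD)
against the theoretical 2.1880 — within 3 standard errors — while ApEn
at the same setting is visibly biased low (2.0734).

A command-line interface mirrors the library
(`entroq generate | interp | entropy | exactp | uniform-entropy |
errors | incidence | ci | experiment`), e.g.:

```sh
entroq generate --dist uniform --n 1000 --seed 1 --out series.csv
entroq entropy --in series.csv --kind both --m 2 --r 0.2 --no-standardize
```

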