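# Methods

## Model and assumptions

Paired measurements (X₁ᵢ, X₂ᵢ), i = 1…n, are modelled as independent draws
from a bivariate normal distribution with means (μ₁, μ₂), SDs (σ₁, σ₂) and
correlation ρ. Agreement is summarized two ways:

* **Limits of agreement (LoA).** With dᵢ = X₂ᵢ − X₁ᵢ, d̄ the mean
  difference and S_d² the 1/(n−1) variance of the differences, the LoA are
  d̄ ± t₍ₙ₋₁,α/2₎·S_d. They contain roughly 100(1−α)% of differences and
  are judged against an externally supplied acceptable difference.
* **Concordance correlation coefficient (CCC).** ρ_c = ρ·C_b with
  C_b = 2/(σ₁/σ₂ + σ₂/σ₁ + (μ₁−μ₂)²/(σ₁σ₂)) ∈ (0, 1]. The sample version
  is Lin's estimator ρ̂_c = 2s₁₂/(s₁² + s₂² + (x̄₁−x̄₂)²) with 1/n moment
  denominators, and Ĉ_b = ρ̂_c/ρ̂.

The **reference band** connects the two. Under the homogeneity assumption
C_b = 1 (μ₁ = μ₂, σ₁ = σ₂ = σ), √n(X̄₂−X̄₁)/S_d follows Student's t with
ν = n−1 degrees of freedom, and S_d² estimates 2σ²(1−ρ). Fixing a
concordance threshold ρ_L, the band |d| ≤ ω_RB with

ω_RB = t₍ν,α/2₎·S_d·√((1−ρ_L)/(1−ρ̂)) = t₍ν,α/2₎·σ̂·√(2(1−ρ_L)),
σ̂ = S_d/√(2(1−ρ̂)),

is centred on zero (not on d̄: under concordance the differences scatter
around zero). The construction gives three exact order relations: ρ̂ ⋛ ρ_L
iff ω_RB ⋛ ω (the LoA half-width). If the data are concordant at least at
ρ_L and C_b = 1, about 100(1−α)% of differences fall inside; a point with
|dᵢ| > ω_RB (strict inequality; boundary points are inside) is reported as
an outlier, and the outlier percentage is empirically anti-correlated with
the sample CCC.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| α | band/LoA confidence complement | 0.05 | two-sided |
| ρ_L | lower bound of excellent concordance | 0.75 | widely used CCC benchmark; user-configurable |
| denominator | moment convention in `summarize_pairs` | 1/n | CCC always uses 1/n; S_d always uses 1/(n−1), as the LoA definition fixes it |

The difference orientation is d = X₂ − X₁ with the column order taken from
the caller; the bundled PEFR data set orients the mini meter as X₁ so the
mean difference is large-minus-mini (−2.12 l/min).

## Numerical choices and degenerate inputs

* ρ̂ is the plain product-moment correlation (denominator-invariant) and is
  clipped to [−1, 1] against floating-point overshoot.
* When 1 − ρ̂ < 10⁻⁸ the ratio S_d/√(2(1−ρ̂)) is numerically unstable
  (0/0 in the limit of identical columns); σ̂ falls back to the pooled form
  √((s₁²+s₂²)/2), which is algebraically equal under the band's σ₁ = σ₂
  assumption. Both closed forms of ω_RB are otherwise evaluated and
  cross-checked to 10⁻¹⁰ relative tolerance on every call.
* Negative ρ̂ is allowed (it only narrows the band) but triggers a warning,
  since agreement with negatively correlated measurements is implausible.
* Zero variance in a column makes ρ̂ and ρ̂_c undefined: the estimator
  operations raise, while the moment-level summary reports NaN.
* A CCC of exactly 0 leaves Ĉ_b undefined; it is reported as missing
  rather than as a number.

## Diagnostics

The band's width is valid under σ₁ = σ₂. The package checks this with the
Pitman-Morgan paired-sample test: for bivariate normal pairs,
σ₁ = σ₂ iff corr(X₁+X₂, X₁−X₂) = 0, so the test computes that correlation
r and refers r√(n−2)/√(1−r²) to t with n−2 df (two-sided, level 0.05 by
default). An unpaired F-test would ignore the pairing and is not offered.
When homogeneity is rejected the analysis still runs but a warning is
logged, because the band width may then be unreliable. The slope of the
least-squares line of differences on averages is reported as a second,
graphical heterogeneity cue: its sign tracks sign(σ₂ − σ₁) in expectation,
and the vertical offset tracks μ₂ − μ₁.

## Monte-Carlo engine

`run_scenario` draws independent samples per run (master seed spawning one
substream per run, so results are reproducible and order-independent),
computes Lin's CCC, both half-widths and the band-outlier percentage per
run, and `summarize_runs` reports medians and ranges over runs; degenerate
runs are flagged and excluded with a count. The built-in registry holds
four bivariate-normal scenarios — I (μ₁=μ₂=1, σ₁=σ₂=1, ρ=0.75), II (same,
ρ=0.85), III (σ₁=σ₂=2, ρ=0.85) and IV (μ₁=1, μ₂=1.5, σ₁=1, σ₂=1.2,
ρ=0.6725, so C_b=0.8922 and ρ_c=0.6) — and four correlated-uniform
scenarios at ρ_u = 0.65/0.75/0.85/0.9, all with α=0.05 and ρ_L=0.75,
defaulting to 10,000 runs of n=1000 pairs. The test suite and the
acceptance script use 2000 runs of n=1000, which stabilizes the medians to
within ~0.1 percentage point (bootstrap SE of the median ≈ 0.03–0.05) at a
few seconds per scenario; the full 10,000-run configuration is a flag away.

### Correlated uniforms

Two generators produce uniform [0, 1] marginals with a target Pearson
correlation ρ_u:

* **mixture** (default): x₂ = x₁ with probability |ρ_u| (x₂ = 1 − x₁ for
  negative targets), an independent uniform otherwise. The correlation is
  exactly ρ_u and the construction covers the full range [−1, 1].
* **gaussian_copula**: a latent bivariate normal with correlation
  ρ_z = 2·sin(πρ_u/6) — the exact inverse of the uniform-marginal Pearson
  mapping — pushed through the normal CDF.

Marginals and correlation are identical; the joint laws are not, and the
band-outlier rate depends on the joint law. The mixture concentrates
dependence in a perfectly concordant component and scatters the rest, so
at ρ_u = 0.85 about 5% of differences leave the band; the copula's
differences are nearly Gaussian and only ~2% do. The mixture is the
default because its outlier behaviour matches the published behaviour of
full-range uniform generators of this family; the copula is retained for
studies that want a smooth joint law.

## What the generators do and do not emulate

The bivariate-normal sampler reproduces the assumed data model exactly, so
simulation results validate the band's distribution theory, not its
robustness. Real method-comparison data commonly show proportional error
(SD growing with the mean), occasional gross outliers and non-normal
tails; of these only non-normality (via the uniform family) and variance
heterogeneity (scenario IV) are explored. Passing tests therefore show the
band behaves as designed under its assumptions and degrades as predicted
under the modelled violations — not that it is safe for arbitrary real
data, which is why the variance-homogeneity check is part of the default
report.

## Design choices

* The sample CCC uses 1/n moments (Lin's original estimator); with n = 17
  the 1/(n−1) variant differs only in the fourth decimal, below the
  precision of any reported value.
* The log transform offered at ingestion is the natural log; only
  strict positivity is checked, no shift parameter is estimated.
* Boundary points (|dᵢ| = ω_RB exactly) count as inside the band —
  "exceeds" is read strictly.
* The JSON report stores floats at full repr precision, so a written and
  re-read report is numerically identical.

## Known limitations

* No confidence intervals for the LoA, the CCC or the band width; the band
  is a descriptive reference, not a test with controlled error rates.
* Two measurements only — no repeated-measurement or multi-rater designs,
  and no intraclass correlation.
* The band's nominal content is exact only under bivariate normality with
  equal variances; under the uniform mixture at the threshold it is
  conservative by a few percentage points (see the uniform example).
* The median sample CCC in heterogeneous scenarios sits a hair below the
  population ρ_c (Lin's estimator is mildly biased downward at n = 1000),
  visible in scenario IV as ~0.5995 against the population 0.6.
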