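# Methods

## Generative model

A cohort is n individuals measured at two timepoints an interval
`followup_years` apart. True baseline LTL is drawn i.i.d. from
N(μ_b, σ_b²) in kilobases; true change from N(μ_Δ, σ_Δ²), independent
of baseline; true follow-up is their sum, exactly, for every
individual. Independence of baseline and change encodes the assumption
that adult attrition rate is unrelated to the length a person starts
with; it also makes the truth-track baseline–change correlation exactly
zero, which is what gives the regression-to-the-mean contrast its
interpretation.

An optional binary exposure, assigned to the first
`round(exposure_fraction · n)` individuals (i.i.d. draws are
exchangeable, so deterministic allocation is equivalent to
randomization), shifts mean change by −d·σ_Δ: positive `d` means extra
attrition. Exposure never affects baseline — the scenario is a
randomized exposure, so ANCOVA's collider-bias caveat (baseline
differing by exposure) is deliberately out of scope.

The proxy assay is generated at each timepoint t as

    proxy_t = r_t · z_t(true_t) + sqrt(1 − r_t²) · ε_t,   ε_t ~ N(0, 1) i.i.d.

where z_t standardizes by the **population** moments of the unexposed
generating distribution at that timepoint (baseline: μ_b, σ_b;
follow-up: μ_b + μ_Δ, sqrt(σ_b² + σ_Δ²)). This makes the proxy
unitless with population variance 1 and population proxy–truth
correlation exactly r_t — the assay's validity. The two timepoints'
noise draws are independent: technical error is assumed uncorrelated
across visits (same-batch or storage artifacts correlated within
person are *not* modelled and would change the change-score algebra).

Two consequences of the per-timepoint standardized scale are worth
stating because they are easy to miss:

* the proxy change score has population mean zero whatever μ_Δ is, so
  the proxy's expected apparent-lengthening fraction is 50% *even at
  r = 1*; the lengthening artifact is a property of reporting change on
  a per-timepoint relative scale, compounded (not created) by noise;
* at r = 1 the proxy agrees perfectly with truth cross-sectionally, but
  its change score is not an affine image of true change (the two
  timepoints standardize by different SDs), so change-score agreement
  tops out just below 1 (≈ 0.984 at the defaults).

An alternative proxy form — additive noise in kb — reproduces the
attenuated change-score agreement but predicts a materially different
baseline–change correlation (≈ −0.31 rather than ≈ −0.38 at the
defaults) and does not produce the 50% lengthening fraction; the
standardized form is the one whose implied sampling distributions match
the reference medians this package reproduces, and is the default and
only form implemented.

## Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| n_individuals | 20 | people | small two-assay validation cohort |
| mean_baseline_kb | 7.0 | kb | typical adult LTL; all computed statistics are location-invariant, so this value affects nothing but the printed kb scale |
| sd_baseline_kb | 0.4524 | kb | back-derived from a mean change of −0.19 kb reported as 0.42 baseline SDs (0.19/0.42) |
| mean_change_kb | −0.19 | kb / 6.6 y | ≈ 29 bp/year, the consensus adult attrition rate |
| sd_change_kb | 0.17 | kb | back-derived from a one-sample t of −5.05 at n = 20 (σ_Δ = 0.19·√20/5.05 = 0.1683, rounded so that 0.5 σ_Δ is exactly 85 bp); the unrounded value is accepted via config |
| followup_years | 6.6 | y | expresses attrition per year only |
| validity_r_* | 0.875 | — | mean of cross-sectional validities of 0.90 (baseline) and 0.85 (follow-up); used at both timepoints, overridable per timepoint |
| exposure_fraction, exposure_effect_d | 0, 0 | — | no exposure unless a power study sets them |

`estimate_power` always sets `exposure_fraction = 0.5` (equal
allocation, the randomized-trial scenario) and uses d = 0.5 — a
conventional medium effect, 85 bp at follow-up — in the shipped
examples and acceptance run.

## Statistics

* **Signature statistics** (per cohort, n ≥ 4): Pearson correlations
  between tracks at baseline, follow-up and for change; within-track
  baseline–change correlations; strict lengthening fractions
  (change > 0; ties are measure-zero under the continuous model and
  count as non-lengthening); mean change in units of the track's sample
  baseline SD (n−1 denominator). A constant series makes the affected
  correlation NaN with a warning, never a silent 0.
* **Replicated studies**: medians and IQRs (linear interpolation
  between order statistics; immaterial at 1,000 replicates) over
  independently seeded cohorts; replicates with an undefined statistic
  are excluded from that statistic's summary and counted.
  `prop_proxy_lengthening_exceeds_true` uses a strict inequality; ties
  count against.
* **Strategies**: equal-variance two-sample t-tests (the generative
  model is homoscedastic; Welch behind a flag), two-sided at α = 0.05
  by default. ANCOVA p-values come from the exposure-coefficient t with
  n − 3 df. The difference-score t is algebraically identical to the
  exposure-coefficient t in a regression of change on exposure; a test
  asserts the identity to 1e-12.
* **Power estimation**: for each grid n, the same simulated cohorts
  feed every strategy and both assays (common random numbers), so
  *orderings* between strategies carry far less Monte-Carlo noise than
  the absolute levels. Errors in a replicate (e.g. a degenerate draw)
  exclude it from that cell, with the count reported. Grid values must
  be even (equal allocation) and ≥ 8.
* **corrstats**: Pearson r with the closed-form t test (n − 2 df;
  |r| = 1 snapped within 1e-12 and reported as p = 0); Fisher z
  = atanh(r); two-correlation comparison in the independent-samples
  form z = (z₁ − z₂)/√(1/(n₁−3) + 1/(n₂−3)) — chosen because it is the
  form that reproduces the reference worked examples — with a
  dependent-samples (Steiger) variant available when the six
  cross-correlations are known; one-way random-effects ICC(1,1) from
  the two ANOVA mean squares, balanced tables only by design.

## Seeding

Every public operation takes an explicit seed. Studies derive replicate
k's seed as `SeedSequence((master_seed, k))`, a stable documented rule,
so single replicates can be re-simulated in isolation and studies are
parallelizable. `simulate_cohort` consumes one stream in a fixed order
(baseline, change, baseline noise, follow-up noise), so the truth track
is identical whether or not a proxy is attached; `attach_proxy` called
separately takes its own seed. CLI runs write a manifest (parameters,
seed, version, output SHA-256 digests) next to their outputs; identical
manifest inputs give byte-identical outputs.

## What the simulations do and do not show

The generator emulates the *statistical* structure of a longitudinal
two-assay comparison: normal cross-sectional variation, small normal
within-person change, calibrated cross-sectional validity, independent
per-visit noise. It does not model plate/well effects, amplification
efficiency, DNA integrity, calibrator normalization, age structure,
more than two waves, heteroscedastic or non-normal error, or error in
the gold standard itself — the truth track is treated as truth, so
proxy-versus-truth power comparisons are *relative*: absolute
truth-track powers are best-case values. Passing tests therefore show
that the implementation reproduces the model's consequences, not that
any particular laboratory assay has these exact error properties.

## Problem sizes and numerical choices

Shipped studies use 1,000 replicates of n = 20 for signature summaries
(median Monte-Carlo SE ≈ 0.008 on a correlation median) and 1,000
replicates per cell for power grids over n ∈ {20, 50, 100, 250, 500,
750, 1000} (binomial SE ≤ 0.016 per cell), sizes at which every
reported contrast is resolved; analytic oracle checks use single
10⁶-person cohorts, where sampling error on a correlation is < 0.002.
Cohort CSVs serialize floats with 17 significant digits and are parsed
with round-trip float precision, so write/read is bit-exact.

One quantitative caveat surfaced by the analytic oracles: the
cross-section strategy's power difference between assays is *not*
uniformly negligible. The standardized follow-up effect is d·σ_Δ/σ_fu
≈ 0.176 on the truth track and r times that (≈ 0.154) on the proxy, so
the two cross-section power curves separate by up to ~0.1 in the
mid-power range (n ≈ 500–1000 at d = 0.5) before re-converging near 1.
"Similar" is a fair description at small n and in the sense of
relative ordering, but a fixed ±0.05 band on the difference is violated
at intermediate-to-large n under this model; the corresponding check in
the test suite documents this by failing at those n.
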