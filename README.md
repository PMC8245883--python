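# telosim

Measurement error in longitudinal telomere-length studies: simulation,
error-signature statistics, and power analysis.

## The problem

Leukocyte telomere length (LTL) shortens by only ~25–30 bp/year in
adults, while between-person variation is ~0.5 kb. A cross-sectional
study therefore tolerates assay noise well, but a longitudinal study —
whose target is the small within-person change ΔLTL = LTL(follow-up) −
LTL(baseline) — both shrinks the signal and doubles the noise. An
error-prone assay (e.g. a qPCR T/S ratio) can correlate r ≈ 0.9 with a
gold standard (e.g. Southern blotting, in kb) in a cross-section yet
agree poorly on ΔLTL, and its change scores show the classic signatures
of measurement error: a spurious negative dependence of measured change
on measured baseline (regression to the mean) and a large fraction of
individuals who appear to *lengthen*.

`telosim` packages this phenomenon for study design. It simulates
two-timepoint cohorts with a truth track and a proxy track, quantifies
the error signatures, and compares the statistical power of the three
standard analysis strategies for a binary exposure X:

* **cross-section** — t-test of follow-up values by X;
* **difference score** — t-test of ΔLTL by X;
* **ANCOVA** — OLS of follow-up on X with baseline as covariate.

## The model

Per individual *i*:

```
baseline_i ~ N(μ_b, σ_b²)                [kb]
change_i   ~ N(μ_Δ − X_i·d·σ_Δ, σ_Δ²)    [kb], independent of baseline
followup_i = baseline_i + change_i
proxy_t,i  = r_t · z_t(true_t,i) + sqrt(1 − r_t²) · ε_t,i   [unitless]
```

where `z_t` standardizes by the *population* mean and SD of the
unexposed distribution at timepoint *t* and `r_t` is the assay's
validity correlation. Defaults: μ_b = 7.0 kb, σ_b = 0.4524 kb,
μ_Δ = −0.19 kb over 6.6 years (29 bp/year), σ_Δ = 0.17 kb,
r = 0.875 at both timepoints.

## Worked example

```python
>>> from telosim import default_params, run_signature_study
>>> study = run_signature_study(default_params(), n_replicates=1000, seed=1)
>>> round(study.medians["r_methods_change"], 3)
0.411
>>> round(study.medians["r_baseline_change_proxy"], 3)
-0.385
>>> study.prop_proxy_lengthening_exceeds_true
0.999
```

Across 1,000 simulated n = 20 cohorts, the proxy–truth correlation is
0.875 at each timepoint by construction, yet the median correlation for
*change* is only ~0.41; the proxy change score correlates ~−0.39 with
proxy baseline (regression to the mean, absent on the truth track,
median ~0.01); and the proxy reports more apparent lengthening than the
truth in ~99.9% of cohorts (~50% vs ~10–15% of individuals).

The `examples/` scripts walk through each capability (simulation,
signatures, power, worked statistics); each prints its numbers with a
short interpretation. A thin CLI mirrors them:

```
telosim simulate --seed 1 --out cohort.csv
telosim signatures --reps 1000 --n 20 --seed 1 --out study.json
telosim power --d 0.5 --reps 1000 --seed 1 --out power.csv
telosim stats compare-corr --r1 0.90 --n1 20 --r2 0.48 --n2 20
```

Power at d = 0.5 (0.5 σ_Δ of extra attrition, an 85 bp group difference
at follow-up; 1,000 replicates, α = 0.05):

```
assay     proxy                                 truth
strategy ancova cross_section difference_score ancova cross_section difference_score
n
50         0.12          0.09             0.11   0.40          0.10             0.40
100        0.18          0.11             0.17   0.69          0.14             0.70
250        0.42          0.21             0.37   0.97          0.27             0.97
500        0.68          0.40             0.61   1.00          0.50             1.00
1000       0.93          0.69             0.89   1.00          0.81             1.00
```

On the truth track the longitudinal strategies dwarf the cross-section
and are nearly identical to each other; on the proxy track the
longitudinal gain is much smaller (ANCOVA keeps a small edge over the
difference score), and a proxy study of n = 1000 has less longitudinal
power than a truth-track study of n = 250.

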