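"""Replicate the measurement-error signature study.

1,000 simulated cohorts of n = 20: within each, correlations between
the two assays at baseline, follow-up and for change, the within-assay
baseline-change correlations, and the apparent-lengthening fractions.
"""

from telosim import default_params, run_signature_study

study = run_signature_study(default_params(), n_replicates=1000, seed=1)

m, iqr = study.medians, study.iqr
for name in ("r_methods_baseline", "r_methods_followup", "r_methods_change",
             "r_baseline_change_proxy", "r_baseline_change_true",
             "frac_lengthening_proxy", "frac_lengthening_true"):
    lo, hi = iqr[name]
    print(f"{name:26s} median {m[name]:+.3f}  IQR [{lo:+.3f}, {hi:+.3f}]")
print(f"proxy lengthening exceeds truth in "
      f"{study.prop_proxy_lengthening_exceeds_true:.1%} of replicates")
print()
print("Cross-sectional agreement stays at its calibrated 0.875, but agreement")
print("for the change score collapses to ~0.42, the proxy change acquires a")
print("spurious negative dependence on proxy baseline (regression to the")
print("mean), and the proxy calls ~50% lengthening where the truth shows")
print("~10-15% (the n=20 median sits on a 5-point grid).")
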