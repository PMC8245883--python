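"""Closed-form moments of the cohort-generating process.

These are exact population values implied by the generative model
(independent normal baseline and change; proxy = r * standardized truth
+ sqrt(1 - r^2) * independent noise at each timepoint).  They serve as
analytic oracles for the Monte-Carlo machinery and as quick design
calculations (expected attrition per year, expected group difference).

All correlations here refer to an unexposed population
(``exposure_fraction = 0``); the exposure mixture changes locations, not
the correlation structure within groups.
"""

from __future__ import annotations

import math

from .params import CohortParams


def corr_true_baseline_followup(params: CohortParams) -> float:
    """corr(true baseline, true follow-up) = sigma_b / sigma_fu.

    High because between-person variation dwarfs within-person change.
    """
    if params.sd_followup_kb == 0:
        raise ValueError("degenerate (zero-variance) follow-up distribution")
    return params.sd_baseline_kb / params.sd_followup_kb


def _proxy_change_var(params: CohortParams) -> float:
    """Variance of the proxy change score (proxy is unit-variance)."""
    rb = params.validity_r_baseline
    rf = params.validity_r_followup
    rho = corr_true_baseline_followup(params)
    # var(rf*z_fu - rb*z_b) + independent noise at both timepoints
    return rb * rb + rf * rf - 2.0 * rb * rf * rho + (1 - rb * rb) + (1 - rf * rf)


def corr_proxy_change_true_change(params: CohortParams) -> float:
    """Population correlation between proxy and true change scores.

    Always below min(r_baseline, r_followup) when r < 1: the change
    score carries measurement error from both timepoints while true
    change is only a small part of the total variation.
    """
    rb = params.validity_r_baseline
    rf = params.validity_r_followup
    sd_d = params.sd_change_kb
    sd_fu = params.sd_followup_kb
    if sd_d == 0:
        raise ValueError("zero-variance change distribution")
    # cov(z_b, change) = 0; cov(z_fu, change) = sd_d^2 / sd_fu
    cov = rf * sd_d * sd_d / sd_fu
    return cov / (math.sqrt(_proxy_change_var(params)) * sd_d)


def corr_proxy_baseline_change(params: CohortParams) -> float:
    """Population correlation between proxy baseline and proxy change.

    Negative whenever the proxy carries error: regression to the mean.
    The truth-track analogue is exactly 0 (baseline and change are
    independent by construction).
    """
    rb = params.validity_r_baseline
    rf = params.validity_r_followup
    rho = corr_true_baseline_followup(params)
    # cov(r_b z_b + s_b e_b, r_f z_fu + s_f e_f - r_b z_b - s_b e_b)
    cov = rb * rf * rho - rb * rb - (1 - rb * rb)
    return cov / math.sqrt(_proxy_change_var(params))


def lengthening_probability_true(params: CohortParams) -> float:
    """P(true change > 0) for an unexposed individual."""
    if params.sd_change_kb == 0:
        return float(params.mean_change_kb > 0)
    z = params.mean_change_kb / params.sd_change_kb
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


def lengthening_probability_proxy(params: CohortParams) -> float:
    """P(proxy change > 0) for an unexposed individual.

    Population standardization makes the proxy change mean-zero, so this
    is exactly 1/2 regardless of the true attrition rate — the proxy's
    apparent-lengthening fraction is driven by noise, not biology.
    """
    if _proxy_change_var(params) == 0:
        return lengthening_probability_true(params)
    return 0.5


def attrition_bp_per_year(params: CohortParams) -> float:
    """Mean attrition rate in base pairs per year (positive = shortening)."""
    return -params.mean_change_kb * 1000.0 / params.followup_years


def exposure_group_difference_bp(params: CohortParams) -> float:
    """Expected unexposed-minus-exposed difference in true follow-up LTL, bp.

    An exposure effect of d standard deviations of change translates to
    d * sd_change_kb kilobases at follow-up.
    """
    return params.exposure_effect_d * params.sd_change_kb * 1000.0
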