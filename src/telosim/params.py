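"""Generative parameters for two-timepoint telomere cohorts.

The default parameter set describes a small adult cohort measured twice
6.6 years apart: true baseline leukocyte telomere length (LTL) is normal
with mean 7.0 kb and SD 0.4524 kb, true change over the interval is normal
with mean -0.19 kb (shortening) and SD 0.17 kb, and the error-prone proxy
assay correlates 0.875 with the truth at each timepoint.  An optional
binary exposure shifts mean change for exposed individuals by
``exposure_effect_d`` standard deviations of the change distribution
(positive d = extra attrition).
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field


class CohortParams(BaseModel):
    """All parameters of the cohort-generating process.

    Attributes
    ----------
    n_individuals
        Number of people in the cohort.
    mean_baseline_kb, sd_baseline_kb
        Mean and SD of true baseline LTL, kilobases.
    mean_change_kb, sd_change_kb
        Mean and SD of true LTL change over the whole follow-up interval,
        kilobases; negative mean = shortening.
    followup_years
        Length of the follow-up interval in years.  Only used to express
        attrition per year; the simulation itself is two-timepoint.
    validity_r_baseline, validity_r_followup
        Population correlation between the proxy assay and true LTL at
        each timepoint.
    exposure_fraction
        Fraction of individuals carrying the binary exposure X.
    exposure_effect_d
        Shift of mean change for exposed individuals in units of
        ``sd_change_kb``; positive = extra attrition, i.e. exposed mean
        change is ``mean_change_kb - d * sd_change_kb``.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    n_individuals: int = Field(default=20, gt=0)
    mean_baseline_kb: float = 7.0
    sd_baseline_kb: float = Field(default=0.4524, ge=0.0)
    mean_change_kb: float = -0.19
    sd_change_kb: float = Field(default=0.17, ge=0.0)
    followup_years: float = Field(default=6.6, gt=0.0)
    validity_r_baseline: float = Field(default=0.875, ge=0.0, le=1.0)
    validity_r_followup: float = Field(default=0.875, ge=0.0, le=1.0)
    exposure_fraction: float = Field(default=0.0, ge=0.0, le=1.0)
    exposure_effect_d: float = 0.0

    def replace(self, **updates) -> "CohortParams":
        """Return a copy with the given fields changed (re-validated)."""
        return CohortParams(**{**self.model_dump(), **updates})

    @property
    def mean_followup_kb(self) -> float:
        """Population mean of unexposed true follow-up LTL, kb."""
        return self.mean_baseline_kb + self.mean_change_kb

    @property
    def sd_followup_kb(self) -> float:
        """Population SD of unexposed true follow-up LTL, kb.

        Baseline and change are independent, so variances add.
        """
        return float((self.sd_baseline_kb**2 + self.sd_change_kb**2) ** 0.5)

    @property
    def n_exposed(self) -> int:
        return int(round(self.exposure_fraction * self.n_individuals))


def default_params(**updates) -> CohortParams:
    """The default parameter set (see module docstring), with overrides."""
    return CohortParams(**updates)
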