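"""Measurement-error signature statistics of a two-track cohort.

The signatures are the footprints classical measurement error leaves on
longitudinal data: agreement between assays collapses for change scores
even when cross-sectional agreement is high; measured change acquires a
spurious negative dependence on measured baseline (regression to the
mean); and a large fraction of individuals appear to lengthen rather
than shorten.  ``signature_stats`` computes them for one cohort;
``run_signature_study`` replicates them over many simulated cohorts and
summarizes the resulting sampling distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields
from typing import Dict, Tuple

import numpy as np

from .cohort import Cohort, simulate_cohort
from .params import CohortParams
from .seeds import child_seed


def _pearson(x: np.ndarray, y: np.ndarray, label: str) -> float:
    """Pearson r, or NaN (with a warning) if either series is constant."""
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn(f"constant series in {label}; correlation undefined", RuntimeWarning)
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass(frozen=True)
class SignatureSummary:
    """Signature statistics of one cohort.

    Correlations named ``r_methods_*`` are between the two assay tracks
    at the stated quantity; ``r_baseline_change_*`` are within-assay
    baseline-versus-change correlations; ``frac_lengthening_*`` are the
    fractions of individuals with strictly positive measured change;
    ``mean_change_sd_units_*`` divide mean change by that assay's sample
    baseline SD (n-1 denominator).
    """

    r_methods_baseline: float
    r_methods_followup: float
    r_methods_change: float
    r_baseline_change_true: float
    r_baseline_change_proxy: float
    frac_lengthening_true: float
    frac_lengthening_proxy: float
    mean_change_sd_units_true: float
    mean_change_sd_units_proxy: float

    def as_dict(self) -> Dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


STATISTIC_NAMES = [f.name for f in fields(SignatureSummary)]


def signature_stats(cohort: Cohort) -> SignatureSummary:
    """Compute the signature statistics of a cohort with both tracks.

    Requires n >= 4.  A constant input series makes the affected
    correlation NaN (with a warning), never silently zero.
    """
    if cohort.n < 4:
        raise ValueError(f"need at least 4 individuals, got {cohort.n}")
    cohort.require_proxy()

    tb, tf = cohort.true_baseline_kb, cohort.true_followup_kb
    pb, pf = cohort.proxy_baseline, cohort.proxy_followup
    tc = cohort.true_change_kb
    pc = pf - pb

    def mean_change_sd_units(change, baseline, label):
        sd = float(np.std(baseline, ddof=1))
        if sd == 0:
            warnings.warn(f"constant baseline in {label}; SD-units change undefined",
                          RuntimeWarning)
            return float("nan")
        return float(np.mean(change) / sd)

    return SignatureSummary(
        r_methods_baseline=_pearson(pb, tb, "methods/baseline"),
        r_methods_followup=_pearson(pf, tf, "methods/followup"),
        r_methods_change=_pearson(pc, tc, "methods/change"),
        r_baseline_change_true=_pearson(tb, tc, "truth baseline/change"),
        r_baseline_change_proxy=_pearson(pb, pc, "proxy baseline/change"),
        frac_lengthening_true=float(np.mean(tc > 0)),
        frac_lengthening_proxy=float(np.mean(pc > 0)),
        mean_change_sd_units_true=mean_change_sd_units(tc, tb, "truth track"),
        mean_change_sd_units_proxy=mean_change_sd_units(pc, pb, "proxy track"),
    )


@dataclass(frozen=True)
class StudySummary:
    """Distributional summary of signature statistics over replicates.

    ``medians`` and ``iqr`` (25th, 75th percentiles; linear
    interpolation between order statistics) are taken over replicates,
    per statistic; replicates where a statistic is undefined are
    excluded from that statistic's summary and counted in
    ``n_undefined``.  ``prop_proxy_lengthening_exceeds_true`` is the
    fraction of replicates whose proxy lengthening fraction strictly
    exceeds the truth-track one (ties count against).
    """

    medians: Dict[str, float]
    iqr: Dict[str, Tuple[float, float]]
    n_undefined: Dict[str, int]
    prop_proxy_lengthening_exceeds_true: float
    n_replicates: int
    n_per_cohort: int
    seed: int
    params: CohortParams = field(repr=False)

    def as_dict(self) -> dict:
        return {
            "medians": dict(self.medians),
            "iqr": {k: list(v) for k, v in self.iqr.items()},
            "n_undefined": dict(self.n_undefined),
            "prop_proxy_lengthening_exceeds_true": self.prop_proxy_lengthening_exceeds_true,
            "n_replicates": self.n_replicates,
            "n_per_cohort": self.n_per_cohort,
            "seed": self.seed,
            "params": self.params.model_dump(),
        }


def run_signature_study(
    params: CohortParams, n_replicates: int, seed: int
) -> StudySummary:
    """Replicate ``signature_stats`` over independently simulated cohorts.

    Replicate k uses ``child_seed(seed, k)``, so any single replicate is
    reproducible in isolation.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")

    values = {name: np.empty(n_replicates) for name in STATISTIC_NAMES}
    for k in range(n_replicates):
        stats = signature_stats(simulate_cohort(params, child_seed(seed, k)))
        for name in STATISTIC_NAMES:
            values[name][k] = getattr(stats, name)

    medians, iqr, n_undef = {}, {}, {}
    for name, v in values.items():
        ok = v[~np.isnan(v)]
        n_undef[name] = int(np.isnan(v).sum())
        if len(ok) == 0:
            medians[name] = float("nan")
            iqr[name] = (float("nan"), float("nan"))
        else:
            medians[name] = float(np.median(ok))
            q25, q75 = np.percentile(ok, [25, 75])
            iqr[name] = (float(q25), float(q75))

    prop = float(
        np.mean(values["frac_lengthening_proxy"] > values["frac_lengthening_true"])
    )
    return StudySummary(
        medians=medians,
        iqr=iqr,
        n_undefined=n_undef,
        prop_proxy_lengthening_exceeds_true=prop,
        n_replicates=n_replicates,
        n_per_cohort=params.n_individuals,
        seed=seed,
        params=params,
    )
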