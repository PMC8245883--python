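"""Correlation and reliability statistics for small assay-comparison studies.

Self-contained utilities for the worked examples that accompany the
simulator: Pearson correlation with its t-based significance test, the
Fisher z transform and z-test comparing two correlations, a one-sample
t-test on change scores, and the one-way random-effects intraclass
correlation for technical replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class CorrelationTest:
    r: float
    n: int
    t_statistic: float
    p_two_sided: float


@dataclass(frozen=True)
class CorrComparison:
    r1: float
    n1: int
    r2: float
    n2: int
    z_statistic: float
    p_two_sided: float


@dataclass(frozen=True)
class ReplicateICC:
    icc: float
    n_subjects: int
    n_replicates_per_subject: int


class TTestResult(NamedTuple):
    t_statistic: float
    p_two_sided: float


def pearson_p(r: float, n: int) -> CorrelationTest:
    """Significance of a pre-computed Pearson r against rho = 0.

    t = r * sqrt(n - 2) / sqrt(1 - r^2), two-sided p from t with n - 2
    degrees of freedom.  |r| = 1 is degenerate and reported as p = 0.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if not -1.0 <= r <= 1.0:
        raise ValueError("correlation outside [-1, 1]")
    if abs(r) == 1.0:
        return CorrelationTest(r=r, n=n, t_statistic=math.copysign(math.inf, r), p_two_sided=0.0)
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return CorrelationTest(r=r, n=n, t_statistic=t, p_two_sided=float(p))


def pearson_test(x, y) -> CorrelationTest:
    """Pearson correlation of two series with its t-test against 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D series of equal length")
    if len(x) < 4:
        raise ValueError("need n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant series")
    r = float(stats.pearsonr(x, y).statistic)
    # snap float noise at the degenerate boundary so perfectly linear
    # inputs report r = +/-1, p = 0
    if 1.0 - abs(r) < 1e-12:
        r = math.copysign(1.0, r)
    return pearson_p(r, len(x))


def fisher_z(r: float) -> float:
    """Variance-stabilizing transform atanh(r); requires |r| < 1."""
    if not -1.0 < r < 1.0:
        raise ValueError("|r| must be < 1")
    return math.atanh(r)


def fisher_z_inverse(z: float) -> float:
    return math.tanh(z)


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> CorrComparison:
    """Fisher z-test for the difference between two correlations.

    Independent-samples form: z = (atanh(r1) - atanh(r2)) /
    sqrt(1/(n1-3) + 1/(n2-3)), two-sided normal p.  The z statistic is
    signed and antisymmetric under swapping the two correlations.
    """
    for n in (n1, n2):
        if n < 4:
            raise ValueError("need n >= 4 in both samples")
    z = (fisher_z(r1) - fisher_z(r2)) / math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return CorrComparison(r1=r1, n1=n1, r2=r2, n2=n2, z_statistic=z, p_two_sided=float(p))


def compare_dependent_correlations(
    r12: float,
    r34: float,
    n: int,
    r13: float,
    r14: float,
    r23: float,
    r24: float,
) -> CorrComparison:
    """Steiger's z-test for two dependent correlations with no shared variable.

    Compares corr(1,2) with corr(3,4) measured on the same n subjects,
    using the full set of cross-correlations to estimate the covariance
    of the two Fisher-z-transformed correlations (Pearson–Filon
    covariance evaluated at the pooled estimate).  With all
    cross-correlations zero it reduces to the independent-samples test
    at equal n.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    psi = (
        0.5 * r12 * r34 * (r13**2 + r14**2 + r23**2 + r24**2)
        + r13 * r24
        + r14 * r23
        - (r12 * r13 * r14 + r12 * r23 * r24 + r34 * r13 * r23 + r34 * r14 * r24)
    )
    cov_z = psi / ((1.0 - r12**2) * (1.0 - r34**2))
    z = (fisher_z(r12) - fisher_z(r34)) * math.sqrt((n - 3) / (2.0 - 2.0 * cov_z))
    p = 2.0 * stats.norm.sf(abs(z))
    return CorrComparison(r1=r12, n1=n, r2=r34, n2=n, z_statistic=z, p_two_sided=float(p))


def one_sample_t(values, mu0: float = 0.0) -> TTestResult:
    """One-sample t-test of the mean against mu0 (two-sided)."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need n >= 2")
    res = stats.ttest_1samp(values, popmean=mu0)
    return TTestResult(float(res.statistic), float(res.pvalue))


def icc_oneway(replicate_table) -> ReplicateICC:
    """One-way random-effects intraclass correlation, ICC(1,1).

    ``replicate_table`` is a balanced subjects x replicates matrix of
    technical replicate measurements.  ICC = (MSB - MSW) /
    (MSB + (k - 1) * MSW) from the one-way ANOVA decomposition; it
    equals 1 exactly when within-subject variance is zero.
    """
    table = np.asarray(replicate_table, dtype=float)
    if table.ndim != 2:
        raise ValueError("replicate table must be 2-D (subjects x replicates)")
    if np.isnan(table).any():
        raise ValueError("unbalanced table (missing values); balanced design required")
    n_subj, k = table.shape
    if n_subj < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 replicates per subject")

    subj_means = table.mean(axis=1)
    grand = table.mean()
    msb = k * np.sum((subj_means - grand) ** 2) / (n_subj - 1)
    msw = np.sum((table - subj_means[:, None]) ** 2) / (n_subj * (k - 1))
    if msb == 0 and msw == 0:
        raise ValueError("all measurements identical; ICC undefined")
    icc = (msb - msw) / (msb + (k - 1) * msw)
    return ReplicateICC(icc=float(icc), n_subjects=n_subj, n_replicates_per_subject=k)
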