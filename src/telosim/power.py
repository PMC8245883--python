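"""Analysis strategies for pre-post exposure designs and their power.

Three ways to test an exposure effect on telomere dynamics in a
two-timepoint cohort:

* ``cross_section`` — two-sample t-test on follow-up values, ignoring
  baseline;
* ``difference_score`` — two-sample t-test on within-individual change;
* ``ancova`` — OLS of follow-up on exposure with baseline as covariate,
  testing the exposure coefficient.

Each can be run on the truth track or on the error-prone proxy track.
``estimate_power`` Monte-Carlo-estimates rejection rates over a grid of
sample sizes; every strategy and assay is evaluated on the *same*
simulated cohorts (common random numbers), so differences and orderings
between strategies are estimated with far less noise than the absolute
power levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .cohort import Cohort, simulate_cohort
from .params import CohortParams
from .seeds import child_seed

STRATEGIES = ("cross_section", "difference_score", "ancova")
ASSAYS = ("truth", "proxy")
DEFAULT_N_GRID = (20, 50, 100, 250, 500, 750, 1000)


@dataclass(frozen=True)
class StrategyResult:
    strategy: str
    assay: str
    effect_estimate: float
    p_value: float


def _groups(cohort: Cohort, values: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    exp = values[cohort.exposed]
    unexp = values[~cohort.exposed]
    if len(exp) < 2 or len(unexp) < 2:
        raise ValueError("need at least 2 exposed and 2 unexposed individuals")
    return exp, unexp


def _two_sample(cohort: Cohort, values: np.ndarray, strategy: str, assay: str,
                welch: bool = False) -> StrategyResult:
    exp, unexp = _groups(cohort, values)
    if not welch and np.ptp(values) == 0:
        raise ValueError("zero pooled variance; t-test undefined")
    res = stats.ttest_ind(exp, unexp, equal_var=not welch)
    return StrategyResult(
        strategy=strategy,
        assay=assay,
        effect_estimate=float(exp.mean() - unexp.mean()),
        p_value=float(res.pvalue),
    )


def analyze_cross_section(cohort: Cohort, assay: str, welch: bool = False) -> StrategyResult:
    """Two-sample t-test of follow-up values by exposure.

    Equal-variance by default (the generative model is homoscedastic);
    set ``welch=True`` for the unequal-variance form.  The effect
    estimate is mean(exposed) - mean(unexposed).
    """
    return _two_sample(cohort, cohort.followup(assay), "cross_section", assay, welch)


def analyze_difference_score(cohort: Cohort, assay: str, welch: bool = False) -> StrategyResult:
    """Two-sample t-test of within-individual change by exposure."""
    return _two_sample(cohort, cohort.change(assay), "difference_score", assay, welch)


def analyze_ancova(cohort: Cohort, assay: str) -> StrategyResult:
    """OLS of follow-up on exposure and baseline; tests the exposure term.

    The p-value comes from the coefficient t statistic with n - 3
    degrees of freedom.  A constant baseline makes the design
    rank-deficient and raises.
    """
    if cohort.n < 4:
        raise ValueError("need n >= 4 for ANCOVA")
    baseline = cohort.baseline(assay)
    followup = cohort.followup(assay)
    _groups(cohort, followup)  # both groups represented
    if np.ptp(baseline) == 0:
        raise ValueError("constant baseline covariate; design is rank-deficient")
    design = sm.add_constant(
        np.column_stack([cohort.exposed.astype(float), baseline]), prepend=True
    )
    fit = sm.OLS(followup, design).fit()
    return StrategyResult(
        strategy="ancova",
        assay=assay,
        effect_estimate=float(fit.params[1]),
        p_value=float(fit.pvalues[1]),
    )


_ANALYZERS = {
    "cross_section": analyze_cross_section,
    "difference_score": analyze_difference_score,
    "ancova": analyze_ancova,
}


def analyze(cohort: Cohort, strategy: str, assay: str) -> StrategyResult:
    """Dispatch to the named analysis strategy."""
    try:
        fn = _ANALYZERS[strategy]
    except KeyError:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    return fn(cohort, assay)


@dataclass(frozen=True)
class PowerCurve:
    """Monte-Carlo power estimates over a sample-size grid.

    ``power`` maps (strategy, assay, n) to the fraction of replicates
    rejecting at ``alpha``; ``reps_used`` counts the replicates that
    completed without error for each cell.
    """

    alpha: float
    effect_d: float
    n_grid: Tuple[int, ...]
    n_replicates: int
    power: Dict[Tuple[str, str, int], float]
    reps_used: Dict[Tuple[str, str, int], int]
    seed: int
    params: CohortParams = field(repr=False)

    def get(self, strategy: str, assay: str, n: int) -> float:
        return self.power[(strategy, assay, n)]

    def to_frame(self):
        """Long table with columns strategy, assay, n, reps_used, power."""
        import pandas as pd

        rows = [
            {"strategy": s, "assay": a, "n": n,
             "reps_used": self.reps_used[(s, a, n)], "power": p}
            for (s, a, n), p in sorted(self.power.items())
        ]
        return pd.DataFrame(rows)


def estimate_power(
    params: CohortParams,
    n_grid: Sequence[int] = DEFAULT_N_GRID,
    n_replicates: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    strategies: Sequence[str] = STRATEGIES,
    assays: Sequence[str] = ASSAYS,
) -> PowerCurve:
    """Estimate power of each strategy x assay over a sample-size grid.

    For each total n (half exposed), ``n_replicates`` cohorts are
    simulated with seeds ``child_seed(seed, k)`` offset per grid point;
    every requested strategy runs on every requested assay of the same
    cohorts.  Replicates where a strategy errors are excluded from that
    cell (``reps_used`` reports the remainder).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    for n in n_grid:
        if n < 8 or n % 2:
            raise ValueError("grid sample sizes must be even and >= 8")
    unknown = set(strategies) - set(STRATEGIES)
    if unknown:
        raise ValueError(f"unknown strategies: {sorted(unknown)}")

    rejections = {(s, a, n): 0 for s in strategies for a in assays for n in n_grid}
    used = {(s, a, n): 0 for s in strategies for a in assays for n in n_grid}
    for i, n in enumerate(n_grid):
        cell_params = params.replace(n_individuals=n, exposure_fraction=0.5)
        for k in range(n_replicates):
            cohort = simulate_cohort(cell_params, child_seed(seed, i * n_replicates + k))
            for s in strategies:
                for a in assays:
                    try:
                        result = analyze(cohort, s, a)
                    except ValueError:
                        continue
                    used[(s, a, n)] += 1
                    rejections[(s, a, n)] += result.p_value < alpha

    power = {
        key: (rejections[key] / used[key]) if used[key] else float("nan")
        for key in rejections
    }
    return PowerCurve(
        alpha=alpha,
        effect_d=params.exposure_effect_d,
        n_grid=tuple(n_grid),
        n_replicates=n_replicates,
        power=power,
        reps_used=used,
        seed=seed,
        params=params,
    )


def plot_power_curve(curve: PowerCurve, path: str) -> None:
    """Save a two-panel power-versus-n figure (one panel per assay)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    assays = sorted({a for (_, a, _) in curve.power})
    fig, axes = plt.subplots(1, len(assays), figsize=(5 * len(assays), 4), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, assay in zip(axes, assays):
        for strategy in STRATEGIES:
            pts = [(n, curve.power[(strategy, assay, n)])
                   for n in curve.n_grid if (strategy, assay, n) in curve.power]
            if pts:
                ax.plot(*zip(*pts), marker="o", label=strategy)
        ax.set_title(f"{assay} track")
        ax.set_xlabel("total sample size")
        ax.set_ylim(0, 1)
    axes[0].set_ylabel(f"power at alpha = {curve.alpha}")
    axes[-1].legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
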