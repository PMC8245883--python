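"""Simulation of two-timepoint telomere cohorts.

A cohort carries two measurement tracks per individual:

* a *truth* track in kilobases — baseline LTL, change, and follow-up LTL
  (follow-up = baseline + change exactly), standing in for a
  gold-standard assay such as Southern blotting of terminal restriction
  fragments;
* an optional *proxy* track — unitless error-prone measurements at each
  timepoint, standing in for a qPCR T/S ratio, generated as
  ``r * z(true) + sqrt(1 - r^2) * noise`` where ``z`` standardizes the
  true value by the population mean and SD of the unexposed generating
  distribution at that timepoint and ``r`` is the assay's validity
  correlation.

Draw order is documented and fixed: baseline normals, then change
normals, then (if a proxy is attached in the same call) baseline noise,
then follow-up noise.  Truth tracks are therefore reproducible from the
seed alone, whether or not a proxy is attached afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .params import CohortParams
from .seeds import child_seed


@dataclass(frozen=True)
class Cohort:
    """Per-individual records of a simulated (or loaded) cohort.

    ``params`` and ``seed`` are generation metadata; both are ``None``
    for cohorts loaded from user CSV files.  ``proxy_baseline`` /
    ``proxy_followup`` are ``None`` for truth-only cohorts.
    """

    ids: np.ndarray
    exposed: np.ndarray
    true_baseline_kb: np.ndarray
    true_change_kb: np.ndarray
    true_followup_kb: np.ndarray
    proxy_baseline: Optional[np.ndarray] = None
    proxy_followup: Optional[np.ndarray] = None
    params: Optional[CohortParams] = None
    seed: Optional[int] = None
    proxy_seed: Optional[int] = None

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def has_proxy(self) -> bool:
        return self.proxy_baseline is not None and self.proxy_followup is not None

    def change(self, assay: str) -> np.ndarray:
        """Change score (follow-up minus baseline) on the given track."""
        if assay == "truth":
            return self.true_change_kb
        if assay == "proxy":
            self.require_proxy()
            return self.proxy_followup - self.proxy_baseline
        raise ValueError(f"unknown assay {assay!r}; expected 'truth' or 'proxy'")

    def baseline(self, assay: str) -> np.ndarray:
        if assay == "truth":
            return self.true_baseline_kb
        if assay == "proxy":
            self.require_proxy()
            return self.proxy_baseline
        raise ValueError(f"unknown assay {assay!r}; expected 'truth' or 'proxy'")

    def followup(self, assay: str) -> np.ndarray:
        if assay == "truth":
            return self.true_followup_kb
        if assay == "proxy":
            self.require_proxy()
            return self.proxy_followup
        raise ValueError(f"unknown assay {assay!r}; expected 'truth' or 'proxy'")

    def require_proxy(self) -> None:
        if not self.has_proxy:
            raise ValueError("cohort has no proxy track; run attach_proxy first")

    def to_frame(self):
        """Wide per-individual table (one row per person)."""
        import pandas as pd

        data = {
            "id": self.ids,
            "exposed": self.exposed.astype(int),
            "true_baseline_kb": self.true_baseline_kb,
            "true_change_kb": self.true_change_kb,
            "true_followup_kb": self.true_followup_kb,
        }
        if self.has_proxy:
            data["proxy_baseline"] = self.proxy_baseline
            data["proxy_followup"] = self.proxy_followup
        return pd.DataFrame(data)


def simulate_true_cohort(params: CohortParams, seed: int) -> Cohort:
    """Draw the truth track of a cohort.

    Baseline ~ Normal(mu_b, sd_b^2) i.i.d.; change ~ Normal(mu_d -
    exposed * d * sd_d, sd_d^2) i.i.d. and independent of baseline;
    follow-up = baseline + change.  Exposure goes to the first
    ``round(exposure_fraction * n)`` individuals — i.i.d. draws are
    exchangeable, so the deterministic allocation is equivalent to a
    random one.
    """
    rng = np.random.default_rng(seed)
    return _simulate_true(params, seed, rng)


def _simulate_true(params: CohortParams, seed: Optional[int], rng: np.random.Generator) -> Cohort:
    n = params.n_individuals
    exposed = np.zeros(n, dtype=bool)
    exposed[: params.n_exposed] = True
    baseline = rng.normal(params.mean_baseline_kb, params.sd_baseline_kb, n)
    mean_change = params.mean_change_kb - exposed * params.exposure_effect_d * params.sd_change_kb
    change = rng.normal(mean_change, params.sd_change_kb)
    return Cohort(
        ids=np.arange(n),
        exposed=exposed,
        true_baseline_kb=baseline,
        true_change_kb=change,
        true_followup_kb=baseline + change,
        params=params,
        seed=seed,
    )


def attach_proxy(
    cohort: Cohort,
    r_baseline: Optional[float] = None,
    r_followup: Optional[float] = None,
    seed: Optional[int] = None,
    _rng: Optional[np.random.Generator] = None,
) -> Cohort:
    """Fill in the proxy track of a truth-only cohort.

    Validity correlations default to those in the cohort's params.  The
    proxy noise uses its own seed, independent of the truth draws.
    Standardization uses the *population* moments of the unexposed
    generating distribution at each timepoint (baseline: mu_b, sd_b;
    follow-up: mu_b + mu_d, sqrt(sd_b^2 + sd_d^2)), not sample moments.
    """
    params = cohort.params
    if params is None:
        raise ValueError("cohort has no generative params; cannot standardize truth")
    if r_baseline is None:
        r_baseline = params.validity_r_baseline
    if r_followup is None:
        r_followup = params.validity_r_followup
    for r in (r_baseline, r_followup):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"validity correlation {r} outside [0, 1]")
    if params.sd_baseline_kb == 0 or params.sd_followup_kb == 0:
        raise ValueError("cannot standardize a zero-variance truth distribution")

    rng = _rng if _rng is not None else np.random.default_rng(seed)
    z_b = (cohort.true_baseline_kb - params.mean_baseline_kb) / params.sd_baseline_kb
    z_fu = (cohort.true_followup_kb - params.mean_followup_kb) / params.sd_followup_kb
    eps_b = rng.standard_normal(cohort.n)
    eps_fu = rng.standard_normal(cohort.n)
    proxy_b = r_baseline * z_b + np.sqrt(1.0 - r_baseline**2) * eps_b
    proxy_fu = r_followup * z_fu + np.sqrt(1.0 - r_followup**2) * eps_fu
    return replace(cohort, proxy_baseline=proxy_b, proxy_followup=proxy_fu, proxy_seed=seed)


def simulate_cohort(params: CohortParams, seed: int) -> Cohort:
    """Simulate a full cohort (truth track plus proxy track) from one seed.

    A single generator stream is consumed in the documented order
    (truth draws first, proxy noise after), so the truth track equals
    ``simulate_true_cohort(params, seed)`` exactly.
    """
    rng = np.random.default_rng(seed)
    truth = _simulate_true(params, seed, rng)
    return attach_proxy(truth, seed=seed, _rng=rng)


def replicate_seeds(master_seed: int, n_replicates: int) -> list[int]:
    """Seeds for the replicates of a study (see :mod:`telosim.seeds`)."""
    return [child_seed(master_seed, k) for k in range(n_replicates)]
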