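"""Desk-scale validation study: power, false-positive rates and MCC.

Mirrors the method's original evaluation design at a scale a workstation can
run: five demographic scenarios (constant size, tenfold expansion, tenfold
bottleneck, and two-population isolation with shallow and deep divergence)
are each simulated at two sampling depths (10 and 50 individuals); each
simulated gene tree is paired with a *surrogate* skyline posterior — a
credible-interval band around the scenario's true size trajectory — and the
posterior predictive check is run on the pair.  Because the two-population
scenarios are analyzed as if the samples came from one panmictic
population, they violate the skyline model; rejection there is a success.

Classification semantics (matching the benchmark's count identities):

* positives   = one-population runs (model adequate);   tp = not rejected
* negatives   = two-population runs (model violated);   tn = rejected

so fp counts one-population runs incorrectly flagged and fn counts missed
violations.  Performance is summarized with the Matthews correlation
coefficient.

The surrogate posterior replaces the full Bayesian Skyline MCMC stage (and
the sequence-simulation / tree re-estimation steps before it); what passing
here shows — and does not show — about the full pipeline is discussed in
docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coalescent_sim import (
    SCENARIO_LABELS,
    DemographicScenario,
    make_scenario,
    simulate_scenario_times,
)
from .ppc import PPCConfig, run_ppc_from_times
from .skyline_log import SkylineTrace

__all__ = [
    "ConfusionCounts",
    "ValidationReport",
    "BENCHMARK_CONFUSION",
    "matthews_cc",
    "surrogate_skyline",
    "run_validation",
]

#: z-quantile for the 95% band of the surrogate posterior.
_Z95 = 1.959963984540054

#: Confusion counts from the method's full-scale benchmark (1,000 datasets:
#: 100 replicates x 5 scenarios x 2 sampling depths, each pushed through
#: Bayesian Skyline MCMC before testing), keyed by sampling group and
#: significance threshold.  Kept as worked examples for the MCC computation
#: and as the reference point the desk-scale study is compared against.
BENCHMARK_CONFUSION: dict[tuple[str, float], "ConfusionCounts"] = {}


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion table under the semantics in the module docstring."""

    tp: int
    tn: int
    fn: int
    fp: int

    @property
    def n_onepop(self) -> int:
        return self.tp + self.fp

    @property
    def n_twopop(self) -> int:
        return self.tn + self.fn


for _group, _alpha, _tp, _tn, _fn, _fp in [
    ("combined", 0.01, 588, 50, 350, 12),
    ("combined", 0.025, 583, 99, 301, 17),
    ("combined", 0.05, 567, 139, 261, 33),
    ("combined", 0.1, 523, 245, 155, 77),
    ("10", 0.01, 290, 11, 189, 10),
    ("10", 0.025, 287, 25, 175, 13),
    ("10", 0.05, 282, 44, 156, 18),
    ("10", 0.1, 259, 101, 99, 41),
    ("50", 0.01, 298, 39, 161, 2),
    ("50", 0.025, 296, 74, 126, 4),
    ("50", 0.05, 285, 95, 105, 15),
    ("50", 0.1, 264, 144, 56, 36),
]:
    BENCHMARK_CONFUSION[(_group, _alpha)] = ConfusionCounts(_tp, _tn, _fn, _fp)


def matthews_cc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient of a 2x2 table.

    Returns 0 when any marginal is empty (the convention of common ML
    toolkits); raises on an all-zero table.
    """
    tp, tn, fn, fp = counts.tp, counts.tn, counts.fn, counts.fp
    if tp == tn == fn == fp == 0:
        raise ValueError("all-zero confusion table")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def surrogate_skyline(
    scenario: DemographicScenario,
    noise_cv: float,
    rng: np.random.Generator,
    n_grid: int = 25,
) -> SkylineTrace:
    """Credible-interval band around a scenario's true size trajectory.

    The grid spans age 0 to the scenario's reference age.  Lower/upper are
    the true Ne times exp(-+ z * noise_cv) (a multiplicative 95% band); the
    median is the true value with lognormal jitter of the same scale,
    clipped into the band.  ``noise_cv = 0`` collapses every row onto the
    truth, so the drawn size-change ratio is exactly the scenario's R.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be nonnegative")
    if scenario.is_twopop:
        # analyzed as a single population, whose census trajectory is two
        # demes totalling 2*theta merging into one ancestral deme of theta
        t_max = 2.0 * scenario.t_div
        grid = np.linspace(0.0, t_max, n_grid)
        truth = np.where(grid < scenario.t_div, 2.0 * scenario.theta, scenario.theta)
    else:
        grid = np.linspace(0.0, scenario.t_ref, n_grid)
        truth = scenario.theta * scenario.ratio ** (grid / scenario.t_ref)
    lower = truth * np.exp(-_Z95 * noise_cv)
    upper = truth * np.exp(_Z95 * noise_cv)
    median = np.clip(truth * np.exp(noise_cv * rng.standard_normal(n_grid)), lower, upper)
    return SkylineTrace(time=grid, mean=median, median=median, lower=lower, upper=upper)


@dataclass(frozen=True)
class ValidationReport:
    """Per-cell p-values plus pooled confusion tables and MCC per alpha."""

    reps: int
    ns: tuple[int, ...]
    alphas: tuple[float, ...]
    noise_cv: float
    seed: int
    p_values: dict  # (scenario label, n) -> np.ndarray of p-values

    def rejection_rate(self, label: str, n: int, alpha: float) -> float:
        p = self.p_values[(label, n)]
        return float(np.mean(p < alpha))

    def confusion(self, alpha: float) -> ConfusionCounts:
        tp = tn = fn = fp = 0
        for (label, _n), p in self.p_values.items():
            rejected = int(np.sum(p < alpha))
            kept = p.size - rejected
            if label.startswith("twopop"):
                tn += rejected
                fn += kept
            else:
                fp += rejected
                tp += kept
        return ConfusionCounts(tp=tp, tn=tn, fn=fn, fp=fp)

    def mcc(self, alpha: float) -> float:
        return matthews_cc(self.confusion(alpha))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (label, n), _p in sorted(self.p_values.items()):
            for alpha in self.alphas:
                rows.append(
                    {
                        "scenario": label,
                        "n": n,
                        "alpha": alpha,
                        "rejection_rate": self.rejection_rate(label, n, alpha),
                    }
                )
        for alpha in self.alphas:
            c = self.confusion(alpha)
            rows.append(
                {
                    "scenario": "POOLED",
                    "n": 0,
                    "alpha": alpha,
                    "rejection_rate": float("nan"),
                    "tp": c.tp,
                    "tn": c.tn,
                    "fn": c.fn,
                    "fp": c.fp,
                    "mcc": self.mcc(alpha),
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_validation(
    reps: int = 100,
    ns: tuple[int, ...] = (10, 50),
    alphas: tuple[float, ...] = (0.01, 0.025, 0.05, 0.1),
    noise_cv: float = 0.25,
    seed: int = 0,
    n_sim: int = 100,
    statistic: str = "cumulative",
    theta: float = 1.0,
    scenarios: tuple[str, ...] = SCENARIO_LABELS,
) -> ValidationReport:
    """Run the scaled-down simulation study.

    For every scenario x sampling depth, ``reps`` replicate gene trees are
    simulated from the true demography, each paired with an independent
    surrogate skyline, and the check is run with ``n_sim`` null replicates.
    Replicates use independently spawned RNG streams, so any single cell is
    reproducible in isolation.
    """
    if reps < 1:
        raise ValueError("reps must be at least 1")
    root = np.random.SeedSequence(seed)
    p_values: dict[tuple[str, int], np.ndarray] = {}
    for label in scenarios:
        scenario = make_scenario(label, theta)
        for n in ns:
            cell_ss = np.random.SeedSequence(
                entropy=root.entropy,
                spawn_key=(SCENARIO_LABELS.index(label), n),
            )
            pvals = np.empty(reps)
            for r, child in enumerate(cell_ss.spawn(reps)):
                rng = np.random.default_rng(child)
                times = simulate_scenario_times(scenario, n, rng)
                trace = surrogate_skyline(scenario, noise_cv, rng)
                config = PPCConfig(n_sim=n_sim, statistic=statistic)
                result = run_ppc_from_times(times, n, trace, config, rng=rng)
                pvals[r] = result.p_value
            p_values[(label, n)] = pvals
    return ValidationReport(
        reps=reps,
        ns=tuple(ns),
        alphas=tuple(alphas),
        noise_cv=noise_cv,
        seed=seed,
        p_values=p_values,
    )
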