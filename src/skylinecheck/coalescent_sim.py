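"""Coalescent simulation of divergence times.

Two samplers back the test and its validation study:

* a one-population sampler under a deterministic size trajectory
  theta(t) = theta * R**(t / t_ref) for ages t <= t_ref, held constant at
  theta * R beyond t_ref (R is the ancestral/current size ratio, t_ref the
  age at which the ancestral size applies).  Coalescence times are drawn by
  time rescaling with the closed-form inverse of the cumulative pair
  intensity — no numerical root finding.  An instantaneous-change variant
  (size jumps from theta to theta*R at t_ref) is available via
  ``trajectory="instantaneous"``.
* a two-population isolation sampler: two constant-size populations of size
  theta coalescing independently until the divergence age t_div, after which
  the surviving lineages enter a single ancestral population of size theta.

Only node ages are generated, never a labeled topology: every summary
statistic used downstream is a function of the ages alone.  Time is in the
same units as theta (the empirical tree's branch-length units).  Under the
ms convention (time in units of 4N generations) a divergence of 4N
generations corresponds to t_div = 2*theta here, and 8N to 4*theta.

The size trajectory is capped at the ancestral value beyond t_ref because an
uncapped exponential with R > 1 leaves a positive probability that lineages
never coalesce (finite total intensity); the cap keeps the tree distribution
proper and mirrors the finite time grid of a skyline reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .tree_io import DivergenceTimes

__all__ = [
    "DemographicScenario",
    "SCENARIO_LABELS",
    "simulate_onepop_times",
    "simulate_onepop_ages_batch",
    "simulate_twopop_times",
    "simulate_scenario_times",
    "make_scenario",
    "ages_to_newick",
]

Trajectory = Literal["exponential", "instantaneous"]

SCENARIO_LABELS = (
    "constant",
    "expansion",
    "bottleneck",
    "twopop_shallow",
    "twopop_deep",
)

#: Default expansion/bottleneck magnitude: 10-fold size change.
DEFAULT_EXPANSION_RATIO = 0.1
DEFAULT_BOTTLENECK_RATIO = 10.0


@dataclass(frozen=True)
class DemographicScenario:
    """One of the five demographic histories used in validation.

    ``theta`` is the (current, per-population) scaled size; ``ratio`` the
    ancestral/current size ratio R (1 for constant and for the isolation
    scenarios, whose populations are individually constant); ``t_ref`` the
    age at which the ancestral size applies; ``t_div`` the divergence age
    for the two-population scenarios, in theta units.
    """

    label: str
    theta: float = 1.0
    ratio: float = 1.0
    t_ref: float = 2.0
    t_div: float | None = None

    def __post_init__(self):
        if self.label not in SCENARIO_LABELS:
            raise ValueError(f"unknown scenario label {self.label!r}")
        if self.theta <= 0 or self.ratio <= 0 or self.t_ref <= 0:
            raise ValueError("theta, ratio and t_ref must be positive")
        if self.is_twopop and (self.t_div is None or self.t_div <= 0):
            raise ValueError("two-population scenarios need t_div > 0")
        if self.label == "constant" and self.ratio != 1.0:
            raise ValueError("constant scenario requires ratio == 1")

    @property
    def is_twopop(self) -> bool:
        return self.label.startswith("twopop")


def make_scenario(label: str, theta: float = 1.0) -> DemographicScenario:
    """Scenario with the study's default parameterization.

    Expansion shrinks the ancestral size tenfold (R = 0.1), bottleneck grows
    it tenfold (R = 10), both reaching the ancestral value at t_ref = 2*theta
    (the scale of the expected tree height).  Divergence ages follow the ms
    4N-unit mapping: shallow = 4N generations = 2*theta, deep = 8N = 4*theta.
    """
    t_ref = 2.0 * theta
    if label == "constant":
        return DemographicScenario(label, theta, 1.0, t_ref)
    if label == "expansion":
        return DemographicScenario(label, theta, DEFAULT_EXPANSION_RATIO, t_ref)
    if label == "bottleneck":
        return DemographicScenario(label, theta, DEFAULT_BOTTLENECK_RATIO, t_ref)
    if label == "twopop_shallow":
        return DemographicScenario(label, theta, 1.0, t_ref, t_div=2.0 * theta)
    if label == "twopop_deep":
        return DemographicScenario(label, theta, 1.0, t_ref, t_div=4.0 * theta)
    raise ValueError(f"unknown scenario label {label!r}")


def _check_onepop_params(n, theta, ratio, t_ref):
    if n < 2:
        raise ValueError(f"need at least 2 samples, got {n}")
    if theta <= 0 or ratio <= 0 or t_ref <= 0:
        raise ValueError("theta, ratio and t_ref must be positive")


def simulate_onepop_ages_batch(
    n: int,
    theta: float,
    ratio: float,
    t_ref: float,
    rng: np.random.Generator,
    n_reps: int,
    trajectory: Trajectory = "exponential",
) -> np.ndarray:
    """Vectorized one-population sampler.

    Returns an (n_reps, n-1) array of node ages, oldest first per row.

    For each lineage count k (n down to 2) an Exp(1) deviate E is mapped to
    the next coalescence age by inverting the cumulative pair intensity
    Lambda(s, t) = C(k,2) * int_s^t du / theta(u) in closed form, piecewise
    over the exponential segment [0, t_ref] and the constant tail.
    """
    _check_onepop_params(n, theta, ratio, t_ref)
    if trajectory not in ("exponential", "instantaneous"):
        raise ValueError(f"unknown trajectory {trajectory!r}")
    beta = np.log(ratio) / t_ref  # theta(t) = theta * exp(beta t) on [0, t_ref]
    ages = np.empty((n_reps, n - 1), dtype=float)
    s = np.zeros(n_reps)
    for j, k in enumerate(range(n, 1, -1)):
        pairs = k * (k - 1) / 2.0
        e = rng.exponential(size=n_reps)
        if ratio == 1.0:
            t = s + theta * e / pairs
        elif trajectory == "instantaneous":
            lam_to_ref = np.where(s < t_ref, pairs * (t_ref - s) / theta, 0.0)
            t = np.where(
                e <= lam_to_ref,
                s + theta * e / pairs,
                np.maximum(s, t_ref) + theta * ratio * (e - lam_to_ref) / pairs,
            )
        else:
            exp_s = np.exp(-beta * np.minimum(s, t_ref))
            exp_ref = np.exp(-beta * t_ref)
            lam_to_ref = np.where(
                s < t_ref, pairs / (theta * beta) * (exp_s - exp_ref), 0.0
            )
            inside = e <= lam_to_ref
            with np.errstate(invalid="ignore", divide="ignore"):
                t_inside = -np.log(exp_s - theta * beta * e / pairs) / beta
            t_tail = np.maximum(s, t_ref) + theta * ratio * (e - lam_to_ref) / pairs
            t = np.where(inside, t_inside, t_tail)
        ages[:, j] = t
        s = t
    return ages[:, ::-1]  # oldest first


def simulate_onepop_times(
    n: int,
    theta: float,
    ratio: float,
    t_ref: float,
    rng: np.random.Generator,
    trajectory: Trajectory = "exponential",
) -> DivergenceTimes:
    """Single replicate of the one-population sampler."""
    ages = simulate_onepop_ages_batch(n, theta, ratio, t_ref, rng, 1, trajectory)
    return DivergenceTimes(ages[0])


def simulate_twopop_times(
    n1: int,
    n2: int,
    theta: float,
    t_div: float,
    rng: np.random.Generator,
) -> DivergenceTimes:
    """Isolation model: two constant-size demes merging at age t_div."""
    if n1 < 1 or n2 < 1:
        raise ValueError("each population needs at least 1 sample")
    if n1 + n2 < 2:
        raise ValueError("need at least 2 samples in total")
    if theta <= 0 or t_div <= 0:
        raise ValueError("theta and t_div must be positive")
    ages: list[float] = []
    survivors = 0
    for n_pop in (n1, n2):
        s, k = 0.0, n_pop
        while k > 1:
            s += rng.exponential(theta / (k * (k - 1) / 2.0))
            if s >= t_div:
                break
            ages.append(s)
            k -= 1
        survivors += k
    s, k = t_div, survivors
    while k > 1:
        s += rng.exponential(theta / (k * (k - 1) / 2.0))
        ages.append(s)
        k -= 1
    return DivergenceTimes(np.sort(np.asarray(ages))[::-1])


def simulate_scenario_times(
    scenario: DemographicScenario,
    n: int,
    rng: np.random.Generator,
    trajectory: Trajectory = "exponential",
) -> DivergenceTimes:
    """Simulate one gene tree's node ages under a validation scenario.

    For the two-population scenarios the n samples are split equally
    between the demes (n must be even).
    """
    if scenario.is_twopop:
        if n % 2:
            raise ValueError("two-population scenarios split n equally; n must be even")
        return simulate_twopop_times(n // 2, n // 2, scenario.theta, scenario.t_div, rng)
    return simulate_onepop_times(
        n, scenario.theta, scenario.ratio, scenario.t_ref, rng, trajectory
    )


def ages_to_newick(ages: DivergenceTimes, labels: list[str] | None = None) -> str:
    """Emit a newick tree with the given node ages and a random-join topology.

    The topology is arbitrary (uniform random join at each coalescence);
    every statistic in this package depends on the ages only, so any
    consistent topology serves for fixtures and interoperability.
    """
    n = ages.n_events + 1
    if labels is None:
        labels = [f"t{i + 1}" for i in range(n)]
    if len(labels) != n:
        raise ValueError(f"need {n} labels, got {len(labels)}")
    rng = np.random.default_rng(ages.n_events)  # topology only; ages fixed
    nodes = [(lab, 0.0) for lab in labels]  # (newick, age)
    for age in sorted(ages.ages):
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (nw_j, age_j) = nodes.pop(j)
        (nw_i, age_i) = nodes.pop(i)
        merged = f"({nw_i}:{age - age_i:.10g},{nw_j}:{age - age_j:.10g})"
        nodes.append((merged, float(age)))
    return nodes[0][0] + ";"
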