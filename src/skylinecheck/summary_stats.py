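"""Tree-shape summary statistics compared between empirical and null trees.

All three statistics are functions of the node ages alone:

* ``cumulative`` — the canonical statistic of the test: with divergence
  times t_1 >= t_2 >= ... >= t_n ordered oldest (rank 1) to youngest
  (rank n),

      S = sum_i t_i / i.

  The oldest events dominate, which makes S sensitive to the branch-length
  distortions that hidden population structure induces near the root.
* ``interval_lengths`` — sum of absolute differences between consecutive
  inter-coalescent interval lengths, youngest interval first (zero for
  equally spaced ages).  Signed and all-pairs variants are available for
  sensitivity analysis.
* ``branching_times`` — the plain sum of node-to-tip distances.

Each is deterministic, permutation-invariant in the input ages and scales
linearly with the time unit.
"""

from __future__ import annotations

import numpy as np

from .tree_io import DivergenceTimes

__all__ = [
    "STATISTICS",
    "cumulative_coalescent_stat",
    "interval_lengths_stat",
    "summed_branching_times",
    "compute_statistic",
]


def _ages_desc(times: DivergenceTimes | np.ndarray) -> np.ndarray:
    if isinstance(times, DivergenceTimes):
        return times.ages
    ages = np.asarray(times, dtype=float)
    if ages.size == 0:
        raise ValueError("empty age vector")
    return np.sort(ages)[::-1]


def cumulative_coalescent_stat(times: DivergenceTimes | np.ndarray) -> float:
    """S = sum of each divergence time divided by its age rank (oldest = 1)."""
    ages = _ages_desc(times)
    ranks = np.arange(1, ages.size + 1)
    return float(np.sum(ages / ranks))


def interval_lengths_stat(
    times: DivergenceTimes | np.ndarray, variant: str = "absolute"
) -> float:
    """Summed differences between consecutive inter-coalescent intervals.

    Ages are anchored at the present (0); interval j is the span between
    successive coalescences walking into the past.  Variants: ``absolute``
    (default, sum |e_j - e_{j+1}|), ``signed`` (sum (e_j - e_{j+1})),
    ``pairwise`` (sum |e_j - e_l| over all pairs j < l).
    """
    ages = _ages_desc(times)
    if ages.size < 2:
        raise ValueError("statistic undefined: needs at least two intervals")
    e = np.diff(np.concatenate([[0.0], ages[::-1]]))  # youngest interval first
    if variant == "absolute":
        return float(np.abs(np.diff(e)).sum())
    if variant == "signed":
        return float(-np.diff(e).sum())  # telescopes to e_1 - e_m
    if variant == "pairwise":
        return float(np.abs(e[:, None] - e[None, :]).sum() / 2.0)
    raise ValueError(f"unknown variant {variant!r}")


def summed_branching_times(times: DivergenceTimes | np.ndarray) -> float:
    """Sum of node-to-tip distances (node ages in an ultrametric tree)."""
    return float(_ages_desc(times).sum())


STATISTICS = {
    "cumulative": cumulative_coalescent_stat,
    "interval_lengths": interval_lengths_stat,
    "branching_times": summed_branching_times,
}


def compute_statistic(name: str, times: DivergenceTimes | np.ndarray) -> float:
    try:
        fn = STATISTICS[name]
    except KeyError:
        raise ValueError(
            f"unknown statistic {name!r}; choose from {sorted(STATISTICS)}"
        ) from None
    return fn(times)
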