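"""Maximum-likelihood estimation of the scaled population size theta.

Under the constant-size coalescent the interval during which k lineages
exist is exponential with rate C(k,2)/theta, so the log-likelihood of a set
of observed intervals {tau_k} is

    l(theta) = sum_k [ log(C(k,2)/theta) - C(k,2) * tau_k / theta ]

which is maximized in closed form at

    theta_hat = sum_k C(k,2) * tau_k / (n_tips - 1).

theta_hat is in the same time units as the tree's branch lengths, and the
identical rate parameterization C(k,2)/theta drives the null simulator, so
estimator and simulator are mutually consistent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateTreeError
from .tree_io import CoalescentIntervals

__all__ = ["ThetaEstimate", "estimate_theta", "theta_loglik"]


@dataclass(frozen=True)
class ThetaEstimate:
    theta: float
    loglik_at_max: float


def estimate_theta(intervals: CoalescentIntervals) -> ThetaEstimate:
    """Closed-form ML estimate of theta from coalescent intervals."""
    weighted = intervals.pairs * intervals.tau
    total = float(weighted.sum())
    if total <= 0.0:
        raise DegenerateTreeError(
            "degenerate tree: all coalescent intervals have zero length"
        )
    n_events = intervals.tau.size
    theta_hat = total / n_events
    return ThetaEstimate(theta=theta_hat, loglik_at_max=theta_loglik(intervals, theta_hat))


def theta_loglik(intervals: CoalescentIntervals, theta: float) -> float:
    """Log-likelihood of the intervals at a given theta (> 0)."""
    if theta <= 0:
        raise ValueError(f"theta must be positive, got {theta}")
    pairs = intervals.pairs.astype(float)
    return float(np.sum(np.log(pairs / theta) - pairs * intervals.tau / theta))
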