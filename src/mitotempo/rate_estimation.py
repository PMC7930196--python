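"""Pairwise modern-vs-ancient substitution-rate estimation.

The per-period rate is the frequentist estimator

    theta = sum(d_ij) / (n * T)          [per genome per year]
    theta_site = theta / L               [per site per year]

where d_ij are pairwise mutational differences between matched modern and
ancient sequences, n the number of pairs, T the period's mean age in years
and L the number of sites (default the full 16,569-bp mitogenome).  Because
the summed count is Poisson under the neutral clock model, the confidence
interval is the exact (Garwood) Poisson interval on sum(d) rescaled by
1/(n*T*L).

The time-dependency of the rate is assessed by ordinary least-squares
regression of the per-period rate on the period's mean age.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .sequence_model import MT_LENGTH

#: Recent germline mutation-rate estimates, per site per year.
GERMLINE_RATE_LOW = 1.30e-8
GERMLINE_RATE_HIGH = 1.89e-8


@dataclass(frozen=True)
class RateEstimate:
    """theta with its Poisson CI and the inputs that produced it."""

    theta_site: float
    theta_genome: float
    ci_low: float  # per site per year
    ci_high: float
    sum_d: int
    n_pairs: int
    T: float
    L: int

    def covers(self, rate_site: float) -> bool:
        return self.ci_low <= rate_site <= self.ci_high


def poisson_interval(k: int, confidence: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) confidence interval for a Poisson mean given count k."""
    if k < 0:
        raise ValueError("count must be non-negative")
    alpha = 1.0 - confidence
    lo = 0.0 if k == 0 else stats.chi2.ppf(alpha / 2, 2 * k) / 2.0
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * k + 2) / 2.0
    return float(lo), float(hi)


def theta(
    sum_d: int,
    n_pairs: int,
    T: float,
    L: int = MT_LENGTH,
    confidence: float = 0.95,
) -> RateEstimate:
    """Rate estimate from a summed pairwise-difference count.

    T is the ancient period's mean age in years; the modern tips' own age
    (-50 BP) is not added to T, matching the estimator's single-T structure.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if T <= 0:
        raise ValueError("T must be positive")
    if L < 1:
        raise ValueError("L must be >= 1")
    if sum_d < 0:
        raise ValueError("sum_d must be non-negative")
    scale = 1.0 / (n_pairs * T)
    theta_genome = sum_d * scale
    lo, hi = poisson_interval(sum_d, confidence)
    return RateEstimate(
        theta_site=theta_genome / L,
        theta_genome=theta_genome,
        ci_low=lo * scale / L,
        ci_high=hi * scale / L,
        sum_d=int(sum_d),
        n_pairs=int(n_pairs),
        T=float(T),
        L=int(L),
    )


def theta_weighted(group_estimates: Sequence[RateEstimate]) -> float:
    """Pair-count-weighted average of per-group per-site rates.

    Equals the rate computed on the pooled counts when all groups share T
    and L.
    """
    if not group_estimates:
        raise ValueError("no group estimates")
    w = np.array([g.n_pairs for g in group_estimates], dtype=float)
    r = np.array([g.theta_site for g in group_estimates], dtype=float)
    return float(np.sum(w * r) / np.sum(w))


def fold_change(rate_a: float, rate_b: float) -> float:
    """How many times faster rate_a is than rate_b."""
    if rate_b <= 0:
        raise ValueError("rate_b must be positive")
    return rate_a / rate_b


def time_dependency_regression(
    points: Sequence[tuple[float, float]] | Mapping[float, float],
) -> tuple[float, float, float, float]:
    """OLS of the per-period rate on the period mean age.

    Returns (slope, intercept, r, p) with a two-sided p-value for slope != 0;
    a significantly negative slope is the time-dependency signature (recent
    periods yield faster apparent rates).
    """
    if isinstance(points, Mapping):
        pts = sorted(points.items())
    else:
        pts = list(points)
    if len(pts) < 3:
        raise ValueError("need at least 3 (T, theta) points")
    T = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    if np.allclose(T, T[0]):
        raise ValueError("all period ages identical; regression undefined")
    res = stats.linregress(T, y)
    return float(res.slope), float(res.intercept), float(res.rvalue), float(res.pvalue)
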