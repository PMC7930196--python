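"""Glue between the stages: per-period rates and the full synthetic pipeline."""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .period_analysis import (
    PeriodBin,
    assign_periods,
    build_pairs,
    pair_difference_vectors,
    period_table,
)
from .rate_estimation import RateEstimate, theta, time_dependency_regression
from .sequence_model import DEFAULT_POLICY, ExclusionPolicy, MT_LENGTH, MitoProfile


def rate_for_bin(
    bin_: PeriodBin,
    profiles: Mapping[str, MitoProfile],
    policy: ExclusionPolicy = DEFAULT_POLICY,
    L: int = MT_LENGTH,
) -> RateEstimate:
    """theta for one period from its summed pairwise differences."""
    groups = pair_difference_vectors(bin_, profiles, policy)
    sum_d = sum(sum(v) for v in groups.values())
    n = sum(len(v) for v in groups.values())
    return theta(sum_d, n, bin_.mean_age, L)


def rates_table(
    bins: Sequence[PeriodBin],
    profiles: Mapping[str, MitoProfile],
    policy: ExclusionPolicy = DEFAULT_POLICY,
    L: int = MT_LENGTH,
) -> pd.DataFrame:
    """Per-period rate estimates, one row per period."""
    rows = []
    for b in sorted(bins, key=lambda b: b.index):
        est = rate_for_bin(b, profiles, policy, L)
        rows.append(
            {
                "period": b.index,
                "mean_age_bp": b.mean_age,
                "n_pairs": est.n_pairs,
                "sum_d": est.sum_d,
                "theta_genome": est.theta_genome,
                "theta_site": est.theta_site,
                "ci_low_site": est.ci_low,
                "ci_high_site": est.ci_high,
            }
        )
    return pd.DataFrame(rows)


def regression_from_rates(rates: pd.DataFrame) -> dict[str, float]:
    """Time-dependency regression of theta_site on period mean age."""
    slope, intercept, r, p = time_dependency_regression(
        list(zip(rates["mean_age_bp"], rates["theta_site"]))
    )
    return {"slope": slope, "intercept": intercept, "r": r, "p": p}


def analyze_profiles(
    profiles: Sequence[MitoProfile],
    edges: Sequence[float] | None = None,
    target_bins: int | None = None,
    policy: ExclusionPolicy = DEFAULT_POLICY,
    L: int = MT_LENGTH,
    pair_mode: str = "best",
) -> dict[str, object]:
    """Full chain: bin ancients, pair moderns, tabulate differences and rates.

    Returns the period bins plus the difference table, the per-period rate
    table, and (when three or more periods exist) the time-dependency
    regression.
    """
    ancients = [p for p in profiles if p.age_bp > 0]
    moderns = [p for p in profiles if p.age_bp <= 0]
    if not ancients or not moderns:
        raise ValueError("need both ancient (age_bp > 0) and modern samples")
    bins = assign_periods(ancients, edges=edges, target_bins=target_bins)
    build_pairs(bins, moderns, mode=pair_mode)
    bins = [b for b in bins if b.pairs]
    if not bins:
        raise ValueError("no period retained any modern/ancient pair")
    by_id = {p.id: p for p in profiles}
    diffs = period_table(bins, by_id, policy, anchor_index=bins[0].index)
    rates = rates_table(bins, by_id, policy, L)
    out: dict[str, object] = {"bins": bins, "differences": diffs, "rates": rates}
    if len(bins) >= 3:
        out["regression"] = regression_from_rates(rates)
    return out
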