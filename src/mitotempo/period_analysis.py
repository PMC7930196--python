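"""Period binning of ancient samples and modern/ancient difference tables.

Ancient mitogenomes are grouped into dated periods; each ancient sample is
paired with phylogenetically equivalent modern samples (longest shared
haplogroup-label prefix within the same macrohaplogroup); the per-period
observed mean pairwise difference is summarised by macrohaplogroup and
pooled, and compared against the expectation under a strict clock anchored
on the youngest period:

    expected_k = (pooled_mean_anchor / mean_age_anchor) * mean_age_k

which is linear in the period's mean age.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sequence_model import DEFAULT_POLICY, ExclusionPolicy, MitoProfile, pair_difference

logger = logging.getLogger(__name__)


@dataclass
class PeriodBin:
    """A dated stratum of ancient samples with their modern pairings."""

    index: int  # 1 = youngest
    ancients: list[MitoProfile]
    pairs: list[tuple[str, str]] = field(default_factory=list)  # (ancient id, modern id)
    mean_age: float = float("nan")
    age_sd: float = float("nan")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass
class DiffSummary:
    """Observed pairwise-difference summary for one period."""

    per_group: dict[str, tuple[float, float, int]]  # macro -> (mean, sd, n)
    pooled_mean: float
    pooled_sd: float
    expected: float = float("nan")

    @property
    def n_pairs(self) -> int:
        return sum(n for _, _, n in self.per_group.values())


def assign_periods(
    ancients: Sequence[MitoProfile],
    edges: Sequence[float] | None = None,
    target_bins: int | None = None,
) -> list[PeriodBin]:
    """Bin ancient samples by calibrated age.

    With explicit ``edges`` the half-open intervals ``[edges[i], edges[i+1])``
    are used; with ``target_bins`` the samples are split into equal-count
    quantile bins.  Bins are ordered youngest to oldest and may not be empty.
    """
    if (edges is None) == (target_bins is None):
        raise ValueError("provide exactly one of edges or target_bins")
    bad = [a.id for a in ancients if a.age_bp <= 0]
    if bad:
        raise ValueError(f"non-ancient samples (age_bp <= 0) passed to assign_periods: {bad}")
    ordered = sorted(ancients, key=lambda a: a.age_bp)
    bins: list[PeriodBin] = []
    if edges is not None:
        edges = sorted(edges)
        for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:]), start=1):
            members = [a for a in ordered if lo <= a.age_bp < hi]
            if not members:
                raise ValueError(f"empty period bin for age interval [{lo}, {hi})")
            bins.append(PeriodBin(index=i, ancients=members))
    else:
        if target_bins < 1 or target_bins > len(ordered):
            raise ValueError(f"target_bins {target_bins} not in [1, {len(ordered)}]")
        for i, chunk in enumerate(np.array_split(np.arange(len(ordered)), target_bins), start=1):
            bins.append(PeriodBin(index=i, ancients=[ordered[j] for j in chunk]))
    return bins


def match_modern(ancient: MitoProfile, modern_pool: Sequence[MitoProfile]) -> list[MitoProfile]:
    """Phylogenetically equivalent moderns for one ancient sample.

    Candidates share the macrohaplogroup; among them, those with the longest
    common haplogroup-label prefix are returned (ties return all).  An empty
    list (with a logged warning) means not even the macrohaplogroup matched.
    """
    if not modern_pool:
        raise ValueError("modern pool is empty")
    candidates = [m for m in modern_pool if m.macrohaplogroup == ancient.macrohaplogroup]
    if not candidates:
        logger.warning(
            "no modern sample shares macrohaplogroup %s with ancient %s",
            ancient.macrohaplogroup, ancient.id,
        )
        return []

    def prefix_len(label: str) -> int:
        n = 0
        for x, y in zip(ancient.haplogroup, label):
            if x != y:
                break
            n += 1
        return n

    best = max(prefix_len(m.haplogroup) for m in candidates)
    return [m for m in candidates if prefix_len(m.haplogroup) == best]


def build_pairs(
    bins: Iterable[PeriodBin],
    modern_pool: Sequence[MitoProfile],
    mode: Literal["best", "cross"] = "best",
    rng: np.random.Generator | None = None,
) -> None:
    """Populate each bin's (ancient, modern) pairs in place.

    ``best`` pairs each ancient with one best-matched modern (deterministic
    first by id unless an rng is given); ``cross`` pairs each ancient with
    every tied best match.
    """
    for b in bins:
        pairs = []
        for a in b.ancients:
            matches = match_modern(a, modern_pool)
            if not matches:
                continue
            matches = sorted(matches, key=lambda m: m.id)
            if mode == "cross":
                pairs.extend((a.id, m.id) for m in matches)
            else:
                pick = matches[0] if rng is None else matches[int(rng.integers(len(matches)))]
                pairs.append((a.id, pick.id))
        b.pairs = pairs
        b.mean_age, b.age_sd = weighted_mean_age(b)


def weighted_mean_age(
    bin_: PeriodBin, weighting: Literal["pairs", "plain"] = "pairs"
) -> tuple[float, float]:
    """Mean age of a period, weighted by each ancient's pair participation.

    ``plain`` ignores pairing and weights every ancient equally.  The sd is
    the same-weighted (population) standard deviation.
    """
    if not bin_.ancients:
        raise ValueError("empty period bin")
    ages = np.array([a.age_bp for a in bin_.ancients], dtype=float)
    if weighting == "plain" or not bin_.pairs:
        w = np.ones_like(ages)
    else:
        counts = {a.id: 0 for a in bin_.ancients}
        for aid, _ in bin_.pairs:
            counts[aid] += 1
        w = np.array([counts[a.id] for a in bin_.ancients], dtype=float)
        if w.sum() == 0:
            w = np.ones_like(ages)
    mean = float(np.average(ages, weights=w))
    sd = float(np.sqrt(np.average((ages - mean) ** 2, weights=w)))
    return mean, sd


def pair_difference_vectors(
    bin_: PeriodBin,
    profiles: Mapping[str, MitoProfile],
    policy: ExclusionPolicy = DEFAULT_POLICY,
) -> dict[str, list[int]]:
    """Per-macrohaplogroup vectors of pairwise differences for one period."""
    groups: dict[str, list[int]] = {}
    for aid, mid in bin_.pairs:
        a, m = profiles[aid], profiles[mid]
        groups.setdefault(a.macrohaplogroup, []).append(pair_difference(a, m, policy))
    return groups


def pooled_mean_from_groups(means: Sequence[float], ns: Sequence[int]) -> float:
    """Pair-count-weighted combination of per-group means."""
    means = np.asarray(means, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if means.shape != ns.shape or ns.sum() <= 0:
        raise ValueError("means and ns must align with positive total n")
    return float(np.sum(means * ns) / np.sum(ns))


def summarize_differences(
    bin_: PeriodBin,
    profiles: Mapping[str, MitoProfile],
    policy: ExclusionPolicy = DEFAULT_POLICY,
) -> DiffSummary:
    """Observed per-group and pooled mean pairwise differences for one period."""
    groups = pair_difference_vectors(bin_, profiles, policy)
    if not groups:
        raise ValueError(f"period {bin_.index} has no resolvable pairs")
    per_group = {}
    all_d: list[int] = []
    for macro, ds in sorted(groups.items()):
        arr = np.asarray(ds, dtype=float)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        per_group[macro] = (float(arr.mean()), sd, int(arr.size))
        all_d.extend(ds)
    pooled = pooled_mean_from_groups(
        [m for m, _, _ in per_group.values()], [n for _, _, n in per_group.values()]
    )
    arr = np.asarray(all_d, dtype=float)
    pooled_sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return DiffSummary(per_group=per_group, pooled_mean=pooled, pooled_sd=pooled_sd)


def expected_differences(bin_mean_age: float, anchor_mean: float, anchor_age: float) -> float:
    """Strict-clock expectation: the anchor period's per-year difference rate
    scaled to the target period's mean age."""
    if anchor_age <= 0:
        raise ValueError("anchor mean age must be positive")
    return (anchor_mean / anchor_age) * bin_mean_age


def homogeneity_test(
    groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
) -> tuple[float, float]:
    """Welch t-test between the two most divergent macrohaplogroup groups.

    Picks the two groups (n >= 2 each) whose means differ most and returns
    the Welch statistic and two-sided p-value; a small p would indicate the
    per-period differences are not homogeneous across macrohaplogroups.
    """
    if isinstance(groups, Mapping):
        vectors = list(groups.values())
    else:
        vectors = list(groups)
    eligible = [np.asarray(v, dtype=float) for v in vectors if len(v) >= 2]
    if len(eligible) < 2:
        raise ValueError("need at least two groups with n >= 2")
    best: tuple[float, int, int] = (-1.0, 0, 1)
    for i in range(len(eligible)):
        for j in range(i + 1, len(eligible)):
            gap = abs(eligible[i].mean() - eligible[j].mean())
            if gap > best[0]:
                best = (gap, i, j)
    _, i, j = best
    t, p = stats.ttest_ind(eligible[i], eligible[j], equal_var=False)
    return float(t), float(p)


def period_table(
    bins: Sequence[PeriodBin],
    profiles: Mapping[str, MitoProfile],
    policy: ExclusionPolicy = DEFAULT_POLICY,
    anchor_index: int = 1,
) -> pd.DataFrame:
    """Observed/expected difference table across periods (one row per period)."""
    summaries = {b.index: summarize_differences(b, profiles, policy) for b in bins}
    anchor = next(b for b in bins if b.index == anchor_index)
    anchor_sum = summaries[anchor.index]
    rows = []
    for b in sorted(bins, key=lambda b: b.index):
        s = summaries[b.index]
        s.expected = expected_differences(b.mean_age, anchor_sum.pooled_mean, anchor.mean_age)
        row = {
            "period": b.index,
            "mean_age_bp": b.mean_age,
            "age_sd": b.age_sd,
            "n_pairs": b.n_pairs,
            "observed_mean": s.pooled_mean,
            "observed_sd": s.pooled_sd,
            "expected": s.expected,
        }
        for macro, (m, sd, n) in s.per_group.items():
            row[f"{macro}_mean"] = m
            row[f"{macro}_sd"] = sd
            row[f"{macro}_n"] = n
        rows.append(row)
    return pd.DataFrame(rows)
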