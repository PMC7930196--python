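"""Period binning, modern matching and the observed/expected difference table."""

import numpy as np
import pytest

from mitotempo import tables
from mitotempo.period_analysis import (
    PeriodBin,
    assign_periods,
    build_pairs,
    expected_differences,
    homogeneity_test,
    match_modern,
    pooled_mean_from_groups,
    summarize_differences,
    weighted_mean_age,
)


def _ancient(make_profile, pid, age, hg="H1"):
    return make_profile(pid, age, hg)


class TestAssignPeriods:
    def test_explicit_edges(self, make_profile):
        ancients = [
            _ancient(make_profile, f"a{i}", age) for i, age in enumerate([100, 200, 5000, 6000])
        ]
        bins = assign_periods(ancients, edges=[0, 1000, 10000])
        assert [len(b.ancients) for b in bins] == [2, 2]
        assert {a.id for a in bins[0].ancients} == {"a0", "a1"}

    def test_single_target_bin_degenerate(self, make_profile):
        ancients = [_ancient(make_profile, f"a{i}", 100 * (i + 1)) for i in range(5)]
        bins = assign_periods(ancients, target_bins=1)
        assert len(bins) == 1 and len(bins[0].ancients) == 5

    def test_quantile_binning_matches_sort_based_oracle(self, make_profile):
        rng = np.random.default_rng(7)
        ages = np.sort(rng.uniform(100, 45000, size=120))
        ancients = [_ancient(make_profile, f"a{i}", age) for i, age in enumerate(ages)]
        bins = assign_periods(ancients, target_bins=10)
        assert len(bins) == 10
        # oracle: equal-count chunks of the sorted age vector
        chunks = np.array_split(ages, 10)
        for b, chunk in zip(bins, chunks):
            got = sorted(a.age_bp for a in b.ancients)
            assert np.allclose(got, chunk)
        means = [np.mean([a.age_bp for a in b.ancients]) for b in bins]
        assert means == sorted(means)

    def test_empty_bin_rejected(self, make_profile):
        ancients = [_ancient(make_profile, "a", 100)]
        with pytest.raises(ValueError, match="empty period"):
            assign_periods(ancients, edges=[0, 1000, 2000])

    def test_modern_sample_rejected(self, make_profile):
        with pytest.raises(ValueError):
            assign_periods([make_profile("m", -50, "H1")], target_bins=1)


class TestWeightedMeanAge:
    def test_single_ancient(self, make_profile):
        b = PeriodBin(1, [_ancient(make_profile, "a", 1000)], pairs=[("a", f"m{i}") for i in range(5)])
        assert weighted_mean_age(b) == (1000, 0)

    def test_symmetric_equal_weights(self, make_profile):
        b = PeriodBin(
            1,
            [_ancient(make_profile, "a", 1000), _ancient(make_profile, "b", 3000)],
            pairs=[("a", "m1"), ("b", "m2")],
        )
        assert weighted_mean_age(b) == (2000, 1000)

    def test_pair_participation_weights(self, make_profile):
        # 1000 BP with 3 pairs, 3000 BP with 1 pair -> 1500 +- 866.03
        b = PeriodBin(
            1,
            [_ancient(make_profile, "a", 1000), _ancient(make_profile, "b", 3000)],
            pairs=[("a", "m1"), ("a", "m2"), ("a", "m3"), ("b", "m1")],
        )
        mean, sd = weighted_mean_age(b)
        assert mean == pytest.approx(1500)
        assert sd == pytest.approx(866.03, abs=0.01)

    def test_plain_weighting_switch(self, make_profile):
        b = PeriodBin(
            1,
            [_ancient(make_profile, "a", 1000), _ancient(make_profile, "b", 3000)],
            pairs=[("a", "m1"), ("a", "m2"), ("a", "m3"), ("b", "m1")],
        )
        mean, _ = weighted_mean_age(b, weighting="plain")
        assert mean == pytest.approx(2000)


class TestMatchModern:
    def test_longest_prefix_wins(self, make_profile):
        ancient = make_profile("a", 1000, "U5a")
        pool = [make_profile(x, -50, x) for x in ("U5a1", "U5b", "H1")]
        assert [m.haplogroup for m in match_modern(ancient, pool)] == ["U5a1"]

    def test_ties_return_all(self, make_profile):
        ancient = make_profile("a", 1000, "H")
        pool = [make_profile("m1", -50, "H"), make_profile("m2", -50, "H")]
        assert len(match_modern(ancient, pool)) == 2

    def test_no_macrohaplogroup_match_is_empty_with_warning(self, make_profile, caplog):
        ancient = make_profile("a", 1000, "M7")
        pool = [make_profile("m1", -50, "R0"), make_profile("m2", -50, "N1")]
        with caplog.at_level("WARNING"):
            assert match_modern(ancient, pool) == []
        assert any("macrohaplogroup" in r.message for r in caplog.records)


class TestSummaries:
    @pytest.mark.parametrize(
        "means,ns,pooled",
        [
            ([1.67, 0.34, 0.65], [3, 18, 119], 0.63),
            ([1.86, 2.90, 3.61], [8, 8, 32], 3.20),
            ([2.5], [10], 2.5),
        ],
    )
    def test_pooled_mean_weighted_combination(self, means, ns, pooled):
        assert pooled_mean_from_groups(means, ns) == pytest.approx(pooled, abs=0.005)

    def test_pooled_mean_order_invariant(self):
        a = pooled_mean_from_groups([1.0, 2.0, 5.0], [3, 7, 2])
        b = pooled_mean_from_groups([5.0, 1.0, 2.0], [2, 3, 7])
        assert a == pytest.approx(b)

    def test_summarize_differences_groups_by_macrohaplogroup(self, make_profile):
        a1 = make_profile("a1", 1000, "U5", [(73, "G")])
        a2 = make_profile("a2", 1200, "M7", [(73, "G"), (263, "A")])
        m1 = make_profile("m1", -50, "U5", [])
        m2 = make_profile("m2", -50, "M7", [])
        b = PeriodBin(1, [a1, a2], pairs=[("a1", "m1"), ("a2", "m2")])
        s = summarize_differences(b, {p.id: p for p in (a1, a2, m1, m2)})
        assert s.per_group["R"] == (1.0, 0.0, 1)
        assert s.per_group["M"] == (2.0, 0.0, 1)
        assert s.pooled_mean == pytest.approx(1.5)
        assert s.n_pairs == 2

    def test_all_printed_pooled_means_recombine(self):
        """Pair-count-weighted recombination reproduces the packaged pooled column.

        One row (period 4) is internally inconsistent in the packaged table:
        its pooled cell (1.51) cannot be produced from its own group entries
        (which give 1.49); that row gets the documented wider band.
        """
        t1 = tables.load_period_differences()
        for _, row in t1.iterrows():
            means, ns = [], []
            for g in ("M", "N", "R"):
                if not np.isnan(row[f"{g}_mean"]):
                    means.append(row[f"{g}_mean"])
                    ns.append(int(row[f"{g}_n"]))
            pooled = pooled_mean_from_groups(means, ns)
            tol = 0.02 if row["period"] == 4 else 0.005
            assert pooled == pytest.approx(row["total_mean"], abs=tol), row["period"]
        assert sum(int(t1.loc[i, "total_n"]) for i in t1.index) == 415


class TestExpectedDifferences:
    def test_anchor_rule_against_packaged_expected_column(self):
        t1 = tables.load_period_differences()
        anchor = t1.iloc[0]
        for _, row in t1.iterrows():
            exp = expected_differences(row["mean_age_bp"], anchor["total_mean"], anchor["mean_age_bp"])
            # one printed cell (period 8) is truncated rather than rounded
            assert exp == pytest.approx(row["expected"], abs=0.006), row["period"]

    def test_linear_in_age(self):
        one = expected_differences(5000, 0.63, 1119)
        two = expected_differences(10000, 0.63, 1119)
        assert two == pytest.approx(2 * one)

    def test_self_anchoring_identity(self):
        assert expected_differences(1119, 0.63, 1119) == pytest.approx(0.63)

    def test_zero_anchor_age_rejected(self):
        with pytest.raises(ValueError):
            expected_differences(5000, 0.63, 0)


class TestHomogeneity:
    def test_identical_groups_give_p_one(self):
        t, p = homogeneity_test({"M": [1, 2, 3], "N": [1, 2, 3]})
        assert p == pytest.approx(1.0)

    def test_extreme_separation(self):
        _, p = homogeneity_test({"M": [0, 0, 0, 0], "R": [10, 10, 10, 10]})
        assert p < 0.001

    def test_picks_most_divergent_pair(self):
        # M vs R differ most; N sits between
        t, p = homogeneity_test({"M": [0.0, 0.1, 0.2], "N": [5.0, 5.1], "R": [9.9, 10.0, 10.1]})
        assert p < 0.001

    def test_requires_two_eligible_groups(self):
        with pytest.raises(ValueError):
            homogeneity_test({"M": [1, 2, 3], "N": [5]})


def test_build_pairs_populates_ages(make_profile):
    ancients = [make_profile(f"a{i}", 1000 + 100 * i, "U5") for i in range(4)]
    moderns = [make_profile(f"m{i}", -50, "U5a") for i in range(3)]
    bins = assign_periods(ancients, target_bins=2)
    build_pairs(bins, moderns)
    for b in bins:
        assert b.n_pairs == len(b.ancients)
        assert b.mean_age > 0
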