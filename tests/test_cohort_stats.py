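import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lcis_scna.cohort import (RegionQuery, arm_level_matrix,
                              build_frequency_table, cohort_table_tests,
                              filter_cnv_regions, fisher_2x2, fisher_rxc,
                              hierarchical_cluster, linkage_to_newick,
                              paired_burden_test, rank_trend_test)
from lcis_scna.genome import arm_table
from lcis_scna.segmentation import Segment


def brute_force_2xc_pvalue(table):
    """Independent oracle: enumerate all 2 x c tables with the observed
    margins and sum the probabilities of those no more likely than the
    observed table (probabilities from factorials directly)."""
    table = np.asarray(table, dtype=int)
    col = table.sum(axis=0)
    r1 = table[0].sum()
    n = table.sum()

    def prob(row1):
        num = (math.factorial(r1) * math.factorial(n - r1)
               * math.prod(math.factorial(c) for c in col))
        den = (math.factorial(n)
               * math.prod(math.factorial(a) for a in row1)
               * math.prod(math.factorial(c - a) for c, a in zip(col, row1)))
        return num / den

    p_obs = prob(table[0])
    total = 0.0
    for row1 in itertools.product(*(range(c + 1) for c in col)):
        if sum(row1) != r1:
            continue
        p = prob(row1)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return total


class TestFisher2x2:
    @pytest.mark.parametrize("table,want", [
        ((4, 0, 8, 16), 0.0242),    # high cyclin D1 vs recurrence
        ((1, 3, 1, 23), 0.2698),    # CCND1 gain vs recurrence
        ((10, 17, 0, 28), 0.0003),  # KLF8 gain, pure vs inv
        ((6, 21, 0, 28), 0.0102),   # MACROD2 gain
        ((5, 22, 0, 28), 0.0232),   # RAB11FIP4 gain
        ((2, 26, 10, 15), 0.0072),  # 6q loss, inv vs invasive
    ])
    def test_study_tables(self, table, want):
        assert fisher_2x2(*table).p_two_sided == pytest.approx(want, abs=5e-5)

    def test_empty_margin(self):
        assert fisher_2x2(0, 0, 10, 10).p_two_sided == 1.0
        assert fisher_2x2(0, 10, 0, 10).p_two_sided == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_2x2(-1, 2, 3, 4)

    @given(st.tuples(*[st.integers(0, 12)] * 4))
    @settings(max_examples=100, deadline=None)
    def test_transposition_and_swap_invariance(self, table):
        a, b, c, d = table
        p = fisher_2x2(a, b, c, d).p_two_sided
        assert fisher_2x2(a, c, b, d).p_two_sided == pytest.approx(p)
        assert fisher_2x2(c, d, a, b).p_two_sided == pytest.approx(p)
        assert fisher_2x2(b, a, d, c).p_two_sided == pytest.approx(p)
        assert 0.0 < p <= 1.0


class TestFisherRxc:
    def test_identical_proportions(self):
        assert fisher_rxc([[1, 1, 1], [1, 1, 1]]).p_two_sided == pytest.approx(1.0)

    def test_collapses_to_2x2(self):
        p3 = fisher_rxc([[4, 0, 0], [8, 16, 0]]).p_two_sided
        p2 = fisher_2x2(4, 0, 8, 16).p_two_sided
        assert p3 == pytest.approx(p2)

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            table = rng.integers(0, 13, size=(2, 3))
            want = brute_force_2xc_pvalue(table)
            got = fisher_rxc(table).p_two_sided
            assert got == pytest.approx(want, rel=1e-9, abs=1e-12)

    def test_oversized_table_refused_with_mc_guidance(self):
        with pytest.raises(ValueError, match="montecarlo"):
            fisher_rxc([[50, 70, 30], [45, 35, 25]])

    def test_monte_carlo_close_to_exact(self):
        table = [[5, 1, 9], [2, 8, 3]]
        exact = fisher_rxc(table).p_two_sided
        mc = fisher_rxc(table, method="montecarlo", n_mc=20000, seed=1).p_two_sided
        assert mc == pytest.approx(exact, abs=0.02)


def _seg(sample, chrom, start, end, scna_class, n_probes=150):
    return Segment(chrom, start, end, n_probes, 0.0, 0.0,
                   scna_class=scna_class, sample_id=sample)


class TestFrequencyTable:
    region = RegionQuery("16q", "chr16", 36_800_001, 90_300_000, "loss")

    def test_universal_event(self):
        calls = {f"s{i}": [_seg(f"s{i}", "chr16", 40e6, 80e6, "loss")]
                 for i in range(6)}
        groups = {f"s{i}": "A" if i < 3 else "B" for i in range(6)}
        (table,) = build_frequency_table(calls, groups, [self.region])
        assert table.counts == {"A": (3, 3), "B": (3, 3)}

    def test_no_overlap_counts_zero_but_totals_kept(self):
        calls = {"s0": [_seg("s0", "chr1", 1e6, 2e6, "loss")], "s1": []}
        groups = {"s0": "A", "s1": "A"}
        (table,) = build_frequency_table(calls, groups, [self.region])
        assert table.counts == {"A": (0, 2)}

    def test_single_bp_overlap_and_type_matching(self):
        calls = {
            "s0": [_seg("s0", "chr16", 36_000_000, 36_800_001, "loss")],
            "s1": [_seg("s1", "chr16", 40e6, 50e6, "cnLOH")],  # wrong type
        }
        groups = {"s0": "A", "s1": "A"}
        (table,) = build_frequency_table(calls, groups, [self.region])
        assert table.counts == {"A": (1, 2)}

    def test_missing_group_label_rejected(self):
        with pytest.raises(ValueError, match="group"):
            build_frequency_table({"s0": []}, {}, [self.region])

    def test_pairwise_and_across_tests(self):
        calls = {}
        groups = {}
        for i in range(10):
            groups[f"a{i}"] = "A"
            calls[f"a{i}"] = [_seg(f"a{i}", "chr16", 40e6, 80e6, "loss")]
            groups[f"b{i}"] = "B"
            calls[f"b{i}"] = []
        (table,) = build_frequency_table(calls, groups, [self.region])
        tests = cohort_table_tests(table, ["A", "B"])
        assert tests["A_vs_B"] == pytest.approx(
            fisher_2x2(10, 0, 0, 10).p_two_sided)
        assert tests["across_all"] == pytest.approx(tests["A_vs_B"])


class TestBlacklistFilter:
    regions = [RegionQuery("r1", "chr1", 100, 200, "gain"),
               RegionQuery("r2", "chr1", 300, 400, "gain")]

    def test_empty_blacklist_identity(self):
        kept, removed = filter_cnv_regions(self.regions, [])
        assert kept == self.regions and removed == []

    def test_contained_region_removed_and_logged(self):
        kept, removed = filter_cnv_regions(self.regions, [("chr1", 90, 250)])
        assert [r.name for r in kept] == ["r2"]
        assert removed[0][0].name == "r1"
        assert removed[0][1] == ("chr1", 90, 250)

    def test_abutting_region_retained(self):
        kept, removed = filter_cnv_regions(
            [RegionQuery("r", "chr1", 100, 200, "gain")], [("chr1", 201, 300)])
        assert len(kept) == 1

    def test_never_increases_count(self):
        kept, removed = filter_cnv_regions(self.regions, [("chr1", 1, 1000)])
        assert len(kept) + len(removed) == len(self.regions)


class TestArmMatrix:
    arms = arm_table()

    def test_single_loss_on_16q(self):
        calls = {"s0": [_seg("s0", "chr16", 40e6, 80e6, "loss", n_probes=150)]}
        m = arm_level_matrix(calls, self.arms)
        assert m.loc["s0", "16q"] == "loss"
        assert (m.loc["s0"].drop("16q") == "none").all()

    def test_small_segment_ignored(self):
        calls = {"s0": [_seg("s0", "chr16", 40e6, 80e6, "loss", n_probes=99)]}
        m = arm_level_matrix(calls, self.arms)
        assert (m.loc["s0"] == "none").all()

    def test_dimensions_and_priority(self):
        calls = {"s0": [_seg("s0", "chr16", 40e6, 60e6, "loss"),
                        _seg("s0", "chr16", 61e6, 80e6, "amplification")],
                 "s1": []}
        m = arm_level_matrix(calls, self.arms)
        assert m.shape == (2, len(self.arms))
        assert m.loc["s0", "16q"] == "amplification"

    def test_missing_arm_definitions_rejected(self):
        with pytest.raises(ValueError):
            arm_level_matrix({}, pd.DataFrame())


class TestClustering:
    def _matrix(self):
        arms = ["1q", "16q", "17p"]
        return pd.DataFrame(
            [["gain", "loss", "none"],
             ["gain", "loss", "none"],
             ["none", "none", "loss"]],
            index=["s0", "s1", "s2"], columns=arms)

    def test_identical_samples_merge_first_at_zero(self):
        linkage, order = hierarchical_cluster(self._matrix())
        assert linkage[0, 2] == 0.0  # first merge distance
        assert {int(linkage[0, 0]), int(linkage[0, 1])} == {0, 1}

    def test_duplicated_cohort_coclusters(self):
        m = pd.DataFrame(
            [["gain", "loss", "none"],
             ["none", "loss", "cnLOH"],
             ["none", "none", "loss"]],
            index=["s0", "s1", "s2"], columns=["1q", "16q", "17p"])
        dup = pd.concat([m, m.rename(index=lambda s: s + "_copy")])
        linkage, order = hierarchical_cluster(dup)
        pos = {name: i for i, name in enumerate(order)}
        for s in m.index:
            assert abs(pos[s] - pos[s + "_copy"]) == 1

    def test_fewer_than_two_samples_refused(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(self._matrix().iloc[:1])

    def test_newick_serialisation(self):
        linkage, _ = hierarchical_cluster(self._matrix())
        nwk = linkage_to_newick(linkage, ["s0", "s1", "s2"])
        assert nwk.endswith(";") and "s2" in nwk


def test_rank_trend_detects_increasing_counts():
    counts = [0, 0, 1, 1, 1, 2, 2, 3, 3, 4]
    ordinals = [0, 0, 0, 1, 1, 1, 1, 2, 2, 2]
    tau, p = rank_trend_test(counts, ordinals)
    assert tau > 0.5 and p < 0.05


def test_paired_burden_test_direction():
    lcis = [3, 4, 2, 5, 3, 4, 2, 3]
    ilc = [x + d for x, d in zip(lcis, [2, 1, 3, 1, 2, 2, 1, 2])]
    stat, p = paired_burden_test(lcis, ilc, alternative="greater")
    assert p < 0.05
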