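"""Recombination estimation, Kosambi mapping, grouping/ordering, map QC."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gras2qtl.errors import DataFormatError, InvalidConfigError
from gras2qtl.linkage import (
    GeneticMap,
    LinkageGroup,
    bridge_maps,
    build_map,
    collapse_duplicate_markers,
    encode_genotypes,
    estimate_recombination,
    gap_filter,
    group_markers,
    kosambi_distance,
    kosambi_inverse,
    order_markers,
    pairwise_recombination,
    segregation_distortion_filter,
    segregation_distortion_test,
    summarize_map,
)
from gras2qtl.simulate import SimConfig, simulate_f2_genotypes
from conftest import genotype_frame


def simulate_pair(rng, r, n):
    """One pair of co-dominant markers at true recombination fraction r."""
    h1a = rng.random(n) < 0.5
    h2a = rng.random(n) < 0.5
    h1b = h1a ^ (rng.random(n) < r)
    h2b = h2a ^ (rng.random(n) < r)
    g1 = h1a.astype(int) + h2a.astype(int)
    g2 = h1b.astype(int) + h2b.astype(int)
    return g1, g2


class TestKosambi:
    def test_zero_r_zero_distance(self):
        assert kosambi_distance(0.0) == 0.0
        assert kosambi_inverse(0.0) == 0.0

    def test_quarter_r_closed_form(self):
        assert kosambi_distance(0.25) == pytest.approx(25.0 * np.log(3.0))
        assert kosambi_distance(0.25) == pytest.approx(27.465, abs=0.001)

    @given(r=st.floats(0.01, 0.49))
    def test_inverse_identity(self, r):
        assert kosambi_inverse(kosambi_distance(r)) == pytest.approx(r, abs=1e-12)

    def test_monotone_and_superlinear(self):
        r = np.linspace(0.01, 0.49, 40)
        d = kosambi_distance(r)
        assert np.all(np.diff(d) > 0)
        assert np.all(d >= 100 * r - 1e-9)  # d(cM) >= 100r, equality only at 0

    def test_vectorized(self):
        r = np.array([0.0, 0.1, 0.25])
        assert kosambi_inverse(kosambi_distance(r)) == pytest.approx(r)


class TestEncodeGenotypes:
    def test_codes(self):
        calls = genotype_frame({"m1": "AHB-", "m2": "DRD-"})
        G = encode_genotypes(calls)
        assert G[0].tolist() == [2, 1, 0, -1]
        assert G[1].tolist() == [3, 0, 3, -1]


class TestDuplicateCollapse:
    def test_identical_columns_collapsed(self):
        calls = genotype_frame({"m1": "AHBAHB", "m2": "AHBAHB", "m3": "BHABHA"})
        out, report = collapse_duplicate_markers(calls)
        assert len(out) == 2
        assert "m1" in out.index and "m3" in out.index

    def test_missing_tolerant_keeps_fewest_missing(self):
        calls = genotype_frame({"m1": "AHB-", "m2": "AHBB"})
        out, _ = collapse_duplicate_markers(calls)
        assert list(out.index) == ["m2"]

    def test_conflict_keeps_both(self):
        calls = genotype_frame({"m1": "AHB", "m2": "AHA"})
        out, _ = collapse_duplicate_markers(calls)
        assert len(out) == 2


class TestDistortion:
    def test_perfect_ratio_retained(self):
        row = np.array([2] * 30 + [1] * 60 + [0] * 30)
        chi2, p = segregation_distortion_test(row)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_moderate_distortion_retained(self):
        # class counts (44, 52, 35): chi-square ~ 6.80, P ~ 0.033 > 0.001
        row = np.array([2] * 44 + [1] * 52 + [0] * 35)
        chi2, p = segregation_distortion_test(row)
        assert chi2 == pytest.approx(6.80, abs=0.01)
        assert p == pytest.approx(0.0334, abs=0.001)

    def test_strong_distortion_removed(self):
        calls = genotype_frame(
            {"bad": "A" * 100 + "H" * 40 + "B" * 10, "ok": "A" * 38 + "H" * 75 + "B" * 37}
        )
        out, report = segregation_distortion_filter(calls, alpha=0.001)
        assert list(out.index) == ["ok"]
        assert report.loc["bad", "p_value"] < 0.001

    def test_dominant_marker_tested_3_to_1(self):
        # 3:1 segregation of a dominant marker should not be flagged
        calls = genotype_frame({"morph": "D" * 113 + "R" * 37})
        out, report = segregation_distortion_filter(calls, alpha=0.001)
        assert list(out.index) == ["morph"]
        assert report.loc["morph", "p_value"] > 0.5


class TestRecombination:
    def test_identical_columns_r_zero(self):
        g = np.array([2, 1, 0] * 20)
        pl = estimate_recombination(g, g.copy())
        assert pl.r == pytest.approx(0.0, abs=1e-6)
        assert pl.lod > 3.0

    def test_independent_markers_r_half(self):
        rng = np.random.default_rng(10)
        g1, g2 = simulate_pair(rng, 0.5, 10_000)
        pl = estimate_recombination(g1, g2)
        assert pl.r == pytest.approx(0.5, abs=0.02)
        assert pl.lod < 1.0

    def test_unbiased_at_r_0_1(self):
        rng = np.random.default_rng(11)
        ests = []
        for _ in range(500):
            g1, g2 = simulate_pair(rng, 0.1, 150)
            ests.append(estimate_recombination(g1, g2).r)
        assert np.mean(ests) == pytest.approx(0.1, abs=0.01)

    def test_dominant_codominant_pair(self):
        # dominant collapse of a perfectly co-segregating co-dominant marker
        rng = np.random.default_rng(12)
        g1, _ = simulate_pair(rng, 0.5, 200)
        dom = np.where(g1 >= 1, 3, 0)
        pl = estimate_recombination(dom, g1)
        assert pl.r < 0.02
        assert pl.lod > 3.0

    def test_string_input_accepted(self):
        calls = genotype_frame({"m1": "AAHHBB" * 10, "m2": "AAHHBB" * 10})
        pl = estimate_recombination(calls.loc["m1"], calls.loc["m2"])
        assert pl.r == pytest.approx(0.0, abs=1e-6)

    def test_too_few_joint_observations(self):
        g = np.array([2, -1, -1, -1])
        with pytest.raises(DataFormatError):
            estimate_recombination(g, g[::-1])

    def test_pairwise_matrix_matches_scalar(self):
        rng = np.random.default_rng(13)
        g1, g2 = simulate_pair(rng, 0.2, 150)
        g3, _ = simulate_pair(rng, 0.5, 150)
        G = np.vstack([g1, g2, g3])
        R, LOD = pairwise_recombination(G)
        assert R == pytest.approx(R.T)
        assert np.allclose(np.diag(R), 0.0)
        pl = estimate_recombination(g1, g2)
        assert R[0, 1] == pytest.approx(pl.r, abs=1e-6)
        assert LOD[0, 1] == pytest.approx(pl.lod, abs=1e-4)


class TestGroupingOrdering:
    def test_huge_lod_min_gives_singletons(self):
        R = np.zeros((3, 3))
        LOD = np.full((3, 3), 10.0)
        groups = group_markers(R, LOD, ["a", "b", "c"], lod_min=np.inf)
        assert sorted(map(tuple, groups)) == [("a",), ("b",), ("c",)]

    def test_r_zero_pair_same_group(self):
        R = np.array([[0.0, 0.0], [0.0, 0.0]])
        LOD = np.array([[0.0, 10.0], [10.0, 0.0]])
        groups = group_markers(R, LOD, ["a", "b"])
        assert groups == [["a", "b"]]

    def test_two_marker_order(self):
        R = np.array([[0.0, 0.1], [0.1, 0.0]])
        order, pos = order_markers(["a", "b"], R)
        assert order in (["a", "b"], ["b", "a"])
        assert pos[1] == pytest.approx(kosambi_distance(0.1))

    def test_input_order_invariance(self, small_dataset):
        calls = small_dataset.truth.genotypes.loc[
            [f"LG1M{j:03d}" for j in range(1, 11)]
        ]
        G = encode_genotypes(calls)
        R, _ = pairwise_recombination(G)
        ids = list(calls.index)
        order1, _ = order_markers(ids, R, seed=0)
        perm = np.random.default_rng(14).permutation(len(ids))
        order2, _ = order_markers(
            [ids[i] for i in perm], R[np.ix_(perm, perm)], seed=0
        )
        assert order1 in (order2, order2[::-1])


@pytest.fixture(scope="module")
def recovered(small_dataset):
    return build_map(small_dataset.truth.genotypes, seed=0)


class TestBuildMap:
    def test_groups_recovered(self, recovered):
        assert len(recovered.groups) == 3
        for g in recovered.groups:
            assert len(g.markers) == 10
            lgs = {m[:3] for m in g.markers}
            assert len(lgs) == 1  # no marker placed in a foreign group

    def test_orders_match_truth_up_to_reversal(self, recovered, small_dataset):
        truth_groups = {
            lg.name: list(lg.markers) for lg in small_dataset.truth.map.groups
        }
        for g in recovered.groups:
            truth_order = truth_groups[g.markers[0][:3]]
            assert list(g.markers) in (truth_order, truth_order[::-1])

    def test_positions_monotone_from_zero(self, recovered):
        for g in recovered.groups:
            assert g.positions[0] == 0.0
            assert np.all(np.diff(g.positions) > 0)

    def test_map_frame_round_trip(self, recovered):
        frame = recovered.to_frame()
        back = GeneticMap.from_frame(frame)
        pd.testing.assert_frame_equal(back.to_frame(), frame)


class TestGapFilterAndSummary:
    def _map(self, positions, name="LG1"):
        markers = [f"{name}x{i}" for i in range(len(positions))]
        return GeneticMap([LinkageGroup(name, markers, np.asarray(positions, float))])

    def test_small_gaps_unchanged(self):
        gmap = self._map([0.0, 10.0, 25.0])
        out, log = gap_filter(gmap, max_gap=20.0)
        assert out.to_frame().equals(gmap.to_frame())
        assert log.empty

    def test_oversized_gap_drops_minority_side(self):
        gmap = self._map([0.0, 5.0, 10.0, 40.0, 45.0])
        out, log = gap_filter(gmap, max_gap=20.0)
        # two markers on the right of the gap vs three on the left
        assert list(log["marker"]) == ["LG1x3", "LG1x4"]
        assert out.groups[0].markers == ["LG1x0", "LG1x1", "LG1x2"]

    def test_tie_drops_right_side(self):
        gmap = self._map([0.0, 5.0, 35.0, 40.0])
        out, log = gap_filter(gmap, max_gap=20.0)
        assert log.iloc[0]["marker"] == "LG1x2"

    def test_idempotent(self):
        gmap = self._map([0.0, 5.0, 10.0, 40.0, 45.0, 80.0])
        once, _ = gap_filter(gmap, max_gap=20.0)
        twice, log2 = gap_filter(once, max_gap=20.0)
        assert twice.to_frame().equals(once.to_frame())
        assert log2.empty

    def test_summary_two_markers(self):
        gmap = self._map([0.0, 10.0])
        s = summarize_map(gmap)
        assert s == {
            "n_groups": 1,
            "n_markers": 2,
            "total_length_cM": 10.0,
            "average_marker_distance_cM": 5.0,
        }

    def test_summary_empty_map_raises(self):
        with pytest.raises(InvalidConfigError):
            summarize_map(GeneticMap([]))

    def test_summary_average_is_length_over_n(self):
        gmap = GeneticMap(
            [
                LinkageGroup("LG1", ["a", "b"], np.array([0.0, 589.9])),
                LinkageGroup("LG2", ["c", "d"], np.array([0.0, 589.9])),
            ]
        )
        s = summarize_map(gmap)
        assert s["total_length_cM"] == 1179.8
        assert s["average_marker_distance_cM"] == round(1179.8 / 4, 2)


class TestBridgeMaps:
    def test_identical_maps_consistent(self, small_dataset):
        gmap = build_map(small_dataset.truth.genotypes, seed=0)
        report = bridge_maps(gmap, gmap)
        assert report.n_shared == gmap.n_markers
        assert report.n_inconsistent == 0

    def test_two_population_samples_share_groups(self):
        # two independent F2 samples from the same genome must bridge cleanly
        cfg = SimConfig(
            n_individuals=100,
            n_linkage_groups=3,
            markers_per_group=10,
            qtl_spec=(),
            flowering_qtl_spec=(),
            seed=15,
        )
        g1 = simulate_f2_genotypes(cfg).genotypes
        g2 = simulate_f2_genotypes(dataclasses.replace(cfg, seed=16)).genotypes
        map1 = build_map(g1, seed=0)
        map2 = build_map(g2, seed=0)
        report = bridge_maps(map1, map2)
        assert report.n_shared == 30
        assert report.n_inconsistent == 0

    def test_injected_fault_detected(self, small_dataset):
        gmap = build_map(small_dataset.truth.genotypes, seed=0)
        groups = [
            LinkageGroup(g.name, list(g.markers), g.positions.copy())
            for g in gmap.groups
        ]
        # move one marker to a foreign group in the second map
        moved = groups[0].markers.pop(-1)
        groups[0] = LinkageGroup(
            groups[0].name, groups[0].markers, groups[0].positions[:-1]
        )
        groups[1] = LinkageGroup(
            groups[1].name,
            list(groups[1].markers) + [moved],
            np.append(groups[1].positions, groups[1].positions[-1] + 5.0),
        )
        report = bridge_maps(gmap, GeneticMap(groups))
        assert report.n_inconsistent == 1
        assert report.inconsistent_markers == [moved]
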