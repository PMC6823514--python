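"""Tree geometry, unit conversion and branch-shortening scenarios."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mmbscan.trees import (SpeciesTree, RateCalibration, LineageScenario,
                           LineageSpec, TreeError, UnitError, MIYATA,
                           PAPER_LINEAR, apply_scenario, cumulative_length,
                           mmb_shortening, myr_to_substitutions, scenario_grid,
                           squamate_study_grid, mammal_study_grid, grid_to_tsv)


class TestMyrConversion:
    @pytest.mark.parametrize("myr,expected", [
        (0.0, 0.0),
        (180.0, 0.3996),   # 180e6 yr x 2.22e-9 /site/yr
        (10.0, 0.0222),
    ])
    def test_branch_lengths_scale_by_mu(self, calib, myr, expected):
        tree = SpeciesTree.from_newick(f"(a:{myr},b:{myr});", unit="myr")
        out = myr_to_substitutions(tree, calib)
        assert out.unit == "subs"
        assert out.find("a").length == pytest.approx(expected, abs=1e-12)

    def test_rejects_wrong_unit(self, calib):
        tree = SpeciesTree.from_newick("(a:1,b:1);", unit="subs")
        with pytest.raises(UnitError):
            myr_to_substitutions(tree, calib)

    def test_myr_metadata_preserved(self, calib, ladder_tree):
        out = myr_to_substitutions(ladder_tree, calib)
        assert out.find("a").myr_length == 1.0


class TestShortening:
    @pytest.mark.parametrize("alpha,myr,expected,tol", [
        (6.0, 10.0, 0.0227, 1e-12),    # calibration anchor
        (2.4, 10.0, 0.00908, 1e-12),   # prints as 0.0091
        (4.0, 10.0, 0.0151, 5e-5),     # prints as 0.0151
        (4.0, 180.0, 0.2724, 1e-12),
    ])
    def test_linear_calibration_constants(self, calib, alpha, myr, expected, tol):
        assert mmb_shortening(alpha, myr, calib) == pytest.approx(expected, abs=tol)

    def test_no_bias_means_no_deficit_in_miyata_mode(self):
        calib = RateCalibration(shortening_mode=MIYATA)
        assert mmb_shortening(1.0, 123.0, calib) == 0.0

    @given(alpha=st.floats(1.0, 20.0), myr=st.floats(0.0, 200.0))
    @settings(max_examples=50, deadline=None)
    def test_miyata_deficit_matches_inverse_xa_ratio(self, alpha, myr):
        calib = RateCalibration(shortening_mode=MIYATA)
        delta = mmb_shortening(alpha, myr, calib)
        expected = calib.mu * myr * 1e6 * (1 - 2 * (2 + alpha) / (3 * (1 + alpha)))
        assert delta == pytest.approx(expected, abs=1e-12)

    @given(a1=st.floats(1.0, 19.0), bump=st.floats(0.01, 5.0),
           mode=st.sampled_from([PAPER_LINEAR, MIYATA]))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_alpha(self, a1, bump, mode):
        calib = RateCalibration(shortening_mode=mode)
        assert mmb_shortening(a1 + bump, 10.0, calib) > mmb_shortening(a1, 10.0, calib)

    def test_zero_duration_gives_zero(self, calib):
        for alpha in (1.0, 2.4, 6.0):
            assert mmb_shortening(alpha, 0.0, calib) == 0.0


class TestScenarioGrid:
    def test_enumeration_includes_null(self):
        grid = scenario_grid(["x"], {"x": 4.0}, system_age=20.0, step=10.0)
        assert len(grid) == 3
        assert [s.lineages["x"].retention_t for s in grid] == [0.0, 10.0, 20.0]

    def test_published_squamate_design_has_16_scenarios(self):
        assert len(squamate_study_grid(["aga"], {"aga": 4.0})) == 16

    def test_published_mammal_design_has_18_scenarios(self):
        assert len(mammal_study_grid(["platypus"], {"platypus": 2.9})) == 18

    def test_grid_tsv_lists_every_lineage(self):
        grid = scenario_grid(["x"], {"x": 4.0}, 20.0,
                             fixed={"bg": LineageSpec(6.0, 15.0)})
        tsv = grid_to_tsv(grid)
        assert tsv.count("\nT0") + tsv.count("\tbg\t") >= len(grid)


def _scenario(lineages, age=100.0):
    return LineageScenario(lineages=lineages, system_age=age, scenario_id="t")


class TestApplyScenario:
    def _subs_tree(self, newick, calib, tags=None):
        t = SpeciesTree.from_newick(newick, unit="myr", lineage_tags=tags)
        return myr_to_substitutions(t, calib)

    def test_null_scenario_is_identity(self, calib):
        subs = self._subs_tree("((a:40,b:40):60,c:100);", calib)
        sc = _scenario({"a": LineageSpec(4.0, 0.0)})
        out, adj = apply_scenario(subs, sc, calib)
        assert out.to_newick() == subs.to_newick()
        assert adj == []

    def test_window_inside_one_branch_shortens_it_alone(self, calib):
        # window [80, 100] lies inside c's single 100-Myr branch
        subs = self._subs_tree("((a:40,b:40):60,c:100);", calib)
        sc = _scenario({"c": LineageSpec(4.0, 20.0)})
        out, adj = apply_scenario(subs, sc, calib)
        assert len(adj) == 1 and adj[0].branch == "c"
        delta = mmb_shortening(4.0, 20.0, calib)
        assert out.find("c").length == pytest.approx(subs.find("c").length - delta)
        assert out.find("a").length == subs.find("a").length

    def test_sister_tips_average_alpha_on_shared_branch(self, calib):
        # window [60, 100] covers only the shared stem (60..100 Myr ago)
        subs = self._subs_tree("((a:40,b:40):60,c:100);", calib)
        sc = _scenario({"a": LineageSpec(2.0, 40.0), "b": LineageSpec(4.0, 40.0)})
        out, adj = apply_scenario(subs, sc, calib)
        stem = next(a for a in adj if a.branch == "a|b")
        assert stem.delta_applied == pytest.approx(
            mmb_shortening(3.0, 40.0, calib))

    def test_total_length_drops_by_per_lineage_deficit(self, calib):
        subs = self._subs_tree("((a:40,b:40):60,c:100);", calib)
        sc = _scenario({"c": LineageSpec(6.0, 70.0)})
        out, adj = apply_scenario(subs, sc, calib)
        assert subs.total_length() - out.total_length() == pytest.approx(
            mmb_shortening(6.0, 70.0, calib))
        assert sum(a.delta_applied for a in adj) == pytest.approx(
            mmb_shortening(6.0, 70.0, calib))

    def test_overshortening_clamps_and_reports(self):
        calib = RateCalibration(shortening_mode=PAPER_LINEAR)
        subs = self._subs_tree("(a:10,b:10);", calib)
        sc = _scenario({"a": LineageSpec(18.0, 10.0)}, age=10.0)
        out, adj = apply_scenario(subs, sc, calib)
        assert adj[0].clamped
        assert out.find("a").length == pytest.approx(1e-6, rel=1e-3)

    def test_unknown_lineage_rejected_by_name(self, calib):
        subs = self._subs_tree("(a:10,b:10);", calib)
        sc = _scenario({"nope": LineageSpec(2.0, 5.0)}, age=10.0)
        with pytest.raises(TreeError, match="nope"):
            apply_scenario(subs, sc, calib)

    def test_lineage_tag_selects_clade(self, calib):
        subs = self._subs_tree("((a:40,b:40):60,c:100);", calib,
                               tags={"a": "grp", "b": "grp", "c": "out"})
        sc = _scenario({"grp": LineageSpec(4.0, 100.0)})
        out, adj = apply_scenario(subs, sc, calib)
        assert {x.branch for x in adj} == {"a", "b", "a|b"}


class TestCumulativeLength:
    def test_parent_gives_leaf_branch(self, ladder_tree):
        assert cumulative_length(ladder_tree, "a",
                                 ladder_tree.find("a").parent) == 1.0

    def test_root_on_ladder_sums_path(self, ladder_tree):
        assert cumulative_length(ladder_tree, "a", ladder_tree.root) == 4.0

    def test_matches_brute_force_walker(self, rng):
        nwk = "(((a:1,b:2):3,(c:4,d:5):6):7,e:8);"
        tree = SpeciesTree.from_newick(nwk, unit="myr")
        for leaf in ("a", "b", "c", "d", "e"):
            node = tree.find(leaf)
            # brute force: accumulate parent pointers
            total, n = 0.0, node
            while n.parent is not None:
                total += n.length
                n = n.parent
            assert cumulative_length(tree, leaf, tree.root) == pytest.approx(total)

    def test_non_ancestor_rejected(self, ladder_tree):
        with pytest.raises(TreeError):
            cumulative_length(ladder_tree, "a", ladder_tree.find("c"))


def test_newick_round_trip_preserves_lengths():
    nwk = "((a:0.1,b:0.25):0.05,c:0.4);"
    tree = SpeciesTree.from_newick(nwk, unit="subs")
    again = SpeciesTree.from_newick(tree.to_newick(), unit="subs")
    assert again.to_newick() == tree.to_newick()


def test_duplicate_leaf_labels_rejected():
    with pytest.raises(TreeError):
        SpeciesTree.from_newick("(a:1,a:1);", unit="myr")
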