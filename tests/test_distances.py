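"""TN93 distances, the four-fold synonymous proxy, and branch-length fitting."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mmbscan.distances import (DistanceError, distance_matrix,
                               fit_branch_lengths, fourfold_sites, ds_proxy,
                               tn93, tn93_from_counts, pair_pattern_counts,
                               FOURFOLD_PREFIXES)
from mmbscan.seqsim import (SubstitutionModel, decode, encode, evolve,
                            simulate_root_sequence)
from mmbscan.trees import SpeciesTree, TreeError, cumulative_length

#: independently computed with R ape::dist.dna(model="TN93") on the sequence
#: pair regenerated below (seed 12345, HKY kappa=3, pi=(.3,.2,.2,.3))
APE_TN93_REFERENCE = 0.190823637443


def _ape_fixture_pair():
    rng = np.random.default_rng(12345)
    tree = SpeciesTree.from_newick("(a:0.08,b:0.12);", unit="subs")
    model = SubstitutionModel.hky(kappa=3.0, frequencies=(0.3, 0.2, 0.2, 0.3))
    root = simulate_root_sequence(600, (0.3, 0.2, 0.2, 0.3), rng)
    aln = evolve(tree, model, root, rng)
    return aln.sequences["a"], aln.sequences["b"]


class TestTN93:
    def test_identical_sequences_have_zero_distance(self):
        assert tn93("ACGTACGT", "ACGTACGT").distance == 0.0

    def test_matches_independent_r_implementation(self):
        a, b = _ape_fixture_pair()
        assert tn93(a, b).distance == pytest.approx(APE_TN93_REFERENCE,
                                                    abs=1e-9)

    def test_collapses_to_jc69_on_equal_frequency_counts(self):
        # counts with uniform composition and all substitution types equally
        # frequent: TN93 must reduce to the Jukes-Cantor formula
        n, mism = 12000, 1200
        M = np.full((4, 4), mism // 12)
        np.fill_diagonal(M, (n - mism) // 4)
        counts = np.concatenate([M.ravel(), [0]])
        p = mism / n
        jc = -0.75 * math.log(1 - 4 * p / 3)
        assert tn93_from_counts(counts).distance == pytest.approx(jc, abs=1e-9)

    def test_consistency_on_simulated_pairs(self):
        tree = SpeciesTree.from_newick("(a:0.05,b:0.05);", unit="subs")
        model = SubstitutionModel.hky()
        est = []
        for rep in range(100):
            rng = np.random.default_rng(rep)
            aln = evolve(tree, model, simulate_root_sequence(3000, rng=rng), rng)
            est.append(tn93(aln.sequences["a"], aln.sequences["b"]).distance)
        se = np.std(est, ddof=1) / np.sqrt(len(est))
        assert abs(np.mean(est) - 0.1) < 3 * se

    def test_ambiguous_columns_excluded_and_counted(self):
        d = tn93("ACGTNN", "ACGT-A")
        assert d.usable_sites == 4 and d.distance == 0.0

    def test_saturation_flagged_not_raised(self):
        # every column a transversion: the transversion log argument goes
        # negative and the distance is flagged, not raised
        d = tn93("ACGT" * 25, "CGTA" * 25)
        assert d.saturated and not d.defined

    def test_no_usable_sites_rejected(self):
        with pytest.raises(DistanceError):
            tn93("NNNN", "ACGT")

    def test_symmetry(self):
        a, b = _ape_fixture_pair()
        assert tn93(a, b).distance == pytest.approx(tn93(b, a).distance,
                                                    abs=1e-12)

    @given(extra=st.integers(1, 50))
    @settings(max_examples=20, deadline=None)
    def test_monotone_in_proportional_mismatch_count(self, extra):
        n = 6000
        def counts_for(mism):
            M = np.full((4, 4), mism // 12)
            np.fill_diagonal(M, (n - 12 * (mism // 12)) // 4)
            return np.concatenate([M.ravel(), [0]])
        d1 = tn93_from_counts(counts_for(240)).distance
        d2 = tn93_from_counts(counts_for(240 + 12 * extra)).distance
        assert d2 > d1


class TestFourfold:
    def test_alanine_codons_extracted(self):
        x, y, audit = fourfold_sites("GCAGCG", "GCCGCT")
        assert audit["fourfold"] == 2
        assert decode(x) == "AG" and decode(y) == "CT"

    def test_methionine_not_fourfold(self):
        _, _, audit = fourfold_sites("ATGATG", "ATGATG")
        assert audit["fourfold"] == 0

    def test_hand_enumeration_against_codon_table(self):
        # ten codons; qualifying = same prefix, prefix in a four-fold family
        a = "GCA CTG ATG TCA CGA GGA TAA ACT GTT AAA".replace(" ", "")
        b = "GCG CTT ATG TCC CGG GGG TAA ACG GTC AAG".replace(" ", "")
        expected = 0
        for i in range(0, 30, 3):
            ca, cb = a[i:i + 3], b[i:i + 3]
            if ca in ("TAA", "TAG", "TGA") or cb in ("TAA", "TAG", "TGA"):
                continue
            if ca[:2] == cb[:2] and ca[:2] in FOURFOLD_PREFIXES:
                expected += 1
        _, _, audit = fourfold_sites(a, b)
        assert audit["fourfold"] == expected == 7

    def test_stop_codons_excluded_and_counted(self):
        _, _, audit = fourfold_sites("TAAGCA", "GCAGCA")
        assert audit["stops_excluded"] == 1 and audit["fourfold"] == 1

    def test_frame_violation_rejected(self):
        with pytest.raises(DistanceError):
            fourfold_sites("GCAG", "GCAG")


class TestDsProxy:
    def test_identical_cds_gives_zero(self):
        cds = "GCAGCGGGTCTA" * 20
        d = ds_proxy(cds, cds, min_sites=10)
        assert d.distance == 0.0 and d.method == "TN93_4fold"

    def test_synonymous_only_divergence_is_positive(self):
        # alanine throughout (100% amino-acid identity), every 4th third
        # position substituted
        block = "GCAGCCGCGGCT"
        a = block * 20
        b = ("GCG" + block[3:] + block * 4) * 4   # one A->G per 20 codons
        d = ds_proxy(a, b, min_sites=10)
        assert 0 < d.distance < 1

    def test_site_floor_enforced(self):
        with pytest.raises(DistanceError):
            ds_proxy("GCAGCA", "GCAGCA", min_sites=50)

    def test_recovers_known_third_position_divergence(self):
        tree = SpeciesTree.from_newick("(a:0.1,b:0.1);", unit="subs")
        model = SubstitutionModel.hky()
        est = []
        for rep in range(60):
            rng = np.random.default_rng(rep)
            third = evolve(tree, model,
                           simulate_root_sequence(1500, rng=rng), rng)
            a = "".join("GC" + c for c in third.sequences["a"])
            b = "".join("GC" + c for c in third.sequences["b"])
            est.append(ds_proxy(a, b).distance)
        se = np.std(est, ddof=1) / np.sqrt(len(est))
        assert abs(np.mean(est) - 0.2) < 3 * se


def _path_distance_matrix(tree):
    labels = tree.leaf_labels()
    D = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, j in itertools.combinations(labels, 2):
        mr = tree.mrca([i, j])
        d = cumulative_length(tree, i, mr) + cumulative_length(tree, j, mr)
        D.loc[i, j] = D.loc[j, i] = d
    return D


class TestFitBranchLengths:
    def test_three_taxon_star_symmetric(self):
        star = SpeciesTree.from_newick("(a:1,b:1,c:1);", unit="subs")
        D = pd.DataFrame([[0, .2, .2], [.2, 0, .2], [.2, .2, 0]],
                         index=list("abc"), columns=list("abc"))
        fitted = fit_branch_lengths(star, D)
        for leaf in "abc":
            assert fitted.find(leaf).length == pytest.approx(0.1, abs=1e-12)

    def test_additive_matrix_recovered_exactly(self, rng):
        tree = SpeciesTree.from_newick(
            "(((a:0.11,b:0.02):0.05,c:0.3):0.07,(d:0.09,e:0.21):0.04);",
            unit="subs")
        fitted = fit_branch_lengths(tree, _path_distance_matrix(tree))
        refit = _path_distance_matrix(fitted)
        orig = _path_distance_matrix(tree)
        assert np.allclose(refit.values, orig.values, atol=1e-9)

    def test_perturbed_matrix_matches_normal_equations(self):
        tree = SpeciesTree.from_newick("((a:0.1,b:0.2):0.05,(c:0.07,d:0.03):0.02);",
                                       unit="subs")
        D = _path_distance_matrix(tree)
        D.loc["a", "c"] = D.loc["c", "a"] = D.loc["a", "c"] + 0.01
        fitted = fit_branch_lengths(tree, D)
        # independent oracle: explicit normal equations on the path design
        labels = tree.leaf_labels()
        pairs = list(itertools.combinations(labels, 2))
        cols = {}  # edge key -> column
        rows = []
        for i, j in pairs:
            mr = tree.mrca([i, j])
            onpath = []
            for leaf in (i, j):
                node = tree.find(leaf)
                while node is not mr:
                    onpath.append(id(node))
                    node = node.parent
            rows.append(onpath)
        edge_ids = sorted({e for r in rows for e in r})
        # merge the two root edges (unidentifiable separately)
        root_children = {id(c) for c in tree.root.children}
        def col_key(e):
            return "ROOT" if e in root_children else e
        keys = sorted({str(col_key(e)) for e in edge_ids})
        X = np.zeros((len(pairs), len(keys)))
        for r, onpath in enumerate(rows):
            for k in {str(col_key(e)) for e in onpath}:
                X[r, keys.index(k)] = 1.0
        y = np.array([D.loc[i, j] for i, j in pairs])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.all(beta > 0)  # clamping inactive: OLS == NNLS here
        rss_oracle = ((X @ beta - y) ** 2).sum()
        refit = _path_distance_matrix(fitted)
        rss_fit = sum((refit.loc[i, j] - D.loc[i, j]) ** 2 for i, j in pairs)
        assert rss_fit == pytest.approx(rss_oracle, abs=1e-12)

    def test_two_taxon_stem_split_evenly(self):
        # only the path sum is identifiable; the stem is halved
        tree = SpeciesTree.from_newick("(a:1,b:1);", unit="subs")
        D = pd.DataFrame([[0, .2], [.2, 0]], index=["a", "b"], columns=["a", "b"])
        fitted = fit_branch_lengths(tree, D)
        assert fitted.find("a").length == pytest.approx(0.1)
        assert fitted.find("b").length == pytest.approx(0.1)

    def test_missing_taxon_rejected(self):
        star = SpeciesTree.from_newick("(a:1,b:1,c:1);", unit="subs")
        D = pd.DataFrame([[0, .2], [.2, 0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(TreeError):
            fit_branch_lengths(star, D)
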