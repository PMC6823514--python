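"""End-to-end analyses chaining the pipeline stages.

Two workflows mirror the package's two analyses:

* intron workflow — filter two-species intron alignments, double-bootstrap
  TN93 rates per chromosome class, and estimate the strength of male
  mutation bias (alpha) through the three Miyata comparisons;

* dating workflow — bootstrap synonymous-rate trees from codon alignments,
  correct X-linked cumulative branch lengths by matched autosomal trees,
  simulate the scenario grid of X-linkage retention times, and date the
  sex-chromosome loss from the observed/simulated CI overlap.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np

from . import synth
from .alpha import RateTriple, alpha_with_ci, COMPARISONS
from .bootstrap import (codon_resample_indices, consensus_tree,
                        double_bootstrap)
from .distances import (fourfold_pattern_categories, tn93, tn93_from_counts,
                        fit_branch_lengths, distance_matrix, DistanceError)
from .preprocess import filter_introns, class_introns
from .scan import (ScanResult, autosomal_correction,
                   cumulative_from_consensus, group_average, overlap_scan)
from .seqsim import SubstitutionModel, encode, replicate_seed, evolve, \
    simulate_root_sequence
from .trees import (SpeciesTree, RateCalibration, apply_scenario,
                    myr_to_substitutions, scenario_grid)

logger = logging.getLogger(__name__)


def intron_rate_analysis(genes, n_boot: int = 1000, seed: int = 0):
    """Filter intron alignments and bootstrap per-class TN93 rates.

    Returns ``(rates, estimates, audit)``: a :class:`RateTriple`, a dict of
    the three Miyata alpha estimates, and the per-gene filter audit.
    """
    filtered, audit = filter_introns(genes)
    ss = np.random.SeedSequence(seed).spawn(3)
    dists = {}
    for cls, sub in zip(("X", "Y", "A"), ss):
        introns = class_introns(filtered, cls)
        if len(introns) < 2:
            raise ValueError(f"class {cls}: fewer than 2 introns survive filtering")
        dists[cls] = double_bootstrap(introns, n=n_boot, seed=sub,
                                      label=f"tn93_{cls}")
    rates = RateTriple(x=dists["X"], y=dists["Y"], a=dists["A"])
    estimates = {comp: alpha_with_ci(rates, comp) for comp in COMPARISONS}
    return rates, estimates, audit


# -- synonymous-rate tree bootstrap ------------------------------------------


def ds_bootstrap_trees(alignment: dict, topology: SpeciesTree,
                       n_boot: int = 100, seed=None,
                       min_sites: int = 50):
    """Codon-bootstrap replicate dS trees on a fixed topology.

    For each replicate, codon columns are resampled with replacement; the
    pairwise synonymous-proxy distance (TN93 on doubly four-fold-degenerate
    third positions) is recomputed from the resample's site-pattern counts
    and branch lengths are refit by least squares.  Returns a list of trees
    (``None`` where a replicate failed, e.g. saturation), length ``n_boot``.
    """
    rng = np.random.default_rng(seed)
    taxa = topology.leaf_labels()
    enc = {t: encode(alignment[t]) for t in taxa}
    n_codons = next(iter(enc.values())).size // 3
    pairs = list(itertools.combinations(taxa, 2))
    cats = {p: fourfold_pattern_categories(enc[p[0]], enc[p[1]]) for p in pairs}
    usable = {p: int((cats[p] < 16).sum()) for p in pairs}
    thin = [p for p, n in usable.items() if n < min_sites]
    if thin:
        raise DistanceError(f"pairs below the {min_sites} four-fold-site floor: {thin}")
    trees = []
    for _ in range(n_boot):
        idx = codon_resample_indices(rng, n_codons)
        try:
            pw = []
            for p in pairs:
                counts = np.bincount(cats[p][idx], minlength=17)
                d = tn93_from_counts(counts, pair=p, method="TN93_4fold")
                if not d.defined:
                    raise DistanceError(f"saturated distance for {p}")
                pw.append(d)
            trees.append(fit_branch_lengths(topology, distance_matrix(pw)))
        except DistanceError as exc:
            logger.warning("bootstrap replicate dropped: %s", exc)
            trees.append(None)
    return trees


def matched_consensus(x_alignment: dict, a_alignment: dict,
                      topology: SpeciesTree, n_boot: int = 100, seed: int = 0):
    """Replicate-matched X and autosomal consensus dS trees."""
    sx, sa = np.random.SeedSequence(seed).spawn(2)
    tx = ds_bootstrap_trees(x_alignment, topology, n_boot, sx)
    ta = ds_bootstrap_trees(a_alignment, topology, n_boot, sa)
    keep = [i for i in range(n_boot) if tx[i] is not None and ta[i] is not None]
    if len(keep) < 2:
        raise DistanceError("too few successful bootstrap replicates")
    return (consensus_tree([tx[i] for i in keep]),
            consensus_tree([ta[i] for i in keep]))


def observed_group_lengths(x_alignment: dict, a_alignment: dict,
                           topology: SpeciesTree, groups: dict,
                           focal_groups, anchor_leaves,
                           n_boot: int = 100, seed: int = 0):
    """Corrected observed cumulative lengths, averaged per group.

    Returns ``(group_arrays, corrected, cons_x, cons_a)`` where
    ``group_arrays[group]`` is the replicate array of the group's mean
    corrected X-linked cumulative length.
    """
    cons_x, cons_a = matched_consensus(x_alignment, a_alignment, topology,
                                       n_boot, seed)
    species = _anchor_descendants(topology, anchor_leaves)
    gx = cumulative_from_consensus(cons_x, list(anchor_leaves), species, groups)
    ga = cumulative_from_consensus(cons_a, list(anchor_leaves), species, groups)
    focal_species = [s for s in species if groups[s] in focal_groups]
    corrected = autosomal_correction(gx, ga, focal_species)
    return group_average(corrected), corrected, cons_x, cons_a


# -- simulation arm ----------------------------------------------------------


def simulated_group_lengths(tree_myr: SpeciesTree, grid, calib: RateCalibration,
                            groups: dict, anchor_leaves,
                            n_replicates: int = 100, length: int = 3000,
                            seed: int = 0,
                            model: SubstitutionModel | None = None):
    """Per-scenario simulated cumulative lengths, averaged per group.

    Each scenario's tree is shortened per its retention time, ``n_replicates``
    random sequences are evolved along it, and each replicate's branch
    lengths are re-estimated from the simulated alignment (TN93 + least
    squares), exactly as the observed data are treated.  Returns
    ``{retention_t: {group: replicate array}}``.
    """
    if model is None:
        model = SubstitutionModel.hky()
    subs = myr_to_substitutions(tree_myr, calib)
    species = _anchor_descendants(tree_myr, anchor_leaves)
    all_taxa = tree_myr.leaf_labels()
    pairs = list(itertools.combinations(all_taxa, 2))
    out = {}
    for sc in grid:
        t = max(ls.retention_t for name, ls in sc.lineages.items()
                if name in _focal_names(sc, grid))
        sim_tree, _ = apply_scenario(subs, sc, calib)
        per_group = {g: [] for g in sorted({groups[s] for s in species})}
        for r in range(n_replicates):
            # common random numbers across scenarios: replicate r shares its
            # stream in every scenario, so between-scenario contrasts are not
            # swamped by independent simulation noise
            rng = np.random.default_rng(replicate_seed(seed, "common", r))
            root = simulate_root_sequence(length, rng=rng)
            aln = evolve(sim_tree, model, root, rng)
            enc = {k: encode(v) for k, v in aln.sequences.items()}
            pw = [tn93(enc[a], enc[b], pair=(a, b)) for a, b in pairs]
            if any(not d.defined for d in pw):
                logger.warning("saturated simulated distance; replicate dropped")
                continue
            fitted = fit_branch_lengths(subs, distance_matrix(pw))
            cons = consensus_tree([fitted])
            gl = cumulative_from_consensus(cons, list(anchor_leaves),
                                           species, groups)
            means = group_average(gl)
            for g, v in means.items():
                per_group[g].append(float(v[0]))
        out[t] = {g: np.asarray(v) for g, v in per_group.items()}
    return out


def _anchor_descendants(tree: SpeciesTree, anchor_leaves) -> list:
    from .trees import _subtree_leaves
    anc = tree.mrca(list(anchor_leaves))
    return sorted(lf.label for lf in _subtree_leaves(anc))


def _focal_names(sc, grid):
    """Lineages whose retention time varies across the grid."""
    names = set(sc.lineages)
    varying = set()
    for name in names:
        ts = {s.lineages[name].retention_t for s in grid if name in s.lineages}
        if len(ts) > 1:
            varying.add(name)
    return varying or names


# -- full dating workflow ----------------------------------------------------


def dating_scan(observed_groups: dict, simulated: dict, focal_lineages,
                reference_group: str, system_age: float) -> ScanResult:
    """Rescale the simulation arm to the observed scale and run the overlap scan.

    Rescaling is replicate-wise: each replicate (observed bootstrap or
    simulation) is normalized by its own reference-group value and re-anchored
    at the observed reference median.  This keeps the values in observed
    units while propagating reference-group uncertainty into both confidence
    intervals — a global median-ratio factor would leave the reference noise
    outside the test and miscalibrate the overlap decision.
    """
    obs_ref = np.asarray(observed_groups[reference_group], float)
    obs_ref_med = float(np.median(obs_ref))
    observed = {lin: np.asarray(observed_groups[lin], float) / obs_ref * obs_ref_med
                for lin in focal_lineages}
    per_scenario = {}
    for t, arrays in simulated.items():
        sim_ref = np.asarray(arrays[reference_group], float)
        if np.median(sim_ref) == 0:
            raise ValueError("simulated reference median is zero; cannot rescale")
        per_scenario[t] = {
            lin: np.asarray(arrays[lin], float) / sim_ref * obs_ref_med
            for lin in focal_lineages}
    return overlap_scan(observed, per_scenario, system_age)


def run_demo_dating(truth_t: float = 80.0, truth_alpha: float = 4.0,
                    n_genes: int = 50, cds_length: int = 999,
                    n_boot: int = 100, n_sim_replicates: int = 20,
                    sim_length: int = 1000, grid_step: float = 10.0,
                    seed: int = 0):
    """End-to-end turnover dating on the packaged 10-taxon demo design.

    Generates codon data in which the agamid-like lineage kept the ancestral
    X for ``truth_t`` Myr under male mutation bias ``truth_alpha`` (the
    pleurodont-like clade keeps it throughout), runs the observed workflow,
    simulates the full retention grid, and returns ``(result, truth)``.
    """
    spec = synth.SynthSpec(
        tree_newick=synth.DEMO_TREE_NEWICK,
        lineage_tags=synth.DEMO_LINEAGE_TAGS,
        scenario=synth.demo_scenario(truth_t, alpha=truth_alpha),
        n_genes_x=n_genes, n_genes_a=n_genes, cds_length=cds_length,
        master_seed=seed)
    dataset, truth = synth.gen_codon_dataset(spec)
    x_aln = synth.concatenate_genes(dataset["X"])
    a_aln = synth.concatenate_genes(dataset["A"])
    tree = SpeciesTree.from_newick(synth.DEMO_TREE_NEWICK, unit="myr",
                                   lineage_tags=synth.DEMO_LINEAGE_TAGS)
    groups = synth.DEMO_LINEAGE_TAGS
    topology = tree.copy()
    calib = spec.calibration()
    obs_groups, corrected, _, _ = observed_group_lengths(
        x_aln, a_aln, topology, groups,
        focal_groups=("snake", "agamid", "pleurodont"),
        anchor_leaves=synth.DEMO_INGROUP_ANCHOR, n_boot=n_boot, seed=seed + 1)
    grid = scenario_grid(
        ["agamid"], {"agamid": truth_alpha},
        system_age=synth.DEMO_SYSTEM_AGE, step=grid_step,
        fixed={"pleurodont": spec.scenario.lineages["pleurodont"]})
    simulated = simulated_group_lengths(
        tree, grid, calib, groups, synth.DEMO_INGROUP_ANCHOR,
        n_replicates=n_sim_replicates, length=sim_length, seed=seed + 2)
    result = dating_scan(obs_groups, simulated, ["agamid"],
                         reference_group="snake",
                         system_age=synth.DEMO_SYSTEM_AGE)
    return result, truth
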