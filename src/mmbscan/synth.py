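"""Synthetic datasets with the statistical structure the analysis assumes.

Two designs, mirroring the two analyses the pipeline performs:

* a two-species intronic design — X-, Y- and autosomal-class intron
  alignments evolved at the rates male mutation bias of a chosen strength
  implies (X at 2(2+alpha)/(3(1+alpha)) of the autosomal rate, Y at
  2 alpha/(1+alpha)), with decoy first introns, exon-flanking columns,
  injected CpG dinucleotides and ambiguity codes so each preprocessing
  filter has real work to do;

* a multi-taxon codon design — coding genes whose third positions of
  four-fold-degenerate codons evolve along a species tree transformed by an
  X-linkage scenario (designated lineages X-linked for a known number of
  Myr), while first and second codon positions evolve at a low rate so
  amino-acid structure stays realistic.

The class rates derive from the Miyata inverses, so generator and estimator
share only the algebra: recovering alpha or the retention time is a genuine
round trip through sequence space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alpha import expected_ratio, XA, YA
from .preprocess import GeneAlignments, Intron, PairwiseAlignment
from .seqsim import (SubstitutionModel, simulate_root_sequence,
                     _evolve_along_branch, decode, encode)
from .trees import (SpeciesTree, RateCalibration, LineageScenario, LineageSpec,
                    PAPER_LINEAR, myr_to_substitutions, apply_scenario,
                    _clade_key)


@dataclass
class SynthSpec:
    """Generating parameters for both synthetic designs."""

    mu: float = 2.22e-9                 # substitutions / site / year
    master_seed: int = 0
    kappa: float = 2.0                  # HKY transition/transversion weight

    # two-species intron design
    alpha: float = 6.0
    divergence_myr: float = 30.0        # split time of the two species
    n_genes_per_class: int = 77
    introns_per_gene: tuple = (2, 5)    # inclusive range, before decoys
    intron_length_range: tuple = (200, 3000)
    flank_nt: int = 20
    cpg_injection_rate: float = 0.01    # per position, sequence A
    ambiguity_injection_rate: float = 0.002  # per position, sequence B
    #: intron backbone composition: cytosine-free, so every detectable CpG
    #: is an injected decoy and the CpG filter cannot confound the rate
    #: estimand (column removal conditioned on C-G adjacency is otherwise
    #: correlated with mismatch status and biases distances)
    backbone_frequencies: tuple = (1 / 3, 0.0, 1 / 3, 1 / 3)
    #: between-intron rate heterogeneity: each intron's branch lengths are
    #: scaled by a lognormal multiplier with this log-scale sd and mean 1
    #: (local mutation-rate variation is why the bootstrap resamples introns)
    intron_rate_sd: float = 0.3

    # multi-taxon codon design
    tree_newick: str | None = None      # Myr, ultrametric
    lineage_tags: dict = field(default_factory=dict)
    scenario: LineageScenario | None = None
    n_genes_x: int = 77
    n_genes_a: int = 77
    cds_length: int = 1500              # nt per gene, divisible by 3
    nondegenerate_rate_factor: float = 0.05
    #: branch-shortening calibration for the codon design; the linear
    #: per-10-Myr constants are the ones the published simulations used
    shortening_mode: str = PAPER_LINEAR

    def calibration(self) -> RateCalibration:
        return RateCalibration(mu=self.mu, shortening_mode=self.shortening_mode)


CLASS_MULTIPLIER = {
    "A": lambda alpha: 1.0,
    "X": lambda alpha: expected_ratio(XA, alpha),
    "Y": lambda alpha: expected_ratio(YA, alpha),
}


def _evolve_pair(root: np.ndarray, half_distance: float,
                 model: SubstitutionModel, rng) -> tuple:
    P = model.transition_matrix(half_distance)
    return (_evolve_along_branch(root, P, rng),
            _evolve_along_branch(root, P, rng))


def gen_intron_dataset(spec: SynthSpec, seed=None):
    """Two-species intron alignments in X, Y and A classes under a known alpha.

    Returns ``(genes, truth)`` where genes feed
    :func:`mmbscan.preprocess.filter_introns` unchanged and truth records
    every generating parameter needed to score recovery.
    """
    rng = np.random.default_rng(spec.master_seed if seed is None else seed)
    freqs = np.asarray(spec.backbone_frequencies, dtype=float)
    model = SubstitutionModel.hky(kappa=spec.kappa, frequencies=freqs)
    base_distance = 2.0 * spec.divergence_myr * spec.mu * 1e6
    genes, class_truth = [], {}
    lo_n, hi_n = spec.introns_per_gene
    lo_l, hi_l = spec.intron_length_range
    for chrom_class in ("X", "Y", "A"):
        mult = CLASS_MULTIPLIER[chrom_class](spec.alpha)
        d = base_distance * mult
        class_truth[chrom_class] = {"rate_multiplier": mult,
                                    "expected_distance": d}
        for g in range(spec.n_genes_per_class):
            n_real = int(rng.integers(lo_n, hi_n + 1))
            introns = []
            for ordinal in range(1, n_real + 2):  # +1 decoy first intron
                core = int(rng.integers(lo_l, hi_l + 1))
                length = core + 2 * spec.flank_nt
                root = simulate_root_sequence(length, freqs, rng)
                m = 1.0
                if spec.intron_rate_sd > 0:
                    s = spec.intron_rate_sd
                    m = float(rng.lognormal(-s * s / 2.0, s))  # mean exactly 1
                a, b = _evolve_pair(root, m * d / 2.0, model, rng)
                sb = _inject_ambiguity(decode(b), spec.ambiguity_injection_rate, rng)
                # decoy CpGs avoid ambiguity-injected columns and the flank
                # regions, so neither the mask nor the flank trim can strip
                # half a decoy pair and leave a stray C behind
                blocked = np.frombuffer(sb.encode(), dtype=np.uint8) == ord("N")
                if spec.flank_nt:
                    blocked[:spec.flank_nt] = True
                    blocked[-spec.flank_nt:] = True
                a = _inject_cpg(a, spec.cpg_injection_rate, rng, blocked)
                introns.append(Intron(index=ordinal,
                                      alignment=PairwiseAlignment(decode(a), sb)))
            genes.append(GeneAlignments(
                gene=f"{chrom_class}_gene{g:04d}", chrom_class=chrom_class,
                introns=introns))
    truth = {"design": "intron_two_species", "alpha": spec.alpha,
             "divergence_myr": spec.divergence_myr, "mu": spec.mu,
             "base_distance": base_distance, "classes": class_truth,
             "seed": int(spec.master_seed if seed is None else seed)}
    return genes, truth


def _inject_cpg(states: np.ndarray, rate: float, rng,
                blocked: np.ndarray | None = None) -> np.ndarray:
    if rate <= 0 or states.size < 2:
        return states
    out = states.copy()
    hits = np.nonzero(rng.random(states.size - 1) < rate)[0]
    # adjacent injections would overwrite a G with a C and leave a stray C
    # after filtering; keep only hits at distance >= 2 and off blocked columns
    keep = []
    last = -2
    for h in hits:
        if h - last < 2:
            continue
        if blocked is not None and (blocked[h] or blocked[h + 1]):
            continue
        keep.append(h)
        last = h
    hits = np.asarray(keep, dtype=int)
    out[hits] = 1      # C
    out[hits + 1] = 2  # G
    return out


def _inject_ambiguity(seq: str, rate: float, rng) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = rng.random(arr.size) < rate
    arr[hits] = ord("N")
    return arr.tobytes().decode()


# -- multi-taxon codon design -----------------------------------------------

#: four-fold-degenerate codon-family prefixes as encoded (pos1, pos2) pairs
_FOURFOLD_PREFIX_STATES = [
    (1, 3), (2, 3), (3, 1), (1, 1), (0, 1), (2, 1), (1, 2), (2, 2)
]  # CT GT TC CC AC GC CG GG


def gen_codon_dataset(spec: SynthSpec, seed=None):
    """Codon alignments whose neutral sites evolved under an X-linkage scenario.

    X-class genes evolve their four-fold third positions along the
    scenario-transformed tree (lineages X-linked for their specified
    retention times accumulate fewer substitutions); autosomal-class genes
    evolve along the untransformed tree.  First/second codon positions
    evolve at ``nondegenerate_rate_factor`` of the neutral rate.

    Returns ``(dataset, truth)``; dataset maps class -> list of per-gene
    alignments (dict taxon -> codon string).
    """
    if spec.tree_newick is None or spec.scenario is None:
        raise ValueError("codon design needs tree_newick and scenario")
    rng = np.random.default_rng(spec.master_seed if seed is None else seed)
    if spec.cds_length % 3:
        raise ValueError("cds_length must be divisible by 3")
    model = SubstitutionModel.hky(kappa=spec.kappa)
    calib = spec.calibration()
    tree = SpeciesTree.from_newick(spec.tree_newick, unit="myr",
                                   lineage_tags=spec.lineage_tags)
    subs = myr_to_substitutions(tree, calib)
    x_tree, adjustments = apply_scenario(subs, spec.scenario, calib)
    class_tree = {"X": x_tree, "A": subs}
    n_codons = spec.cds_length // 3

    dataset = {}
    for chrom_class, n_genes in (("X", spec.n_genes_x), ("A", spec.n_genes_a)):
        ctree = class_tree[chrom_class]
        slow = ctree.copy()
        for node in slow.nodes():
            node.length *= spec.nondegenerate_rate_factor
        genes = []
        for g in range(n_genes):
            prefix_idx = rng.integers(0, len(_FOURFOLD_PREFIX_STATES),
                                      size=n_codons)
            prefixes = np.array(_FOURFOLD_PREFIX_STATES, dtype=np.uint8)[prefix_idx]
            third_root = simulate_root_sequence(n_codons, rng=rng)
            pos12_root = prefixes.ravel()

            third = _evolve_leaves(ctree, model, third_root, rng)
            pos12 = _evolve_leaves(slow, model, pos12_root, rng)
            aln = {}
            for taxon in third:
                codons = np.empty((n_codons, 3), dtype=np.uint8)
                codons[:, :2] = pos12[taxon].reshape(n_codons, 2)
                codons[:, 2] = third[taxon]
                aln[taxon] = decode(codons.ravel())
            genes.append(aln)
        dataset[chrom_class] = genes

    expected_lengths = {_clade_key(n): n.length
                        for n in x_tree.nodes() if n.parent is not None}
    truth = {"design": "codon_multi_taxon",
             "scenario": spec.scenario,
             "mu": spec.mu,
             "x_tree_newick": x_tree.to_newick(),
             "a_tree_newick": subs.to_newick(),
             "expected_x_branch_lengths": expected_lengths,
             "clamped_branches": [a.branch for a in adjustments if a.clamped],
             "seed": int(spec.master_seed if seed is None else seed)}
    return dataset, truth


def _evolve_leaves(tree: SpeciesTree, model, root_states, rng) -> dict:
    leaves = {}
    stack = [(tree.root, np.asarray(root_states, dtype=np.uint8))]
    while stack:
        node, seq = stack.pop()
        if node.is_leaf:
            leaves[node.label] = seq
        for child in node.children:
            P = model.transition_matrix(child.length)
            stack.append((child, _evolve_along_branch(seq, P, rng)))
    return leaves


def concatenate_genes(genes: list) -> dict:
    """Concatenate per-gene alignments (dict taxon -> sequence)."""
    taxa = sorted(genes[0])
    return {t: "".join(g[t] for g in genes) for t in taxa}


def truth_report(truth: dict) -> pd.DataFrame:
    """Machine-readable table of generating parameters."""
    rows = []
    if truth.get("design") == "intron_two_species":
        for cls, rec in truth["classes"].items():
            rows.append({"key": f"class_{cls}", "alpha": truth["alpha"],
                         "retention_t": "", "rate_multiplier": rec["rate_multiplier"],
                         "expected_distance": rec["expected_distance"],
                         "seed": truth["seed"]})
    else:
        sc = truth["scenario"]
        for name, ls in sorted(sc.lineages.items()):
            rows.append({"key": f"lineage_{name}", "alpha": ls.alpha,
                         "retention_t": ls.retention_t, "rate_multiplier": "",
                         "expected_distance": "", "seed": truth["seed"]})
    return pd.DataFrame(rows)


# -- packaged demo tree -------------------------------------------------------

DEMO_TREE_NEWICK = (
    "((((sna1:30,sna2:30):30,sna3:60):60,"
    "(((ple1:40,ple2:40):30,ple3:70):30,(aga1:50,aga2:50):50):20):40,"
    "(og1:120,og2:120):40);"
)

DEMO_LINEAGE_TAGS = {
    "sna1": "snake", "sna2": "snake", "sna3": "snake",
    "ple1": "pleurodont", "ple2": "pleurodont", "ple3": "pleurodont",
    "aga1": "agamid", "aga2": "agamid",
    "og1": "outgroup", "og2": "outgroup",
}

#: ingroup crown age of the demo tree = age of the simulated XY system (Myr)
DEMO_SYSTEM_AGE = 120.0
#: leaves whose MRCA anchors the cumulative branch sums
DEMO_INGROUP_ANCHOR = ("sna1", "aga1")


def demo_scenario(retention_t: float, alpha: float = 4.0,
                  pleurodont_alpha: float = 2.4) -> LineageScenario:
    """Demo truth: agamids X-linked for ``retention_t`` Myr, pleurodonts for
    the full system age.

    The always-X-linked background clade runs at a moderate bias (2.4, the
    value reported for most mammals and birds) so that, under the linear
    shortening calibration, no branch on the demo tree exhausts its length.
    """
    return LineageScenario(
        lineages={"agamid": LineageSpec(alpha=alpha, retention_t=retention_t),
                  "pleurodont": LineageSpec(alpha=pleurodont_alpha,
                                            retention_t=DEMO_SYSTEM_AGE)},
        system_age=DEMO_SYSTEM_AGE,
        scenario_id=f"truth_T{int(retention_t):03d}")
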