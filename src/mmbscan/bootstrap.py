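"""Resampling schemes for rate uncertainty.

Two schemes are used: a hierarchical double bootstrap of intronic alignments
(units = introns, then sites within the concatenated resample) and a codon
bootstrap of concatenated coding alignments (whole codon columns resampled
with replacement, preserving within-codon linkage across every taxon).
Consensus trees take the per-branch median over bootstrap replicates.

Point estimates are medians and confidence intervals are percentile
(2.5/97.5) bounds on the replicate distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distances import pair_pattern_counts, tn93_from_counts, DistanceError
from .seqsim import encode, decode
from .trees import SpeciesTree, _clade_key


@dataclass
class BootstrapDistribution:
    label: str
    values: np.ndarray
    n_excluded: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    @property
    def point(self) -> float:
        return float(np.median(self.values))

    @property
    def ci(self) -> tuple:
        lo, hi = np.percentile(self.values, [2.5, 97.5])
        return float(lo), float(hi)


def double_bootstrap(introns: list, n: int = 1000, seed=None,
                     statistic=None, label: str = "tn93") -> BootstrapDistribution:
    """Intron x site double bootstrap of a set of pairwise intron alignments.

    Each replicate resamples introns with replacement to the original intron
    count, then resamples columns with replacement within the concatenated
    resample to the original total column count, and evaluates the statistic.

    The default statistic (TN93 distance on the concatenate) is computed from
    per-intron site-pattern counts: the column resample is drawn as a
    multinomial over the pooled pattern counts, which has exactly the
    distribution of explicit column resampling.  A custom ``statistic``
    callable ``f(seq_a, seq_b) -> float`` switches to explicit resampling.

    Replicates where the statistic is undefined (saturated distances) are
    excluded and counted.
    """
    if len(introns) < 2:
        raise ValueError("double bootstrap needs at least 2 introns")
    rng = np.random.default_rng(seed)
    k = len(introns)
    if statistic is None:
        per_intron = np.stack([
            pair_pattern_counts(encode(a.seq_a), encode(a.seq_b))
            for a in introns])
        total_cols = int(per_intron.sum())
        values, excluded = [], 0
        for _ in range(n):
            idx = rng.integers(0, k, size=k)
            pooled = per_intron[idx].sum(axis=0)
            m = int(pooled.sum())
            if m == 0:
                excluded += 1
                continue
            counts = rng.multinomial(total_cols, pooled / m)
            try:
                d = tn93_from_counts(counts, pair=(label, "resample"))
            except DistanceError:
                excluded += 1
                continue
            if not d.defined:
                excluded += 1
                continue
            values.append(d.distance)
        return BootstrapDistribution(label, np.array(values), excluded)

    enc = [(encode(a.seq_a), encode(a.seq_b)) for a in introns]
    total_cols = sum(a.size for a, _ in enc)
    values, excluded = [], 0
    for _ in range(n):
        idx = rng.integers(0, k, size=k)
        cat_a = np.concatenate([enc[i][0] for i in idx])
        cat_b = np.concatenate([enc[i][1] for i in idx])
        cols = rng.integers(0, cat_a.size, size=total_cols)
        try:
            v = statistic(decode_safe(cat_a[cols]), decode_safe(cat_b[cols]))
        except (DistanceError, ValueError):
            excluded += 1
            continue
        if v is None or not np.isfinite(v):
            excluded += 1
            continue
        values.append(float(v))
    return BootstrapDistribution(label, np.array(values), excluded)


def decode_safe(arr: np.ndarray) -> str:
    """Decode an encoded array, mapping non-ACGT codes back to 'N'."""
    lookup = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lookup[np.minimum(arr, 4)].tobytes().decode("ascii")


def codon_bootstrap(alignment: dict, n: int = 100, seed=None) -> list:
    """Resample codon columns of a multi-taxon codon alignment.

    Each resample draws codon triplets with replacement (the same codon
    column in every taxon) until the original codon count is reached.
    Returns a list of alignments (dict taxon -> sequence string).
    """
    rng = np.random.default_rng(seed)
    taxa = sorted(alignment)
    enc = {t: encode(alignment[t]) for t in taxa}
    length = len(next(iter(enc.values())))
    if any(v.size != length for v in enc.values()):
        raise ValueError("all sequences must have equal length")
    if length % 3 != 0:
        raise ValueError("codon alignment length must be divisible by 3")
    n_codons = length // 3
    out = []
    for _ in range(n):
        idx = codon_resample_indices(rng, n_codons)
        cols = (idx[:, None] * 3 + np.arange(3)[None, :]).ravel()
        out.append({t: decode_safe(enc[t][cols]) for t in taxa})
    return out


def codon_resample_indices(rng: np.random.Generator, n_codons: int) -> np.ndarray:
    return rng.integers(0, n_codons, size=n_codons)


@dataclass
class ConsensusTree:
    """Per-branch median tree plus the retained replicate distributions."""

    tree: SpeciesTree
    branch_distributions: dict = field(default_factory=dict)  # clade key -> array
    n_replicates: int = 0


def consensus_tree(trees: list[SpeciesTree]) -> ConsensusTree:
    """Median-branch-length consensus of identically shaped trees."""
    if not trees:
        raise ValueError("no trees to take a consensus of")
    ref = trees[0]
    ref_keys = {_clade_key(n) for n in ref.nodes() if n.parent is not None}
    dists = {key: [] for key in ref_keys}
    for t in trees:
        keys = {_clade_key(n): n for n in t.nodes() if n.parent is not None}
        if set(keys) != ref_keys:
            raise ValueError("topology mismatch between bootstrap trees")
        for key, node in keys.items():
            dists[key].append(node.length)
    out = ref.copy()
    arr = {k: np.asarray(v, dtype=float) for k, v in dists.items()}
    for node in out.nodes():
        if node.parent is None:
            continue
        node.length = float(np.median(arr[_clade_key(node)]))
    return ConsensusTree(tree=out, branch_distributions=arr,
                         n_replicates=len(trees))
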