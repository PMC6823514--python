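"""Substitution-rate estimators.

Closed-form pairwise Tamura-Nei (TN93) distances on nucleotide alignments, a
synonymous-rate proxy (TN93 restricted to third positions of codons that are
four-fold degenerate in both sequences), and least-squares branch lengths on
a fixed topology from a pairwise distance matrix.

TN93 distinguishes the two transition types (A<->G within purines, C<->T
within pyrimidines) from transversions and allows unequal base frequencies;
for pairwise data the closed-form estimator coincides with the maximum-
likelihood one.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .trees import SpeciesTree, SUBS, TreeError
from .seqsim import encode

logger = logging.getLogger(__name__)

TN93 = "TN93"
TN93_4FOLD = "TN93_4fold"

A, C, G, T = 0, 1, 2, 3

#: first-two-nucleotide families whose codons are four-fold degenerate
#: (Leu CTN, Val GTN, Ser TCN, Pro CCN, Thr ACN, Ala GCN, Arg CGN, Gly GGN)
FOURFOLD_PREFIXES = {"CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG"}
_FOURFOLD_CODES = frozenset(
    4 * "ACGT".index(p[0]) + "ACGT".index(p[1]) for p in FOURFOLD_PREFIXES)
STOP_CODONS = {"TAA", "TAG", "TGA"}
_STOP_CODES = frozenset(
    16 * "ACGT".index(s[0]) + 4 * "ACGT".index(s[1]) + "ACGT".index(s[2])
    for s in STOP_CODONS)


class DistanceError(ValueError):
    pass


@dataclass
class PairwiseDistance:
    pair: tuple
    distance: float
    usable_sites: int
    method: str = TN93
    saturated: bool = False

    @property
    def defined(self) -> bool:
        return not self.saturated and math.isfinite(self.distance)


def pair_pattern_counts(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """17-vector of site-pattern counts for an encoded sequence pair.

    Cells 0..15 hold counts of (state_a, state_b) = (k // 4, k % 4) over
    columns where both sequences are unambiguous ACGT; cell 16 counts the
    excluded columns.
    """
    if a.shape != b.shape:
        raise DistanceError("sequences must be aligned to equal length")
    usable = (a <= 3) & (b <= 3)
    codes = np.where(usable, a.astype(np.int64) * 4 + b, 16)
    return np.bincount(codes, minlength=17)


def tn93_from_counts(counts: np.ndarray, pair=("seqA", "seqB"),
                     method: str = TN93) -> PairwiseDistance:
    """TN93 distance from a 17-cell site-pattern count vector."""
    n = int(counts[:16].sum())
    if n == 0:
        raise DistanceError(f"no usable sites for pair {pair}")
    M = counts[:16].reshape(4, 4).astype(float)
    pi = (M.sum(axis=1) + M.sum(axis=0)) / (2.0 * n)
    p1 = (M[A, G] + M[G, A]) / n                      # purine transitions
    p2 = (M[C, T] + M[T, C]) / n                      # pyrimidine transitions
    ident = np.trace(M) / n
    q = 1.0 - ident - p1 - p2                          # transversions

    pi_r = pi[A] + pi[G]
    pi_y = pi[C] + pi[T]
    if pi_r <= 0 or pi_y <= 0:
        raise DistanceError("degenerate base composition (no purines or no pyrimidines)")
    c1 = 2.0 * pi[A] * pi[G] / pi_r
    c2 = 2.0 * pi[C] * pi[T] / pi_y
    c3 = 2.0 * pi_r * pi_y - c1 * pi_y - c2 * pi_r

    def term(coef, arg):
        if coef <= 0.0:
            return 0.0, arg > 0.0
        if arg <= 0.0:
            return math.inf, False
        return -coef * math.log(arg), True

    t1, ok1 = term(c1, 1.0 - (p1 / c1 if c1 > 0 else 0.0) - q / (2.0 * pi_r))
    t2, ok2 = term(c2, 1.0 - (p2 / c2 if c2 > 0 else 0.0) - q / (2.0 * pi_y))
    t3, ok3 = term(c3, 1.0 - q / (2.0 * pi_r * pi_y))
    if not (ok1 and ok2 and ok3):
        logger.warning("TN93 saturation for pair %s (log argument <= 0)", pair)
        return PairwiseDistance(tuple(pair), math.inf, n, method, saturated=True)
    return PairwiseDistance(tuple(pair), t1 + t2 + t3, n, method)


def tn93(seq_a, seq_b, pair=("seqA", "seqB")) -> PairwiseDistance:
    """Closed-form TN93 distance between two aligned sequences.

    Accepts ACGT strings or encoded uint8 arrays; columns with a gap or
    ambiguity in either member are excluded (and counted).
    """
    a = encode(seq_a) if isinstance(seq_a, str) else np.asarray(seq_a, dtype=np.uint8)
    b = encode(seq_b) if isinstance(seq_b, str) else np.asarray(seq_b, dtype=np.uint8)
    return tn93_from_counts(pair_pattern_counts(a, b), pair=pair)


# -- four-fold degenerate synonymous-site proxy -----------------------------


def _as_codon_array(seq) -> np.ndarray:
    arr = encode(seq) if isinstance(seq, str) else np.asarray(seq, dtype=np.uint8)
    if arr.size % 3 != 0:
        raise DistanceError("codon alignment length must be divisible by 3")
    return arr.reshape(-1, 3)


def fourfold_site_mask(seq_a, seq_b):
    """Per-codon mask of doubly four-fold-degenerate sites plus audit counts.

    A codon column qualifies when both members are unambiguous, neither is a
    stop codon, and both first-two-nucleotide prefixes belong to the same
    four-fold family.  Returns ``(mask, codons_a, codons_b, audit)``.
    """
    ca, cb = _as_codon_array(seq_a), _as_codon_array(seq_b)
    if ca.shape != cb.shape:
        raise DistanceError("codon alignments must have equal length")
    clean = (ca <= 3).all(axis=1) & (cb <= 3).all(axis=1)
    code_a = np.where(clean, 16 * ca[:, 0] + 4 * ca[:, 1] + ca[:, 2], 64)
    code_b = np.where(clean, 16 * cb[:, 0] + 4 * cb[:, 1] + cb[:, 2], 64)
    stop_codes = np.array(sorted(_STOP_CODES))
    is_stop = np.isin(code_a, stop_codes) | np.isin(code_b, stop_codes)
    n_stop = int(is_stop.sum())
    if n_stop:
        logger.warning("%d codon columns with internal stop codons excluded", n_stop)
    pref_a = ca[:, 0].astype(np.int16) * 4 + ca[:, 1]
    pref_b = cb[:, 0].astype(np.int16) * 4 + cb[:, 1]
    ff_codes = np.array(sorted(_FOURFOLD_CODES))
    mask = (clean & ~is_stop & (pref_a == pref_b) & np.isin(pref_a, ff_codes))
    audit = {"codons": int(ca.shape[0]), "fourfold": int(mask.sum()),
             "stops_excluded": n_stop}
    return mask, ca, cb, audit


def fourfold_sites(seq_a, seq_b):
    """Third positions of codons four-fold degenerate in both sequences."""
    mask, ca, cb, audit = fourfold_site_mask(seq_a, seq_b)
    return ca[mask, 2], cb[mask, 2], audit


def fourfold_pattern_categories(seq_a, seq_b) -> np.ndarray:
    """Per-codon TN93 pattern category for fast codon resampling.

    Categories 0..15 encode the third-position state pair of doubly
    four-fold-degenerate codons; 16 marks codons excluded from the proxy.
    ``np.bincount(cat[idx], minlength=17)`` over a codon resample ``idx``
    feeds :func:`tn93_from_counts` directly.
    """
    mask, ca, cb, _ = fourfold_site_mask(seq_a, seq_b)
    cat = np.full(ca.shape[0], 16, dtype=np.int64)
    cat[mask] = ca[mask, 2].astype(np.int64) * 4 + cb[mask, 2]
    return cat


def ds_proxy(seq_a, seq_b, pair=("seqA", "seqB"),
             min_sites: int = 50) -> PairwiseDistance:
    """Synonymous-rate proxy: TN93 on doubly four-fold-degenerate third positions."""
    x, y, audit = fourfold_sites(seq_a, seq_b)
    if audit["fourfold"] < min_sites:
        raise DistanceError(
            f"pair {pair}: only {audit['fourfold']} four-fold sites "
            f"(< {min_sites} floor)")
    d = tn93(x, y, pair=pair)
    d.method = TN93_4FOLD
    return d


def distance_matrix(pairwise: list[PairwiseDistance]) -> pd.DataFrame:
    """Square symmetric DataFrame from a list of pairwise distances."""
    taxa = sorted({t for p in pairwise for t in p.pair})
    df = pd.DataFrame(0.0, index=taxa, columns=taxa)
    for p in pairwise:
        i, j = p.pair
        df.loc[i, j] = df.loc[j, i] = p.distance
    return df


# -- least-squares branch lengths on a fixed topology ------------------------


def _unrooted_edges(tree: SpeciesTree):
    """Identifiable edge set: the two child edges of a degree-2 root merge."""
    nodes = [n for n in tree.nodes() if n.parent is not None]
    merged = None
    if len(tree.root.children) == 2:
        merged = tuple(tree.root.children)
    edges, col_of = [], {}
    if merged:
        edges.append(merged)
        for child in merged:
            col_of[id(child)] = 0
    for node in nodes:
        if merged and node in merged:
            continue
        col_of[id(node)] = len(edges)
        edges.append((node,))
    return edges, col_of


def fit_branch_lengths(topology: SpeciesTree, dist: pd.DataFrame) -> SpeciesTree:
    """Non-negative least-squares branch lengths on the fixed species topology.

    The design matrix indicates which edges lie on each leaf-pair path; the
    NNLS solution equals ordinary least squares with negative estimates
    clamped to zero and the remainder refit.  The two child edges of a
    degree-2 root are unidentifiable individually and receive half the
    fitted stem length each.  Exact on additive matrices.
    """
    leaves = topology.leaf_labels()
    missing = [t for t in leaves if t not in dist.index or t not in dist.columns]
    if missing:
        raise TreeError(f"distance matrix lacks taxa: {missing}")
    edges, col_of = _unrooted_edges(topology)
    pairs = list(itertools.combinations(leaves, 2))
    X = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    # node-id paths first: the two half-edges of a merged root edge must
    # count as a single crossing for pairs spanning the root
    paths = {lf.label: {id(n) for n in topology.path_to_root(lf)[:-1]}
             for lf in topology.leaves()}
    for r, (i, j) in enumerate(pairs):
        cols = {col_of[nid] for nid in paths[i].symmetric_difference(paths[j])}
        X[r, sorted(cols)] = 1.0
        y[r] = dist.loc[i, j]
    if np.linalg.matrix_rank(X) < len(edges):
        raise TreeError("singular design: branch lengths not identifiable "
                        "from pairwise distances on this topology")
    beta, _ = nnls(X, y)
    fitted = topology.copy()
    fitted.unit = SUBS
    # map original nodes to fitted copies by traversal order
    orig = list(topology.nodes())
    copy_nodes = list(fitted.nodes())
    for onode, cnode in zip(orig, copy_nodes):
        if onode.parent is None:
            cnode.length = 0.0
            continue
        col = col_of[id(onode)]
        value = beta[col]
        if len(edges[col]) == 2:
            value /= 2.0
        cnode.length = value
    return fitted


def matrix_to_tsv(dist: pd.DataFrame) -> str:
    return dist.to_csv(sep="\t", float_format="%.10g")
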