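"""Alignment-filtering rules applied before rate estimation.

Intronic pairwise alignments pass through a fixed filter order:

1. drop each gene's first intron (regulatory content),
2. trim the 20 intronic nucleotides flanking the exons on both ends
   (splice sites and enhancers),
3. mask columns with gaps or ambiguity codes in either sequence,
4. remove detectable CpG columns (hypermutable, clouds the male-mutation-
   bias signal),
5. drop genes whose total retained intronic alignment is not > 1,000 bp.

Every filter reports exactly how many columns it removed; the per-gene audit
ledger conserves column counts.  Filters are idempotent and the two
column-deletion steps (3 and 4) commute, because the CpG scanner skips
non-ACGT symbols when pairing a C with the next G.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

GAP_TOLERANT_BASES = set("ACGT")


@dataclass
class PairwiseAlignment:
    seq_a: str
    seq_b: str

    def __post_init__(self):
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned sequences must have equal length")

    def __len__(self):
        return len(self.seq_a)


@dataclass
class Intron:
    index: int                  # 1-based ordinal along the gene
    alignment: PairwiseAlignment


@dataclass
class GeneAlignments:
    gene: str
    chrom_class: str            # "X" | "Y" | "A"
    introns: list = field(default_factory=list)

    def __post_init__(self):
        if self.chrom_class not in ("X", "Y", "A"):
            raise ValueError(f"chromosome class must be X, Y or A, "
                             f"got {self.chrom_class!r}")
        order = [i.index for i in self.introns]
        if order != sorted(order):
            raise ValueError(f"gene {self.gene}: introns out of positional order")


def mask_ambiguous_columns(aln: PairwiseAlignment):
    """Remove columns containing gaps or non-ACGT symbols in either sequence."""
    keep = [i for i in range(len(aln))
            if aln.seq_a[i] in GAP_TOLERANT_BASES
            and aln.seq_b[i] in GAP_TOLERANT_BASES]
    removed = len(aln) - len(keep)
    out = PairwiseAlignment("".join(aln.seq_a[i] for i in keep),
                            "".join(aln.seq_b[i] for i in keep))
    return out, removed


def _cpg_columns_once(aln: PairwiseAlignment) -> set:
    """Columns participating in a C-then-G dinucleotide in either sequence.

    The scan runs over columns that are unambiguous ACGT in BOTH sequences
    (gaps and ambiguity codes are skipped): a C pairs with the next clean
    column of the alignment.  Restricting to both-clean columns makes CpG
    removal commute with the ambiguity mask.
    """
    marked = set()
    positions = [i for i in range(len(aln))
                 if aln.seq_a[i] in GAP_TOLERANT_BASES
                 and aln.seq_b[i] in GAP_TOLERANT_BASES]
    for seq in (aln.seq_a, aln.seq_b):
        for i, j in zip(positions, positions[1:]):
            if seq[i] == "C" and seq[j] == "G":
                marked.update((i, j))
    return marked


def remove_cpg(aln: PairwiseAlignment):
    """Delete every column in a detectable CpG, iterated to a fixpoint.

    Deleting a CG pair can juxtapose a fresh C and G; repeating until no CpG
    remains makes the filter idempotent.
    """
    removed = 0
    while True:
        marked = _cpg_columns_once(aln)
        if not marked:
            return aln, removed
        keep = [i for i in range(len(aln)) if i not in marked]
        aln = PairwiseAlignment("".join(aln.seq_a[i] for i in keep),
                                "".join(aln.seq_b[i] for i in keep))
        removed += len(marked)


def trim_flanks(aln: PairwiseAlignment, flank: int = 20):
    """Drop ``flank`` columns from both ends (exon-adjacent regulatory sites)."""
    if len(aln) <= 2 * flank:
        return PairwiseAlignment("", ""), len(aln)
    return PairwiseAlignment(aln.seq_a[flank:-flank],
                             aln.seq_b[flank:-flank]), 2 * flank


def filter_introns(genes: list[GeneAlignments], flank: int = 20,
                   min_total_bp: int = 1000, min_intron_bp: int = 40,
                   drop_first_intron: bool = True):
    """Apply the full intron filter cascade; returns (retained genes, audit).

    The audit DataFrame has one row per gene with the exact column ledger:
    columns_in = removed_first_intron + removed_flanks + removed_short +
    removed_ambiguous + removed_cpg + columns_out.
    """
    retained, rows = [], []
    for gene in genes:
        columns_in = sum(len(i.alignment) for i in gene.introns)
        removed_first = removed_flank = removed_short = 0
        removed_ambig = removed_cpg_cols = 0
        kept_introns = []
        for intron in gene.introns:
            if drop_first_intron and intron.index == 1:
                removed_first += len(intron.alignment)
                continue
            aln, n_flank = trim_flanks(intron.alignment, flank)
            removed_flank += n_flank
            if len(aln) < min_intron_bp:  # too short once flanks are gone
                removed_short += len(aln)
                continue
            aln, n_ambig = mask_ambiguous_columns(aln)
            removed_ambig += n_ambig
            aln, n_cpg = remove_cpg(aln)
            removed_cpg_cols += n_cpg
            if len(aln):
                kept_introns.append(Intron(index=intron.index, alignment=aln))
        columns_out = sum(len(i.alignment) for i in kept_introns)
        keep_gene = columns_out > min_total_bp
        rows.append({
            "gene": gene.gene, "class": gene.chrom_class,
            "columns_in": columns_in,
            "removed_first_intron": removed_first,
            "removed_flanks": removed_flank,
            "removed_short_intron": removed_short,
            "removed_ambiguous": removed_ambig,
            "removed_cpg": removed_cpg_cols,
            "columns_out": columns_out,
            "retained": keep_gene,
        })
        if keep_gene:
            retained.append(GeneAlignments(gene.gene, gene.chrom_class,
                                           kept_introns))
    audit = pd.DataFrame(rows)
    return retained, audit


def concatenate_class(genes: list[GeneAlignments], chrom_class: str) -> PairwiseAlignment:
    """Concatenated pairwise alignment over all retained introns of a class."""
    parts_a, parts_b = [], []
    for gene in genes:
        if gene.chrom_class != chrom_class:
            continue
        for intron in gene.introns:
            parts_a.append(intron.alignment.seq_a)
            parts_b.append(intron.alignment.seq_b)
    return PairwiseAlignment("".join(parts_a), "".join(parts_b))


def class_introns(genes: list[GeneAlignments], chrom_class: str) -> list[PairwiseAlignment]:
    return [i.alignment for g in genes if g.chrom_class == chrom_class
            for i in g.introns]
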