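"""Peptide-to-genome coordinate mapping and annotation classification.

A peptide identified within a coordinate-tracked six-frame entry occupies
exactly ``3 * len(peptide)`` contiguous nucleotides of the parent's span;
its genomic interval follows from the parent's coordinates and the
peptide's amino-acid offset.  Intervals are then classified against gene
annotation as intergenic, intronic or exonic (in-frame / not-in-frame /
exon-extending), with multi-locus peptides set aside as ``multi_target``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
import pandas as pd
from intervaltree import IntervalTree

from sixframe.sixframe_db import OrfEntry

logger = logging.getLogger(__name__)

LOCUS_LABELS = (
    "intergenic",
    "intronic",
    "exonic_in_frame",
    "exonic_not_in_frame",
    "exonic_extending_5p",
    "exonic_extending_3p",
    "multi_target",
)


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded, 1-based inclusive genomic interval."""

    chrom_id: str
    strand: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start > end")
        if self.strand not in (1, -1):
            raise ValueError("strand must be +1 or -1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def to_bed(self, name: str = ".", score: int = 0) -> str:
        """BED6 line: 0-based half-open, strand as +/-."""
        strand = "+" if self.strand == 1 else "-"
        return "\t".join(
            [self.chrom_id, str(self.start - 1), str(self.end), name, str(score), strand]
        )


@dataclass(frozen=True)
class LocusClass:
    label: str
    gene_ids: tuple[str, ...] = ()
    exon_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.label not in LOCUS_LABELS:
            raise ValueError(f"unknown locus label {self.label!r}")


def map_peptide_locus(parent: OrfEntry, offset_aa: int, len_aa: int) -> GenomicInterval:
    """Genomic interval of a peptide positioned inside its parent entry.

    Plus strand: start = parent_start + 3*offset; minus strand counts from
    the parent's genomic end (the reading-strand 5' side).
    """
    if offset_aa < 0 or len_aa < 1 or offset_aa + len_aa > len(parent.aa_seq):
        raise ValueError(
            f"peptide span (offset {offset_aa}, length {len_aa}) outside parent "
            f"{parent.accession} of length {len(parent.aa_seq)}"
        )
    if parent.strand == 1:
        start = parent.genomic_start + 3 * offset_aa
        end = start + 3 * len_aa - 1
    else:
        end = parent.genomic_end - 3 * offset_aa
        start = end - 3 * len_aa + 1
    return GenomicInterval(parent.chrom_id, parent.strand, start, end)


@dataclass
class _Exon:
    exon_id: str
    gene_id: str
    strand: int
    start: int
    end: int
    frame: int  # phase: nt to skip from the exon's transcript-5' end to the first full codon


class Annotation:
    """Interval-indexed gene annotation built from an exon table.

    The exon table carries columns ``gene_id, transcript_id, exon_id,
    chrom_id, strand, start, end, rank`` plus optional ``frame`` (codon
    phase at the exon's 5' end; defaults to 0).  A gene's span is taken as
    min exon start to max exon end over its exons.
    """

    def __init__(self, exon_table: pd.DataFrame):
        df = exon_table.copy()
        if "frame" not in df.columns:
            df["frame"] = 0
        df["frame"] = df["frame"].fillna(0).astype(int)
        self.exon_table = df
        self.chroms: set[str] = set(df["chrom_id"].unique())
        self._gene_trees: dict[str, IntervalTree] = {}
        self._exon_trees: dict[str, IntervalTree] = {}

        genes = df.groupby("gene_id").agg(
            chrom_id=("chrom_id", "first"),
            strand=("strand", "first"),
            start=("start", "min"),
            end=("end", "max"),
        )
        for gene_id, row in genes.sort_index().iterrows():
            tree = self._gene_trees.setdefault(row["chrom_id"], IntervalTree())
            tree.addi(int(row["start"]), int(row["end"]) + 1, str(gene_id))
        seen_exons = set()
        for row in df.itertuples():
            if row.exon_id in seen_exons:
                continue
            seen_exons.add(row.exon_id)
            tree = self._exon_trees.setdefault(row.chrom_id, IntervalTree())
            tree.addi(
                int(row.start),
                int(row.end) + 1,
                _Exon(
                    exon_id=str(row.exon_id),
                    gene_id=str(row.gene_id),
                    strand=int(row.strand),
                    start=int(row.start),
                    end=int(row.end),
                    frame=int(row.frame),
                ),
            )

    def genes_overlapping(self, interval: GenomicInterval) -> list[str]:
        tree = self._gene_trees.get(interval.chrom_id)
        if tree is None:
            return []
        return sorted({iv.data for iv in tree.overlap(interval.start, interval.end + 1)})

    def exons_overlapping(self, interval: GenomicInterval) -> list[_Exon]:
        tree = self._exon_trees.get(interval.chrom_id)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(interval.start, interval.end + 1)]
        return sorted(hits, key=lambda e: (e.start, e.end, e.exon_id))


def _in_frame(interval: GenomicInterval, exon: _Exon) -> bool:
    """Codon-phase agreement between a peptide interval and an exon's
    annotated reading frame (strand must also agree)."""
    if interval.strand != exon.strand:
        return False
    if exon.strand == 1:
        first_codon_nt = exon.start + exon.frame
        return (interval.start - first_codon_nt) % 3 == 0
    first_codon_nt = exon.end - exon.frame
    return (first_codon_nt - interval.end) % 3 == 0


def classify_locus(
    interval: GenomicInterval,
    annotation: Annotation,
    n_genomic_matches: int = 1,
) -> LocusClass:
    """Classify a peptide locus against gene annotation.

    Peptides matching multiple genomic loci are ``multi_target``.  Otherwise
    the locus is intergenic (no gene overlap), intronic (within a gene but
    touching no exon), exonic in-frame / not-in-frame (fully inside an
    exon, by codon-phase agreement with the annotated frame), or
    exon-extending (crossing an exon edge into flanking sequence; the 5'/3'
    label follows the exceeded edge in the exon's transcript orientation).
    Gene and exon overlap is strand-agnostic; the in-frame test is
    strand- and phase-aware.
    """
    if interval.chrom_id not in annotation.chroms:
        raise ValueError(f"chromosome {interval.chrom_id!r} absent from annotation")
    if n_genomic_matches > 1:
        return LocusClass("multi_target")
    genes = annotation.genes_overlapping(interval)
    if not genes:
        return LocusClass("intergenic")
    if len(genes) > 1:
        logger.warning(
            "interval %s:%d-%d overlaps multiple genes %s; classifying by %s",
            interval.chrom_id, interval.start, interval.end, genes, genes[0],
        )
    exons = annotation.exons_overlapping(interval)
    if not exons:
        return LocusClass("intronic", gene_ids=tuple(genes))
    containing = [e for e in exons if e.start <= interval.start and interval.end <= e.end]
    if containing:
        for exon in containing:
            if _in_frame(interval, exon):
                return LocusClass(
                    "exonic_in_frame", gene_ids=(exon.gene_id,), exon_ids=(exon.exon_id,)
                )
        exon = containing[0]
        return LocusClass(
            "exonic_not_in_frame", gene_ids=(exon.gene_id,), exon_ids=(exon.exon_id,)
        )
    # partial overlap: extending past an exon edge
    def overlap_len(e: _Exon) -> int:
        return min(interval.end, e.end) - max(interval.start, e.start) + 1

    exon = max(exons, key=lambda e: (overlap_len(e), -e.start))
    left_overhang = max(0, exon.start - interval.start)
    right_overhang = max(0, interval.end - exon.end)
    # orient the exceeded edge by the exon's transcript direction
    if exon.strand == 1:
        five_over, three_over = left_overhang, right_overhang
    else:
        five_over, three_over = right_overhang, left_overhang
    label = "exonic_extending_3p" if three_over >= five_over else "exonic_extending_5p"
    return LocusClass(label, gene_ids=(exon.gene_id,), exon_ids=(exon.exon_id,))


def count_genomic_matches(peptide_dna: str, genome) -> int:
    """Occurrences of a peptide's coding DNA anywhere in the genome, on
    either strand (exact substring count, overlapping occurrences counted)."""
    from sixframe.sixframe_db import reverse_complement

    total = 0
    for rec in genome.values() if hasattr(genome, "values") else genome:
        for hay in (rec.sequence,):
            for needle in (peptide_dna, reverse_complement(peptide_dna)):
                start = 0
                while True:
                    idx = hay.find(needle, start)
                    if idx < 0:
                        break
                    total += 1
                    start = idx + 1
    return total
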