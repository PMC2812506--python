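"""Coordinate-tracked six-frame translation and exon-junction databases.

A six-frame database enumerates every stop-to-stop segment in all three
codon phases on both strands of each chromosome.  Each retained segment is
a putative protein (an ORF in the loose, promoter-free sense) whose genomic
coordinates are recorded so that any peptide identified inside it can later
be placed back on the genome exactly.

The exon-junction database complements it: tryptic peptides whose coding
sequence spans a splice junction are invisible to linear genomic
translation, so donor-3' / acceptor-5' exon-end concatenations are
translated in three frames and searched for such peptides.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Iterable, Literal, Mapping, Sequence

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

# Standard genetic code; stop codons map to '*'.
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TABLE[_stop] = "*"

UNAMBIGUOUS = set("ACGT")
# Nucleotide IUPAC ambiguity letters.
AMBIGUOUS = set("NRYSWKMBDHV")
IUPAC_NT = UNAMBIGUOUS | AMBIGUOUS

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

DECOY_PREFIX = "DECOY_"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeRecord:
    """One chromosome (or contig): an id and its forward-strand sequence."""

    chrom_id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OrfEntry:
    """A stop-to-stop putative protein from one frame of one strand.

    Coordinates are 1-based inclusive on the forward chromosome; minus-strand
    entries translate the reverse complement of ``[genomic_start,
    genomic_end]``.  ``frame`` is the offset (1..3) of the first translated
    nucleotide on the reading strand's 5' end.
    """

    accession: str
    chrom_id: str
    strand: int  # +1 or -1
    frame: int  # 1, 2 or 3
    genomic_start: int
    genomic_end: int
    aa_seq: str
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if self.strand not in (1, -1):
            raise ValueError(f"strand must be +1 or -1, got {self.strand}")
        if self.frame not in (1, 2, 3):
            raise ValueError(f"frame must be 1..3, got {self.frame}")
        if self.genomic_start > self.genomic_end:
            raise ValueError("genomic_start > genomic_end")
        if "*" in self.aa_seq:
            raise ValueError("aa_seq must not contain a stop symbol")


@dataclass(frozen=True)
class JunctionEntry:
    """A donor-3'-end + acceptor-5'-end exon concatenation and its
    three-frame translation."""

    accession: str
    gene_id: str
    donor_exon_id: str
    acceptor_exon_id: str
    nt_seq: str
    aa_seqs: tuple[str, str, str]
    end_len: int = 54


def _validate_sequence(seq: str, chrom_id: str) -> None:
    for pos, base in enumerate(seq):
        if base not in IUPAC_NT:
            raise ValueError(
                f"non-IUPAC nucleotide {base!r} at position {pos + 1} "
                f"of {chrom_id}"
            )


def _orf_accession(chrom: str, strand: int, frame: int, start: int, end: int) -> str:
    s = "p" if strand == 1 else "m"
    return f"SF_{chrom}_{s}{frame}_{start}_{end}"


def translate_six_frame(
    record: GenomeRecord,
    min_len: int = 6,
    require_kr: bool = True,
    ambiguity: Literal["terminate", "skip"] = "terminate",
) -> list[OrfEntry]:
    """Enumerate stop-to-stop translation products in all six frames.

    Translation starts at the first, second and third nucleotide of each
    strand and a segment ends whenever a stop codon is encountered.
    Segments shorter than ``min_len`` amino acids, and (when ``require_kr``)
    segments containing neither Lys nor Arg, are dropped: without an
    internal K/R a putative protein cannot yield a fully tryptic peptide.

    Ambiguity codons (any triplet containing an IUPAC ambiguity letter)
    terminate the current segment by default; ``ambiguity="skip"`` instead
    drops the codon and continues, in which case the entry's genomic span
    includes the skipped codons and exceeds ``3 * len(aa_seq)``.
    """
    if not record.sequence:
        raise ValueError("record sequence is empty")
    _validate_sequence(record.sequence, record.chrom_id)
    if ambiguity not in ("terminate", "skip"):
        raise ValueError(f"unknown ambiguity mode {ambiguity!r}")

    n = record.length
    entries: list[OrfEntry] = []
    for strand in (1, -1):
        reading = record.sequence if strand == 1 else reverse_complement(record.sequence)
        for frame in (1, 2, 3):
            aa: list[str] = []
            seg_start = -1  # reading-strand 0-based index of first codon nt
            seg_end = -1

            def flush() -> None:
                nonlocal aa, seg_start, seg_end
                if aa:
                    seq = "".join(aa)
                    if len(seq) >= min_len and (
                        not require_kr or "K" in seq or "R" in seq
                    ):
                        if strand == 1:
                            g_start, g_end = seg_start + 1, seg_end + 1
                        else:
                            g_start, g_end = n - seg_end, n - seg_start
                        entries.append(
                            OrfEntry(
                                accession=_orf_accession(
                                    record.chrom_id, strand, frame, g_start, g_end
                                ),
                                chrom_id=record.chrom_id,
                                strand=strand,
                                frame=frame,
                                genomic_start=g_start,
                                genomic_end=g_end,
                                aa_seq=seq,
                            )
                        )
                aa = []
                seg_start = seg_end = -1

            i = frame - 1
            while i + 3 <= n:
                codon = reading[i : i + 3]
                if not UNAMBIGUOUS.issuperset(codon):
                    if ambiguity == "terminate":
                        flush()
                    # skip: drop the codon, keep accumulating
                elif CODON_TABLE[codon] == "*":
                    flush()
                else:
                    if not aa:
                        seg_start = i
                    aa.append(CODON_TABLE[codon])
                    seg_end = i + 2
                i += 3
            flush()
    return entries


def make_decoy(entries: Sequence[OrfEntry]) -> list[OrfEntry]:
    """Reverse every amino-acid sequence and mark the accession as decoy.

    One decoy per target; counts, lengths and residue composition are
    preserved, so decoy hit counts estimate chance matching.
    """
    out = []
    for e in entries:
        acc = e.accession[len(DECOY_PREFIX):] if e.is_decoy else DECOY_PREFIX + e.accession
        out.append(replace(e, accession=acc, aa_seq=e.aa_seq[::-1], is_decoy=not e.is_decoy))
    return out


_HEADER_FIELDS = ("accession", "chrom", "strand", "frame", "start", "end", "decoy")


def encode_header(entry: OrfEntry) -> str:
    """FASTA header carrying full coordinate provenance:
    ``ACC|chrom|strand|frame|start|end|decoy_flag``."""
    strand = "+1" if entry.strand == 1 else "-1"
    decoy = "1" if entry.is_decoy else "0"
    return "|".join(
        [
            entry.accession,
            entry.chrom_id,
            strand,
            str(entry.frame),
            str(entry.genomic_start),
            str(entry.genomic_end),
            decoy,
        ]
    )


def parse_header(header: str, aa_seq: str = "") -> OrfEntry:
    """Inverse of :func:`encode_header`; raises naming the offending token."""
    tokens = header.strip().split("|")
    if len(tokens) != len(_HEADER_FIELDS):
        raise ValueError(
            f"malformed header {header!r}: expected "
            f"{len(_HEADER_FIELDS)} '|'-separated fields "
            f"({', '.join(_HEADER_FIELDS)}), got {len(tokens)}"
        )
    acc, chrom, strand_s, frame_s, start_s, end_s, decoy_s = tokens
    if strand_s not in ("+1", "-1"):
        raise ValueError(f"malformed strand token {strand_s!r} in header {header!r}")
    for name, tok in (("frame", frame_s), ("start", start_s), ("end", end_s)):
        if not re.fullmatch(r"\d+", tok):
            raise ValueError(f"malformed {name} token {tok!r} in header {header!r}")
    if decoy_s not in ("0", "1"):
        raise ValueError(f"malformed decoy token {decoy_s!r} in header {header!r}")
    return OrfEntry(
        accession=acc,
        chrom_id=chrom,
        strand=1 if strand_s == "+1" else -1,
        frame=int(frame_s),
        genomic_start=int(start_s),
        genomic_end=int(end_s),
        aa_seq=aa_seq,
        is_decoy=decoy_s == "1",
    )


def extract_orf_dna(entry: OrfEntry, genome: Mapping[str, GenomeRecord]) -> str:
    """Reading-strand nucleotide sequence underlying an entry."""
    rec = genome[entry.chrom_id]
    seg = rec.sequence[entry.genomic_start - 1 : entry.genomic_end]
    return seg if entry.strand == 1 else reverse_complement(seg)


def _translate_three_frames(nt: str) -> tuple[str, str, str]:
    out = []
    for f in range(3):
        sub = nt[f:]
        sub = sub[: len(sub) - len(sub) % 3]
        out.append(str(Seq(sub).translate()))
    return tuple(out)  # type: ignore[return-value]


def build_junction_db(
    gene_models,
    genome: Mapping[str, GenomeRecord],
    end_len: int = 54,
    pairing: Literal["gene", "transcript"] = "gene",
) -> list[JunctionEntry]:
    """Concatenate donor-3' and acceptor-5' exon ends and translate in three
    frames, covering all possible splice-variant junctions.

    ``gene_models`` is an exon table (``pandas.DataFrame``) with columns
    ``gene_id, transcript_id, exon_id, chrom_id, strand, start, end, rank``
    (1-based inclusive coordinates, rank in transcript 5'->3' order).

    Each exon contributes at most ``end_len`` nt per side (the whole exon
    when shorter).  A transcript's 5'-terminal exon contributes only its 3'
    end (donor), a 3'-terminal exon only its 5' end (acceptor).  With
    ``pairing="gene"`` (default) all ordered donor x acceptor pairs within a
    gene are emitted, capturing exon skipping and alternative junctions;
    ``pairing="transcript"`` restricts to donor rank < acceptor rank within
    one transcript.
    """
    entries: list[JunctionEntry] = []

    def exon_seq(row) -> str:
        rec = genome.get(row.chrom_id)
        if rec is None:
            raise ValueError(f"exon {row.exon_id} references unknown chromosome {row.chrom_id}")
        if row.start < 1 or row.end > rec.length:
            raise ValueError(
                f"exon {row.exon_id} coordinates {row.start}-{row.end} outside "
                f"chromosome {row.chrom_id} (length {rec.length})"
            )
        seg = rec.sequence[row.start - 1 : row.end]
        return seg if row.strand == 1 else reverse_complement(seg)

    for gene_id, gdf in gene_models.groupby("gene_id", sort=True):
        # donor/acceptor eligibility per transcript rank
        donor_ok: dict[str, bool] = {}
        acceptor_ok: dict[str, bool] = {}
        seqs: dict[str, str] = {}
        pairs: set[tuple[str, str]] = set()
        for _tid, tdf in gdf.groupby("transcript_id", sort=True):
            tdf = tdf.sort_values("rank")
            max_rank = tdf["rank"].max()
            for row in tdf.itertuples():
                seqs.setdefault(row.exon_id, exon_seq(row))
                if row.rank < max_rank:  # not 3'-terminal: may donate its 3' end
                    donor_ok[row.exon_id] = True
                if row.rank > 1:  # not 5'-terminal: may accept at its 5' end
                    acceptor_ok[row.exon_id] = True
            if pairing == "transcript":
                rows = list(tdf.itertuples())
                for a, b in product(rows, rows):
                    if a.rank < b.rank:
                        pairs.add((a.exon_id, b.exon_id))
        donors = sorted(k for k, v in donor_ok.items() if v)
        acceptors = sorted(k for k, v in acceptor_ok.items() if v)
        if pairing == "gene":
            pairs = set(product(donors, acceptors))
        for d, a in sorted(pairs):
            nt = seqs[d][-end_len:] + seqs[a][:end_len]
            entries.append(
                JunctionEntry(
                    accession=f"JX_{gene_id}_{d}_{a}",
                    gene_id=str(gene_id),
                    donor_exon_id=d,
                    acceptor_exon_id=a,
                    nt_seq=nt,
                    aa_seqs=_translate_three_frames(nt),
                    end_len=end_len,
                )
            )
    return entries


def junction_contains(junctions: Iterable[JunctionEntry], peptide: str) -> bool:
    """True when a peptide occurs in any junction's three-frame translation."""
    return any(peptide in aa for j in junctions for aa in j.aa_seqs)
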