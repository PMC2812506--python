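"""File-format I/O: FASTA (genome, ORF databases with coordinate headers,
proteins), MGF spectra, GTF gene models, BED repeats, bedGraph conservation
tracks and tab-separated PSM tables."""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mgf as _mgf

from sixframe.filters import ConservationTrack
from sixframe.mapping import GenomicInterval
from sixframe.search import PSM, PeptideSpan, ProteinEntry, Spectrum
from sixframe.sixframe_db import GenomeRecord, OrfEntry, encode_header, parse_header


# ---------------------------------------------------------------- FASTA

def read_genome_fasta(path: str | Path) -> list[GenomeRecord]:
    return [
        GenomeRecord(chrom_id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_genome_fasta(records: Iterable[GenomeRecord], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(r.sequence), id=r.chrom_id, description="") for r in records],
        str(path),
        "fasta",
    )


def write_orf_fasta(entries: Iterable[OrfEntry], path: str | Path) -> None:
    """Write an ORF database with coordinate-carrying headers
    (``>ACC|chrom|strand|frame|start|end|decoy_flag``), 60-column wrapped."""
    with open(path, "w") as fh:
        for e in entries:
            fh.write(f">{encode_header(e)}\n")
            for i in range(0, len(e.aa_seq), 60):
                fh.write(e.aa_seq[i : i + 60] + "\n")


def read_orf_fasta(path: str | Path) -> list[OrfEntry]:
    return [
        parse_header(rec.id, aa_seq=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_protein_fasta(path: str | Path) -> list[ProteinEntry]:
    return [
        ProteinEntry(accession=rec.id, aa_seq=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_protein_fasta(entries: Iterable[ProteinEntry], path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in entries:
            fh.write(f">{e.accession}\n")
            for i in range(0, len(e.aa_seq), 60):
                fh.write(e.aa_seq[i : i + 60] + "\n")


def write_plain_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for acc, seq in records:
            fh.write(f">{acc}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_plain_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


# ------------------------------------------------------------------ MGF

def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read spectra from Mascot generic format; TITLE becomes the spectrum
    id, PEPMASS and CHARGE are honoured."""
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            charge = params.get("charge")
            if charge:
                charge = int(charge[0])
            spectra.append(
                Spectrum(
                    spectrum_id=str(params.get("title", f"index={len(spectra)}")),
                    precursor_mz=float(params["pepmass"][0]),
                    precursor_charge=charge,
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                )
            )
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    entries = []
    for s in spectra:
        params = {"title": s.spectrum_id, "pepmass": s.precursor_mz}
        if s.precursor_charge:
            params["charge"] = s.precursor_charge
        entries.append(
            {"params": params, "m/z array": s.mz, "intensity array": s.intensity}
        )
    _mgf.write(entries, str(path), file_mode="w")


# ------------------------------------------------------------------ GTF

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')

GTF_COLUMNS = [
    "chrom_id", "source", "feature", "start", "end",
    "score", "strand_sym", "frame_sym", "attributes",
]


def read_gtf_exons(path: str | Path) -> pd.DataFrame:
    """Parse a GTF restricted to exon/CDS features into the exon table used
    across the package (columns ``gene_id, transcript_id, exon_id, chrom_id,
    strand, start, end, rank, frame``).

    CDS frame (phase) is attached to the exon with identical coordinates
    when present; exons without a CDS default to frame 0.
    """
    df = pd.read_csv(
        str(path), sep="\t", comment="#", header=None, names=GTF_COLUMNS,
        dtype={"start": int, "end": int},
    )
    rows = []
    cds_frames: dict[tuple[str, int, int, str], int] = {}
    for r in df.itertuples():
        attrs = dict(_ATTR_RE.findall(r.attributes))
        if r.feature == "CDS" and r.frame_sym not in (".", ""):
            cds_frames[(r.chrom_id, r.start, r.end, attrs.get("transcript_id", ""))] = int(
                r.frame_sym
            )
        if r.feature != "exon":
            continue
        rows.append(
            {
                "gene_id": attrs["gene_id"],
                "transcript_id": attrs["transcript_id"],
                "exon_id": attrs.get(
                    "exon_id", f'{attrs["transcript_id"]}.{attrs.get("exon_number", "?")}'
                ),
                "chrom_id": r.chrom_id,
                "strand": 1 if r.strand_sym == "+" else -1,
                "start": r.start,
                "end": r.end,
                "rank": int(attrs.get("exon_number", 0)),
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["frame"] = [
            cds_frames.get((r.chrom_id, r.start, r.end, r.transcript_id), 0)
            for r in out.itertuples()
        ]
    return out


def write_gtf_exons(exon_table: pd.DataFrame, path: str | Path) -> None:
    """Write the exon table as GTF exon + CDS lines (CDS carries the frame)."""
    with open(path, "w") as fh:
        for r in exon_table.sort_values(
            ["chrom_id", "gene_id", "transcript_id", "rank"]
        ).itertuples():
            strand = "+" if r.strand == 1 else "-"
            attrs = (
                f'gene_id "{r.gene_id}"; transcript_id "{r.transcript_id}"; '
                f'exon_id "{r.exon_id}"; exon_number "{r.rank}";'
            )
            frame = int(getattr(r, "frame", 0))
            fh.write(
                f"{r.chrom_id}\tsixframe\texon\t{r.start}\t{r.end}\t.\t{strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{r.chrom_id}\tsixframe\tCDS\t{r.start}\t{r.end}\t.\t{strand}\t{frame}\t{attrs}\n"
            )


# ------------------------------------------------------------------ BED

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED (0-based half-open) into 1-based closed intervals; a
    missing strand column defaults to +1."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            strand = 1
            if len(fields) >= 6 and fields[5] == "-":
                strand = -1
            out.append(
                GenomicInterval(
                    chrom_id=fields[0],
                    strand=strand,
                    start=int(fields[1]) + 1,
                    end=int(fields[2]),
                )
            )
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fh.write(iv.to_bed(name=f"region{i}") + "\n")


# -------------------------------------------------------------- bedGraph

def read_bedgraph(path: str | Path) -> ConservationTrack:
    """Read a bedGraph (0-based half-open) into a sparse per-base track."""
    track = ConservationTrack()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, value = line.split("\t")
            track.set_range(chrom, int(start) + 1, int(end), float(value))
    return track


def write_bedgraph(
    regions: Iterable[tuple[str, int, int, float]], path: str | Path
) -> None:
    """Write ``(chrom, start_1based, end_1based, value)`` regions as bedGraph."""
    with open(path, "w") as fh:
        for chrom, start, end, value in regions:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{value:g}\n")


# ------------------------------------------------------------ PSM tables

PSM_COLUMNS = [
    "spectrum_id", "peptide", "parent_accession", "offset_aa",
    "missed_cleavages", "tryptic_status", "shared_peaks", "confidence",
    "is_decoy",
]


def write_psm_table(psms: Iterable[PSM], path: str | Path) -> None:
    rows = [
        {
            "spectrum_id": p.spectrum_id,
            "peptide": p.peptide.aa_seq,
            "parent_accession": p.peptide.parent_accession,
            "offset_aa": p.peptide.offset_aa,
            "missed_cleavages": p.peptide.missed_cleavages,
            "tryptic_status": p.peptide.tryptic_status,
            "shared_peaks": p.shared_peaks,
            "confidence": p.confidence,
            "is_decoy": int(p.is_decoy),
        }
        for p in psms
    ]
    pd.DataFrame(rows, columns=PSM_COLUMNS).to_csv(str(path), sep="\t", index=False)


def read_psm_table(path: str | Path) -> list[PSM]:
    df = pd.read_csv(str(path), sep="\t")
    missing = set(PSM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"PSM table missing columns: {sorted(missing)}")
    return [
        PSM(
            spectrum_id=str(r.spectrum_id),
            peptide=PeptideSpan(
                aa_seq=r.peptide,
                parent_accession=str(r.parent_accession),
                offset_aa=int(r.offset_aa),
                missed_cleavages=int(r.missed_cleavages),
                tryptic_status=r.tryptic_status,
            ),
            shared_peaks=int(r.shared_peaks),
            confidence=float(r.confidence),
            is_decoy=bool(r.is_decoy),
        )
        for r in df.itertuples()
    ]
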