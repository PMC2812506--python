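"""Self-contained synthetic datasets with known ground truth.

The generator emulates the inputs of a whole-genome proteogenomics study:
a small random genome carrying planted multi-exon protein-coding genes
(the "known" proteome), planted novel ORFs in intergenic and intronic
space, planted pseudogene-derived ORFs (whose DNA is also emitted as a
pseudogene cDNA record so the exact-match filter removes them), repeat
intervals, a conservation track (positive over real coding loci, negative
or absent over background), and MS/MS spectra — theoretical b/y ladders
with noise peaks and optional chimeric contamination — for known, novel,
pseudogene and pure-noise precursors.

Everything derives deterministically from a single seed through named
substreams, so each stage of the pipeline can be tested in isolation with
byte-identical inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from sixframe.filters import ConservationTrack
from sixframe.mapping import GenomicInterval
from sixframe.search import (
    ModConfig,
    ProteinEntry,
    Spectrum,
    digest,
    peptide_mz,
    theoretical_ions,
)
from sixframe.sixframe_db import GenomeRecord, reverse_complement

AA20 = "ACDEFGHIKLMNPQRSTVWY"
# internal residues of generated tryptic blocks: no K/R (single cleavage
# site per block) and no P (so the preceding K/R always cleaves)
AA_INTERNAL = "".join(c for c in AA20 if c not in "KRP")

# deterministic codon choice per amino acid (first codon in lexicographic order)
_CODONS: dict[str, str] = {}
from sixframe.sixframe_db import CODON_TABLE as _CT  # noqa: E402

for _codon in sorted(_CT):
    _aa = _CT[_codon]
    if _aa != "*" and _aa not in _CODONS:
        _CODONS[_aa] = _codon

STOP = "TAA"


@dataclass
class FixtureConfig:
    n_chroms: int = 2
    chrom_len: int = 50_000
    n_genes: int = 10
    n_novel: int = 5
    n_pseudogenes: int = 3
    n_repeats: int = 5
    novel_classes: tuple[str, ...] = (
        "intergenic",
        "intergenic",
        "intergenic",
        "intronic",
        "intronic",
    )
    intron_len: int = 300
    margin: int = 120
    noise_peaks: int = 20
    chimera_rate: float = 0.05
    n_noise_spectra: int = 20
    charge: int = 2

    def __post_init__(self) -> None:
        if len(self.novel_classes) != self.n_novel:
            raise ValueError("novel_classes must list one class per novel ORF")
        for c in self.novel_classes:
            if c not in ("intergenic", "intronic"):
                raise ValueError(f"unsupported planted class {c!r}")


@dataclass
class PlantedPeptide:
    peptide_id: str
    aa_seq: str
    kind: str  # known | known_junction | novel | pseudogene
    class_label: str  # exonic_in_frame | intergenic | intronic | junction
    chrom_id: str | None = None
    strand: int = 1
    start: int = 0  # 1-based inclusive locus of the peptide codons
    end: int = 0
    dna: str = ""  # reading-strand coding sequence
    gene_id: str | None = None
    spectrum_id: str | None = None


@dataclass
class FixtureManifest:
    seed: int
    config: dict
    genes: list[dict] = field(default_factory=list)
    peptides: list[PlantedPeptide] = field(default_factory=list)
    noise_spectrum_ids: list[str] = field(default_factory=list)
    conservation_regions: list[tuple[str, int, int, float]] = field(default_factory=list)

    def peptides_of_kind(self, *kinds: str) -> list[PlantedPeptide]:
        return [p for p in self.peptides if p.kind in kinds]

    def to_json(self) -> str:
        d = {
            "seed": self.seed,
            "config": self.config,
            "genes": self.genes,
            "peptides": [asdict(p) for p in self.peptides],
            "noise_spectrum_ids": self.noise_spectrum_ids,
            "conservation_regions": [list(r) for r in self.conservation_regions],
        }
        def _default(o):
            if isinstance(o, np.integer):
                return int(o)
            if isinstance(o, np.floating):
                return float(o)
            raise TypeError(f"not JSON serializable: {type(o)}")

        return json.dumps(d, indent=1, sort_keys=True, default=_default)

    @classmethod
    def from_json(cls, text: str) -> "FixtureManifest":
        d = json.loads(text)
        m = cls(seed=d["seed"], config=d["config"], genes=d["genes"])
        m.peptides = [PlantedPeptide(**p) for p in d["peptides"]]
        m.noise_spectrum_ids = d["noise_spectrum_ids"]
        m.conservation_regions = [tuple(r) for r in d["conservation_regions"]]
        return m


@dataclass
class Fixture:
    """In-memory synthetic dataset plus its ground-truth manifest."""

    config: FixtureConfig
    manifest: FixtureManifest
    genome: dict[str, GenomeRecord]
    exon_table: pd.DataFrame
    reference_proteins: list[ProteinEntry]
    pseudogenes: list[tuple[str, str]]
    ests: list[tuple[str, str]]
    repeats: list[GenomicInterval]
    conservation: ConservationTrack
    spectra: list[Spectrum]


def _rand_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _tryptic_block(rng: np.random.Generator, length: int) -> str:
    body = "".join(
        AA_INTERNAL[i] for i in rng.integers(0, len(AA_INTERNAL), size=length - 1)
    )
    return body + ("K" if rng.integers(0, 2) == 0 else "R")


def _encode(protein: str) -> str:
    return "".join(_CODONS[aa] for aa in protein)


class _Placer:
    """Non-overlapping interval placement on the synthetic chromosomes."""

    def __init__(self, rng: np.random.Generator, chrom_lens: dict[str, int], margin: int):
        self.rng = rng
        self.chrom_lens = chrom_lens
        self.margin = margin
        self.occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lens}

    def _free(self, chrom: str, start: int, end: int) -> bool:
        m = self.margin
        return all(e < start - m or s > end + m for s, e in self.occupied[chrom])

    def reserve(self, chrom: str, start: int, end: int) -> None:
        self.occupied[chrom].append((start, end))

    def place(self, length: int, chrom: str | None = None) -> tuple[str, int]:
        """Return (chrom, 0-based start) of a free slot of ``length`` nt."""
        chroms = sorted(self.chrom_lens) if chrom is None else [chrom]
        for _ in range(2000):
            c = chroms[int(self.rng.integers(0, len(chroms)))]
            limit = self.chrom_lens[c] - length - self.margin
            if limit <= self.margin:
                continue
            start = int(self.rng.integers(self.margin, limit))
            if self._free(c, start, start + length - 1):
                self.reserve(c, start, start + length - 1)
                return c, start
        raise ValueError(
            "config infeasible: could not place an interval of length "
            f"{length} on the synthetic genome"
        )


def _plant_orf_dna(rng: np.random.Generator) -> tuple[str, str]:
    """DNA of a planted stop-to-stop ORF: stop + Lys + peptide + stop.

    The leading Lys makes the peptide a fully tryptic product of its parent
    ORF; returns ``(peptide, dna)``.
    """
    length = int(rng.integers(9, 13))
    peptide = _tryptic_block(rng, length)
    return peptide, STOP + _CODONS["K"] + _encode(peptide) + STOP


def spectra_from_peptides(
    peptides: Sequence[tuple[str, str]],
    noise_peaks: int = 20,
    chimera_rate: float = 0.0,
    seed: int = 0,
    charge: int = 2,
    mods: ModConfig | None = None,
    noise_mz_range: tuple[float, float] = (100.0, 1500.0),
) -> list[Spectrum]:
    """Generate one spectrum per ``(spectrum_id, peptide)`` pair.

    Each spectrum holds the peptide's singly charged b/y ladder at high
    intensity, ``noise_peaks`` uniform-m/z low-intensity peaks, and, with
    probability ``chimera_rate``, the ladder of a different co-isolated
    peptide at intermediate intensity.  The precursor m/z is set from the
    peptide mass at ``charge``.  Deterministic given ``seed``.
    """
    mods = mods if mods is not None else ModConfig()
    rng = np.random.default_rng(seed)
    out: list[Spectrum] = []
    for i, (sid, pep) in enumerate(peptides):
        ions = theoretical_ions(pep, mods)
        mz = list(ions)
        inten = [100.0] * len(ions)
        if chimera_rate > 0 and len(peptides) > 1 and rng.random() < chimera_rate:
            j = int(rng.integers(0, len(peptides) - 1))
            if j >= i:
                j += 1
            other = theoretical_ions(peptides[j][1], mods)
            mz.extend(other)
            inten.extend([50.0] * len(other))
        if noise_peaks > 0:
            lo, hi = noise_mz_range
            noise_mz = rng.uniform(lo, hi, size=noise_peaks)
            noise_in = rng.exponential(5.0, size=noise_peaks) + 1.0
            mz.extend(noise_mz)
            inten.extend(noise_in)
        out.append(
            Spectrum(
                spectrum_id=sid,
                precursor_mz=peptide_mz(pep, charge, mods),
                precursor_charge=charge,
                mz=np.array(mz),
                intensity=np.array(inten),
            )
        )
    return out


def noise_spectra(
    n: int,
    seed: int = 0,
    n_peaks: int = 60,
    mz_range: tuple[float, float] = (150.0, 1500.0),
    precursor_range: tuple[float, float] = (400.0, 1200.0),
    charge: int = 2,
    prefix: str = "NOISE",
) -> list[Spectrum]:
    """Pure-noise spectra: uniform random peaks, random precursor m/z."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        mz = rng.uniform(*mz_range, size=n_peaks)
        inten = rng.exponential(10.0, size=n_peaks) + 1.0
        out.append(
            Spectrum(
                spectrum_id=f"{prefix}_{i}",
                precursor_mz=float(rng.uniform(*precursor_range)),
                precursor_charge=charge,
                mz=mz,
                intensity=inten,
            )
        )
    return out


def _gene_structure(rng: np.random.Generator) -> tuple[str, list[int]]:
    """Random protein plus coding-space exon cut points (2 cuts, 3 exons)."""
    blocks = [_tryptic_block(rng, int(rng.integers(8, 14))) for _ in range(7)]
    protein = "".join(blocks)
    coding_len = 3 * len(protein)
    cut1 = int(rng.integers(coding_len // 4, coding_len // 2))
    cut2 = int(rng.integers(cut1 + coding_len // 6, coding_len - 21))
    return protein, [cut1, cut2]


def generate_fixture(
    config: FixtureConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> Fixture:
    """Generate the full synthetic dataset; optionally write it to disk.

    Files written to ``out_dir``: genome.fa, genes.gtf,
    reference_proteins.fa, pseudogenes.fa, ests.fa, repeats.bed,
    conservation.bedgraph, spectra.mgf, manifest.json.
    """
    config = config or FixtureConfig()
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(8)
    rng_genome = np.random.default_rng(streams[0])
    rng_genes = np.random.default_rng(streams[1])
    rng_novel = np.random.default_rng(streams[2])
    rng_pseudo = np.random.default_rng(streams[3])
    rng_repeats = np.random.default_rng(streams[4])
    rng_conserve = np.random.default_rng(streams[5])
    rng_spectra = np.random.default_rng(streams[6])
    rng_place = np.random.default_rng(streams[7])

    chrom_ids = [f"chr{i + 1}" for i in range(config.n_chroms)]
    genome_chars = {
        c: np.array(list(_rand_dna(rng_genome, config.chrom_len))) for c in chrom_ids
    }
    placer = _Placer(rng_place, {c: config.chrom_len for c in chrom_ids}, config.margin)

    manifest = FixtureManifest(
        seed=seed,
        config={k: v if not isinstance(v, tuple) else list(v) for k, v in asdict(config).items()},
    )
    exon_rows: list[dict] = []
    reference_proteins: list[ProteinEntry] = []
    conservation_regions: list[tuple[str, int, int, float]] = []
    intron_slots: list[dict] = []  # candidate intervals for intronic plants

    def write_seg(chrom: str, start0: int, seg: str) -> None:
        genome_chars[chrom][start0 : start0 + len(seg)] = list(seg)

    # ----- genes -------------------------------------------------------
    for gi in range(config.n_genes):
        gene_id = f"g{gi}"
        protein, cuts = _gene_structure(rng_genes)
        coding = _encode(protein)
        exon_cod = [coding[: cuts[0]], coding[cuts[0] : cuts[1]], coding[cuts[1] :]]
        introns = [
            _rand_dna(rng_genes, config.intron_len),
            _rand_dna(rng_genes, config.intron_len),
        ]
        seg = exon_cod[0] + introns[0] + exon_cod[1] + introns[1] + exon_cod[2]
        strand = 1 if rng_genes.integers(0, 2) == 0 else -1
        chrom, start0 = placer.place(len(seg))
        write_seg(chrom, start0, seg if strand == 1 else reverse_complement(seg))

        # exon genomic coordinates (1-based inclusive), transcript order
        lens = [len(x) for x in (exon_cod[0], introns[0], exon_cod[1], introns[1], exon_cod[2])]
        offs = np.concatenate([[0], np.cumsum(lens)])[:5]
        tx_spans = []  # (start, end) genomic, transcript order
        for k, piece in enumerate([0, 2, 4]):
            s_rel, e_rel = offs[piece], offs[piece] + lens[piece] - 1
            if strand == 1:
                tx_spans.append((start0 + 1 + s_rel, start0 + 1 + e_rel))
            else:
                L = len(seg)
                tx_spans.append((start0 + L - e_rel, start0 + L - s_rel))
        cum = [0, cuts[0], cuts[1]]
        for k, (gs, ge) in enumerate(tx_spans):
            exon_rows.append(
                {
                    "gene_id": gene_id,
                    "transcript_id": f"{gene_id}.t1",
                    "exon_id": f"{gene_id}.e{k + 1}",
                    "chrom_id": chrom,
                    "strand": strand,
                    "start": gs,
                    "end": ge,
                    "rank": k + 1,
                    "frame": (3 - cum[k] % 3) % 3,
                }
            )
            conservation_regions.append((chrom, gs, ge, 2.0))
        # intron genomic intervals, usable for intronic plants
        for piece in (1, 3):
            s_rel, e_rel = offs[piece], offs[piece] + lens[piece] - 1
            if strand == 1:
                iv = (start0 + 1 + s_rel, start0 + 1 + e_rel)
            else:
                L = len(seg)
                iv = (start0 + L - e_rel, start0 + L - s_rel)
            intron_slots.append({"gene_id": gene_id, "chrom": chrom, "span": iv})

        reference_proteins.append(ProteinEntry(accession=f"REF_{gene_id}", aa_seq=protein))

        # known tryptic peptides: within-exon vs junction-crossing
        exon_bounds = [(0, cuts[0]), (cuts[0], cuts[1]), (cuts[1], 3 * len(protein))]
        n_within = n_cross = 0
        for span in digest(protein, missed=0, min_len=7):
            if len(span.aa_seq) > 15:
                continue
            c0, c1 = 3 * span.offset_aa, 3 * (span.offset_aa + len(span.aa_seq)) - 1
            host = [k for k, (bs, be) in enumerate(exon_bounds) if bs <= c0 and c1 < be]
            if host and n_within < 3:
                k = host[0]
                bs, _ = exon_bounds[k]
                gs, ge = tx_spans[k]
                if strand == 1:
                    ps, pe = gs + (c0 - bs), gs + (c1 - bs)
                else:
                    ps, pe = ge - (c1 - bs), ge - (c0 - bs)
                pid = f"KNOWN_{gene_id}_{n_within}"
                manifest.peptides.append(
                    PlantedPeptide(
                        peptide_id=pid,
                        aa_seq=span.aa_seq,
                        kind="known",
                        class_label="exonic_in_frame",
                        chrom_id=chrom,
                        strand=strand,
                        start=ps,
                        end=pe,
                        dna=coding[c0 : c1 + 1],
                        gene_id=gene_id,
                        spectrum_id=f"SPEC_{pid}",
                    )
                )
                n_within += 1
            elif not host and n_cross < 1:
                pid = f"JUNC_{gene_id}_{n_cross}"
                manifest.peptides.append(
                    PlantedPeptide(
                        peptide_id=pid,
                        aa_seq=span.aa_seq,
                        kind="known_junction",
                        class_label="junction",
                        chrom_id=chrom,
                        strand=strand,
                        dna=coding[c0 : c1 + 1],
                        gene_id=gene_id,
                        spectrum_id=f"SPEC_{pid}",
                    )
                )
                n_cross += 1
        manifest.genes.append(
            {
                "gene_id": gene_id,
                "chrom_id": chrom,
                "strand": strand,
                "protein": protein,
                "exons": [list(s) for s in tx_spans],
            }
        )

    # ----- novel ORFs --------------------------------------------------
    def plant_novel(idx: int, class_label: str, kind: str, rng: np.random.Generator) -> None:
        peptide, dna = _plant_orf_dna(rng)
        strand = 1 if rng.integers(0, 2) == 0 else -1
        if class_label == "intergenic":
            chrom, start0 = placer.place(len(dna))
        else:  # intronic: inside a gene's intron, clear of its exons
            pad = 15
            for _attempt in range(500):
                slot = intron_slots[int(rng.integers(0, len(intron_slots)))]
                s, e = slot["span"]
                if e - s + 1 < len(dna) + 2 * pad:
                    continue
                start0 = int(rng.integers(s - 1 + pad, e - len(dna) - pad))
                taken = slot.setdefault("taken", [])
                if all(
                    t_e < start0 or t_s > start0 + len(dna) - 1 for t_s, t_e in taken
                ):
                    taken.append((start0, start0 + len(dna) - 1))
                    chrom = slot["chrom"]
                    break
            else:
                raise ValueError("config infeasible: no intron slot fits the plant")
        write_seg(chrom, start0, dna if strand == 1 else reverse_complement(dna))
        # peptide codons sit after the leading stop (3 nt) + Lys codon (3 nt)
        plen_nt = 3 * len(peptide)
        if strand == 1:
            ps = start0 + 1 + 6
            pe = ps + plen_nt - 1
        else:
            pe = start0 + len(dna) - 6
            ps = pe - plen_nt + 1
        prefix = "NOV" if kind == "novel" else "PSG"
        pid = f"{prefix}_{idx}"
        manifest.peptides.append(
            PlantedPeptide(
                peptide_id=pid,
                aa_seq=peptide,
                kind=kind,
                class_label=class_label,
                chrom_id=chrom,
                strand=strand,
                start=ps,
                end=pe,
                dna=_encode(peptide),
                gene_id=None,
                spectrum_id=f"SPEC_{pid}",
            )
        )
        if kind == "novel":
            conservation_regions.append((chrom, ps, pe, 2.0))

    for i, label in enumerate(config.novel_classes):
        plant_novel(i, label, "novel", rng_novel)
    pseudo_records: list[tuple[str, str]] = []
    for i in range(config.n_pseudogenes):
        plant_novel(i, "intergenic", "pseudogene", rng_pseudo)
        planted = manifest.peptides[-1]
        # the pseudogene cDNA carries the same reading-strand sequence
        pseudo_records.append(
            (f"PSEUDO_{i}", STOP + _CODONS["K"] + planted.dna + STOP)
        )

    # ----- repeats & background conservation & ESTs --------------------
    repeats: list[GenomicInterval] = []
    for i in range(config.n_repeats):
        length = int(rng_repeats.integers(200, 400))
        chrom, start0 = placer.place(length)
        repeats.append(GenomicInterval(chrom, 1, start0 + 1, start0 + length))
    for _ in range(6):
        length = 200
        chrom, start0 = placer.place(length)
        conservation_regions.append((chrom, start0 + 1, start0 + length, -1.0))

    ests: list[tuple[str, str]] = []
    novel_plants = manifest.peptides_of_kind("novel")
    if novel_plants:
        ests.append(("EST_0", STOP + _CODONS["K"] + novel_plants[0].dna + STOP))
    ests.append(("EST_BG", _rand_dna(rng_conserve, 300)))

    track = ConservationTrack()
    for chrom, s, e, v in conservation_regions:
        track.set_range(chrom, s, e, v)

    # ----- spectra -----------------------------------------------------
    peptide_specs = [
        (p.spectrum_id, p.aa_seq)
        for p in manifest.peptides
        if p.spectrum_id is not None
    ]
    spectra = spectra_from_peptides(
        peptide_specs,
        noise_peaks=config.noise_peaks,
        chimera_rate=config.chimera_rate,
        seed=int(rng_spectra.integers(0, 2**31 - 1)),
        charge=config.charge,
    )
    noise = noise_spectra(
        config.n_noise_spectra, seed=int(rng_spectra.integers(0, 2**31 - 1))
    )
    spectra = spectra + noise
    manifest.noise_spectrum_ids = [s.spectrum_id for s in noise]
    manifest.conservation_regions = conservation_regions

    genome = {c: GenomeRecord(c, "".join(genome_chars[c])) for c in chrom_ids}

    # construction guarantee: every planted ORF peptide coding sequence is
    # unique in the genome (no accidental multi-target loci)
    from sixframe.mapping import count_genomic_matches

    for p in manifest.peptides_of_kind("novel", "pseudogene"):
        n = count_genomic_matches(p.dna, genome)
        if n != 1:
            raise ValueError(
                f"config infeasible: planted peptide {p.peptide_id} occurs "
                f"{n} times in the generated genome"
            )

    exon_table = pd.DataFrame(exon_rows)
    fixture = Fixture(
        config=config,
        manifest=manifest,
        genome=genome,
        exon_table=exon_table,
        reference_proteins=reference_proteins,
        pseudogenes=pseudo_records,
        ests=ests,
        repeats=repeats,
        conservation=track,
        spectra=spectra,
    )
    if out_dir is not None:
        _write_fixture(fixture, Path(out_dir))
    return fixture


def _write_fixture(fx: Fixture, out_dir: Path) -> None:
    from sixframe import io as sfio

    out_dir.mkdir(parents=True, exist_ok=True)
    sfio.write_genome_fasta(fx.genome.values(), out_dir / "genome.fa")
    sfio.write_gtf_exons(fx.exon_table, out_dir / "genes.gtf")
    sfio.write_protein_fasta(fx.reference_proteins, out_dir / "reference_proteins.fa")
    sfio.write_plain_fasta(fx.pseudogenes, out_dir / "pseudogenes.fa")
    sfio.write_plain_fasta(fx.ests, out_dir / "ests.fa")
    sfio.write_bed(fx.repeats, out_dir / "repeats.bed")
    sfio.write_bedgraph(fx.manifest.conservation_regions, out_dir / "conservation.bedgraph")
    sfio.write_mgf(fx.spectra, out_dir / "spectra.mgf")
    (out_dir / "manifest.json").write_text(fx.manifest.to_json() + "\n")
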