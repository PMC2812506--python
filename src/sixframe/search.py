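"""In-silico tryptic digestion, b/y fragment generation, and a stand-in
peptide-spectrum matcher.

The matcher is declared plumbing: it reproduces the *contract* a database
search engine must satisfy for target/decoy FDR estimation — every target
and decoy candidate within the precursor window competes for each spectrum,
exactly one best match is reported, and a calibrated confidence in [0, 1]
makes "confidence >= 95%" thresholds expressible — without claiming to
reproduce any commercial engine's internal scoring.  Externally produced
PSM tables can be used in its place throughout the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from pyteomics import mass as _pmass

from sixframe._matching import max_common_count

PROTON = 1.00727646688
WATER = _pmass.calculate_mass(formula="H2O")

RESIDUE_MASS: dict[str, float] = dict(_pmass.std_aa_mass)

# Stand-in confidence calibration: logistic in the matched-ion fraction.
CONF_STEEPNESS = 12.0
CONF_MIDPOINT = 0.5

# Fixed-modification mass shifts (Da)
MMTS_DELTA = 45.98772  # methylmethanethiosulphate on Cys
ITRAQ4_DELTA = 144.10207  # 4-plex isobaric tag on Lys and peptide N-terminus


@dataclass(frozen=True)
class ModConfig:
    """Fixed modifications: per-residue mass shifts plus terminal shifts.

    Defaults follow an iTRAQ/MMTS sample-preparation protocol: Cys blocked
    by MMTS, isobaric tags on Lys side chains and peptide N-termini.
    """

    residue_shifts: Mapping[str, float] = field(
        default_factory=lambda: {"C": MMTS_DELTA, "K": ITRAQ4_DELTA}
    )
    nterm_shift: float = ITRAQ4_DELTA
    cterm_shift: float = 0.0

    @classmethod
    def none(cls) -> "ModConfig":
        return cls(residue_shifts={}, nterm_shift=0.0, cterm_shift=0.0)

    def residue_mass(self, aa: str) -> float:
        try:
            base = RESIDUE_MASS[aa]
        except KeyError:
            raise ValueError(f"unknown amino-acid residue {aa!r}") from None
        return base + self.residue_shifts.get(aa, 0.0)


@dataclass
class Spectrum:
    """A centroided peak list with precursor information."""

    spectrum_id: str
    precursor_mz: float
    precursor_charge: int | None
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if np.any(self.mz <= 0):
            raise ValueError("all peak m/z values must be positive")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)


@dataclass(frozen=True)
class ProteinEntry:
    """A plain protein database entry (e.g. a reference proteome record)."""

    accession: str
    aa_seq: str
    is_decoy: bool = False


@dataclass(frozen=True)
class PeptideSpan:
    """A proteolytic peptide located within its parent protein."""

    aa_seq: str
    parent_accession: str
    offset_aa: int
    missed_cleavages: int
    tryptic_status: Literal["full", "semi"] = "full"


@dataclass(frozen=True)
class PSM:
    """A scored peptide-spectrum match with target/decoy provenance."""

    spectrum_id: str
    peptide: PeptideSpan
    shared_peaks: int
    confidence: float
    is_decoy: bool


def cleavage_sites(aa_seq: str) -> list[int]:
    """0-based positions *after* which trypsin cleaves: C-terminal to K/R
    except when the next residue is Pro."""
    return [
        i + 1
        for i in range(len(aa_seq) - 1)
        if aa_seq[i] in "KR" and aa_seq[i + 1] != "P"
    ]


def digest(
    aa_seq: str,
    missed: int = 1,
    mode: Literal["full", "semi"] = "full",
    parent_accession: str = "",
    min_len: int = 1,
) -> list[PeptideSpan]:
    """Tryptic digestion with up to ``missed`` missed cleavages.

    ``mode="semi"`` additionally emits every product with exactly one
    non-tryptic terminus (pseudo-tryptic peptides).
    """
    if not aa_seq:
        raise ValueError("aa_seq is empty")
    bounds = [0] + cleavage_sites(aa_seq) + [len(aa_seq)]
    seen: set[tuple[int, int]] = set()
    spans: list[PeptideSpan] = []

    def emit(s: int, e: int, status: str) -> None:
        if e - s < min_len or (s, e) in seen:
            return
        seen.add((s, e))
        n_internal = sum(1 for b in bounds if s < b < e)
        spans.append(
            PeptideSpan(
                aa_seq=aa_seq[s:e],
                parent_accession=parent_accession,
                offset_aa=s,
                missed_cleavages=n_internal,
                tryptic_status=status,  # type: ignore[arg-type]
            )
        )

    for bi in range(len(bounds) - 1):
        for bj in range(bi + 1, min(bi + 2 + missed, len(bounds))):
            s, e = bounds[bi], bounds[bj]
            emit(s, e, "full")
            if mode == "semi":
                for e2 in range(s + 1, e):
                    if e2 not in bounds:
                        emit(s, e2, "semi")
                for s2 in range(s + 1, e):
                    if s2 not in bounds:
                        emit(s2, e, "semi")
    spans.sort(key=lambda p: (p.offset_aa, len(p.aa_seq), p.tryptic_status))
    return spans


def peptide_neutral_mass(peptide: str, mods: ModConfig | None = None) -> float:
    mods = mods if mods is not None else ModConfig()
    return (
        sum(mods.residue_mass(aa) for aa in peptide)
        + mods.nterm_shift
        + mods.cterm_shift
        + WATER
    )


def peptide_mz(peptide: str, charge: int, mods: ModConfig | None = None) -> float:
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (peptide_neutral_mass(peptide, mods) + charge * PROTON) / charge


def theoretical_ions(peptide: str, mods: ModConfig | None = None) -> np.ndarray:
    """Singly charged monoisotopic b- and y-ion m/z ladder (b1..b(n-1),
    y1..y(n-1)), sorted ascending, with fixed modifications applied."""
    mods = mods if mods is not None else ModConfig()
    masses = np.array([mods.residue_mass(aa) for aa in peptide])
    n = len(peptide)
    if n < 2:
        return np.empty(0)
    prefix = np.cumsum(masses)
    b = prefix[:-1] + mods.nterm_shift + PROTON
    suffix = np.cumsum(masses[::-1])
    y = suffix[:-1] + mods.cterm_shift + WATER + PROTON
    return np.sort(np.concatenate([b, y]))


def _confidence(fraction: float) -> float:
    return 1.0 / (1.0 + math.exp(-CONF_STEEPNESS * (fraction - CONF_MIDPOINT)))


def match_score(
    spectrum: Spectrum, ions: Sequence[float], tol: float = 0.2
) -> tuple[int, float]:
    """Count theoretical ions matched one-to-one to spectrum peaks within
    ``tol`` Th (maximum matching) and map the matched fraction through the
    logistic confidence calibration."""
    ions = np.asarray(ions, dtype=float)
    if ions.size == 0:
        raise ValueError("ions must be non-empty")
    shared = max_common_count(ions, spectrum.mz, tol)
    return shared, _confidence(shared / ions.size)


@dataclass
class SearchParams:
    precursor_tol: float = 0.5  # Th, on precursor m/z
    frag_tol: float = 0.2  # Th, on fragment m/z
    missed: int = 1
    mode: Literal["full", "semi"] = "full"
    mods: ModConfig = field(default_factory=ModConfig)
    min_peptide_len: int = 6
    max_peptide_len: int = 40
    default_charge: int = 1


class PeptideIndex:
    """Mass-sorted index of all digestion products of a protein database."""

    def __init__(self, entries: Sequence, params: SearchParams):
        self.params = params
        pep_seqs: list[str] = []
        records: list[tuple] = []  # (span, is_decoy)
        for entry in entries:
            for span in digest(
                entry.aa_seq,
                missed=params.missed,
                mode=params.mode,
                parent_accession=entry.accession,
                min_len=params.min_peptide_len,
            ):
                if len(span.aa_seq) > params.max_peptide_len:
                    continue
                pep_seqs.append(span.aa_seq)
                records.append((span, getattr(entry, "is_decoy", False)))
        masses = np.array(
            [peptide_neutral_mass(p, params.mods) for p in pep_seqs]
        ) if pep_seqs else np.empty(0)
        order = np.argsort(masses, kind="stable")
        self.masses = masses[order]
        self.records = [records[i] for i in order]

    def candidates(self, neutral_mass: float, mass_tol: float) -> list[tuple]:
        lo = np.searchsorted(self.masses, neutral_mass - mass_tol, side="left")
        hi = np.searchsorted(self.masses, neutral_mass + mass_tol, side="right")
        return self.records[lo:hi]


def search(
    spectra: Iterable[Spectrum],
    entries: Sequence,
    params: SearchParams | None = None,
) -> list[PSM]:
    """Best-per-spectrum competitive search of target and decoy entries.

    Every database entry (target or decoy) whose digestion products fall in
    the precursor-mass window competes for each spectrum; the single best
    PSM is returned per spectrum (ties broken by lexicographically smallest
    peptide, then target over decoy, then smallest accession).  Spectra with
    no candidate in the window are left unassigned (absent from the output).
    """
    params = params or SearchParams()
    if not entries:
        raise ValueError("database is empty")
    index = PeptideIndex(entries, params)
    ion_cache: dict[str, np.ndarray] = {}
    psms: list[PSM] = []
    for spectrum in spectra:
        z = spectrum.precursor_charge or params.default_charge
        neutral = z * (spectrum.precursor_mz - PROTON)
        cands = index.candidates(neutral, z * params.precursor_tol)
        best: tuple | None = None
        scored: dict[str, tuple[int, float]] = {}
        for span, is_decoy in cands:
            pep = span.aa_seq
            if pep not in scored:
                ions = ion_cache.get(pep)
                if ions is None:
                    ions = theoretical_ions(pep, params.mods)
                    ion_cache[pep] = ions
                if ions.size == 0:
                    continue
                scored[pep] = match_score(spectrum, ions, params.frag_tol)
            shared, conf = scored[pep]
            key = (-conf, -shared, pep, is_decoy, span.parent_accession, span.offset_aa)
            if best is None or key < best[0]:
                best = (key, span, is_decoy, shared, conf)
        if best is not None:
            _, span, is_decoy, shared, conf = best
            psms.append(
                PSM(
                    spectrum_id=spectrum.spectrum_id,
                    peptide=span,
                    shared_peaks=shared,
                    confidence=conf,
                    is_decoy=is_decoy,
                )
            )
    return psms


def unassigned_ids(spectra: Iterable[Spectrum], psms: Iterable[PSM]) -> list[str]:
    assigned = {p.spectrum_id for p in psms}
    return [s.spectrum_id for s in spectra if s.spectrum_id not in assigned]
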