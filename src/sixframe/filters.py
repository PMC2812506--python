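"""Annotation filters for candidate novel-peptide loci.

Candidates surviving the search are screened against (i) a pseudogene cDNA
set — an exact, strand-aware DNA match means the peptide likely derives
from a processed pseudogene, not a novel locus; (ii) repeat annotation —
any overlap with a repeat interval disqualifies the locus; and (iii) a
per-base substitution-deficit conservation track (GERP-style R = expected
minus observed substitutions), aggregated as a length-normalised sum over
the locus.  EST evidence uses the same exact-match machinery but is
reported as optional support rather than used for exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree
from scipy import stats

from sixframe.mapping import GenomicInterval
from sixframe.sixframe_db import reverse_complement


@dataclass
class ConservationTrack:
    """Sparse per-base conservation scores; absent positions score 0.

    Stored as ``{chrom_id: {1-based position: R}}``.
    """

    scores: dict[str, dict[int, float]] = field(default_factory=dict)

    def set_range(self, chrom_id: str, start: int, end: int, value: float) -> None:
        d = self.scores.setdefault(chrom_id, {})
        for pos in range(start, end + 1):
            d[pos] = value

    def get(self, chrom_id: str, pos: int) -> float:
        return self.scores.get(chrom_id, {}).get(pos, 0.0)


def exact_dna_filter(
    peptide_dna: str,
    reference_set: Sequence[tuple[str, str]],
    stranded: bool = True,
) -> tuple[bool, str | None]:
    """Exact substring match of a peptide's coding DNA against a sequence set.

    ``peptide_dna`` is the reading-strand (coding) sequence of the peptide
    locus.  ``reference_set`` is ``[(accession, sequence), ...]``.  The query
    is tested verbatim; its reverse complement is tested only when the
    reference set is declared unstranded.  Returns ``(matched, accession)``.
    In pseudogene mode a match excludes the peptide; in EST mode it counts
    as transcription support.
    """
    if not peptide_dna:
        raise ValueError("peptide_dna is empty")
    queries = [peptide_dna.upper()]
    if not stranded:
        queries.append(reverse_complement(peptide_dna.upper()))
    for acc, seq in reference_set:
        s = seq.upper()
        for q in queries:
            if q in s:
                return True, acc
    return False, None


class RepeatIndex:
    """Interval-indexed repeat annotation (closed 1-based intervals)."""

    def __init__(self, repeats: Iterable[GenomicInterval] = ()):
        self._trees: dict[str, IntervalTree] = {}
        for iv in repeats:
            self.add(iv)

    def add(self, iv: GenomicInterval) -> None:
        self._trees.setdefault(iv.chrom_id, IntervalTree()).addi(
            iv.start, iv.end + 1, iv
        )

    def overlapping(self, interval: GenomicInterval) -> list[GenomicInterval]:
        tree = self._trees.get(interval.chrom_id)
        if tree is None:
            return []
        return sorted(
            (h.data for h in tree.overlap(interval.start, interval.end + 1)),
            key=lambda r: (r.start, r.end),
        )


def repeat_overlap(
    interval: GenomicInterval, repeats: RepeatIndex | Iterable[GenomicInterval]
) -> bool:
    """True (filter failure) iff the locus overlaps any repeat interval by
    at least one nucleotide, regardless of strand."""
    index = repeats if isinstance(repeats, RepeatIndex) else RepeatIndex(repeats)
    return bool(index.overlapping(interval))


def conservation_sigma(interval: GenomicInterval, track: ConservationTrack) -> float:
    """Length-normalised conservation sum over the locus.

    Sums per-base R across ``[start, end]`` (absent positions contribute 0)
    and divides by the interval length, so a fully unscored region yields
    exactly 0 and a constant track yields that constant.
    """
    chrom = track.scores.get(interval.chrom_id, {})
    total = sum(chrom.get(pos, 0.0) for pos in range(interval.start, interval.end + 1))
    return total / interval.length


@dataclass(frozen=True)
class SigmaCutoffResult:
    cutoff: float
    statistic: float
    pvalue: float
    n_exonic: int
    n_candidate: int


def choose_sigma_cutoff(
    exonic_sigmas: Sequence[float],
    candidate_sigmas: Sequence[float],
    cutoff: float = 0.0,
) -> SigmaCutoffResult:
    """Rank-sum comparison of conserved (exonic) versus candidate locus
    scores, after removing exact zeros (unscored loci carry no signal).

    Returns the Mann-Whitney U statistic and two-sided p-value together
    with the configured cutoff; survivors downstream satisfy
    ``sigma >= cutoff``.
    """
    ex = [x for x in exonic_sigmas if x != 0]
    ca = [x for x in candidate_sigmas if x != 0]
    if not ex or not ca:
        raise ValueError("a score list is empty after removing zeros")
    res = stats.mannwhitneyu(ex, ca, alternative="two-sided", method="auto")
    return SigmaCutoffResult(
        cutoff=cutoff,
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        n_exonic=len(ex),
        n_candidate=len(ca),
    )


@dataclass
class FilterVerdict:
    """Per-peptide filter outcomes with supporting evidence."""

    peptide_id: str
    pseudogene_pass: bool
    repeat_pass: bool
    conservation_pass: bool
    pseudogene_evidence: str | None = None
    repeat_evidence: GenomicInterval | None = None
    sigma: float = 0.0
    est_support: str | None = None

    @property
    def passed(self) -> bool:
        return self.pseudogene_pass and self.repeat_pass and self.conservation_pass


def apply_filters(
    candidates: Sequence[tuple[str, GenomicInterval, str]],
    pseudogenes: Sequence[tuple[str, str]] = (),
    repeats: RepeatIndex | Iterable[GenomicInterval] = (),
    track: ConservationTrack | None = None,
    sigma_cutoff: float = 0.0,
    ests: Sequence[tuple[str, str]] = (),
) -> list[FilterVerdict]:
    """Run all filters over ``(peptide_id, interval, coding_dna)`` triples.

    The filters are independent, so their application order cannot change
    the survivor set.  EST matches are recorded as support only.
    """
    index = repeats if isinstance(repeats, RepeatIndex) else RepeatIndex(repeats)
    track = track or ConservationTrack()
    verdicts = []
    for pid, interval, dna in candidates:
        pg_hit, pg_acc = exact_dna_filter(dna, pseudogenes) if pseudogenes else (False, None)
        rep_hits = index.overlapping(interval)
        sigma = conservation_sigma(interval, track)
        est_hit, est_acc = exact_dna_filter(dna, ests) if ests else (False, None)
        verdicts.append(
            FilterVerdict(
                peptide_id=pid,
                pseudogene_pass=not pg_hit,
                repeat_pass=not rep_hits,
                conservation_pass=sigma >= sigma_cutoff,
                pseudogene_evidence=pg_acc,
                repeat_evidence=rep_hits[0] if rep_hits else None,
                sigma=sigma,
                est_support=est_acc,
            )
        )
    return verdicts
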