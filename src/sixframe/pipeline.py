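"""Two-stage target/decoy search orchestration, FDR estimation, orphan
identification and the stage-by-stage funnel report.

Searching a whole-genome six-frame database in one pass is infeasible for
most engines, so the pipeline first pre-screens each chromosome's target
and decoy databases separately, keeping every decoy hit regardless of
confidence, then re-searches all spectra against a single amalgamated
database (reference proteome + all pre-screen target and decoy hit
parents) so that candidate sequences compete directly.  The FDR is
estimated from decoy counts; "orphan" peptides are those identified only
by the six-frame search at high confidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from sixframe.search import PSM, SearchParams, Spectrum, search

DEFAULT_CONFIDENCE = 0.95


@dataclass
class UnitHits:
    """Pre-screen output for one unit (chromosome)."""

    target_hits: list[PSM]
    decoy_hits: list[PSM]
    # every target PSM regardless of confidence, kept so that peptides later
    # explained by a sub-threshold six-frame assignment can be accounted for
    target_hits_anyconf: list[PSM] = field(default_factory=list)


@dataclass
class PrescreenResult:
    units: dict[str, UnitHits]

    @property
    def target_hits(self) -> list[PSM]:
        return [p for u in self.units.values() for p in u.target_hits]

    @property
    def decoy_hits(self) -> list[PSM]:
        return [p for u in self.units.values() for p in u.decoy_hits]

    @property
    def target_hits_anyconf(self) -> list[PSM]:
        return [p for u in self.units.values() for p in u.target_hits_anyconf]

    def target_peptides(self) -> set[str]:
        return {p.peptide.aa_seq for p in self.target_hits}


def prescreen(
    spectra: Sequence[Spectrum],
    unit_dbs: Mapping[str, tuple[Sequence, Sequence]],
    confidence_min: float = DEFAULT_CONFIDENCE,
    params: SearchParams | None = None,
) -> PrescreenResult:
    """Search each unit's concatenated target+decoy database separately.

    Target hits are kept at ``confidence >= confidence_min``; decoy hits
    are kept regardless of confidence so the later amalgamated search can
    still estimate the FDR.  Competition across units is deferred to the
    second search.
    """
    units: dict[str, UnitHits] = {}
    for unit in sorted(unit_dbs):
        targets, decoys = unit_dbs[unit]
        if not targets or not decoys:
            raise ValueError(f"unit {unit!r} is missing a target or decoy database")
        psms = search(spectra, list(targets) + list(decoys), params)
        target_psms = [p for p in psms if not p.is_decoy]
        units[unit] = UnitHits(
            target_hits=[p for p in target_psms if p.confidence >= confidence_min],
            decoy_hits=[p for p in psms if p.is_decoy],
            target_hits_anyconf=target_psms,
        )
    return PrescreenResult(units=units)


def build_amalgamated_db(
    reference_entries: Sequence,
    prescreen_result: PrescreenResult,
    unit_dbs: Mapping[str, tuple[Sequence, Sequence]],
) -> list:
    """Reference proteome plus parent entries of all pre-screen hits.

    De-duplicates by accession; an accession shared between the reference
    and six-frame namespaces is an error (the two databases must not
    collide, or decoy bookkeeping becomes ambiguous).
    """
    entry_by_acc: dict[str, object] = {}
    for unit in sorted(unit_dbs):
        targets, decoys = unit_dbs[unit]
        for e in list(targets) + list(decoys):
            entry_by_acc[e.accession] = e
    hit_accs: set[str] = set()
    for unit in sorted(prescreen_result.units):
        uh = prescreen_result.units[unit]
        for psm in uh.target_hits + uh.decoy_hits:
            hit_accs.add(psm.peptide.parent_accession)
    ref_accs = {e.accession for e in reference_entries}
    collisions = ref_accs & hit_accs
    if collisions:
        raise ValueError(
            f"accession collision between reference and six-frame namespaces: "
            f"{sorted(collisions)[:5]}"
        )
    out = list(reference_entries)
    for acc in sorted(hit_accs):
        if acc not in entry_by_acc:
            raise ValueError(f"pre-screen hit parent {acc!r} not found in unit databases")
        out.append(entry_by_acc[acc])
    return out


def compute_fdr(
    n_target: int, n_decoy: int, method: str = "target"
) -> float:
    """Decoy-based FDR estimate, in percent.

    ``method="target"`` (default): FDR% = 100 * D / T, estimating false
    positives by the decoy count and FP+TP by the accepted target count.
    ``method="concatenated"``: FDR% = 100 * 2D / (T + D).  Capped at 100.
    """
    if n_target < 0 or n_decoy < 0:
        raise ValueError("counts must be non-negative")
    if n_target == 0:
        return 0.0 if n_decoy == 0 else 100.0
    if method == "target":
        fdr = 100.0 * n_decoy / n_target
    elif method == "concatenated":
        fdr = 100.0 * 2 * n_decoy / (n_target + n_decoy)
    else:
        raise ValueError(f"unknown FDR method {method!r}")
    return min(fdr, 100.0)


@dataclass
class OrphanSet:
    """Six-frame-only peptides and the exclusion ledger explaining every
    peptide that was removed or accounted for."""

    orphans: set[str]
    multi_target: set[str]
    low_confidence_reference: set[str]
    reference_unique: set[str]
    junction_explained: set[str]
    lowconf_explained: set[str]
    overlap: set[str]


def identify_orphans(
    sixframe_hits: Sequence[PSM],
    reference_hits: Sequence[PSM],
    reference_all_conf_hits: Sequence[PSM] = (),
    junction_db: Sequence = (),
    confidence_min: float = DEFAULT_CONFIDENCE,
    locus_counts: Mapping[str, int] | None = None,
) -> OrphanSet:
    """Compare six-frame and reference identifications by exact peptide
    sequence.

    Orphans are six-frame peptides at >= ``confidence_min`` with no exact
    sequence match among reference peptides at >= ``confidence_min``, minus
    peptides matching multiple genomic loci and minus peptides that do
    match a reference hit below the threshold.  Reference-unique peptides
    whose sequence occurs in the junction-database translations are
    annotated junction-explained.
    """
    six_conf = {
        p.peptide.aa_seq
        for p in sixframe_hits
        if not p.is_decoy and p.confidence >= confidence_min
    }
    ref_conf = {
        p.peptide.aa_seq
        for p in reference_hits
        if not p.is_decoy and p.confidence >= confidence_min
    }
    ref_any = {p.peptide.aa_seq for p in reference_all_conf_hits if not p.is_decoy}
    overlap = six_conf & ref_conf
    unique = six_conf - ref_conf

    if locus_counts is None:
        locus_counts = {}
        by_pep: dict[str, set[str]] = {}
        for p in sixframe_hits:
            if not p.is_decoy:
                by_pep.setdefault(p.peptide.aa_seq, set()).add(
                    p.peptide.parent_accession
                )
        locus_counts = {pep: len(accs) for pep, accs in by_pep.items()}

    multi = {pep for pep in unique if locus_counts.get(pep, 1) > 1}
    lowconf = {pep for pep in unique - multi if pep in ref_any}
    orphans = unique - multi - lowconf

    reference_unique = ref_conf - six_conf
    junction_explained = set()
    if junction_db:
        from sixframe.sixframe_db import junction_contains

        junction_explained = {
            pep for pep in reference_unique if junction_contains(junction_db, pep)
        }
    six_any = {p.peptide.aa_seq for p in sixframe_hits if not p.is_decoy}
    lowconf_explained = (reference_unique & six_any) - junction_explained
    return OrphanSet(
        orphans=orphans,
        multi_target=multi,
        low_confidence_reference=lowconf,
        reference_unique=reference_unique,
        junction_explained=junction_explained,
        lowconf_explained=lowconf_explained,
        overlap=overlap,
    )


def _truncate2(x: float) -> float:
    return math.floor(x * 100.0) / 100.0


@dataclass
class FunnelReport:
    """Stage-by-stage peptide accounting with derived percentages.

    Input counts are peptide-level; derived quantities follow fixed rounding
    rules: the overlap percentage is rounded to an integer, the adjusted
    correspondence (overlap plus junction-explained plus six-frame
    low-confidence-explained reference peptides) is truncated to two
    decimals.
    """

    reference_total: int
    sixframe_total: int
    overlap: int
    junction_explained: int = 0
    lowconf_explained: int = 0
    multi_target_excluded: int = 0
    reference_lowconf_excluded: int = 0
    class_counts: dict[str, int] = field(default_factory=dict)
    filter_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "reference_total",
            "sixframe_total",
            "overlap",
            "junction_explained",
            "lowconf_explained",
            "multi_target_excluded",
            "reference_lowconf_excluded",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"negative count for {name}")
        for name in ("sixframe_unique", "reference_unique", "post_exclusion"):
            if getattr(self, name) < 0:
                raise ValueError(f"inconsistent stages: negative derived {name}")

    @property
    def sixframe_unique(self) -> int:
        return self.sixframe_total - self.overlap

    @property
    def reference_unique(self) -> int:
        return self.reference_total - self.overlap

    @property
    def post_exclusion(self) -> int:
        return (
            self.sixframe_unique
            - self.multi_target_excluded
            - self.reference_lowconf_excluded
        )

    @property
    def overlap_percent(self) -> int:
        if self.reference_total == 0:
            return 0
        return round(100.0 * self.overlap / self.reference_total)

    @property
    def adjusted_percent(self) -> float:
        if self.reference_total == 0:
            return 0.0
        return _truncate2(
            100.0
            * (self.overlap + self.junction_explained + self.lowconf_explained)
            / self.reference_total
        )

    @property
    def class_total(self) -> int:
        return sum(self.class_counts.values())

    def filter_total(self, filter_name: str) -> int:
        return sum(self.filter_counts.get(filter_name, {}).values())

    def to_text(self) -> str:
        lines = [
            "Stage\tCount",
            f"reference_total\t{self.reference_total}",
            f"sixframe_total\t{self.sixframe_total}",
            f"overlap\t{self.overlap}",
            f"overlap_percent\t{self.overlap_percent}",
            f"reference_unique\t{self.reference_unique}",
            f"junction_explained\t{self.junction_explained}",
            f"lowconf_explained\t{self.lowconf_explained}",
            f"adjusted_percent\t{self.adjusted_percent}",
            f"sixframe_unique\t{self.sixframe_unique}",
            f"multi_target_excluded\t{self.multi_target_excluded}",
            f"reference_lowconf_excluded\t{self.reference_lowconf_excluded}",
            f"post_exclusion\t{self.post_exclusion}",
        ]
        if self.class_counts:
            lines.append("Class\tCount")
            for k in sorted(self.class_counts):
                lines.append(f"{k}\t{self.class_counts[k]}")
            lines.append(f"class_total\t{self.class_total}")
        for fname in sorted(self.filter_counts):
            lines.append(f"Filter {fname}\tCount")
            for k in sorted(self.filter_counts[fname]):
                lines.append(f"{k}\t{self.filter_counts[fname][k]}")
            lines.append(f"{fname}_total\t{self.filter_total(fname)}")
        return "\n".join(lines)


def funnel_report(
    reference_total: int,
    sixframe_total: int,
    overlap: int,
    junction_explained: int = 0,
    lowconf_explained: int = 0,
    multi_target_excluded: int = 0,
    reference_lowconf_excluded: int = 0,
    class_counts: dict[str, int] | None = None,
    filter_counts: dict[str, dict[str, int]] | None = None,
) -> FunnelReport:
    """Assemble the funnel report; raises on any negative derived count."""
    return FunnelReport(
        reference_total=reference_total,
        sixframe_total=sixframe_total,
        overlap=overlap,
        junction_explained=junction_explained,
        lowconf_explained=lowconf_explained,
        multi_target_excluded=multi_target_excluded,
        reference_lowconf_excluded=reference_lowconf_excluded,
        class_counts=class_counts or {},
        filter_counts=filter_counts or {},
    )
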