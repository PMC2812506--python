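"""End-to-end pipeline driver: six-frame databases -> per-chromosome
pre-screen -> amalgamated competitive re-search -> orphan identification ->
genome mapping and classification -> annotation filters -> funnel report,
with optional spectral validation against clean synthetic-peptide spectra.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from sixframe.filters import FilterVerdict, RepeatIndex, apply_filters
from sixframe.mapping import (
    Annotation,
    GenomicInterval,
    classify_locus,
    count_genomic_matches,
    map_peptide_locus,
)
from sixframe.pipeline import (
    OrphanSet,
    PrescreenResult,
    build_amalgamated_db,
    compute_fdr,
    funnel_report,
    identify_orphans,
    prescreen,
)
from sixframe.search import PSM, ProteinEntry, SearchParams, search
from sixframe.simulate import Fixture, spectra_from_peptides
from sixframe.sixframe_db import (
    OrfEntry,
    build_junction_db,
    extract_orf_dna,
    make_decoy,
    translate_six_frame,
)
from sixframe.validation import build_null, common_ion_score, empirical_fdr


def reference_decoys(entries: Sequence[ProteinEntry]) -> list[ProteinEntry]:
    return [
        ProteinEntry(
            accession=f"DECOY_{e.accession}", aa_seq=e.aa_seq[::-1], is_decoy=True
        )
        for e in entries
    ]


@dataclass
class OrphanAnnotation:
    peptide: str
    parent_accession: str
    interval: GenomicInterval
    n_genomic_matches: int
    class_label: str
    dna: str


@dataclass
class PipelineResult:
    prescreen_result: PrescreenResult
    prescreen_fdr: float
    second_psms: list[PSM]
    second_fdr: float
    orphan_set: OrphanSet
    annotations: list[OrphanAnnotation]
    verdicts: list[FilterVerdict]
    funnel: "object"
    validation: dict | None = None

    @property
    def survivors(self) -> list[str]:
        return [v.peptide_id for v in self.verdicts if v.passed]


def run_pipeline(
    fixture: Fixture,
    confidence_min: float = 0.95,
    params: SearchParams | None = None,
    sigma_cutoff: float = 0.0,
    validate: bool = False,
    seed: int = 0,
) -> PipelineResult:
    """Run the whole discovery pipeline on a (synthetic or loaded) dataset."""
    params = params or SearchParams()
    genome = fixture.genome

    # stage 1: per-chromosome six-frame target/decoy databases + pre-screen
    unit_dbs: dict[str, tuple[list[OrfEntry], list[OrfEntry]]] = {}
    entry_by_acc: dict[str, OrfEntry] = {}
    for chrom in sorted(genome):
        targets = translate_six_frame(genome[chrom])
        decoys = make_decoy(targets)
        unit_dbs[chrom] = (targets, decoys)
        for e in targets + decoys:
            entry_by_acc[e.accession] = e
    pre = prescreen(fixture.spectra, unit_dbs, confidence_min, params)
    pre_fdr = compute_fdr(
        len({p.peptide.aa_seq for p in pre.target_hits}),
        len(
            {
                p.peptide.aa_seq
                for p in pre.decoy_hits
                if p.confidence >= confidence_min
            }
        ),
    )

    # reference search (the "known proteome" side of the funnel)
    ref_targets = list(fixture.reference_proteins)
    ref_db = ref_targets + reference_decoys(ref_targets)
    ref_psms = [p for p in search(fixture.spectra, ref_db, params) if not p.is_decoy]

    # stage 2: amalgamated competitive re-search of all spectra
    amal = build_amalgamated_db(ref_db, pre, unit_dbs)
    second = search(fixture.spectra, amal, params)
    acc_t = {
        p.peptide.aa_seq
        for p in second
        if not p.is_decoy and p.confidence >= confidence_min
    }
    acc_d = {
        p.peptide.aa_seq
        for p in second
        if p.is_decoy and p.confidence >= confidence_min
    }
    second_fdr = compute_fdr(len(acc_t), len(acc_d))

    junctions = build_junction_db(fixture.exon_table, genome)

    # the funnel compares the pre-screen six-frame search to the separate
    # reference search; the six-frame side keeps sub-threshold assignments
    # so reference-unique peptides can be explained by low-confidence hits
    six_psms = pre.target_hits_anyconf
    six_conf_peps = {
        p.peptide.aa_seq for p in six_psms if p.confidence >= confidence_min
    }

    # multi-target detection by exact genomic DNA occurrence counting
    pep_info: dict[str, tuple[OrfEntry, int, str, int]] = {}
    for p in six_psms:
        pep = p.peptide.aa_seq
        if pep not in six_conf_peps or pep in pep_info:
            continue
        parent = entry_by_acc[p.peptide.parent_accession]
        offset = p.peptide.offset_aa
        dna = extract_orf_dna(parent, genome)[3 * offset : 3 * (offset + len(pep))]
        pep_info[pep] = (parent, offset, dna, count_genomic_matches(dna, genome))
    locus_counts = {pep: info[3] for pep, info in pep_info.items()}

    orphan_set = identify_orphans(
        six_psms,
        ref_psms,
        reference_all_conf_hits=ref_psms,
        junction_db=junctions,
        confidence_min=confidence_min,
        locus_counts=locus_counts,
    )

    # orphans must survive the amalgamated competitive re-search: the best
    # assignment stays a high-confidence six-frame (non-reference) target
    second_best = {
        p.peptide.aa_seq: p
        for p in second
        if not p.is_decoy and p.confidence >= confidence_min
        and not p.peptide.parent_accession.startswith("REF_")
    }
    post_second = {pep for pep in orphan_set.orphans if pep in second_best}

    # map & classify orphans surviving the second search
    annotation = Annotation(fixture.exon_table)
    annotations: list[OrphanAnnotation] = []
    for pep in sorted(post_second):
        parent, offset, dna, n_matches = pep_info[pep]
        interval = map_peptide_locus(parent, offset, len(pep))
        cls = classify_locus(interval, annotation, n_matches)
        annotations.append(
            OrphanAnnotation(
                peptide=pep,
                parent_accession=parent.accession,
                interval=interval,
                n_genomic_matches=n_matches,
                class_label=cls.label,
                dna=dna,
            )
        )

    # annotation filters
    verdicts = apply_filters(
        [(a.peptide, a.interval, a.dna) for a in annotations],
        pseudogenes=fixture.pseudogenes,
        repeats=RepeatIndex(fixture.repeats),
        track=fixture.conservation,
        sigma_cutoff=sigma_cutoff,
        ests=fixture.ests,
    )

    class_counts: dict[str, int] = {}
    for a in annotations:
        class_counts[a.class_label] = class_counts.get(a.class_label, 0) + 1
    survivor_by_class: dict[str, int] = {}
    by_pep = {a.peptide: a.class_label for a in annotations}
    for v in verdicts:
        if v.passed:
            lbl = by_pep[v.peptide_id]
            survivor_by_class[lbl] = survivor_by_class.get(lbl, 0) + 1

    funnel = funnel_report(
        reference_total=len(orphan_set.overlap) + len(orphan_set.reference_unique),
        sixframe_total=len(six_conf_peps),
        overlap=len(orphan_set.overlap),
        junction_explained=len(orphan_set.junction_explained),
        lowconf_explained=len(orphan_set.lowconf_explained),
        multi_target_excluded=len(orphan_set.multi_target),
        reference_lowconf_excluded=len(orphan_set.low_confidence_reference),
        class_counts=class_counts,
        filter_counts={"all_filters": survivor_by_class},
    )

    validation = None
    if validate:
        validation = validate_candidates(fixture, [v.peptide_id for v in verdicts if v.passed], seed=seed)

    return PipelineResult(
        prescreen_result=pre,
        prescreen_fdr=pre_fdr,
        second_psms=second,
        second_fdr=second_fdr,
        orphan_set=orphan_set,
        annotations=annotations,
        verdicts=verdicts,
        funnel=funnel,
        validation=validation,
    )


def validate_candidates(
    fixture: Fixture,
    candidate_peptides: Sequence[str],
    seed: int = 0,
    target_fdr: float = 5.0,
    n_reps: int | None = None,
    set_size: int = 5,
) -> dict:
    """Common-ion validation of candidates against clean synthetic spectra.

    Synthetic references are noise-free spectra of the candidate sequences;
    real scores compare each candidate's experimental spectrum to its
    synthetic counterpart; the null scores randomly drawn non-candidate
    spectra against all references.
    """
    spec_by_id = {s.spectrum_id: s for s in fixture.spectra}
    planted = {p.aa_seq: p for p in fixture.manifest.peptides if p.spectrum_id}
    candidates = [p for p in candidate_peptides if p in planted]
    if not candidates:
        return {"n_candidates": 0}
    references = spectra_from_peptides(
        [(f"SYN_{planted[p].peptide_id}", p) for p in candidates],
        noise_peaks=0,
        chimera_rate=0.0,
        seed=seed,
        charge=fixture.config.charge,
    )
    real_scores = []
    candidate_spec_ids = set()
    for pep, ref in zip(candidates, references):
        sid = planted[pep].spectrum_id
        candidate_spec_ids.add(sid)
        real_scores.append(common_ion_score(spec_by_id[sid], ref))
    pool = [s for s in fixture.spectra if s.spectrum_id not in candidate_spec_ids]
    if n_reps is None:
        n_reps = max(1, len(pool) // set_size)
    null = build_null(pool, references, n_reps=n_reps, set_size=set_size, seed=seed)
    curve = empirical_fdr(real_scores, null)
    out = {
        "n_candidates": len(candidates),
        "real_scores": real_scores,
        "null_mean": float(null.scores.mean()),
        "null_max": float(null.scores.max()),
        "fdr_at_scores": [curve.fdr_at(s) for s in real_scores],
    }
    try:
        out["threshold_at_target"] = curve.threshold_at(target_fdr)
    except ValueError as exc:
        out["threshold_at_target"] = None
        out["threshold_note"] = str(exc)
    return out
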