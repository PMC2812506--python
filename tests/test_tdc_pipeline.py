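"""Two-stage target/decoy orchestration, FDR arithmetic and the funnel."""

import numpy as np
import pytest

from sixframe.pipeline import (
    build_amalgamated_db,
    compute_fdr,
    funnel_report,
    identify_orphans,
    prescreen,
)
from sixframe.search import PSM, PeptideSpan, ProteinEntry, search
from sixframe.simulate import spectra_from_peptides


def _psm(pep, conf, acc="ACC", decoy=False, sid="s"):
    return PSM(
        spectrum_id=sid,
        peptide=PeptideSpan(pep, acc, 0, 0, "full"),
        shared_peaks=10,
        confidence=conf,
        is_decoy=decoy,
    )


class TestComputeFdr:
    @pytest.mark.parametrize(
        "t,d,expected",
        [(100, 0, 0.0), (40, 2, 5.0), (1000, 250, 25.0), (0, 0, 0.0), (10, 20, 100.0)],
    )
    def test_formula(self, t, d, expected):
        assert compute_fdr(t, d) == expected

    def test_concatenated_variant(self):
        assert compute_fdr(90, 10, method="concatenated") == pytest.approx(20.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_fdr(-1, 0)

    def test_monotone_nonincreasing_in_threshold(self):
        """Raising the confidence threshold never raises the FDR, on any
        fixed PSM set (decoy confidences stochastically below targets)."""
        rng = np.random.default_rng(0)
        psms = [_psm(f"T{i}", c) for i, c in enumerate(rng.beta(5, 1, 400))] + [
            _psm(f"D{i}", c, decoy=True) for i, c in enumerate(rng.beta(1, 3, 120))
        ]
        fdrs = []
        for thr in np.linspace(0, 1, 21):
            t = sum(1 for p in psms if not p.is_decoy and p.confidence >= thr)
            d = sum(1 for p in psms if p.is_decoy and p.confidence >= thr)
            fdrs.append(compute_fdr(t, d))
        assert all(a >= b for a, b in zip(fdrs, fdrs[1:]))


class TestPrescreen:
    def _dbs(self):
        t1 = [ProteinEntry("U1_P", "MAGICPEPTIDEKR")]
        d1 = [ProteinEntry("DECOY_U1_P", "RKEDITPEPCIGAM", is_decoy=True)]
        t2 = [ProteinEntry("U2_P", "WANDERINGPROTEINK")]
        d2 = [ProteinEntry("DECOY_U2_P", "KNIETORPGNIREDNAW", is_decoy=True)]
        return {"u1": (t1, d1), "u2": (t2, d2)}

    def test_planted_truth_appears_in_matching_unit(self):
        specs = spectra_from_peptides([("s1", "MAGICPEPTIDEK")], noise_peaks=0)
        res = prescreen(specs, self._dbs(), confidence_min=0.95)
        assert {p.peptide.aa_seq for p in res.units["u1"].target_hits} == {
            "MAGICPEPTIDEK"
        }
        # competition deferred: the other unit may or may not assign, but
        # nothing is merged across units at this stage
        assert set(res.units) == {"u1", "u2"}

    def test_decoy_only_database_keeps_decoy_pool(self):
        decoy_db = {
            "u": (
                [ProteinEntry("T", "WWWWWWK")],  # far-mass target
                [ProteinEntry("DECOY_X", "EDITPEPCIGAMK", is_decoy=True)],
            )
        }
        specs = spectra_from_peptides([("s1", "EDITPEPCIGAMK")], noise_peaks=0)
        res = prescreen(specs, decoy_db, confidence_min=0.95)
        assert res.units["u"].target_hits == []
        assert len(res.units["u"].decoy_hits) == 1

    def test_decoy_hits_kept_regardless_of_confidence(self):
        decoy_db = {
            "u": (
                [ProteinEntry("T", "WWWWWWK")],
                [ProteinEntry("DECOY_X", "EDITPEPCIGAMK", is_decoy=True)],
            )
        }
        # spectrum of the decoy peptide but with most peaks missing -> low conf
        (full,) = spectra_from_peptides([("s1", "EDITPEPCIGAMK")], noise_peaks=0)
        import numpy as np
        from sixframe.search import Spectrum

        sparse = Spectrum("s1", full.precursor_mz, 2, full.mz[:3], full.intensity[:3])
        res = prescreen([sparse], decoy_db, confidence_min=0.95)
        (hit,) = res.units["u"].decoy_hits
        assert hit.confidence < 0.95

    def test_missing_unit_database_is_error(self):
        with pytest.raises(ValueError, match="u1"):
            prescreen([], {"u1": ([], [ProteinEntry("D", "AK", is_decoy=True)])})


class TestAmalgamatedDb:
    def test_empty_prescreen_returns_reference(self):
        ref = [ProteinEntry("REF_1", "AAAK")]
        res = prescreen(
            spectra_from_peptides([("s", "MAGICPEPTIDEK")], noise_peaks=0),
            {"u": ([ProteinEntry("T", "WWWWWWK")],
                   [ProteinEntry("DECOY_T", "WWWWWWK", is_decoy=True)])},
        )
        assert build_amalgamated_db(ref, res, {"u": ([], [])}) == ref

    def test_cardinality_and_deduplication(self):
        ref = [ProteinEntry("REF_1", "AAAK")]
        t = [ProteinEntry("SF_A", "MAGICPEPTIDEKR")]
        d = [ProteinEntry("DECOY_SF_A", "RKEDITPEPCIGAM", is_decoy=True)]
        dbs = {"u1": (t, d), "u2": (t, d)}  # same entries in both units
        specs = spectra_from_peptides([("s", "MAGICPEPTIDEK")], noise_peaks=0)
        res = prescreen(specs, dbs)
        amal = build_amalgamated_db(ref, res, dbs)
        accs = [e.accession for e in amal]
        assert accs == ["REF_1", "SF_A"]  # duplicate across units collapsed

    def test_reference_collision_is_error(self):
        ref = [ProteinEntry("SF_A", "AAAK")]
        t = [ProteinEntry("SF_A", "MAGICPEPTIDEKR")]
        d = [ProteinEntry("DECOY_SF_A", "RKEDITPEPCIGAM", is_decoy=True)]
        dbs = {"u": (t, d)}
        specs = spectra_from_peptides([("s", "MAGICPEPTIDEK")], noise_peaks=0)
        res = prescreen(specs, dbs)
        with pytest.raises(ValueError, match="collision"):
            build_amalgamated_db(ref, res, dbs)


class TestIdentifyOrphans:
    def test_identical_sets_give_no_orphans(self):
        six = [_psm("PEPTIDEK", 0.99)]
        ref = [_psm("PEPTIDEK", 0.99)]
        o = identify_orphans(six, ref)
        assert o.orphans == set() and o.overlap == {"PEPTIDEK"}

    def test_low_confidence_reference_match_excluded_with_reason(self):
        six = [_psm("PEPTIDEK", 0.99)]
        ref_low = [_psm("PEPTIDEK", 0.90)]
        o = identify_orphans(six, [], reference_all_conf_hits=ref_low)
        assert o.orphans == set()
        assert o.low_confidence_reference == {"PEPTIDEK"}

    def test_multi_target_peptides_excluded(self):
        six = [
            _psm("PEPTIDEK", 0.99, acc="SF_1"),
            _psm("PEPTIDEK", 0.99, acc="SF_2", sid="s2"),
            _psm("LONESOMEK", 0.99, acc="SF_3", sid="s3"),
        ]
        o = identify_orphans(six, [])
        assert o.orphans == {"LONESOMEK"}
        assert o.multi_target == {"PEPTIDEK"}

    def test_planted_mixture_returns_exactly_the_novel_peptides(self):
        shared = [f"SHARED{i}K" for i in range(20)]
        novel = ["NOVELAAK", "NOVELBBK", "NOVELCCK"]
        six = [_psm(p, 0.99, acc=f"SF_{p}") for p in shared + novel]
        ref = [_psm(p, 0.99, acc=f"REF_{p}") for p in shared]
        o = identify_orphans(six, ref, reference_all_conf_hits=ref)
        assert o.orphans == set(novel)

    def test_funnel_additivity_partition(self):
        """Every peptide lands in exactly one terminal bucket."""
        six = [
            _psm("AK", 0.99, acc="SF_1"),  # overlap
            _psm("BK", 0.99, acc="SF_2"),  # orphan
            _psm("CK", 0.99, acc="SF_3"),
            _psm("CK", 0.99, acc="SF_4", sid="s2"),  # multi-target
            _psm("DK", 0.99, acc="SF_5"),  # low-confidence reference
            _psm("EK", 0.50, acc="SF_6"),  # six-frame low-conf -> explains ref-unique
        ]
        ref = [_psm("AK", 0.99), _psm("EK", 0.99), _psm("FK", 0.99)]
        ref_any = ref + [_psm("DK", 0.90)]
        o = identify_orphans(six, ref, reference_all_conf_hits=ref_any)
        six_conf = {"AK", "BK", "CK", "DK"}
        ref_conf = {"AK", "EK", "FK"}
        buckets = [
            o.overlap,
            o.orphans,
            o.multi_target,
            o.low_confidence_reference,
            o.junction_explained,
            o.lowconf_explained,
            o.reference_unique - o.junction_explained - o.lowconf_explained,
        ]
        union = set().union(*buckets)
        assert union == six_conf | ref_conf
        assert sum(len(b) for b in buckets) == len(union)
        assert o.lowconf_explained == {"EK"}


class TestFunnelReport:
    def test_derived_quantities_from_stage_counts(self):
        """Published-scale stage counts reproduce the derived percentages:
        integer-rounded overlap 74%, truncated adjusted 94.54%."""
        r = funnel_report(
            reference_total=6219,
            sixframe_total=8349,
            overlap=4603,
            junction_explained=1110,
            lowconf_explained=167,
            multi_target_excluded=119,
            reference_lowconf_excluded=85,
        )
        assert r.overlap_percent == 74
        assert r.adjusted_percent == 94.54
        assert r.sixframe_unique == 3746
        assert r.reference_unique == 1616
        assert r.post_exclusion == 3542

    def test_class_and_filter_totals(self):
        r = funnel_report(
            reference_total=0,
            sixframe_total=0,
            overlap=0,
            class_counts={
                "intergenic": 279, "intronic": 53,
                "exonic_not_in_frame": 9, "exonic_extending": 5,
            },
            filter_counts={
                "conservation": {
                    "intergenic": 101, "intronic": 15,
                    "exonic_not_in_frame": 3, "exonic_extending": 3,
                }
            },
        )
        assert r.class_total == 346
        assert r.filter_total("conservation") == 122

    def test_all_zero_stages(self):
        r = funnel_report(0, 0, 0)
        assert r.overlap_percent == 0 and r.adjusted_percent == 0.0
        assert r.post_exclusion == 0

    def test_negative_derived_count_is_error(self):
        with pytest.raises(ValueError, match="negative"):
            funnel_report(reference_total=10, sixframe_total=5, overlap=8)

    def test_text_report_contains_stages(self):
        text = funnel_report(10, 8, 6, class_counts={"intergenic": 2}).to_text()
        assert "overlap_percent\t60" in text
        assert "intergenic\t2" in text


class TestDecoyCalibration:
    def test_fdr_estimate_tracks_true_false_match_rate(self):
        """With planted-signal and pure-noise spectra against a target+decoy
        database, the decoy-based FDR estimate agrees with the realized
        false-match fraction within 3 binomial standard errors."""
        from sixframe.simulate import noise_spectra

        rng = np.random.default_rng(21)
        alphabet = np.array(list("ACDEFGHILMNPQSTVWY"))
        planted, db = [], []
        for i in range(60):
            pep = "".join(alphabet[rng.integers(0, len(alphabet), 9)]) + "K"
            planted.append((f"sig{i}", pep))
            db.append(ProteinEntry(f"PL{i:03d}", pep))
        for i in range(240):
            db.append(
                ProteinEntry(
                    f"BG{i:03d}",
                    "".join(alphabet[rng.integers(0, len(alphabet), 40)]) + "K",
                )
            )
        decoys = [
            ProteinEntry(f"DECOY_{e.accession}", e.aa_seq[::-1], is_decoy=True)
            for e in db
        ]
        specs = spectra_from_peptides(planted * 5, noise_peaks=20, seed=3)
        # re-id the repeated spectra uniquely
        for i, s in enumerate(specs):
            s.spectrum_id = f"{s.spectrum_id}_{i}"
        specs += noise_spectra(250, seed=4)
        assert len(specs) >= 500
        truth = {s.spectrum_id: s.spectrum_id.split("_")[0] for s in specs}
        pep_of = dict(planted)
        psms = search(specs, db + decoys)
        for thr in (0.2, 0.5, 0.95):
            acc = [p for p in psms if p.confidence >= thr]
            t = [p for p in acc if not p.is_decoy]
            d = [p for p in acc if p.is_decoy]
            if not t:
                continue
            false_t = sum(
                1
                for p in t
                if pep_of.get(truth[p.spectrum_id]) != p.peptide.aa_seq
            )
            realized = false_t / len(t)
            estimated = compute_fdr(len(t), len(d)) / 100.0
            p_hat = max(realized, estimated, 1.0 / len(t))
            se = (p_hat * (1 - p_hat) / len(t)) ** 0.5
            assert abs(estimated - realized) <= 3 * se + 1e-12, (
                thr, realized, estimated, len(t), len(d)
            )
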