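"""Tryptic digestion, fragment mass generation and the stand-in matcher."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sixframe.search import (
    PROTON,
    WATER,
    ModConfig,
    Spectrum,
    digest,
    match_score,
    peptide_mz,
    peptide_neutral_mass,
    search,
    theoretical_ions,
    unassigned_ids,
)
from sixframe.simulate import spectra_from_peptides
from conftest import brute_force_digest, brute_force_matching, rand_spectrum

NO_MODS = ModConfig.none()

# independent monoisotopic residue masses (Unimod/expasy values, re-typed)
ORACLE_MASS = {"G": 57.02146, "A": 71.03711, "K": 128.09496, "R": 156.10111}


class TestDigest:
    @pytest.mark.parametrize(
        "seq,missed,expected",
        [
            ("AAKAAR", 0, {"AAK", "AAR"}),
            ("AAKPAA", 0, {"AAKPAA"}),  # KP is not a cleavage site
            ("AAKAAR", 1, {"AAK", "AAR", "AAKAAR"}),
        ],
    )
    def test_rule_application(self, seq, missed, expected):
        assert {p.aa_seq for p in digest(seq, missed=missed)} == expected

    @pytest.mark.parametrize("seq", ["AKRKAA", "KAKPKRKA", "RRRR", "PKPRPA"])
    @pytest.mark.parametrize("missed", [0, 1, 2])
    def test_matches_enumeration_oracle(self, seq, missed):
        assert {p.aa_seq for p in digest(seq, missed=missed)} == brute_force_digest(
            seq, missed
        )

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30))
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_full_tryptic_products_tile_the_parent(self, seq):
        spans = [
            p for p in digest(seq, missed=0) if p.missed_cleavages == 0
        ]
        spans.sort(key=lambda p: p.offset_aa)
        assert "".join(p.aa_seq for p in spans) == seq
        for p in spans:
            assert seq[p.offset_aa : p.offset_aa + len(p.aa_seq)] == p.aa_seq

    def test_semi_mode_emits_single_ragged_terminus(self):
        spans = digest("AAKAAR", missed=0, mode="semi")
        semi = {p.aa_seq for p in spans if p.tryptic_status == "semi"}
        assert "AK" in semi and "AA" in semi  # ragged N-term / C-term of AAK
        full = {p.aa_seq for p in spans if p.tryptic_status == "full"}
        assert full == {"AAK", "AAR"}


class TestTheoreticalIons:
    def test_GG_ladder_against_independent_mass_table(self):
        ions = theoretical_ions("GG", NO_MODS)
        b1 = ORACLE_MASS["G"] + 1.00728
        y1 = ORACLE_MASS["G"] + 18.01056 + 1.00728
        assert ions == pytest.approx(sorted([b1, y1]), abs=1e-4)

    @pytest.mark.parametrize("pep", ["GG", "AKGR", "PEPTIDEK"])
    def test_mass_conservation_identity(self, pep):
        """b_i + y_(n-i) = neutral mass + 2 protons, for every cut site."""
        mods = NO_MODS
        masses = [mods.residue_mass(a) for a in pep]
        neutral = peptide_neutral_mass(pep, mods)
        n = len(pep)
        for i in range(1, n):
            b_i = sum(masses[:i]) + PROTON
            y_ni = sum(masses[i:]) + WATER + PROTON
            assert b_i + y_ni == pytest.approx(neutral + 2 * PROTON, abs=1e-4)
            ions = theoretical_ions(pep, mods)
            assert np.isclose(ions, b_i, atol=1e-9).any()
            assert np.isclose(ions, y_ni, atol=1e-9).any()

    def test_fixed_mod_shifts_only_ions_containing_the_residue(self):
        delta = 144.10207
        plain = theoretical_ions("GKGG", NO_MODS)
        modded = theoretical_ions(
            "GKGG", ModConfig(residue_shifts={"K": delta}, nterm_shift=0.0)
        )
        # b ions: b1 (G) unshifted; b2,b3 contain K -> +delta
        # y ions: y1,y2 (GG, GGG... wait y3 contains K) -> y1,y2 unshifted, y3 shifted
        diffs = sorted(np.round(np.sort(modded) - np.sort(plain), 5))
        # after sorting each ladder, exactly 3 of 6 ions shift by delta
        shifted = [d for d in diffs if d > 1]
        assert len(shifted) == 3 and all(
            d == pytest.approx(delta, abs=1e-5) for d in shifted
        )

    def test_unknown_residue_is_error(self):
        with pytest.raises(ValueError, match="unknown amino-acid"):
            theoretical_ions("GXG", NO_MODS)


class TestMatchScore:
    def test_identity_spectrum_matches_all_ions(self):
        ions = theoretical_ions("PEPTIDEK", NO_MODS)
        spec = Spectrum("s", 500.0, 1, ions.copy(), np.ones_like(ions))
        shared, conf = match_score(spec, ions)
        assert shared == len(ions)
        assert conf > 0.99

    def test_empty_spectrum_scores_zero_with_minimal_confidence(self):
        spec = Spectrum("s", 500.0, 1, np.empty(0), np.empty(0))
        ions = theoretical_ions("PEPTIDEK", NO_MODS)
        shared, conf = match_score(spec, ions)
        assert shared == 0 and conf < 0.01

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_bipartite_matching_oracle(self, seed):
        rng = np.random.default_rng(seed)
        spec = rand_spectrum(rng, int(rng.integers(1, 20)))
        ions = rng.uniform(100, 1500, size=int(rng.integers(1, 20)))
        tol = 5.0  # wide tolerance to force matching conflicts
        shared, _ = match_score(spec, ions, tol=tol)
        assert shared == brute_force_matching(ions, spec.mz, tol)

    def test_invariant_to_ion_order_and_intensity_scaling(self):
        rng = np.random.default_rng(9)
        spec = rand_spectrum(rng, 30)
        scaled = Spectrum("s2", spec.precursor_mz, 2, spec.mz, spec.intensity * 1e3)
        ions = rng.uniform(100, 1500, size=15)
        assert match_score(spec, ions) == match_score(spec, ions[::-1])
        assert match_score(spec, ions) == match_score(scaled, ions)

    def test_confidence_monotone_in_shared_fraction(self):
        ions = theoretical_ions("PEPTIDEKR", NO_MODS)
        confs = []
        for k in range(0, len(ions) + 1, 4):
            spec = Spectrum("s", 500.0, 1, ions[:k] if k else np.empty(0),
                            np.ones(k))
            confs.append(match_score(spec, ions)[0:2][1])
        assert confs == sorted(confs)


class TestSearch:
    def _db(self):
        from sixframe.search import ProteinEntry

        return [
            ProteinEntry("P1", "MAGICPEPTIDEKAAAR"),
            ProteinEntry("P2", "WANDERINGPROTEINKR"),
        ]

    def test_planted_truth_recovered_from_noise_free_spectrum(self):
        (spec,) = spectra_from_peptides([("s1", "MAGICPEPTIDEK")], noise_peaks=0)
        psms = search([spec], self._db())
        assert len(psms) == 1
        assert psms[0].peptide.aa_seq == "MAGICPEPTIDEK"
        assert psms[0].peptide.parent_accession == "P1"
        assert psms[0].confidence > 0.95

    def test_duplicate_entries_resolve_deterministically(self):
        from sixframe.search import ProteinEntry

        db = [ProteinEntry("B", "MAGICPEPTIDEKR"), ProteinEntry("A", "MAGICPEPTIDEKR")]
        (spec,) = spectra_from_peptides([("s1", "MAGICPEPTIDEK")], noise_peaks=0)
        psms = search([spec], db)
        assert psms[0].peptide.parent_accession == "A"  # smallest accession wins

    def test_no_candidate_in_mass_window_reports_unassigned(self):
        spec = Spectrum("far", 5000.0, 1, np.array([200.0]), np.array([1.0]))
        psms = search([spec], self._db())
        assert psms == []
        assert unassigned_ids([spec], psms) == ["far"]

    def test_determinism_bit_identical(self):
        rng = np.random.default_rng(2)
        specs = spectra_from_peptides(
            [("s1", "MAGICPEPTIDEK"), ("s2", "WANDERINGPROTEINK")],
            noise_peaks=15,
            seed=4,
        ) + [rand_spectrum(rng, 40, "noise")]
        a = search(specs, self._db())
        b = search(specs, self._db())
        assert a == b

    def test_target_beats_decoy_on_equal_score_only_by_tiebreak(self):
        """A decoy that matches strictly better than any target must win:
        competition is honest, targets get no scoring bonus."""
        from sixframe.search import ProteinEntry

        # same residue multiset as MAGICPEPTIDEK -> identical precursor mass,
        # different ion ladder
        decoy_pep = "EDITPEPCIGAMK"
        db = [
            ProteinEntry("T", "MAGICPEPTIDEKR"),
            ProteinEntry("DECOY_T", decoy_pep, is_decoy=True),
        ]
        (spec,) = spectra_from_peptides([("s", decoy_pep)], noise_peaks=0)
        psms = search([spec], db)
        assert psms[0].is_decoy

    def test_fixture_recovery_small_regression(self):
        """Planted peptides recovered at top rank from a noisy database of
        distractor proteins (small-scale regression of the search stack)."""
        rng = np.random.default_rng(12)
        from sixframe.search import ProteinEntry

        alphabet = np.array(list("ACDEFGHILMNPQSTVWY"))
        planted = []
        db = []
        for i in range(20):
            pep = "".join(alphabet[rng.integers(0, len(alphabet), 9)]) + "K"
            planted.append((f"s{i}", pep))
            db.append(ProteinEntry(f"PL{i:03d}", pep))
        for i in range(200):
            db.append(
                ProteinEntry(
                    f"BG{i:03d}",
                    "".join(alphabet[rng.integers(0, len(alphabet), 30)]) + "K",
                )
            )
        specs = spectra_from_peptides(planted, noise_peaks=20, seed=5)
        psms = {p.spectrum_id: p for p in search(specs, db)}
        truth = dict(planted)
        recovered = sum(
            1 for sid, pep in truth.items()
            if sid in psms and psms[sid].peptide.aa_seq == pep
        )
        assert recovered >= 0.9 * len(planted)


def test_peptide_mz_charge_consistency():
    m1 = peptide_mz("PEPTIDEK", 1, NO_MODS)
    m2 = peptide_mz("PEPTIDEK", 2, NO_MODS)
    assert 2 * (m2 - PROTON) == pytest.approx(m1 - PROTON, abs=1e-9)
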