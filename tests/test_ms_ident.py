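"""Variant database, tryptic digestion, mass arithmetic, ppm matching."""

import itertools

import numpy as np
import pytest
from pyteomics import mass as pyteomics_mass

from readthrough import ms_ident, synth_data
from readthrough.ms_ident import (
    GAP,
    MSConfig,
    PeakList,
    Peptide,
    build_variant_db,
    cleavage_sites,
    digest,
    fragment_ions,
    match,
    mz,
    peptide_mass,
    ppm_error,
    read_mgf,
    spanning_peptides,
    write_mgf,
)
from readthrough.synth_data import MsSpec, SimSpec


class TestVariantDb:
    def test_21_entries_with_gap_last(self):
        db = build_variant_db("AAXGGK")
        assert len(db.variants) == 21
        labels = [lab for lab, _ in db.variants]
        assert labels[-1] == GAP
        assert labels[:-1] == sorted(labels[:-1])
        seqs = dict(db.variants)
        assert seqs["W"] == "AAWGGK"
        assert seqs["R"] == "AARGGK"
        assert seqs[GAP] == "AAGGK"

    def test_tryptophan_variant_equals_sense_codon_control(self):
        db = build_variant_db(synth_data.DEFAULT_MS_BASE_CONSTRUCT)
        control = synth_data.DEFAULT_MS_BASE_CONSTRUCT.replace("X", "W")
        assert db.sequence("W") == control

    def test_variant_lengths_and_single_gap(self):
        base = "AAXGGK"
        db = build_variant_db(base)
        lengths = [len(seq) for _, seq in db.variants]
        assert lengths.count(len(base)) == 20
        assert lengths.count(len(base) - 1) == 1
        for lab, seq in db.variants[:-1]:
            diffs = [i for i, (a, b) in enumerate(zip(seq, base)) if a != b or b == "X"]
            assert diffs == [2]

    def test_marker_count_enforced(self):
        with pytest.raises(ValueError):
            build_variant_db("AAGGK")
        with pytest.raises(ValueError):
            build_variant_db("AXXGGK")


def brute_force_digest(seq, max_missed=1):
    """Independent enumerator of Keil-rule-bounded substrings."""
    sites = [0] + [
        i for i in range(1, len(seq)) if seq[i - 1] in "KR" and seq[i] != "P"
    ] + [len(seq)]
    out = set()
    for i, j in itertools.combinations(range(len(sites)), 2):
        if j - i - 1 <= max_missed:
            out.add((seq[sites[i] : sites[j]], sites[i] + 1, sites[j], j - i - 1))
    return out


class TestDigest:
    def test_keil_rule_example(self):
        peps = digest("AKRP", max_missed=1)
        zero = {(p.sequence, p.missed_cleavages) for p in peps if p.missed_cleavages == 0}
        assert zero == {("AK", 0), ("RP", 0)}
        one = {p.sequence for p in peps if p.missed_cleavages == 1}
        assert one == {"AKRP"}

    def test_no_cut_sites_returns_whole_sequence(self):
        peps = digest("AGSTNQ")
        assert [(p.sequence, p.missed_cleavages) for p in peps] == [("AGSTNQ", 0)]

    def test_zero_missed_peptides_partition_the_sequence(self):
        seq = "MKWVTFISLLLLFSSAYSRGVFRR"
        zero = sorted(
            (p for p in digest(seq) if p.missed_cleavages == 0), key=lambda p: p.start
        )
        assert "".join(p.sequence for p in zero) == seq

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            digest("")

    def test_matches_bruteforce_oracle_on_random_sequences(self):
        rng = np.random.default_rng(2024)
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(500):
            seq = "".join(rng.choice(aas, size=rng.integers(1, 40)))
            got = {
                (p.sequence, p.start, p.end, p.missed_cleavages) for p in digest(seq)
            }
            assert got == brute_force_digest(seq)


class TestMassArithmetic:
    def test_gg_dipeptide_mass(self):
        assert peptide_mass("GG") == pytest.approx(132.05349, abs=1e-4)

    def test_mz_formula(self):
        assert mz(999.0, 2) == pytest.approx(500.507276, abs=1e-6)

    def test_carbamidomethyl_adds_57(self):
        plain = peptide_mass("ACK")
        modded = peptide_mass("ACK", [(2, "carbamidomethyl", ms_ident.MOD_DELTAS["carbamidomethyl"])])
        assert modded - plain == pytest.approx(57.021464, abs=1e-6)

    def test_agrees_with_independent_mass_calculator(self):
        for seq in ("GG", "EVDLNR", "EVDLNWLEAEVAGNSQPTK", "PEPTIDE"):
            assert peptide_mass(seq) == pytest.approx(
                pyteomics_mass.calculate_mass(sequence=seq, monoisotopic=True), abs=2e-3
            )

    def test_mass_additivity(self):
        assert peptide_mass("EVDLNR") + peptide_mass("GG") - ms_ident.WATER == pytest.approx(
            peptide_mass("EVDLNRGG"), abs=1e-9
        )

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError):
            peptide_mass("ABZ")


class TestFragmentIons:
    def test_y1_of_lysine_terminated_peptide(self):
        ions = dict(fragment_ions("ASNVGSSK"))
        assert ions["y1"] == pytest.approx(147.11280, abs=1e-4)

    def test_ion_counts(self):
        seq = "EVDLNR"
        ions = fragment_ions(seq)
        bs = [i for i in ions if i[0].startswith("b")]
        ys = [i for i in ions if i[0].startswith("y")]
        assert len(bs) == len(ys) == len(seq) - 1

    def test_complementarity_identity(self):
        seq = "EVDLNWLEAK"
        ions = dict(fragment_ions(seq))
        total = peptide_mass(seq)
        for i in range(1, len(seq)):
            assert ions[f"b{i}"] + ions[f"y{len(seq) - i}"] == pytest.approx(
                total + 2 * ms_ident.PROTON, abs=1e-9
            )


class TestMatch:
    def test_synthetic_trp_arg_spectra_give_stringent_w_r(self, variant_db):
        spec = SimSpec(seed=5, ms=MsSpec(variant_labels=("W", "R"), ppm_jitter=1.0))
        peaklists, _ = synth_data.gen_peaklists(spec, variant_db)
        stringent, relaxed = match(peaklists, variant_db)
        assert stringent.residues == frozenset({"W", "R"})
        assert stringent.residues <= relaxed.residues

    def test_arg_spanning_peptide_shorter_than_trp(self, variant_db):
        """Arg at the readthrough position creates a new tryptic site."""
        w = min(spanning_peptides(variant_db, "W", 0), key=lambda p: len(p.sequence))
        r = min(spanning_peptides(variant_db, "R", 0), key=lambda p: len(p.sequence))
        assert len(r.sequence) < len(w.sequence)

    def test_offset_precursor_outside_3ppm_not_matched(self, variant_db):
        pep = min(spanning_peptides(variant_db, "W", 0), key=lambda p: len(p.sequence))
        theo = mz(pep.mono_mass, 3)
        off = theo * (1 + 5e-6)  # +5 ppm
        pl = PeakList(id="off", precursor_mz=off, precursor_charge=3)
        stringent, relaxed = match([pl], variant_db)
        assert relaxed.residues == frozenset()

    def test_precursor_only_spectrum_is_relaxed_not_stringent(self, variant_db):
        spec = SimSpec(
            seed=6, ms=MsSpec(variant_labels=("Q",), ppm_jitter=0.5, precursor_only=True, decoy_peaks=0)
        )
        peaklists, _ = synth_data.gen_peaklists(spec, variant_db)
        stringent, relaxed = match(peaklists, variant_db)
        assert "Q" in relaxed.residues
        assert stringent.residues == frozenset()

    def test_leucine_isoleucine_collapse_to_ambiguity_set(self, variant_db):
        spec = SimSpec(seed=8, ms=MsSpec(variant_labels=("L",), ppm_jitter=0.5))
        peaklists, _ = synth_data.gen_peaklists(spec, variant_db)
        stringent, relaxed = match(peaklists, variant_db)
        assert "L/I" in stringent.residues
        assert "L" not in stringent.residues and "I" not in stringent.residues

    def test_spectrum_without_precursor_skipped_with_warning(self, variant_db):
        pl = PeakList(id="nopre", precursor_mz=None, precursor_charge=None)
        with pytest.warns(UserWarning, match="no precursor"):
            stringent, relaxed = match([pl], variant_db)
        assert relaxed.residues == frozenset()

    def test_ppm_error_is_relative_and_signed(self):
        assert ppm_error(1000.001, 1000.0) == pytest.approx(1.0)
        assert ppm_error(999.999, 1000.0) == pytest.approx(-1.0)


def test_mgf_round_trip(tmp_path, variant_db):
    spec = SimSpec(seed=4)
    peaklists, _ = synth_data.gen_peaklists(spec, variant_db)
    path = tmp_path / "spectra.mgf"
    write_mgf(peaklists, path)
    loaded = read_mgf(path)
    assert [pl.id for pl in loaded] == [pl.id for pl in peaklists]
    for a, b in zip(loaded, peaklists):
        assert a.precursor_mz == pytest.approx(b.precursor_mz, abs=1e-5)
        assert a.precursor_charge == b.precursor_charge
        assert len(a.fragments) == len(b.fragments)
    stringent, _ = match(loaded, variant_db)
    assert stringent.residues == frozenset({"W", "R"})
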