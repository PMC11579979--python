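"""Fragment mass chemistry against hand computations and an independent
composition-summation oracle (pyteomics)."""

import random

import pytest
from pyteomics import mass as pyt_mass

from speclibkit import testkit
from speclibkit.masses import (
    CONSTANTS, Peptidoform, ProformaError, UNIMOD_MASSES,
    UnresolvableMassError, annotation_mz, fragment_neutral_mass, mass_error,
    parse_formula, parse_proforma_subset, verify_spectrum,
)
from speclibkit.mzpaf import (
    Immonium, Internal, IonAnnotation, MassError, Named, PeakAnnotationSet,
    Precursor, Series, parse_annotations,
)

PROTON = CONSTANTS.proton


class TestProforma:
    def test_bare_sequence(self):
        p = parse_proforma_subset("PEPTIDE")
        assert p.residues == "PEPTIDE" and not p.residue_mods
        assert p.nterm_mod == p.cterm_mod == 0.0

    def test_bracketed_mass_deltas(self):
        p = parse_proforma_subset("EM[+15.995]EVEES[+79.966]PEK")
        assert p.residues == "EMEVEESPEK"
        assert p.residue_mods == {2: 15.995, 7: 79.966}

    def test_named_nterm_mod_resolves_from_bundled_table(self):
        p = parse_proforma_subset("[iTRAQ4plex]-EMEVEESPEK")
        assert p.nterm_mod == UNIMOD_MASSES["iTRAQ4plex"]

    def test_named_residue_mod_and_charge_suffix(self):
        p = parse_proforma_subset("EM[Oxidation]EVEESPEK/2")
        assert p.residue_mods == {2: UNIMOD_MASSES["Oxidation"]}
        assert p.charge == 2

    @pytest.mark.parametrize("text, kind", [
        ("EM[NoSuchMod]K", "unresolvable-mod"),
        ("EM[+15.995EK", "syntax"),
        ("EM[Oxidation#g1]K", "unsupported"),
        ("PE[Formula:CO]K", "unsupported"),
    ])
    def test_errors_never_drop_mass(self, text, kind):
        with pytest.raises(ProformaError) as exc:
            parse_proforma_subset(text)
        assert exc.value.kind == kind

    def test_agreement_with_reference_parser(self):
        """Cross-check against pyteomics' ProForma implementation."""
        from pyteomics import proforma

        text = "EM[+15.995]EVEES[+79.966]PEK"
        ours = parse_proforma_subset(text)
        theirs = proforma.ProForma.parse(text)
        assert ours.neutral_mass() == pytest.approx(theirs.mass, abs=1e-4)


class TestFragmentMasses:
    """Frozen values computed from the residue+offset hand sums."""

    def test_y1_of_cterm_lysine(self):
        p = parse_proforma_subset("AK")
        neutral = fragment_neutral_mass(p, Series("y", 1))
        assert neutral == pytest.approx(146.10553, abs=2e-5)
        assert annotation_mz(p, IonAnnotation(Series("y", 1))) == pytest.approx(
            147.11280, abs=2e-5
        )

    def test_b2_of_pe(self):
        p = parse_proforma_subset("PEPTIDEK")
        assert annotation_mz(p, IonAnnotation(Series("b", 2))) == pytest.approx(
            227.10263, abs=2e-5
        )

    def test_leucine_immonium(self):
        assert annotation_mz(None, IonAnnotation(Immonium("L"))) == pytest.approx(
            86.09643, abs=2e-5
        )

    def test_single_glycine_precursor(self):
        assert parse_proforma_subset("G").neutral_mass() == pytest.approx(
            75.03203, abs=2e-5
        )

    def test_y2_of_tk_context(self):
        # hand sum: T 101.04768 + K 128.09496 + H2O 18.01056 + proton 1.00728
        p = parse_proforma_subset("QQTK")
        assert annotation_mz(p, IonAnnotation(Series("y", 2))) == pytest.approx(
            248.16048, abs=2e-5
        )

    def test_terminal_mods_attach_to_their_series_only(self):
        p = parse_proforma_subset("[+10.0]-PEPTIDEK-[+5.0]")
        bare = parse_proforma_subset("PEPTIDEK")
        assert fragment_neutral_mass(p, Series("b", 3)) == pytest.approx(
            fragment_neutral_mass(bare, Series("b", 3)) + 10.0, abs=1e-9
        )
        assert fragment_neutral_mass(p, Series("y", 3)) == pytest.approx(
            fragment_neutral_mass(bare, Series("y", 3)) + 5.0, abs=1e-9
        )

    def test_positional_mod_inside_fragment_only(self):
        p = parse_proforma_subset("EM[+15.995]EVK")
        bare = parse_proforma_subset("EMEVK")
        assert fragment_neutral_mass(p, Series("b", 2)) == pytest.approx(
            fragment_neutral_mass(bare, Series("b", 2)) + 15.995, abs=1e-9
        )
        assert fragment_neutral_mass(p, Series("y", 2)) == pytest.approx(
            fragment_neutral_mass(bare, Series("y", 2)), abs=1e-12
        )

    def test_bounds_and_x_residue(self):
        p = parse_proforma_subset("PEPTIDEK")
        with pytest.raises(ValueError):
            fragment_neutral_mass(p, Series("y", 8))
        with pytest.raises(UnresolvableMassError):
            fragment_neutral_mass(parse_proforma_subset("PXK"), Series("b", 2))

    def test_internal_uses_by_chemistry(self):
        p = parse_proforma_subset("PEPTIDEK")
        assert fragment_neutral_mass(p, Internal(2, 4)) == pytest.approx(
            p.span_mass(2, 4), abs=1e-12
        )


class TestAnnotationMz:
    def test_charge_scaling_identity(self):
        p = parse_proforma_subset("PEPTIDEK")
        mz1 = annotation_mz(p, IonAnnotation(Series("y", 3)))
        for k in range(2, 7):
            mzk = annotation_mz(p, IonAnnotation(Series("y", 3), charge=k))
            assert mzk == pytest.approx((mz1 + (k - 1) * PROTON) / k, abs=1e-9)

    def test_isotope_shift(self):
        p = parse_proforma_subset("PEPTIDEK")
        base = annotation_mz(p, IonAnnotation(Series("y", 3), charge=2))
        shifted = annotation_mz(p, IonAnnotation(Series("y", 3), charge=2,
                                                 isotope=2))
        assert shifted - base == pytest.approx(2 * 1.003355 / 2, abs=1e-9)

    def test_sodium_carriers_replace_protons(self):
        p = parse_proforma_subset("PEPTIDEK")
        protonated = annotation_mz(p, IonAnnotation(Series("y", 3), charge=2))
        sodiated = annotation_mz(
            p, IonAnnotation(Series("y", 3), charge=2, adducts=("+Na", "+Na"))
        )
        na, h = parse_formula("Na").mass(), parse_formula("H").mass()
        assert sodiated - protonated == pytest.approx(na - h, abs=1e-6)

    def test_adduct_count_must_match_charge(self):
        p = parse_proforma_subset("PEPTIDEK")
        with pytest.raises(ValueError, match="net count"):
            annotation_mz(p, IonAnnotation(Series("y", 3), charge=2,
                                           adducts=("+Na",)))


class TestSeriesComplementarity:
    """Closed-form series-pair offsets on random tryptic peptides."""

    def test_offset_table(self):
        rng = random.Random(5)
        c = CONSTANTS
        h2 = 2 * c.hydrogen
        for _ in range(100):
            p = Peptidoform(testkit.random_tryptic_peptide(rng))
            L, M = len(p), p.neutral_mass()
            for n in range(1, L):
                b = fragment_neutral_mass(p, Series("b", n))
                y = fragment_neutral_mass(p, Series("y", L - n))
                assert abs(b + y - M) < 1e-9
                a = fragment_neutral_mass(p, Series("a", n))
                x = fragment_neutral_mass(p, Series("x", L - n))
                assert abs(a + x - (M - h2)) < 1e-9
                cc = fragment_neutral_mass(p, Series("c", n))
                z = fragment_neutral_mass(p, Series("z", L - n))
                assert abs(cc + z - (M + c.hydrogen)) < 1e-9

    def test_brute_force_composition_oracle(self):
        """Independent path: sum elemental compositions with pyteomics and
        compare b/y fragment masses to 1e-6 Da."""
        rng = random.Random(6)
        for _ in range(100):
            seq = testkit.random_tryptic_peptide(rng)
            p = Peptidoform(seq)
            n = rng.randint(1, len(seq) - 1)
            b_oracle = pyt_mass.calculate_mass(sequence=seq[:n], ion_type="b",
                                               charge=0)
            y_oracle = pyt_mass.calculate_mass(sequence=seq[-n:], ion_type="y",
                                               charge=0)
            assert fragment_neutral_mass(p, Series("b", n)) == pytest.approx(
                b_oracle, abs=1e-6
            )
            assert fragment_neutral_mass(p, Series("y", n)) == pytest.approx(
                y_oracle, abs=1e-6
            )


class TestMassError:
    def test_zero(self):
        assert mass_error(500.000, 500.000, "ppm") == 0.0

    def test_ppm(self):
        assert mass_error(500.000, 500.005, "ppm") == pytest.approx(-10.0,
                                                                    abs=1e-3)

    def test_mz(self):
        assert mass_error(100.001, 100.000, "mz") == pytest.approx(0.001,
                                                                   abs=1e-12)


class TestVerifySpectrum:
    def _peak(self, p, text, shift=0.0):
        annset = parse_annotations(text)
        mz = annotation_mz(p, annset.annotations[0]) + shift
        return (mz, 100.0, annset)

    def test_self_consistent_peak_passes(self):
        p = parse_proforma_subset("AK")
        issues = verify_spectrum([self._peak(p, "y1/0.0")], {1: p}, tol_ppm=10)
        assert issues == []

    def test_shifted_peak_flagged(self):
        p = parse_proforma_subset("AK")
        issues = verify_spectrum([self._peak(p, "y1", shift=0.5)], {1: p},
                                 tol_ppm=10)
        assert [i.severity for i in issues] == ["error"]

    def test_named_compound_is_warning_only(self):
        p = parse_proforma_subset("AK")
        issues = verify_spectrum([(123.0, 5.0, parse_annotations("0@_{Adenine}"))],
                                 {1: p}, tol_ppm=10)
        assert [i.severity for i in issues] == ["warning"]
        assert "unverifiable" in issues[0].message

    def test_missing_analyte_is_error(self):
        issues = verify_spectrum([(100.0, 1.0, parse_annotations("3@y1"))],
                                 {}, tol_ppm=10)
        assert [i.severity for i in issues] == ["error"]

    def test_context_only_contaminant_is_verifiable(self):
        annset = parse_annotations("0@y2{TK}")
        mz = annotation_mz(None, annset.annotations[0])
        # hand sum: T + K + H2O + proton
        assert mz == pytest.approx(248.16048, abs=2e-5)
        issues = verify_spectrum([(mz, 1.0, annset)], {}, tol_ppm=10)
        assert issues == []
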