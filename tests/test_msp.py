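"""Legacy MSP reading, CV mapping, annotation translation, reverse writing."""

import pytest

from speclibkit import testkit
from speclibkit.model import Analyte, Library, Spectrum
from speclibkit.msp import (
    MspError, convert_annotations, library_from_msp, load_key_mapping,
    map_record, read_msp, tokenize_comment, write_msp,
)
from speclibkit.mzpaf import Series, Unknown, parse_annotations
from speclibkit.serializers import dumps_text

TWO_RECORDS = """\
Name: AAELQK/2
MW: 1316.68
Comment: Spec=Consensus Nreps=27/31 HCD=30eV Parent=659.34 Protein="sp|P12345 Something" Foo=bar
Num peaks: 3
147.11\t100\t"y1/0.002"
218.15\t50\t"b2-NH3/0.001 2/2"
300.12\t10\t"?"

Name: PEPTIDER/3
Comment: Spec=Single CE=25 Polarity=Negative Pep=Tryptic Mods=1(2,P,Oxidation)
Num peaks: 2
100.1\t5\t"IKA"
200.2\t6\t"y1/0.0"
"""


class TestReadMsp:
    def test_two_records_with_peak_counts(self):
        records = read_msp(TWO_RECORDS)
        assert [r.name for r in records] == ["AAELQK/2", "PEPTIDER/3"]
        assert [len(r.peaks) for r in records] == [3, 2]
        assert all(not r.warnings for r in records)

    def test_comment_tokenized_with_quotes(self):
        record = read_msp(TWO_RECORDS)[0]
        pairs = dict(record.comment_pairs)
        assert pairs["Nreps"] == "27/31"
        assert pairs["Spec"] == "Consensus"
        assert pairs["Protein"] == "sp|P12345 Something"

    def test_num_peaks_mismatch_warns(self):
        text = TWO_RECORDS.replace("Num peaks: 3", "Num peaks: 4", 1)
        record = read_msp(text)[0]
        assert any("Num peaks" in w for w in record.warnings)

    def test_record_without_name_is_an_error(self):
        with pytest.raises(MspError, match="line 1"):
            read_msp("MW: 100\n")


class TestTokenizeComment:
    def test_quoted_value_with_spaces_kept_intact(self):
        pairs = tokenize_comment('Spec=Consensus Protein="sp|P1 name with spaces"')
        assert pairs == [("Spec", "Consensus"),
                         ("Protein", "sp|P1 name with spaces")]

    def test_bare_flag_token(self):
        assert tokenize_comment("Tryptic CE=25") == [("Tryptic", ""), ("CE", "25")]


class TestMapRecord:
    def test_nreps_expansion(self):
        spectrum, _ = map_record(read_msp(TWO_RECORDS)[0])
        by_accession = {a.accession: a for a in spectrum.attributes}
        assert by_accession["MS:1003070"].value == 27
        assert by_accession["MS:1003069"].value == 31
        grouped = by_accession["MS:1003254"]
        assert grouped.group_id is not None
        assert grouped.value.accession == "MS:1003279"

    def test_hcd_and_ce_map_to_same_term(self):
        records = read_msp(TWO_RECORDS)
        s1, _ = map_record(records[0])
        s2, _ = map_record(records[1])
        ce1 = [a for a in s1.attributes if a.accession == "MS:1000045"]
        ce2 = [a for a in s2.attributes if a.accession == "MS:1000045"]
        assert ce1[0].value == 30 and ce2[0].value == 25

    def test_precursor_synonym(self):
        spectrum, _ = map_record(read_msp(TWO_RECORDS)[0])
        mz = [a for a in spectrum.attributes if a.accession == "MS:1000744"]
        assert mz[0].value == 659.34

    def test_unknown_key_preserved_with_warning(self):
        spectrum, issues = map_record(read_msp(TWO_RECORDS)[0])
        names = [a.value for a in spectrum.attributes
                 if a.accession == "MS:1003275"]
        assert "Foo" in names
        assert any("Foo" in i.message for i in issues if i.severity == "warning")

    def test_name_synthesizes_analyte_with_charge(self):
        spectrum, _ = map_record(read_msp(TWO_RECORDS)[0])
        analyte = spectrum.analytes[1]
        assert analyte.peptidoform_string() == "AAELQK"
        charge = [a for a in analyte.attributes if a.accession == "MS:1000041"]
        assert charge[0].value == 2

    def test_mods_dialect_produces_proforma(self):
        spectrum, _ = map_record(read_msp(TWO_RECORDS)[1])
        assert spectrum.analytes[1].peptidoform_string() == \
            "PEP[Oxidation]TIDER"

    def test_polarity_value_mapped_to_term(self):
        spectrum, _ = map_record(read_msp(TWO_RECORDS)[1])
        pol = [a for a in spectrum.attributes if a.accession == "MS:1000465"]
        assert pol[0].value.accession == "MS:1000129"


class TestConvertAnnotations:
    def test_shared_syntax_subset_passes_through(self):
        annset, issues = convert_annotations("y7/0.02")
        assert issues == []
        assert annset.annotations[0].ion == Series("y", 7)

    def test_question_mark(self):
        annset, issues = convert_annotations("?")
        assert annset.annotations[0].ion == Unknown() and issues == []

    def test_occurrence_suffix_stripped(self):
        annset, _ = convert_annotations('b2-NH3/0.001 2/2')
        a = annset.annotations[0]
        assert a.ion == Series("b", 2) and a.neutral_deltas[0].payload == "NH3"

    def test_legacy_dialect_preserved_as_unknown(self):
        annset, issues = convert_annotations("IKA")
        a = annset.annotations[0]
        assert a.ion == Unknown()
        assert a.raw_source == "IKA"
        assert issues and "not translatable" in issues[0]


class TestRoundTrip:
    def test_no_data_loss_forward(self):
        records = read_msp(TWO_RECORDS)
        lib, _ = library_from_msp(TWO_RECORDS)
        for record, spectrum in zip(records, lib.spectra):
            assert len(spectrum.peaks) == len(record.peaks)
            mapped_or_preserved = {a.accession for a in spectrum.attributes}
            preserved_names = {a.value for a in spectrum.attributes
                               if a.accession == "MS:1003275"}
            analyte_accessions = {
                a.accession
                for analyte in spectrum.analytes.values()
                for a in analyte.attributes
            }
            for key, _value in list(record.toplevel.items()) + record.comment_pairs:
                known = key in ("Mods", "MW", "Pep", "Foo", "Protein")
                assert (
                    key in preserved_names
                    or known
                    or mapped_or_preserved | analyte_accessions
                )
            # every comment key is accounted for: either mapped to a CV term
            # or preserved verbatim as a name/value pair
            unaccounted = [
                key for key, _ in record.comment_pairs
                if key not in preserved_names and key not in (
                    "Spec", "Nreps", "HCD", "CE", "Parent", "Polarity", "Mods",
                )
            ]
            assert unaccounted == []

    def test_msp_mzspeclib_msp_round_trip(self):
        lib, _ = library_from_msp(TWO_RECORDS)
        back = write_msp(Library(spectra=lib.spectra))
        lib2, _ = library_from_msp(back)
        assert dumps_text(lib) == dumps_text(lib2)

    def test_peak_fidelity(self):
        spec = testkit.FixtureSpec(n_spectra=2, seed=3)
        msp_text = testkit.generate_fixture_msp(spec)
        lib, _ = library_from_msp(msp_text)
        original = testkit.generate_fixture(spec)
        for orig_s, back_s in zip(original.spectra, lib.spectra):
            assert [(p.mz, p.intensity) for p in orig_s.sorted_peaks()] == \
                [(p.mz, p.intensity) for p in back_s.sorted_peaks()]

    def test_collision_energy_written_as_ce(self):
        lib, _ = library_from_msp(TWO_RECORDS)
        text = write_msp(Library(spectra=[lib.spectra[1]]))
        assert "CE=25" in text

    def test_multi_analyte_spectrum_rejected(self):
        spectrum = Spectrum(1, analytes={1: Analyte(1), 2: Analyte(2)})
        with pytest.raises(MspError, match="keys: \\[1\\]"):
            write_msp(Library(spectra=[spectrum]))

    def test_header_attributes_dropped_with_warning(self, fixture_library):
        issues = []
        write_msp(fixture_library, issues=issues)
        assert any("no library header" in i.message for i in issues)
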