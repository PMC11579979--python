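"""Data-model behaviour: attribute-set cascade, validation, merge/subset."""

import pytest

from speclibkit.cv import Attribute, TermValue
from speclibkit.model import (
    Analyte, Cluster, Interpretation, Library, Spectrum, merge_libraries,
    resolve_attributes, subset_library, validate_library,
)
from speclibkit.serializers import dumps_text


def attr(accession, name, value, group=None):
    return Attribute(accession, name, value, group_id=group)


def make_library(**kwargs):
    lib = Library(header_attributes=[
        attr("MS:1003186", "library format version", "1.0"),
        attr("MS:1003188", "library name", "t"),
    ], **kwargs)
    return lib


class TestCascade:
    def test_identity_without_sets(self):
        lib = make_library()
        spectrum = Spectrum(1, attributes=[attr("MS:1000041", "charge state", 2)])
        lib.spectra.append(spectrum)
        assert resolve_attributes(spectrum, lib) == spectrum.attributes

    def test_entity_overrides_all_set(self):
        lib = make_library()
        lib.attribute_sets["Spectrum"] = {
            "all": [attr("MS:1000045", "collision energy", 25)],
        }
        spectrum = Spectrum(1, attributes=[attr("MS:1000045",
                                                "collision energy", 30)])
        lib.spectra.append(spectrum)
        resolved = resolve_attributes(spectrum, lib)
        assert [a.value for a in resolved
                if a.accession == "MS:1000045"] == [30]

    def test_later_named_set_wins(self):
        lib = make_library()
        lib.attribute_sets["Spectrum"] = {
            "A": [attr("MS:1000045", "collision energy", 25)],
            "B": [attr("MS:1000045", "collision energy", 35)],
        }
        spectrum = Spectrum(1, attribute_set_refs=["A", "B"])
        lib.spectra.append(spectrum)
        resolved = resolve_attributes(spectrum, lib)
        assert [a.value for a in resolved] == [35]

    def test_accumulating_terms_do_not_override(self):
        lib = make_library()
        lib.attribute_sets["Spectrum"] = {
            "all": [attr("MS:1001456", "analysis software", "one")],
        }
        spectrum = Spectrum(1, attributes=[attr("MS:1001456",
                                                "analysis software", "two")])
        lib.spectra.append(spectrum)
        values = [a.value for a in resolve_attributes(spectrum, lib)]
        assert values == ["one", "two"]

    def test_groups_replaced_wholesale_and_renumbered(self):
        lib = make_library()
        lib.attribute_sets["Spectrum"] = {
            "all": [
                attr("MS:1003254", "peak attribute",
                     TermValue("MS:1003279", "observation frequency of peak"),
                     group=4),
                attr("MS:1002350", "PSM-level global FDR", 0.01, group=4),
            ],
        }
        spectrum = Spectrum(1, attributes=[
            attr("MS:1002350", "PSM-level global FDR", 0.05),
        ])
        lib.spectra.append(spectrum)
        resolved = resolve_attributes(spectrum, lib)
        # the whole group is displaced by the overriding member
        assert [a.accession for a in resolved] == ["MS:1002350"]

    def test_idempotent(self):
        lib = make_library()
        lib.attribute_sets["Spectrum"] = {
            "all": [attr("MS:1000045", "collision energy", 25)],
        }
        spectrum = Spectrum(1, attributes=[attr("MS:1000041", "charge state", 2)])
        lib.spectra.append(spectrum)
        once = resolve_attributes(spectrum, lib)
        again = Spectrum(1, attributes=once)
        lib2 = make_library()
        lib2.attribute_sets["Spectrum"] = {
            "all": [attr("MS:1000045", "collision energy", 25)],
        }
        lib2.spectra.append(again)
        assert resolve_attributes(again, lib2) == once

    def test_unknown_set_name(self):
        lib = make_library()
        spectrum = Spectrum(1, attribute_set_refs=["missing"])
        lib.spectra.append(spectrum)
        with pytest.raises(KeyError):
            resolve_attributes(spectrum, lib)


class TestValidation:
    def test_generated_fixture_is_clean(self, fixture_library, registry):
        assert validate_library(fixture_library, registry) == []

    def test_duplicate_spectrum_key(self):
        lib = make_library(spectra=[Spectrum(1), Spectrum(1)])
        issues = [i for i in validate_library(lib) if i.severity == "error"]
        assert len(issues) == 1 and "duplicate spectrum key" in issues[0].message

    def test_interpretation_member_must_resolve(self):
        spectrum = Spectrum(1, analytes={1: Analyte(1)})
        spectrum.interpretations[1] = Interpretation(1, members={9: []})
        lib = make_library(spectra=[spectrum])
        issues = [i for i in validate_library(lib) if i.severity == "error"]
        assert len(issues) == 1 and "missing analyte 9" in issues[0].message

    def test_unidentified_spectrum_is_first_class(self):
        lib = make_library(spectra=[Spectrum(1)])
        assert [i for i in validate_library(lib) if i.severity == "error"] == []

    def test_missing_header_attributes_warn(self):
        issues = validate_library(Library())
        assert {i.severity for i in issues} == {"warning"}

    def test_cluster_member_must_resolve(self):
        lib = make_library(
            spectra=[Spectrum(1)],
            clusters=[Cluster(1, [attr("MS:1003267",
                                       "cluster member spectrum keys", "1 7")])],
        )
        issues = [i for i in validate_library(lib) if i.severity == "error"]
        assert len(issues) == 1 and "missing spectrum 7" in issues[0].message

    def test_usi_shaped_members_are_external(self):
        lib = make_library(
            spectra=[Spectrum(1)],
            clusters=[Cluster(1, [attr(
                "MS:1003267", "cluster member spectrum keys",
                "1 mzspec:PXD000001:run1:scan:42",
            )])],
        )
        assert [i for i in validate_library(lib) if i.severity == "error"] == []


class TestMergeSubset:
    def test_merge_with_empty_is_identity(self, fixture_library):
        merged = merge_libraries(fixture_library, Library())
        assert dumps_text(merged) == dumps_text(fixture_library)

    def test_merge_rekeys_collisions(self):
        a = make_library(spectra=[Spectrum(1)])
        b = make_library(spectra=[Spectrum(1)])
        merged = merge_libraries(a, b)
        assert [s.key for s in merged.spectra] == [1, 2]
        assert [i for i in validate_library(merged)
                if i.severity == "error"] == []

    def test_merge_adds_no_errors(self, fixture_library):
        from speclibkit.testkit import FixtureSpec, generate_fixture

        other = generate_fixture(FixtureSpec(n_spectra=3, seed=9))
        for lib in (fixture_library, other):
            assert [i for i in validate_library(lib)
                    if i.severity == "error"] == []
        merged = merge_libraries(fixture_library, other)
        assert [i for i in validate_library(merged)
                if i.severity == "error"] == []

    def test_merge_rewrites_cluster_references(self):
        b = make_library(
            spectra=[Spectrum(1), Spectrum(2)],
            clusters=[Cluster(1, [attr("MS:1003267",
                                       "cluster member spectrum keys", "1 2")])],
        )
        a = make_library(spectra=[Spectrum(1)])
        merged = merge_libraries(a, b)
        internal, _ = merged.clusters[0].member_keys()
        assert internal == [2, 3]

    def test_colliding_attribute_sets_are_inlined(self):
        a = make_library()
        a.attribute_sets["Spectrum"] = {
            "frag": [attr("MS:1000045", "collision energy", 25)],
        }
        a.spectra.append(Spectrum(1, attribute_set_refs=["frag"]))
        b = make_library()
        b.attribute_sets["Spectrum"] = {
            "frag": [attr("MS:1000045", "collision energy", 35)],
        }
        b.spectra.append(Spectrum(1, attribute_set_refs=["frag"]))
        merged = merge_libraries(a, b)
        s2 = merged.spectrum_by_key(2)
        assert s2.attribute_set_refs == []
        assert [a_.value for a_ in s2.attributes] == [35]
        # a's set definition survives untouched
        assert merged.attribute_sets["Spectrum"]["frag"][0].value == 25

    def test_subset_recovers_merged_content(self, fixture_library):
        from speclibkit.testkit import FixtureSpec, generate_fixture

        other = generate_fixture(FixtureSpec(n_spectra=2, seed=13))
        merged = merge_libraries(fixture_library, other)
        n = len(fixture_library.spectra)
        recovered, _ = subset_library(merged, [s.key for s in fixture_library.spectra])
        spectra_text = dumps_text(recovered).split("<Spectrum=", 1)[1]
        original_text = dumps_text(fixture_library).split("<Spectrum=", 1)[1]
        assert spectra_text == original_text

    def test_subset_flags_partially_emptied_cluster(self):
        lib = make_library(
            spectra=[Spectrum(1), Spectrum(2)],
            clusters=[Cluster(1, [attr("MS:1003267",
                                       "cluster member spectrum keys", "1 2")])],
        )
        sub, issues = subset_library(lib, [1])
        assert len(sub.clusters) == 1
        assert [i.severity for i in issues] == ["warning"]

    def test_subset_drops_fully_emptied_cluster(self):
        lib = make_library(
            spectra=[Spectrum(1), Spectrum(2)],
            clusters=[Cluster(1, [attr("MS:1003267",
                                       "cluster member spectrum keys", "2")])],
        )
        sub, issues = subset_library(lib, [1])
        assert sub.clusters == [] and issues == []
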