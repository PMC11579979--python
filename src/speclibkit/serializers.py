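"""Text and JSON serializations of the library model, losslessly
interconvertible.

The text dialect (``.mzlib.txt``) is section-oriented: a ``<mzSpecLib>``
header of library attributes, optional ``<AttributeSet Scope=name>``
declarations, ``<Cluster=key>`` entries, then ``<Spectrum=key>`` entries
whose sub-sections are ``<Analyte=id>``, ``<Interpretation=id>`` (with
nested ``<InterpretationMember=id>``) and ``<Peaks>``, under which each line
is tab-separated ``m/z  intensity  annotation  [aggregation ...]``.

The JSON dialect (``.mzlib.json``) mirrors the same model with explicit
objects and is checked against the bundled schema asset.  Both writers are
canonical — attribute lines carry no padding, floats use shortest
round-trip formatting, peaks are sorted by m/z, sections appear in a fixed
order — so converting a document along any path through {text, json} yields
the same canonical rendering.
"""

from __future__ import annotations

import io
import json
import os
import re
import tempfile
from dataclasses import dataclass
from importlib import resources
from typing import Optional, TextIO, Union

from . import mzpaf
from .cv import (
    Attribute, AttributeSyntaxError, TermValue, format_value,
    parse_attribute_line,
)
from .model import (
    ATTRIBUTE_SET_REF_ACCESSION, Analyte, Cluster, Interpretation, Library,
    Peak, SCOPES, Spectrum, validate_library,
)
from .mzpaf import UNKNOWN_PEAK, PeakAnnotationSet

__all__ = [
    "FormatError", "read_text", "write_text", "dumps_text", "loads_text",
    "read_json", "write_json", "convert", "ConversionReport",
]

HEADER_SECTION = "mzSpecLib"
FORMAT_VERSION = "1.0"


class FormatError(ValueError):
    def __init__(self, message: str, line: Optional[int] = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


# ---------------------------------------------------------------------------
# Text reading

_SECTION_RE = re.compile(r"^<([A-Za-z]+)(?:\s*[= ]\s*(.*?)\s*)?>$")
_ATTRSET_RE = re.compile(r"^(Spectrum|Analyte|Interpretation|Cluster)\s*=\s*(\S+)$")


def _num(token: str, what: str, line_no: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise FormatError(f"non-numeric {what} {token!r}", line_no)


def _parse_peak_line(line: str, line_no: int) -> Peak:
    columns = line.split("\t")
    if len(columns) < 2:
        raise FormatError(
            f"peak line needs at least m/z and intensity columns: {line!r}",
            line_no,
        )
    mz = _num(columns[0].strip(), "peak m/z", line_no)
    intensity = _num(columns[1].strip(), "peak intensity", line_no)
    ann_text = columns[2].strip() if len(columns) > 2 else ""
    if ann_text in ("", "?"):
        annotations = UNKNOWN_PEAK
    else:
        try:
            annotations = mzpaf.parse_annotations(ann_text)
        except mzpaf.AnnotationError as exc:
            raise FormatError(f"bad peak annotation {ann_text!r}: {exc}", line_no)
    aggregations: list[Union[str, float]] = []
    for col in columns[3:]:
        token = col.strip()
        try:
            aggregations.append(float(token))
        except ValueError:
            aggregations.append(token)
    return Peak(mz, intensity, annotations, aggregations,
                raw_columns=tuple(columns))


def read_text(stream: Union[TextIO, str]) -> Library:
    """Parse the text dialect into a :class:`Library`."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lib = Library()
    spectrum: Optional[Spectrum] = None
    analyte: Optional[Analyte] = None
    interp: Optional[Interpretation] = None
    member_id: Optional[int] = None
    attr_target: Optional[list[Attribute]] = None
    in_peaks = False
    saw_header = False

    def route_attribute(attr: Attribute, line_no: int):
        if attr_target is None:
            raise FormatError("attribute line outside any section", line_no)
        if (spectrum is not None and analyte is None and interp is None
                and not in_peaks
                and attr.accession == ATTRIBUTE_SET_REF_ACCESSION):
            spectrum.attribute_set_refs.append(str(attr.value))
            return
        attr_target.append(attr)

    for line_no, raw_line in enumerate(stream, start=1):
        line = raw_line.rstrip("\r\n")
        if not line.strip():
            continue
        if line.startswith("<"):
            m = _SECTION_RE.match(line.strip())
            if not m:
                raise FormatError(f"malformed section header {line!r}", line_no)
            name, arg = m.group(1), m.group(2)
            if not saw_header:
                if name != HEADER_SECTION:
                    raise FormatError(
                        f"file must begin with <{HEADER_SECTION}>, found <{name}>",
                        line_no,
                    )
                saw_header = True
                attr_target = lib.header_attributes
                continue
            if name == HEADER_SECTION:
                raise FormatError("duplicate library header section", line_no)
            if name == "AttributeSet":
                am = _ATTRSET_RE.match(arg or "")
                if not am:
                    raise FormatError(
                        f"malformed attribute-set header {line!r} "
                        "(expected <AttributeSet Scope=name>)", line_no,
                    )
                scope, set_name = am.group(1), am.group(2)
                target: list[Attribute] = []
                lib.attribute_sets.setdefault(scope, {})[set_name] = target
                attr_target = target
                spectrum = analyte = interp = None
                in_peaks = False
                continue
            if name == "Cluster":
                if arg is None or not arg.isdigit():
                    raise FormatError(f"cluster key must be an integer: {line!r}",
                                      line_no)
                cluster = Cluster(int(arg))
                lib.clusters.append(cluster)
                attr_target = cluster.attributes
                spectrum = analyte = interp = None
                in_peaks = False
                continue
            if name == "Spectrum":
                if arg is None or not arg.isdigit():
                    raise FormatError(f"spectrum key must be an integer: {line!r}",
                                      line_no)
                spectrum = Spectrum(int(arg))
                lib.spectra.append(spectrum)
                attr_target = spectrum.attributes
                analyte = interp = None
                in_peaks = False
                continue
            if name not in ("Analyte", "Interpretation", "InterpretationMember",
                            "Peaks"):
                raise FormatError(f"unknown section <{name}>", line_no)
            if spectrum is None:
                raise FormatError(
                    f"<{name}> section outside a <Spectrum> entry", line_no
                )
            if name == "Analyte":
                if arg is None or not arg.isdigit():
                    raise FormatError(f"analyte id must be an integer: {line!r}",
                                      line_no)
                analyte = Analyte(int(arg))
                if analyte.id in spectrum.analytes:
                    raise FormatError(f"duplicate analyte id {analyte.id}", line_no)
                spectrum.analytes[analyte.id] = analyte
                attr_target = analyte.attributes
                interp = None
                in_peaks = False
                continue
            if name == "Interpretation":
                if arg is None or not arg.isdigit():
                    raise FormatError(
                        f"interpretation id must be an integer: {line!r}", line_no
                    )
                interp = Interpretation(int(arg))
                spectrum.interpretations[interp.id] = interp
                attr_target = interp.attributes
                analyte = None
                member_id = None
                in_peaks = False
                continue
            if name == "InterpretationMember":
                if interp is None:
                    raise FormatError(
                        "<InterpretationMember> outside an <Interpretation>",
                        line_no,
                    )
                if arg is None or not arg.isdigit():
                    raise FormatError(f"member id must be an integer: {line!r}",
                                      line_no)
                member_id = int(arg)
                interp.members[member_id] = []
                attr_target = interp.members[member_id]
                continue
            # name == "Peaks" (the only remaining known section)
            in_peaks = True
            attr_target = None
            analyte = interp = None
            continue
        if not saw_header:
            raise FormatError("content before the <mzSpecLib> header", line_no)
        if in_peaks:
            assert spectrum is not None
            spectrum.peaks.append(_parse_peak_line(line, line_no))
            continue
        try:
            route_attribute(parse_attribute_line(line.strip()), line_no)
        except AttributeSyntaxError as exc:
            raise FormatError(str(exc), line_no)
    if not saw_header:
        raise FormatError(f"empty document: no <{HEADER_SECTION}> header")
    for spectrum in lib.spectra:
        mzs = [p.mz for p in spectrum.peaks]
        spectrum.was_sorted = all(a <= b for a, b in zip(mzs, mzs[1:]))
    return lib


def loads_text(text: str) -> Library:
    return read_text(io.StringIO(text))


# ---------------------------------------------------------------------------
# Text writing


def _fmt_float(x: float) -> str:
    return str(int(x)) if x == int(x) and abs(x) < 1e15 else repr(x)


def _canonical_attr_line(attr: Attribute) -> str:
    prefix = f"[{attr.group_id}]" if attr.group_id is not None else ""
    return f"{prefix}{attr.accession}|{attr.name}={format_value(attr.value)}"


def _annotation_text(annotations: PeakAnnotationSet) -> str:
    if annotations == UNKNOWN_PEAK:
        return "?"
    return mzpaf.serialize_annotations(annotations)


def _write_attrs(out: list[str], attrs: list[Attribute]):
    out.extend(_canonical_attr_line(a) for a in attrs)


def write_text(lib: Library, stream: Optional[TextIO] = None) -> Optional[str]:
    """Write the canonical text rendering; refuses when structural
    validation reports errors.  With no stream, returns the text."""
    errors = [i for i in validate_library(lib) if i.severity == "error"]
    if errors:
        raise FormatError(
            "library has validation errors; refusing to write: "
            + "; ".join(str(e) for e in errors[:5])
        )
    out: list[str] = [f"<{HEADER_SECTION}>"]
    header = list(lib.header_attributes)
    if not any(a.accession == "MS:1003186" for a in header):
        header.insert(
            0, Attribute("MS:1003186", "library format version", FORMAT_VERSION)
        )
    _write_attrs(out, header)
    for scope in SCOPES:
        sets = lib.attribute_sets.get(scope, {})
        names = sorted(sets, key=lambda n: (n != "all", n))
        for name in names:
            out.append(f"<AttributeSet {scope}={name}>")
            _write_attrs(out, sets[name])
    for cluster in sorted(lib.clusters, key=lambda c: c.key):
        out.append(f"<Cluster={cluster.key}>")
        _write_attrs(out, cluster.attributes)
    for spectrum in sorted(lib.spectra, key=lambda s: s.key):
        out.append(f"<Spectrum={spectrum.key}>")
        for name in spectrum.attribute_set_refs:
            out.append(
                f"{ATTRIBUTE_SET_REF_ACCESSION}|library attribute set name={name}"
            )
        _write_attrs(out, spectrum.attributes)
        for aid in sorted(spectrum.analytes):
            out.append(f"<Analyte={aid}>")
            _write_attrs(out, spectrum.analytes[aid].attributes)
        for iid in sorted(spectrum.interpretations):
            interp = spectrum.interpretations[iid]
            out.append(f"<Interpretation={iid}>")
            _write_attrs(out, interp.attributes)
            for mid in sorted(interp.members):
                out.append(f"<InterpretationMember={mid}>")
                _write_attrs(out, interp.members[mid])
        out.append("<Peaks>")
        for peak in spectrum.sorted_peaks():
            columns = [
                _fmt_float(peak.mz),
                _fmt_float(peak.intensity),
                _annotation_text(peak.annotations),
            ]
            columns.extend(
                _fmt_float(a) if isinstance(a, float) else str(a)
                for a in peak.aggregations
            )
            out.append("\t".join(columns))
    text = "\n".join(out) + "\n"
    if stream is None:
        return text
    stream.write(text)
    return None


def dumps_text(lib: Library) -> str:
    return write_text(lib)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# JSON serialization


def _attr_to_json(attr: Attribute) -> dict:
    d: dict = {"accession": attr.accession, "name": attr.name}
    if isinstance(attr.value, TermValue):
        d["value"] = attr.value.name
        d["value_accession"] = attr.value.accession
    else:
        d["value"] = attr.value
    if attr.group_id is not None:
        d["group"] = attr.group_id
    return d


def _attr_from_json(d: dict) -> Attribute:
    value: Union[int, float, str, TermValue] = d["value"]
    if "value_accession" in d:
        value = TermValue(d["value_accession"], str(d["value"]))
    return Attribute(d["accession"], d["name"], value, d.get("group"))


def library_to_json(lib: Library) -> dict:
    doc: dict = {
        "format_version": FORMAT_VERSION,
        "attributes": [_attr_to_json(a) for a in lib.header_attributes],
    }
    if lib.attribute_sets:
        doc["attribute_sets"] = {
            scope: {name: [_attr_to_json(a) for a in attrs]
                    for name, attrs in sets.items()}
            for scope, sets in lib.attribute_sets.items()
        }
    if lib.clusters:
        doc["clusters"] = [
            {"key": c.key, "attributes": [_attr_to_json(a) for a in c.attributes]}
            for c in sorted(lib.clusters, key=lambda c: c.key)
        ]
    doc["spectra"] = []
    for spectrum in sorted(lib.spectra, key=lambda s: s.key):
        sd: dict = {
            "key": spectrum.key,
            "attributes": [_attr_to_json(a) for a in spectrum.attributes],
        }
        if spectrum.attribute_set_refs:
            sd["attribute_set_refs"] = list(spectrum.attribute_set_refs)
        if spectrum.analytes:
            sd["analytes"] = [
                {"id": aid,
                 "attributes": [_attr_to_json(a)
                                for a in spectrum.analytes[aid].attributes]}
                for aid in sorted(spectrum.analytes)
            ]
        if spectrum.interpretations:
            sd["interpretations"] = []
            for iid in sorted(spectrum.interpretations):
                interp = spectrum.interpretations[iid]
                sd["interpretations"].append({
                    "id": iid,
                    "attributes": [_attr_to_json(a) for a in interp.attributes],
                    "members": [
                        {"analyte_id": mid,
                         "attributes": [_attr_to_json(a)
                                        for a in interp.members[mid]]}
                        for mid in sorted(interp.members)
                    ],
                })
        sd["peaks"] = [
            {
                "mz": p.mz,
                "intensity": p.intensity,
                "annotations": mzpaf.to_json(p.annotations),
                **({"aggregations": list(p.aggregations)} if p.aggregations else {}),
            }
            for p in spectrum.sorted_peaks()
        ]
        doc["spectra"].append(sd)
    return doc


def library_from_json(doc: dict) -> Library:
    issues = check_schema(doc)
    if issues:
        raise FormatError("JSON document violates the schema: " + "; ".join(issues))
    lib = Library(header_attributes=[_attr_from_json(a) for a in doc["attributes"]])
    for scope, sets in doc.get("attribute_sets", {}).items():
        lib.attribute_sets[scope] = {
            name: [_attr_from_json(a) for a in attrs]
            for name, attrs in sets.items()
        }
    for cd in doc.get("clusters", []):
        lib.clusters.append(
            Cluster(cd["key"], [_attr_from_json(a) for a in cd["attributes"]])
        )
    for sd in doc["spectra"]:
        spectrum = Spectrum(
            sd["key"],
            attributes=[_attr_from_json(a) for a in sd["attributes"]],
            attribute_set_refs=list(sd.get("attribute_set_refs", [])),
        )
        for ad in sd.get("analytes", []):
            spectrum.analytes[ad["id"]] = Analyte(
                ad["id"], [_attr_from_json(a) for a in ad["attributes"]]
            )
        for idoc in sd.get("interpretations", []):
            interp = Interpretation(
                idoc["id"], [_attr_from_json(a) for a in idoc["attributes"]]
            )
            for md in idoc.get("members", []):
                interp.members[md["analyte_id"]] = [
                    _attr_from_json(a) for a in md.get("attributes", [])
                ]
            spectrum.interpretations[interp.id] = interp
        for pd in sd.get("peaks", []):
            spectrum.peaks.append(Peak(
                pd["mz"], pd["intensity"],
                mzpaf.from_json(pd["annotations"]),
                list(pd.get("aggregations", [])),
            ))
        lib.spectra.append(spectrum)
    return lib


def write_json(lib: Library, stream: Optional[TextIO] = None) -> Optional[str]:
    errors = [i for i in validate_library(lib) if i.severity == "error"]
    if errors:
        raise FormatError(
            "library has validation errors; refusing to write: "
            + "; ".join(str(e) for e in errors[:5])
        )
    doc = library_to_json(lib)
    issues = check_schema(doc)
    if issues:  # defensive: the writer should always emit schema-valid JSON
        raise FormatError("emitted JSON violates the schema: " + "; ".join(issues))
    text = json.dumps(doc, indent=2, sort_keys=False) + "\n"
    if stream is None:
        return text
    stream.write(text)
    return None


def read_json(stream: Union[TextIO, str]) -> Library:
    if isinstance(stream, str):
        doc = json.loads(stream)
    else:
        doc = json.load(stream)
    return library_from_json(doc)


# ---------------------------------------------------------------------------
# Minimal JSON-Schema subset checker (type/required/properties/items/
# additionalProperties/enum/$ref into $defs), reporting JSON-pointer paths.

_TYPE_MAP = {
    "object": dict, "array": list, "string": str,
    "integer": int, "boolean": bool,
}


def _load_schema() -> dict:
    text = resources.files("speclibkit.assets").joinpath(
        "mzspeclib-schema.json").read_text("utf-8")
    return json.loads(text)


_SCHEMA = _load_schema()


def _check_node(doc, schema: dict, path: str, issues: list[str], root: dict):
    if "$ref" in schema:
        ref = schema["$ref"]
        assert ref.startswith("#/$defs/")
        schema = root["$defs"][ref.rsplit("/", 1)[1]]
    expected = schema.get("type")
    if expected is not None:
        types = expected if isinstance(expected, list) else [expected]
        ok = False
        for t in types:
            if t == "number":
                ok = ok or (isinstance(doc, (int, float))
                            and not isinstance(doc, bool))
            elif t == "integer":
                ok = ok or (isinstance(doc, int) and not isinstance(doc, bool))
            else:
                ok = ok or isinstance(doc, _TYPE_MAP[t])
        if not ok:
            issues.append(f"{path or '/'}: expected {expected}, "
                          f"got {type(doc).__name__}")
            return
    if "enum" in schema and doc not in schema["enum"]:
        issues.append(f"{path or '/'}: {doc!r} not one of {schema['enum']}")
    if isinstance(doc, dict):
        for key in schema.get("required", []):
            if key not in doc:
                issues.append(f"{path or '/'}: missing required member {key!r}")
        props = schema.get("properties", {})
        extra = schema.get("additionalProperties")
        for key, value in doc.items():
            if key in props:
                _check_node(value, props[key], f"{path}/{key}", issues, root)
            elif isinstance(extra, dict):
                _check_node(value, extra, f"{path}/{key}", issues, root)
    elif isinstance(doc, list) and "items" in schema:
        for i, item in enumerate(doc):
            _check_node(item, schema["items"], f"{path}/{i}", issues, root)


def check_schema(doc: dict) -> list[str]:
    """Validate a library JSON document against the bundled schema; returns
    human-readable issues with JSON-pointer paths (empty when valid)."""
    issues: list[str] = []
    _check_node(doc, _SCHEMA, "", issues, _SCHEMA)
    return issues


# ---------------------------------------------------------------------------
# Conversion driver


@dataclass
class ConversionReport:
    source: str
    target: str
    n_spectra: int = 0
    errors: list[str] = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.errors is None:
            self.errors = []

    @property
    def ok(self) -> bool:
        return not self.errors


_READERS = {"text": read_text, "json": read_json}


def _write_atomic(path: str, text: str):
    directory = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as handle:
            handle.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def convert(
    in_path: str,
    out_path: str,
    source_format: str,
    target_format: str,
) -> ConversionReport:
    """Convert between the text and JSON serializations.

    Output is written atomically (temp file + rename); on a reader error no
    partial output file appears.  The MSP legacy format is handled one level
    up, in the CLI, via :mod:`speclibkit.msp`.
    """
    report = ConversionReport(source_format, target_format)
    try:
        with open(in_path, "r", encoding="utf-8") as handle:
            lib = _READERS[source_format](handle)
        report.n_spectra = len(lib.spectra)
        text = (dumps_text(lib) if target_format == "text"
                else write_json(lib))
        _write_atomic(out_path, text)
    except (FormatError, OSError, KeyError) as exc:
        report.errors.append(f"{in_path}: {exc}")
    return report
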