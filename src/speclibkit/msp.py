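"""Legacy NIST-style MSP libraries: reader, CV mapping, and best-effort
writer.

An MSP record is a ``Name:`` line, a handful of top-level ``Key: value``
lines, a single ``Comment:`` line packing ad hoc ``key=value`` pairs (values
may be double-quoted to protect spaces), a ``Num peaks:`` count, and the
peak lines.  Conversion to the standard model goes through a curated
synonym table (a TSV asset): the many historical spellings of precursor
m/z, scan polarity and collision energy collapse onto single CV terms,
``Nreps=a/b`` expands into used/available replicate counts plus a grouped
peak-attribute declaration, and every unmapped key is preserved as a
name/value attribute pair so the forward conversion loses nothing.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, TextIO, Union

from . import mzpaf
from .cv import (
    Attribute, TermValue, ValidationIssue, _type_value, load_bundled_registry,
)
from .model import Analyte, Interpretation, Library, Peak, Spectrum
from .mzpaf import UNKNOWN_PEAK, IonAnnotation, PeakAnnotationSet, Unknown
from .serializers import _fmt_float

__all__ = [
    "MspRecord", "MspError", "read_msp", "load_key_mapping", "map_record",
    "library_from_msp", "convert_annotations", "write_msp",
]


class MspError(ValueError):
    def __init__(self, message: str, line: Optional[int] = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass
class MspRecord:
    name: str
    toplevel: dict[str, str] = field(default_factory=dict)
    comment_pairs: list[tuple[str, str]] = field(default_factory=list)
    peaks: list[tuple[float, float, str, Optional[str]]] = field(
        default_factory=list
    )
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Reading


def tokenize_comment(comment: str) -> list[tuple[str, str]]:
    """Split a Comment line into key/value pairs, respecting double-quoted
    values that contain spaces; bare tokens become flag pairs (value "")."""
    pairs: list[tuple[str, str]] = []
    pos = 0
    n = len(comment)
    while pos < n:
        while pos < n and comment[pos] == " ":
            pos += 1
        if pos >= n:
            break
        start = pos
        eq = -1
        while pos < n and comment[pos] != " ":
            if comment[pos] == "=" and eq < 0:
                eq = pos
                pos += 1
                if pos < n and comment[pos] == '"':
                    close = comment.find('"', pos + 1)
                    if close < 0:
                        pos = n
                    else:
                        pos = close + 1
                continue
            pos += 1
        token = comment[start:pos]
        if eq < 0:
            pairs.append((token, ""))
        else:
            key = comment[start:eq]
            value = comment[eq + 1:pos]
            if len(value) >= 2 and value[0] == '"' and value[-1] == '"':
                value = value[1:-1]
            pairs.append((key, value))
    return pairs


_PEAK_LINE_RE = re.compile(
    r"^\s*(\S+)\s+(\S+)(?:\s+\"([^\"]*)\"|\s+(\S+))?(?:\s+(.*))?$"
)
_NUM_PEAKS_RE = re.compile(r"^Num\s?[Pp]eaks\s*:\s*(\d+)\s*$")


def read_msp(stream: Union[TextIO, str]) -> list[MspRecord]:
    """Parse an MSP stream into raw records (no CV mapping yet).

    Records are blank-line separated and must start with ``Name:``.  Peak
    annotation strings are captured verbatim, including their quoting.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    records: list[MspRecord] = []
    record: Optional[MspRecord] = None
    expecting_peaks = 0
    in_peaks = False

    def finish():
        nonlocal record, in_peaks, expecting_peaks
        if record is None:
            return
        if expecting_peaks and len(record.peaks) != expecting_peaks:
            record.warnings.append(
                f"Num peaks says {expecting_peaks} but {len(record.peaks)} "
                "peak lines were read"
            )
        records.append(record)
        record, in_peaks, expecting_peaks = None, False, 0

    for line_no, raw in enumerate(stream, start=1):
        line = raw.rstrip("\r\n")
        if not line.strip():
            finish()
            continue
        key, colon, value = line.partition(":")
        if record is None:
            if key.strip() != "Name" or not colon:
                raise MspError(
                    f"record must start with 'Name:', found {line!r}", line_no
                )
            record = MspRecord(name=value.strip())
            continue
        if in_peaks:
            m = _PEAK_LINE_RE.match(line)
            if not m:
                record.warnings.append(f"line {line_no}: unparseable peak line {line!r}")
                continue
            try:
                mz = float(m.group(1))
                intensity = float(m.group(2))
            except ValueError:
                record.warnings.append(
                    f"line {line_no}: non-numeric peak values in {line!r}"
                )
                continue
            annotation = m.group(3) if m.group(3) is not None else (m.group(4) or "")
            extra = m.group(5) or None
            record.peaks.append((mz, intensity, annotation, extra))
            continue
        m = _NUM_PEAKS_RE.match(line)
        if m:
            expecting_peaks = int(m.group(1))
            in_peaks = True
            continue
        if colon and key.strip() and " " not in key.strip():
            if key.strip() == "Comment":
                record.comment_pairs = tokenize_comment(value.strip())
            else:
                record.toplevel[key.strip()] = value.strip()
            continue
        record.warnings.append(f"line {line_no}: unrecognized line {line!r}")
    finish()
    return records


# ---------------------------------------------------------------------------
# Mapping to the standard model


@dataclass(frozen=True)
class KeyMapping:
    msp_key: str
    accession: str
    name: str
    context: str  # spectrum | analyte | interpretation
    transform: str  # identity | number | polarity | aggregation | nreps | charge


def load_key_mapping() -> dict[str, KeyMapping]:
    text = resources.files("speclibkit.assets").joinpath(
        "msp-key-map.tsv").read_text("utf-8")
    mapping: dict[str, KeyMapping] = {}
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        msp_key, accession, name, context, transform = line.split("\t")
        mapping[msp_key] = KeyMapping(msp_key, accession, name, context, transform)
    return mapping


_POLARITY_VALUES = {
    "positive": TermValue("MS:1000130", "positive scan"),
    "pos": TermValue("MS:1000130", "positive scan"),
    "+": TermValue("MS:1000130", "positive scan"),
    "p": TermValue("MS:1000130", "positive scan"),
    "1": TermValue("MS:1000130", "positive scan"),
    "negative": TermValue("MS:1000129", "negative scan"),
    "neg": TermValue("MS:1000129", "negative scan"),
    "-": TermValue("MS:1000129", "negative scan"),
    "n": TermValue("MS:1000129", "negative scan"),
}
_AGGREGATION_VALUES = {
    "consensus": TermValue("MS:1003067", "consensus spectrum"),
    "single": TermValue("MS:1003066", "singleton spectrum"),
    "singleton": TermValue("MS:1003066", "singleton spectrum"),
}
_REGISTRY = load_bundled_registry()
_NUMBER_PREFIX_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)")
_MODS_RE = re.compile(r"^(\d+)\(([^)]*)\)(.*)$")
_CUSTOM_NAME = ("MS:1003275", "other attribute name")
_CUSTOM_VALUE = ("MS:1003276", "other attribute value")


def _numberish(value: str) -> Union[int, float, str]:
    m = _NUMBER_PREFIX_RE.match(value)
    if not m or (m.end() != len(value)
                 and not value[m.end():].strip().lower() in ("ev", "v", "%")):
        return value
    token = m.group(0)
    return int(token) if re.fullmatch(r"[+-]?\d+", token) else float(token)


def _parse_mods_field(value: str, warnings: list[str]) -> Optional[dict[int, str]]:
    """Parse the common ``Mods=n(pos,aa,Name)(pos,aa,Name)...`` and
    ``Mods=n/pos,aa,Name/...`` dialects; returns 1-based position -> name."""
    value = value.strip()
    if value in ("0", ""):
        return {}
    mods: dict[int, str] = {}
    m = _MODS_RE.match(value)
    if m:
        count, rest = int(m.group(1)), value[len(m.group(1)):]
        entries = re.findall(r"\(([^)]*)\)", rest)
    elif "/" in value:
        head, _, rest = value.partition("/")
        if not head.isdigit():
            return None
        count = int(head)
        entries = rest.split("/")
    else:
        return None
    for entry in entries:
        parts = entry.split(",")
        if len(parts) != 3:
            return None
        pos_text, _aa, name = (p.strip() for p in parts)
        if not pos_text.lstrip("-").isdigit():
            return None
        mods[int(pos_text) + 1] = name  # MSP positions are 0-based
    if len(mods) != count:
        warnings.append(
            f"Mods= declares {count} modifications but lists {len(entries)}"
        )
    return mods


def _synthesize_proforma(sequence: str, mods: dict[int, str]) -> str:
    out = []
    nterm = mods.get(0)
    if nterm:
        out.append(f"[{nterm}]-")
    for i, aa in enumerate(sequence, start=1):
        out.append(aa)
        if i in mods:
            out.append(f"[{mods[i]}]")
    return "".join(out)


def map_record(
    rec: MspRecord,
    mapping: Optional[dict[str, KeyMapping]] = None,
    key: int = 1,
) -> tuple[Spectrum, list[ValidationIssue]]:
    """Convert a raw MSP record to a Spectrum with CV attributes.

    Mapped keys become attributes in their declared context; everything
    unmapped is preserved as a grouped name/value pair ("other attribute"),
    never dropped.
    """
    if mapping is None:
        mapping = load_key_mapping()
    issues: list[ValidationIssue] = []
    ctx = f"Spectrum={key}"
    spectrum = Spectrum(key)
    analyte = Analyte(1)
    next_group = [1]

    def custom_pair(attrs: list[Attribute], name: str, value: str):
        gid = next_group[0]
        next_group[0] += 1
        attrs.append(Attribute(*_CUSTOM_NAME, name, group_id=gid))
        attrs.append(Attribute(*_CUSTOM_VALUE, value, group_id=gid))

    def emit(attrs: list[Attribute], km: KeyMapping, value: str):
        if km.transform == "number":
            typed = _numberish(value)
            if isinstance(typed, str):
                issues.append(ValidationIssue(
                    "warning", ctx,
                    f"{km.msp_key}={value!r} is not numeric; preserved verbatim",
                ))
                custom_pair(attrs, km.msp_key, value)
                return
            attrs.append(Attribute(km.accession, km.name, typed))
        elif km.transform == "polarity":
            tv = _POLARITY_VALUES.get(value.strip().lower())
            if tv is None:
                issues.append(ValidationIssue(
                    "warning", ctx, f"unrecognized polarity value {value!r}"
                ))
                custom_pair(attrs, km.msp_key, value)
                return
            attrs.append(Attribute(km.accession, km.name, tv))
        elif km.transform == "aggregation":
            tv = _AGGREGATION_VALUES.get(value.strip().lower())
            if tv is None:
                custom_pair(attrs, km.msp_key, value)
                return
            attrs.append(Attribute(km.accession, km.name, tv))
        elif km.transform == "charge":
            typed = _numberish(value)
            attrs.append(Attribute(km.accession, km.name, typed))
        elif km.transform == "nreps":
            used, slash, available = value.partition("/")
            try:
                attrs.append(Attribute(
                    "MS:1003070", "number of replicate spectra used", int(used)
                ))
                if slash:
                    attrs.append(Attribute(
                        "MS:1003069", "number of replicate spectra available",
                        int(available),
                    ))
            except ValueError:
                issues.append(ValidationIssue(
                    "warning", ctx, f"unparseable Nreps value {value!r}"
                ))
                custom_pair(attrs, km.msp_key, value)
                return
            gid = next_group[0]
            next_group[0] += 1
            attrs.append(Attribute(
                "MS:1003254", "peak attribute",
                TermValue("MS:1003279", "observation frequency of peak"),
                group_id=gid,
            ))
        else:
            attrs.append(Attribute(km.accession, km.name, value))

    # Name: "PEPT/2" conventions carry the peptide and precursor charge.
    spectrum.attributes.append(
        Attribute("MS:1003061", "library spectrum name", rec.name)
    )
    name_seq, slash, name_charge = rec.name.partition("/")
    charge_from_name = name_charge if slash and name_charge.isdigit() else None
    sequence = name_seq if re.fullmatch(r"[A-Z]+", name_seq or "") else None

    mods: Optional[dict[int, str]] = {}
    pending: list[tuple[str, str]] = []
    for k, v in list(rec.toplevel.items()) + list(rec.comment_pairs):
        if k == "Mods":
            mods = _parse_mods_field(v, rec.warnings)
            if mods is None:
                issues.append(ValidationIssue(
                    "warning", ctx,
                    f"unsupported Mods syntax {v!r}; analyte carries the bare sequence",
                ))
                mods = {}
                pending.append((k, v))
            continue
        pending.append((k, v))

    for k, v in pending:
        if k.startswith("MzSpecLib_"):
            rest = k[len("MzSpecLib_"):]
            target = spectrum.attributes
            if rest.startswith("Analyte_"):
                rest = rest[len("Analyte_"):]
                target = analyte.attributes
            accession = rest.replace("_", ":", 1)
            term = _REGISTRY.get(accession)
            target.append(Attribute(
                accession, term.name if term else accession, _type_value(v)
            ))
            continue
        km = mapping.get(k)
        if km is None:
            custom_pair(spectrum.attributes, k, v)
            issues.append(ValidationIssue(
                "warning", ctx, f"unmapped MSP key {k!r} preserved verbatim"
            ))
            continue
        target = analyte.attributes if km.context == "analyte" else spectrum.attributes
        emit(target, km, v)

    if sequence and not any(
        a.accession == "MS:1003169" for a in analyte.attributes
    ):
        proforma = _synthesize_proforma(sequence, mods or {})
        analyte.attributes.insert(0, Attribute(
            "MS:1003169", "proforma peptidoform sequence", proforma
        ))
        analyte.attributes.insert(1, Attribute(
            "MS:1000888", "stripped peptide sequence", sequence
        ))
        if charge_from_name and not any(
            a.accession == "MS:1000041" for a in analyte.attributes
        ):
            analyte.attributes.append(
                Attribute("MS:1000041", "charge state", int(charge_from_name))
            )
    if analyte.attributes:
        spectrum.analytes[1] = analyte
        interp = Interpretation(1)
        interp.members[1] = []
        spectrum.interpretations[1] = interp

    for mz, intensity, raw_annotation, extra in rec.peaks:
        annotations, peak_issues = convert_annotations(raw_annotation)
        for issue in peak_issues:
            issues.append(ValidationIssue("warning", ctx, issue))
        aggregations: list[Union[str, float]] = []
        if extra:
            aggregations.append(extra)
        spectrum.peaks.append(Peak(mz, intensity, annotations, aggregations))
    mzs = [p.mz for p in spectrum.peaks]
    spectrum.was_sorted = all(a <= b for a, b in zip(mzs, mzs[1:]))
    for w in rec.warnings:
        issues.append(ValidationIssue("warning", ctx, w))
    return spectrum, issues


def library_from_msp(
    stream: Union[TextIO, str],
    mapping: Optional[dict[str, KeyMapping]] = None,
) -> tuple[Library, list[ValidationIssue]]:
    """Read MSP and convert every record into a library."""
    if mapping is None:
        mapping = load_key_mapping()
    lib = Library()
    issues: list[ValidationIssue] = []
    for i, rec in enumerate(read_msp(stream), start=1):
        spectrum, record_issues = map_record(rec, mapping, key=i)
        lib.spectra.append(spectrum)
        issues.extend(record_issues)
    lib.header_attributes.append(
        Attribute("MS:1003059", "number of spectra", len(lib.spectra))
    )
    return lib, issues


# ---------------------------------------------------------------------------
# Legacy annotation dialect

_LEGACY_STRIP_RE = re.compile(r"\s+\d+/\d+$")  # trailing occurrence counts


def convert_annotations(raw: str) -> tuple[PeakAnnotationSet, list[str]]:
    """Translate a NIST/SpectraST-style peak annotation into the standard
    grammar where the dialects coincide; anything else becomes an Unknown
    annotation that preserves the raw text (never a fabricated component)."""
    text = raw.strip().strip('"')
    if text in ("", "?"):
        return UNKNOWN_PEAK, []
    issues: list[str] = []
    out: list[IonAnnotation] = []
    for part in text.split(","):
        candidate = _LEGACY_STRIP_RE.sub("", part.strip())
        try:
            parsed = mzpaf.parse_annotations(candidate)
        except mzpaf.AnnotationError:
            out.append(IonAnnotation(Unknown(), raw_source=part.strip()))
            issues.append(
                f"legacy annotation {part.strip()!r} not translatable; "
                "preserved as unknown"
            )
            continue
        out.extend(parsed.annotations)
    return PeakAnnotationSet(tuple(out)), issues


# ---------------------------------------------------------------------------
# Writing

_INVERSE_PREFERRED = {
    "MS:1000744": "PrecursorMZ",
    "MS:1000045": "CE",
    "MS:1003057": "Scan",
    "MS:1003063": "USI",
}
_SKIP_ON_WRITE = {
    "MS:1003061",  # spectrum name -> the Name: line
    "MS:1000888", "MS:1000041",  # encoded in Name/Comment
}


def _mods_from_proforma(proforma: str) -> Optional[list[tuple[int, str, str]]]:
    """Recover ``(0-based position, residue, mod name)`` triples from a
    simple proforma string; None when the string uses constructs (terminal
    mods, numeric deltas) the Mods= dialect cannot carry."""
    mods: list[tuple[int, str, str]] = []
    idx = 0
    prev = ""
    i = 0
    while i < len(proforma):
        ch = proforma[i]
        if ch == "[":
            close = proforma.find("]", i)
            if close < 0 or idx == 0:
                return None
            name = proforma[i + 1:close]
            if re.fullmatch(r"[+-]\d+(\.\d+)?", name):
                return None
            mods.append((idx - 1, prev, name))
            i = close + 1
        elif ch.isupper() and ch.isalpha():
            idx += 1
            prev = ch
            i += 1
        else:
            return None
    return mods


def _msp_value(value) -> str:
    if isinstance(value, TermValue):
        return value.name
    if isinstance(value, float):
        return _fmt_float(value)
    return str(value)


def _quote_if_needed(value: str) -> str:
    return f'"{value}"' if " " in value else value


def write_msp(
    lib: Library,
    stream: Optional[TextIO] = None,
    issues: Optional[list[ValidationIssue]] = None,
) -> Optional[str]:
    """Best-effort reverse conversion to MSP.

    Spectra must carry at most one analyte and one interpretation (MSP has
    no way to express more).  Attributes without an MSP synonym are emitted
    as ``MzSpecLib_<accession>=value`` Comment keys so a re-import loses
    nothing; library-level attributes are dropped with a warning (MSP has
    no header) appended to ``issues`` when a list is passed.
    """
    if issues is not None and lib.header_attributes:
        issues.append(ValidationIssue(
            "warning", "Library",
            f"MSP has no library header; {len(lib.header_attributes)} "
            "library-level attributes dropped",
        ))
    offenders = [
        s.key for s in lib.spectra
        if len(s.analytes) > 1 or len(s.interpretations) > 1
    ]
    if offenders:
        raise MspError(
            "MSP cannot represent multi-analyte/multi-interpretation spectra; "
            f"offending keys: {offenders}"
        )
    out: list[str] = []
    mapping = load_key_mapping()
    inverse: dict[str, str] = {}
    for km in mapping.values():
        preferred = _INVERSE_PREFERRED.get(km.accession)
        inverse.setdefault(km.accession, preferred or km.msp_key)

    for spectrum in sorted(lib.spectra, key=lambda s: s.key):
        name = None
        for attr in spectrum.attributes:
            if attr.accession == "MS:1003061":
                name = str(attr.value)
                break
        analyte = next(iter(spectrum.analytes.values()), None)
        if name is None:
            seq = analyte.peptidoform_string() if analyte else None
            name = seq or f"Spectrum_{spectrum.key}"
        out.append(f"Name: {name}")
        comment_parts: list[str] = []
        pending_nreps: dict[str, str] = {}

        def emit_attr(attr: Attribute, escape_prefix: str = "MzSpecLib_"):
            if attr.accession in _SKIP_ON_WRITE:
                return
            if attr.accession == "MS:1003070":
                pending_nreps["used"] = _msp_value(attr.value)
                pending_nreps.setdefault("index", str(len(comment_parts)))
                return
            if attr.accession == "MS:1003069":
                pending_nreps["available"] = _msp_value(attr.value)
                pending_nreps.setdefault("index", str(len(comment_parts)))
                return
            if attr.accession == "MS:1003254":
                return  # grouped declaration implied by Nreps
            if attr.accession == "MS:1003275":
                emit_attr.pending_name = str(attr.value)  # type: ignore[attr-defined]
                return
            if attr.accession == "MS:1003276":
                key = getattr(emit_attr, "pending_name", None)
                if key is not None:
                    comment_parts.append(
                        f"{key}={_quote_if_needed(str(attr.value))}"
                    )
                    emit_attr.pending_name = None  # type: ignore[attr-defined]
                return
            if attr.accession == "MS:1000465":
                value = attr.value.name if isinstance(attr.value, TermValue) \
                    else str(attr.value)
                comment_parts.append(
                    f"Polarity={_quote_if_needed(value.replace(' scan', ''))}"
                )
                return
            if attr.accession == "MS:1003065":
                value = attr.value
                token = ("Consensus"
                         if isinstance(value, TermValue)
                         and value.accession == "MS:1003067" else "Single")
                comment_parts.append(f"Spec={token}")
                return
            msp_key = inverse.get(attr.accession)
            if msp_key is not None:
                comment_parts.append(
                    f"{msp_key}={_quote_if_needed(_msp_value(attr.value))}"
                )
            else:
                comment_parts.append(
                    f"{escape_prefix}{attr.accession.replace(':', '_')}"
                    f"={_quote_if_needed(_msp_value(attr.value))}"
                )

        for attr in spectrum.attributes:
            emit_attr(attr)
        if analyte is not None:
            for attr in analyte.attributes:
                if attr.accession == "MS:1000041":
                    out.append(f"Charge: {_msp_value(attr.value)}")
                    continue
                if attr.accession == "MS:1003169":
                    proforma = str(attr.value)
                    bare = name.partition("/")[0]
                    if proforma == bare:
                        continue  # fully encoded by the Name: line
                    triples = _mods_from_proforma(proforma)
                    if triples is not None and re.sub(
                        r"\[[^\]]*\]", "", proforma
                    ) == bare:
                        body = "".join(
                            f"({p},{aa},{name_})" for p, aa, name_ in triples
                        )
                        comment_parts.append(f"Mods={len(triples)}{body}")
                        continue
                emit_attr(attr, escape_prefix="MzSpecLib_Analyte_")
        if pending_nreps:
            used = pending_nreps.get("used", "1")
            available = pending_nreps.get("available")
            token = f"Nreps={used}/{available}" if available else f"Nreps={used}"
            comment_parts.insert(int(pending_nreps.get("index", "0")), token)
        if comment_parts:
            out.append("Comment: " + " ".join(comment_parts))
        peaks = spectrum.sorted_peaks()
        out.append(f"Num peaks: {len(peaks)}")
        for peak in peaks:
            if peak.annotations == UNKNOWN_PEAK:
                annotation = "?"
            else:
                annotation = mzpaf.serialize_annotations(peak.annotations)
            out.append(
                f"{_fmt_float(peak.mz)}\t{_fmt_float(peak.intensity)}"
                f"\t\"{annotation}\""
            )
        out.append("")
    text = "\n".join(out)
    if stream is None:
        return text
    stream.write(text)
    return None
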