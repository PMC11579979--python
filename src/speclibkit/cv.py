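"""Controlled-vocabulary attributes — the metadata currency of the library.

Every piece of metadata in the spectral-library model is an *attribute*: a
single statement keyed by a CV term (``accession|name``), optionally grouped
with related statements via a leading ``[n]`` marker, e.g.::

    MS:1002350|PSM-level global FDR=0.01
    [1]MS:1003254|peak attribute=MS:1003279|observation frequency of peak

A small static PSI-MS subset ships as a TSV asset; it is a snapshot meant to
be swapped for a current psi-ms.obo extract, so unknown terms validate as
warnings, never hard errors.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Optional, Union

__all__ = [
    "CvTerm",
    "TermValue",
    "Attribute",
    "ValidationIssue",
    "AttributeSyntaxError",
    "parse_attribute_line",
    "format_attribute",
    "validate_attributes",
    "load_bundled_registry",
]

CURIE_RE = re.compile(r"^[A-Za-z]+:[A-Za-z0-9_]+$")
_NUMBER_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")
_GROUP_RE = re.compile(r"^\[([^\]]*)\]")


class AttributeSyntaxError(ValueError):
    """Raised for a malformed attribute line; ``kind`` names the defect."""

    def __init__(self, message: str, kind: str):
        super().__init__(message)
        self.kind = kind


@dataclass(frozen=True)
class CvTerm:
    accession: str
    name: str
    value_kind: str = "string"  # one of {number, string, term, none}

    def __post_init__(self):
        if not CURIE_RE.match(self.accession):
            raise ValueError(f"invalid CURIE accession: {self.accession!r}")
        if not self.name:
            raise ValueError("CV term name must be non-empty")


@dataclass(frozen=True)
class TermValue:
    """A CURIE-prefixed value, e.g. ``EFO:0005148|Col-0``."""

    accession: str
    name: str


@dataclass
class Attribute:
    accession: str
    name: str
    value: Union[int, float, str, TermValue]
    group_id: Optional[int] = None
    # Original line text; when present, formatting reproduces it byte-for-byte.
    raw: Optional[str] = field(default=None, compare=False, repr=False)

    @property
    def key(self) -> str:
        return f"{self.accession}|{self.name}"

    def without_raw(self) -> "Attribute":
        return replace(self, raw=None)


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" | "warning"
    context: str  # path-like locator, e.g. "Spectrum=3/Analyte=1"
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.severity.upper()} [{self.context}] {self.message}"


def _type_value(text: str) -> Union[int, float, str, TermValue]:
    """Type a raw value token: full-token number, CURIE|name term, else string."""
    if _NUMBER_RE.match(text):
        try:
            return int(text)
        except ValueError:
            return float(text)
    if "|" in text:
        acc, _, name = text.partition("|")
        if CURIE_RE.match(acc):
            return TermValue(acc, name)
    return text


def parse_attribute_line(line: str) -> Attribute:
    """Parse one attribute statement, optionally prefixed by ``[n]``.

    The raw text is retained on the result so re-serialization of an
    unmodified attribute is byte-identical to the input.
    """
    body = line
    group_id = None
    m = _GROUP_RE.match(body)
    if m:
        token = m.group(1)
        if not token.isdigit() or int(token) < 1:
            raise AttributeSyntaxError(
                f"group prefix must be a positive integer, got [{token}]",
                "malformed-group",
            )
        group_id = int(token)
        body = body[m.end():]
    key, eq, value_text = body.partition("=")
    if not eq:
        raise AttributeSyntaxError(
            f"attribute line lacks '=': {line!r}", "malformed-attribute"
        )
    if "|" not in key:
        raise AttributeSyntaxError(
            f"attribute key lacks '|' separator: {key.strip()!r}", "malformed-term"
        )
    accession, _, name = key.strip().partition("|")
    if not CURIE_RE.match(accession):
        raise AttributeSyntaxError(
            f"malformed term accession: {accession!r}", "malformed-term"
        )
    if not name:
        raise AttributeSyntaxError(f"empty term name in {line!r}", "malformed-term")
    value = _type_value(value_text.strip())
    return Attribute(accession, name, value, group_id=group_id, raw=line)


def format_value(value: Union[int, float, str, TermValue]) -> str:
    if isinstance(value, TermValue):
        return f"{value.accession}|{value.name}"
    if isinstance(value, float):
        return repr(value)  # shortest round-trip form
    return str(value)


def format_attribute(attr: Attribute) -> str:
    """Serialize an attribute line.

    Returns the retained raw text when the attribute came from the parser
    unmodified; otherwise the canonical padding-free ``key=value`` form.
    """
    if attr.raw is not None:
        return attr.raw
    prefix = f"[{attr.group_id}]" if attr.group_id is not None else ""
    return f"{prefix}{attr.accession}|{attr.name}={format_value(attr.value)}"


# ---------------------------------------------------------------------------
# Registry + validation


def _read_tsv_asset(filename: str) -> Iterable[list[str]]:
    text = resources.files("speclibkit.assets").joinpath(filename).read_text("utf-8")
    for line in text.splitlines():
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        yield line.split("\t")


def load_bundled_registry() -> dict[str, CvTerm]:
    """Load the bundled PSI-MS subset as an accession -> CvTerm map."""
    registry: dict[str, CvTerm] = {}
    for row in _read_tsv_asset("psi-ms-subset.tsv"):
        accession, name, value_kind = row[0], row[1], row[2]
        if accession in registry:
            raise ValueError(f"duplicate accession in registry: {accession}")
        registry[accession] = CvTerm(accession, name, value_kind)
    return registry


def _value_kind_of(value) -> str:
    if isinstance(value, (int, float)):
        return "number"
    if isinstance(value, TermValue):
        return "term"
    return "string"


def validate_attributes(
    attrs: list[Attribute],
    registry: dict[str, CvTerm],
    context: str = "",
) -> list[ValidationIssue]:
    """Check attributes against a registry.

    Unknown accessions are warnings (the model places no formal restriction
    on which CV terms appear); a name that contradicts the bundled name for
    its accession, or a value whose kind contradicts the term's declared
    kind, is an error.
    """
    issues: list[ValidationIssue] = []
    group_counts: dict[int, int] = {}
    for attr in attrs:
        if attr.group_id is not None:
            group_counts[attr.group_id] = group_counts.get(attr.group_id, 0) + 1
        term = registry.get(attr.accession)
        if term is None:
            issues.append(
                ValidationIssue(
                    "warning", context, f"unknown CV accession {attr.accession}"
                )
            )
            continue
        if term.name != attr.name:
            issues.append(
                ValidationIssue(
                    "error",
                    context,
                    f"{attr.accession} written as {attr.name!r} but registry "
                    f"names it {term.name!r}",
                )
            )
        kind = _value_kind_of(attr.value)
        if term.value_kind == "number" and kind != "number":
            issues.append(
                ValidationIssue(
                    "error",
                    context,
                    f"{attr.key} expects a numeric value, got {attr.value!r}",
                )
            )
        elif term.value_kind == "term" and kind != "term":
            issues.append(
                ValidationIssue(
                    "error",
                    context,
                    f"{attr.key} expects a CV-term value, got {attr.value!r}",
                )
            )
    for gid, count in sorted(group_counts.items()):
        if count < 2:
            issues.append(
                ValidationIssue(
                    "warning",
                    context,
                    f"attribute group [{gid}] has a single member",
                )
            )
    return issues
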