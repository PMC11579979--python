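"""Fragment-ion peak annotations: the mzPAF compact notation.

A peak annotation names the fragment ion thought to produce a peak in a
compact, software-parsable string such as::

    y16-H3PO4^2/0.001
    m2:15+2i[M+2Na]^2/-20ppm
    0@y2{TK}
    b2*0.97

The grammar components, in canonical serialization order, are: analyte
reference (``1@``), the ion body (series ``y16``, internal ``m2:15``,
precursor ``p``, immonium ``IL``, reference ``r[TMT127N]``, formula
``f{C13H9}``, SMILES ``s{CN=C=O}``, named compound ``_{Adenine}``, or
unknown ``?``), an optional sequence context ``{TK}``, neutral gains/losses
(``-H3PO4``, ``+[Hex]``), an isotope token (``+2i``), non-proton charge
carriers (``[M+2Na]``), the charge (``^2``), the mass error relative to the
theoretical m/z (``/0.001`` or ``/-20ppm``, always measured minus computed),
and a confidence in [0, 1] (``*0.97``). Alternative interpretations of one
peak are comma-separated, most likely first; a less-likely duplicate of an
annotation used on a nearby peak is enclosed in square brackets.

This module owns the abstract syntax, a cursor-based state-machine parser
with column-accurate errors, the canonical serializer, and a field-explicit
JSON object-model mapping.  Mass resolution lives in
:mod:`speclibkit.masses`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Union

__all__ = [
    "Series", "Internal", "Precursor", "Immonium", "Reference", "Formula",
    "Smiles", "Named", "Unknown", "IonVariant", "NeutralDelta", "MassError",
    "IonAnnotation", "PeakAnnotationSet", "AnnotationError",
    "UnsupportedFeatureError", "parse_annotations", "serialize_annotations",
    "serialize_annotation", "to_json", "from_json", "mark_ambiguous",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWYUOX")
SERIES_LETTERS = set("abcxyz")


class AnnotationError(ValueError):
    """Syntax or range error in an annotation string; carries the column."""

    def __init__(self, message: str, column: int = 0, kind: str = "syntax"):
        super().__init__(f"{message} (column {column})")
        self.column = column
        self.kind = kind


class UnsupportedFeatureError(AnnotationError):
    def __init__(self, message: str, column: int = 0):
        super().__init__(message, column, kind="unsupported")


# ---------------------------------------------------------------------------
# Abstract syntax


@dataclass(frozen=True)
class Series:
    series: str  # a|b|c|x|y|z
    ordinal: int

    def __post_init__(self):
        if self.series not in SERIES_LETTERS:
            raise ValueError(f"unknown series letter {self.series!r}")
        if self.ordinal < 1:
            raise ValueError("series ordinal must be >= 1")


@dataclass(frozen=True)
class Internal:
    start: int  # 1-based, inclusive, counted from the N terminus
    end: int

    def __post_init__(self):
        if self.start < 1 or self.start >= self.end:
            raise ValueError("internal ion requires 1 <= start < end")


@dataclass(frozen=True)
class Precursor:
    pass


@dataclass(frozen=True)
class Immonium:
    residue: str
    modification: Optional[str] = None

    def __post_init__(self):
        if self.residue not in AMINO_ACIDS:
            raise ValueError(f"invalid immonium residue {self.residue!r}")


@dataclass(frozen=True)
class Reference:
    name: str


@dataclass(frozen=True)
class Formula:
    formula: str


@dataclass(frozen=True)
class Smiles:
    smiles: str


@dataclass(frozen=True)
class Named:
    name: str


@dataclass(frozen=True)
class Unknown:
    label: Optional[int] = None


IonVariant = Union[
    Series, Internal, Precursor, Immonium, Reference, Formula, Smiles, Named,
    Unknown,
]


@dataclass(frozen=True)
class NeutralDelta:
    sign: int  # +1 gain, -1 loss
    payload: str  # molecular formula, or a bracketed species name
    multiplier: int = 1
    bracketed: bool = False  # True for named species like [Hex]

    def __post_init__(self):
        if self.sign not in (1, -1):
            raise ValueError("delta sign must be +-1")
        if self.multiplier < 1:
            raise ValueError("delta multiplier must be >= 1")


@dataclass(frozen=True)
class MassError:
    value: float
    unit: str = "mz"  # "mz" | "ppm"

    def __post_init__(self):
        if self.unit not in ("mz", "ppm"):
            raise ValueError(f"unknown mass-error unit {self.unit!r}")


@dataclass(frozen=True)
class IonAnnotation:
    ion: IonVariant
    analyte_ref: int = 1  # 0 = unspecified contaminant
    is_auxiliary: bool = False
    sequence_context: Optional[str] = None
    neutral_deltas: tuple[NeutralDelta, ...] = ()
    isotope: int = 0
    adducts: Optional[tuple[str, ...]] = None  # signed species, e.g. ("+Na", "+Na")
    charge: int = 1
    mass_error: Optional[MassError] = None
    confidence: Optional[float] = None
    # Legacy-dialect source text (set by the MSP converter); never serialized.
    raw_source: Optional[str] = field(default=None, compare=False)

    def __post_init__(self):
        if self.analyte_ref < 0:
            raise ValueError("analyte reference must be >= 0")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if self.confidence is not None and not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")


@dataclass(frozen=True)
class PeakAnnotationSet:
    annotations: tuple[IonAnnotation, ...] = ()

    def __iter__(self):
        return iter(self.annotations)

    def __len__(self):
        return len(self.annotations)

    @property
    def is_unknown_only(self) -> bool:
        return all(isinstance(a.ion, Unknown) for a in self.annotations)


UNKNOWN_PEAK = PeakAnnotationSet((IonAnnotation(Unknown()),))


# ---------------------------------------------------------------------------
# Parser

_FORMULA_TOKEN_RE = re.compile(r"[A-Za-z][a-z]?\d*")


class _Cursor:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def peek(self, offset: int = 0) -> str:
        i = self.pos + offset
        return self.text[i] if i < len(self.text) else ""

    def take(self) -> str:
        ch = self.peek()
        self.pos += 1
        return ch

    def eat(self, ch: str) -> bool:
        if self.peek() == ch:
            self.pos += 1
            return True
        return False

    def expect(self, ch: str, what: str):
        if not self.eat(ch):
            self.fail(f"expected {ch!r} {what}")

    def digits(self) -> str:
        start = self.pos
        while self.peek().isdigit():
            self.pos += 1
        return self.text[start:self.pos]

    def number(self, what: str) -> float:
        start = self.pos
        self.eat("+") or self.eat("-")
        self.digits()
        if self.eat("."):
            self.digits()
        if self.peek() in "eE":
            self.pos += 1
            self.eat("+") or self.eat("-")
            self.digits()
        token = self.text[start:self.pos]
        try:
            return float(token)
        except ValueError:
            self.fail(f"expected a number for {what}", start)

    def until(self, closer: str, what: str) -> str:
        start = self.pos
        depth = 0
        while self.pos < len(self.text):
            ch = self.text[self.pos]
            if ch == closer and depth == 0:
                return self.text[start:self.pos]
            self.pos += 1
        self.fail(f"unterminated {what} (missing {closer!r})", start)

    def fail(self, message: str, column: Optional[int] = None):
        raise AnnotationError(message, self.pos if column is None else column)


_DELIMS = set(",]")


def _at_boundary(cur: _Cursor) -> bool:
    return cur.peek() == "" or cur.peek() in _DELIMS


def _parse_ion(cur: _Cursor) -> IonVariant:
    ch = cur.peek()
    col = cur.pos
    if ch == "?":
        cur.take()
        label = cur.digits()
        return Unknown(int(label)) if label else Unknown()
    if ch in SERIES_LETTERS:
        cur.take()
        ordinal = cur.digits()
        if not ordinal:
            cur.fail(f"series ion {ch!r} requires an ordinal")
        if int(ordinal) < 1:
            cur.fail(f"series ordinal must be >= 1, got {ordinal}", col)
        return Series(ch, int(ordinal))
    if ch == "p":
        cur.take()
        return Precursor()
    if ch == "I":
        cur.take()
        residue = cur.take()
        if residue not in AMINO_ACIDS:
            cur.fail(f"invalid immonium residue {residue!r}", col + 1)
        mod = None
        # "[M+...]" after an immonium ion is an adduct list, not a modification
        if cur.peek() == "[" and not (
            cur.peek(1) == "M" and cur.peek(2) in "+-"
        ):
            cur.take()
            mod = cur.until("]", "immonium modification")
            cur.take()
        return Immonium(residue, mod)
    if ch == "r":
        cur.take()
        cur.expect("[", "to open a reference-ion name")
        name = cur.until("]", "reference-ion name")
        cur.take()
        if not name:
            cur.fail("empty reference-ion name", col)
        return Reference(name)
    if ch == "f":
        cur.take()
        cur.expect("{", "to open a formula")
        formula = cur.until("}", "formula")
        cur.take()
        if not formula:
            cur.fail("empty formula", col)
        return Formula(formula)
    if ch == "s":
        cur.take()
        cur.expect("{", "to open a SMILES string")
        smiles = cur.until("}", "SMILES string")
        cur.take()
        if not smiles:
            cur.fail("empty SMILES string", col)
        return Smiles(smiles)
    if ch == "_":
        cur.take()
        cur.expect("{", "to open a compound name")
        name = cur.until("}", "compound name")
        cur.take()
        if not name:
            cur.fail("empty compound name", col)
        return Named(name)
    cur.fail(f"unknown ion type prefix {ch!r}" if ch else "empty annotation")


def _parse_internal(cur: _Cursor) -> Internal:
    col = cur.pos
    cur.take()  # 'm'
    start = cur.digits()
    if not start:
        cur.fail("internal ion requires start position")
    cur.expect(":", "between internal-ion positions")
    end = cur.digits()
    if not end:
        cur.fail("internal ion requires end position")
    s, e = int(start), int(end)
    if s >= e:
        raise AnnotationError(
            f"internal ion positions must satisfy start < end, got {s}:{e}",
            col, kind="bounds",
        )
    if s < 1:
        raise AnnotationError("internal ion positions are 1-based", col, "bounds")
    return Internal(s, e)


def _parse_delta_or_isotope(cur: _Cursor):
    """After a +/- sign: an isotope token (``2i``), or a neutral-delta payload."""
    sign = 1 if cur.take() == "+" else -1
    col = cur.pos
    mult = cur.digits()
    if cur.peek() == "i" and not cur.peek(1).isalnum():
        cur.take()
        return ("isotope", sign * (int(mult) if mult else 1))
    if cur.peek() == "i" and cur.peek(1).isalnum():
        raise UnsupportedFeatureError(
            "element-specific isotope labels are reserved", col
        )
    if cur.peek() == "[":
        cur.take()
        name = cur.until("]", "named neutral species")
        cur.take()
        if not name:
            cur.fail("empty named neutral species", col)
        return ("delta", NeutralDelta(sign, name, int(mult) if mult else 1, True))
    start = cur.pos
    while cur.peek().isalnum():
        cur.pos += 1
    payload = cur.text[start:cur.pos]
    if not payload:
        cur.fail("dangling delta sign", col - 1)
    if not _FORMULA_TOKEN_RE.match(payload):
        cur.fail(f"malformed neutral-delta formula {payload!r}", start)
    return ("delta", NeutralDelta(sign, payload, int(mult) if mult else 1, False))


def _parse_adducts(cur: _Cursor) -> tuple[str, ...]:
    col = cur.pos
    cur.take()  # '['
    cur.expect("M", "at the start of an adduct expression")
    carriers: list[str] = []
    while not cur.eat("]"):
        if cur.peek() == "":
            cur.fail("unterminated adduct expression", col)
        sign = cur.peek()
        if sign not in "+-":
            cur.fail(f"expected '+' or '-' in adduct list, got {sign!r}")
        cur.take()
        count = cur.digits()
        start = cur.pos
        while cur.peek().isalnum():
            cur.pos += 1
        species = cur.text[start:cur.pos]
        if not species:
            cur.fail("empty adduct species", start)
        carriers.extend([f"{sign}{species}"] * (int(count) if count else 1))
    if not carriers:
        cur.fail("adduct expression lists no charge carriers", col)
    return tuple(carriers)


def _parse_single(cur: _Cursor, is_auxiliary: bool) -> IonAnnotation:
    # analyte reference: digits followed by '@'
    analyte_ref = 1
    save = cur.pos
    ref = cur.digits()
    if ref and cur.eat("@"):
        analyte_ref = int(ref)
    else:
        cur.pos = save

    if cur.peek() == "m" and cur.peek(1).isdigit():
        ion: IonVariant = _parse_internal(cur)
    else:
        ion = _parse_ion(cur)

    sequence_context = None
    if cur.peek() == "{" and isinstance(ion, (Series, Unknown, Precursor)):
        col = cur.pos
        cur.take()
        sequence_context = cur.until("}", "sequence context")
        cur.take()
        bad = [c for c in sequence_context if c not in AMINO_ACIDS]
        if bad:
            cur.fail(f"invalid residue {bad[0]!r} in sequence context", col)

    deltas: list[NeutralDelta] = []
    isotope = 0
    adducts: Optional[tuple[str, ...]] = None
    saw_isotope = False
    while True:
        ch = cur.peek()
        if ch and ch in "+-":
            kind, payload = _parse_delta_or_isotope(cur)
            if kind == "isotope":
                if saw_isotope:
                    cur.fail("multiple isotope tokens")
                isotope = payload
                saw_isotope = True
            else:
                deltas.append(payload)
        elif ch == "[" and cur.peek(1) == "M" and adducts is None:
            adducts = _parse_adducts(cur)
        else:
            break

    charge = 1
    if cur.eat("^"):
        z = cur.digits()
        if not z:
            cur.fail("dangling '^' (expected a charge)")
        charge = int(z)
        if charge < 1:
            cur.fail("charge must be >= 1")

    mass_error = None
    if cur.eat("/"):
        if _at_boundary(cur):
            cur.fail("dangling '/' (expected a mass error)")
        value = cur.number("mass error")
        unit = "mz"
        if cur.peek() == "p" and cur.text[cur.pos:cur.pos + 3] == "ppm":
            cur.pos += 3
            unit = "ppm"
        mass_error = MassError(value, unit)

    confidence = None
    if cur.eat("*"):
        col = cur.pos
        confidence = cur.number("confidence")
        if not 0.0 <= confidence <= 1.0:
            raise AnnotationError(
                f"confidence {confidence} outside [0, 1]", col, kind="range"
            )

    if not _at_boundary(cur):
        cur.fail(f"unexpected trailing character {cur.peek()!r}")
    return IonAnnotation(
        ion=ion,
        analyte_ref=analyte_ref,
        is_auxiliary=is_auxiliary,
        sequence_context=sequence_context,
        neutral_deltas=tuple(deltas),
        isotope=isotope,
        adducts=adducts,
        charge=charge,
        mass_error=mass_error,
        confidence=confidence,
    )


def parse_annotations(s: str) -> PeakAnnotationSet:
    """Parse a full (possibly comma-separated, possibly bracketed) annotation
    string into an ordered :class:`PeakAnnotationSet`."""
    if not s:
        raise AnnotationError("empty annotation string", 0)
    cur = _Cursor(s)
    annotations: list[IonAnnotation] = []
    while True:
        if cur.eat("["):
            # ambiguity bracket: one or more auxiliary annotations
            while True:
                annotations.append(_parse_single(cur, is_auxiliary=True))
                if cur.eat("]"):
                    break
                cur.expect(",", "between bracketed annotations")
        else:
            annotations.append(_parse_single(cur, is_auxiliary=False))
        if cur.peek() == "":
            break
        cur.expect(",", "between annotations")
        if cur.peek() == "":
            cur.fail("dangling ',' at end of annotation list")
    return PeakAnnotationSet(tuple(annotations))


# ---------------------------------------------------------------------------
# Serializer


def _format_number(x: float) -> str:
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(x)


def _serialize_ion(ion: IonVariant) -> str:
    if isinstance(ion, Series):
        return f"{ion.series}{ion.ordinal}"
    if isinstance(ion, Internal):
        return f"m{ion.start}:{ion.end}"
    if isinstance(ion, Precursor):
        return "p"
    if isinstance(ion, Immonium):
        mod = f"[{ion.modification}]" if ion.modification else ""
        return f"I{ion.residue}{mod}"
    if isinstance(ion, Reference):
        return f"r[{ion.name}]"
    if isinstance(ion, Formula):
        return f"f{{{ion.formula}}}"
    if isinstance(ion, Smiles):
        return f"s{{{ion.smiles}}}"
    if isinstance(ion, Named):
        return f"_{{{ion.name}}}"
    if isinstance(ion, Unknown):
        return f"?{ion.label}" if ion.label is not None else "?"
    raise TypeError(f"not an ion variant: {ion!r}")


def _serialize_adducts(adducts: tuple[str, ...]) -> str:
    parts = []
    i = 0
    while i < len(adducts):
        j = i
        while j < len(adducts) and adducts[j] == adducts[i]:
            j += 1
        sign, species = adducts[i][0], adducts[i][1:]
        count = j - i
        parts.append(f"{sign}{count if count > 1 else ''}{species}")
        i = j
    return f"[M{''.join(parts)}]"


def serialize_annotation(a: IonAnnotation, check_resolvable: bool = False) -> str:
    """Serialize one annotation in canonical component order, eliding the
    defaults (analyte 1, isotope 0, charge 1)."""
    if check_resolvable and isinstance(a.ion, Formula):
        from .masses import parse_formula  # local import: avoid module cycle

        parse_formula(a.ion.formula)  # raises on an unresolvable payload
    parts = []
    if a.analyte_ref != 1:
        parts.append(f"{a.analyte_ref}@")
    parts.append(_serialize_ion(a.ion))
    if a.sequence_context is not None:
        parts.append(f"{{{a.sequence_context}}}")
    for d in a.neutral_deltas:
        sign = "+" if d.sign > 0 else "-"
        mult = str(d.multiplier) if d.multiplier > 1 else ""
        payload = f"[{d.payload}]" if d.bracketed else d.payload
        parts.append(f"{sign}{mult}{payload}")
    if a.isotope:
        sign = "+" if a.isotope > 0 else "-"
        mag = abs(a.isotope)
        parts.append(f"{sign}{mag if mag > 1 else ''}i")
    if a.adducts:
        parts.append(_serialize_adducts(a.adducts))
    if a.charge != 1:
        parts.append(f"^{a.charge}")
    if a.mass_error is not None:
        suffix = "ppm" if a.mass_error.unit == "ppm" else ""
        parts.append(f"/{_format_number(a.mass_error.value)}{suffix}")
    if a.confidence is not None:
        parts.append(f"*{_format_number(a.confidence)}")
    body = "".join(parts)
    return f"[{body}]" if a.is_auxiliary else body


def serialize_annotations(annset: PeakAnnotationSet) -> str:
    if not annset.annotations:
        raise ValueError("cannot serialize an empty annotation set")
    return ",".join(serialize_annotation(a, check_resolvable=True)
                    for a in annset.annotations)


# ---------------------------------------------------------------------------
# JSON object model

_ION_TYPE_NAMES = {
    Series: "series", Internal: "internal", Precursor: "precursor",
    Immonium: "immonium", Reference: "reference", Formula: "formula",
    Smiles: "smiles", Named: "named", Unknown: "unknown",
}


class JsonModelError(ValueError):
    """JSON object-model violation; the message names the offending path."""


def _ion_to_json(ion: IonVariant) -> dict:
    d: dict = {"ion_type": _ION_TYPE_NAMES[type(ion)]}
    if isinstance(ion, Series):
        d.update(series=ion.series, ordinal=ion.ordinal)
    elif isinstance(ion, Internal):
        d.update(start_position=ion.start, end_position=ion.end)
    elif isinstance(ion, Immonium):
        d["residue"] = ion.residue
        if ion.modification:
            d["modification"] = ion.modification
    elif isinstance(ion, Reference):
        d["name"] = ion.name
    elif isinstance(ion, Formula):
        d["formula"] = ion.formula
    elif isinstance(ion, Smiles):
        d["smiles"] = ion.smiles
    elif isinstance(ion, Named):
        d["name"] = ion.name
    elif isinstance(ion, Unknown) and ion.label is not None:
        d["label"] = ion.label
    return d


def _annotation_to_json(a: IonAnnotation) -> dict:
    d = _ion_to_json(a.ion)
    d["analyte_reference"] = a.analyte_ref
    d["charge"] = a.charge
    if a.is_auxiliary:
        d["auxiliary"] = True
    if a.sequence_context is not None:
        d["sequence_context"] = a.sequence_context
    if a.neutral_deltas:
        d["neutral_deltas"] = [
            {"sign": nd.sign, "payload": nd.payload,
             "multiplier": nd.multiplier, "named": nd.bracketed}
            for nd in a.neutral_deltas
        ]
    if a.isotope:
        d["isotope"] = a.isotope
    if a.adducts:
        d["adducts"] = list(a.adducts)
    if a.mass_error is not None:
        d["mass_error"] = {"value": a.mass_error.value, "unit": a.mass_error.unit}
    if a.confidence is not None:
        d["confidence"] = a.confidence
    return d


def to_json(annset: PeakAnnotationSet) -> list[dict]:
    """Map to the explicit-field JSON object model (a list of objects, most
    likely interpretation first)."""
    return [_annotation_to_json(a) for a in annset.annotations]


def _require(obj: dict, key: str, types, path: str):
    if key not in obj:
        raise JsonModelError(f"missing required field at {path}.{key}")
    if not isinstance(obj[key], types):
        raise JsonModelError(
            f"field {path}.{key} has wrong type {type(obj[key]).__name__}"
        )
    return obj[key]


def _ion_from_json(d: dict, path: str) -> IonVariant:
    ion_type = _require(d, "ion_type", str, path)
    try:
        if ion_type == "series":
            return Series(_require(d, "series", str, path),
                          _require(d, "ordinal", int, path))
        if ion_type == "internal":
            return Internal(_require(d, "start_position", int, path),
                            _require(d, "end_position", int, path))
        if ion_type == "precursor":
            return Precursor()
        if ion_type == "immonium":
            return Immonium(_require(d, "residue", str, path),
                            d.get("modification"))
        if ion_type == "reference":
            return Reference(_require(d, "name", str, path))
        if ion_type == "formula":
            return Formula(_require(d, "formula", str, path))
        if ion_type == "smiles":
            return Smiles(_require(d, "smiles", str, path))
        if ion_type == "named":
            return Named(_require(d, "name", str, path))
        if ion_type == "unknown":
            return Unknown(d.get("label"))
    except ValueError as exc:
        raise JsonModelError(f"invalid ion at {path}: {exc}") from exc
    raise JsonModelError(f"unknown ion_type {ion_type!r} at {path}.ion_type")


def from_json(objs: Iterable[dict]) -> PeakAnnotationSet:
    annotations = []
    for i, d in enumerate(objs):
        path = f"annotations[{i}]"
        if not isinstance(d, dict):
            raise JsonModelError(f"{path} is not an object")
        ion = _ion_from_json(d, path)
        deltas = []
        for j, nd in enumerate(d.get("neutral_deltas", [])):
            ndp = f"{path}.neutral_deltas[{j}]"
            deltas.append(NeutralDelta(
                _require(nd, "sign", int, ndp),
                _require(nd, "payload", str, ndp),
                nd.get("multiplier", 1),
                nd.get("named", False),
            ))
        me = d.get("mass_error")
        mass_error = None
        if me is not None:
            mep = f"{path}.mass_error"
            mass_error = MassError(
                float(_require(me, "value", (int, float), mep)),
                _require(me, "unit", str, mep),
            )
        try:
            annotations.append(IonAnnotation(
                ion=ion,
                analyte_ref=d.get("analyte_reference", 1),
                is_auxiliary=bool(d.get("auxiliary", False)),
                sequence_context=d.get("sequence_context"),
                neutral_deltas=tuple(deltas),
                isotope=d.get("isotope", 0),
                adducts=tuple(d["adducts"]) if d.get("adducts") else None,
                charge=d.get("charge", 1),
                mass_error=mass_error,
                confidence=d.get("confidence"),
            ))
        except ValueError as exc:
            raise JsonModelError(f"invalid annotation at {path}: {exc}") from exc
    return PeakAnnotationSet(tuple(annotations))


def mark_ambiguous(
    annset: PeakAnnotationSet,
    indices: Iterable[int],
    auxiliary: bool = True,
) -> PeakAnnotationSet:
    """Return a copy with the auxiliary (ambiguity-bracket) flag set — or
    cleared, with ``auxiliary=False`` — on the given annotation indices."""
    idx = set(indices)
    for i in idx:
        if i < 0 or i >= len(annset.annotations):
            raise IndexError(f"annotation index {i} out of range")
    return PeakAnnotationSet(tuple(
        replace(a, is_auxiliary=auxiliary) if i in idx else a
        for i, a in enumerate(annset.annotations)
    ))
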