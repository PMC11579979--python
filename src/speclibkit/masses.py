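"""Theoretical fragment masses and annotation mass verification.

Peptide backbone fragments follow the Roepstorff/Biemann nomenclature.  With
``Σres`` the sum of residue masses over the fragment span, the neutral
monoisotopic masses are::

    b_n = Σres(1..n)            a_n = b_n − CO        c_n = b_n + NH3
    y_n = Σres(L−n+1..L) + H2O  x_n = y_n + CO − H2   z_n = y_n − NH3 + H
    internal(i,j) = Σres(i..j)  (b/y-type chemistry, no water)
    immonium(R) = residue(R) − CO
    precursor   = Σres(1..L) + H2O (+ terminal mods)

The z series is the radical z-dot species observed in ETD; the even-electron
form is obtainable with an explicit ``-H`` neutral delta.  An ion of charge
``z`` observed with carriers ``c_1..c_z`` (neutral atoms; protons by default,
i.e. H atoms whose electrons are then removed) has

    m/z = (neutral + Σ deltas + isotope·Δ13C + Σ mass(c_i) − z·m_e) / z

with Δ13C = 1.003355 Da the carbon isotope spacing.  Mass errors are always
measured minus computed, in m/z units or ppm.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

from . import mzpaf
from .cv import ValidationIssue
from .mzpaf import (
    Formula, Immonium, Internal, IonAnnotation, Named, NeutralDelta,
    PeakAnnotationSet, Precursor, Reference, Series, Smiles, Unknown,
    UnsupportedFeatureError,
)

__all__ = [
    "Peptidoform", "Composition", "MassConstants", "CONSTANTS",
    "UnresolvableMassError", "ProformaError", "parse_formula",
    "parse_proforma_subset", "fragment_neutral_mass", "annotation_mz",
    "mass_error", "verify_spectrum", "check_smiles_syntax",
]


class UnresolvableMassError(ValueError):
    """The species cannot be assigned a mass (unknown name, X residue, ...)."""


class ProformaError(ValueError):
    def __init__(self, message: str, kind: str = "syntax"):
        super().__init__(message)
        self.kind = kind


def _load_tsv(filename: str):
    text = resources.files("speclibkit.assets").joinpath(filename).read_text("utf-8")
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        yield line.split("\t")


def _load_element_masses() -> dict[str, float]:
    return {row[0]: float(row[1]) for row in _load_tsv("elements.tsv")}


ELEMENT_MASSES = _load_element_masses()
UNIMOD_MASSES: dict[str, float] = {
    row[0]: float(row[1]) for row in _load_tsv("unimod-subset.tsv")
}
_UNIMOD_LOWER = {k.lower(): v for k, v in UNIMOD_MASSES.items()}
REFERENCE_IONS: dict[str, float] = {
    row[0]: float(row[2]) for row in _load_tsv("reference-ions.tsv")
}


class Composition(dict):
    """Element -> count map; counts may be negative for deltas."""

    def mass(self) -> float:
        total = 0.0
        for element, count in self.items():
            try:
                total += ELEMENT_MASSES[element] * count
            except KeyError:
                raise UnresolvableMassError(f"unknown element {element!r}")
        return total

    def __add__(self, other: "Composition") -> "Composition":
        out = Composition(self)
        for element, count in other.items():
            out[element] = out.get(element, 0) + count
        return out


_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(-?\d*)")


def parse_formula(formula: str) -> Composition:
    """Parse ``C6H12O6``-style molecular formulas (multi-letter elements,
    optional per-element counts)."""
    comp = Composition()
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise UnresolvableMassError(
                f"malformed formula {formula!r} at offset {pos}"
            )
        element, count = m.group(1), m.group(2)
        if element not in ELEMENT_MASSES:
            raise UnresolvableMassError(f"unknown element {element!r} in {formula!r}")
        comp[element] = comp.get(element, 0) + (int(count) if count else 1)
        pos = m.end()
    if pos != len(formula) or not comp:
        raise UnresolvableMassError(f"malformed formula {formula!r}")
    return comp


@dataclass(frozen=True)
class MassConstants:
    proton: float = 1.00727646688
    electron: float = 0.00054857990946
    isotope_spacing: float = 1.003355  # 13C - 12C
    include_electron_mass: bool = True

    @property
    def water(self) -> float:
        return parse_formula("H2O").mass()

    @property
    def ammonia(self) -> float:
        return parse_formula("NH3").mass()

    @property
    def co(self) -> float:
        return parse_formula("CO").mass()

    @property
    def hydrogen(self) -> float:
        return ELEMENT_MASSES["H"]


CONSTANTS = MassConstants()

# Residue elemental compositions (the residue, i.e. amino acid minus water).
RESIDUE_FORMULAS = {
    "G": "C2H3NO", "A": "C3H5NO", "S": "C3H5NO2", "P": "C5H7NO",
    "V": "C5H9NO", "T": "C4H7NO2", "C": "C3H5NOS", "L": "C6H11NO",
    "I": "C6H11NO", "N": "C4H6N2O2", "D": "C4H5NO3", "Q": "C5H8N2O2",
    "K": "C6H12N2O", "E": "C5H7NO3", "M": "C5H9NOS", "H": "C6H7N3O",
    "F": "C9H9NO", "R": "C6H12N4O", "Y": "C9H9NO2", "W": "C11H10N2O",
    "U": "C3H5NOSe", "O": "C12H19N3O2",
}
RESIDUE_MASSES = {aa: parse_formula(f).mass() for aa, f in RESIDUE_FORMULAS.items()}

# Named neutral species accepted in bracketed deltas, e.g. "-[Hex]".
NAMED_SPECIES_MASSES = {
    "Hex": 162.052824, "HexNAc": 203.079373, "dHex": 146.057909,
    "NeuAc": 291.095417, "NeuGc": 307.090331, "Pent": 132.042259,
    "Water": 18.010565, "Ammonia": 17.026549, "Carbonyl": 27.994915,
}
NAMED_SPECIES_MASSES.update(UNIMOD_MASSES)


def delta_mass(delta: NeutralDelta) -> float:
    """Signed mass contribution of one neutral gain/loss."""
    if delta.bracketed:
        try:
            base = NAMED_SPECIES_MASSES[delta.payload]
        except KeyError:
            raise UnresolvableMassError(
                f"unknown named neutral species [{delta.payload}]"
            )
    else:
        base = parse_formula(delta.payload).mass()
    return delta.sign * delta.multiplier * base


# ---------------------------------------------------------------------------
# Peptidoforms (ProForma subset)


@dataclass
class Peptidoform:
    residues: str
    residue_mods: dict[int, float] = field(default_factory=dict)  # 1-based
    nterm_mod: float = 0.0
    cterm_mod: float = 0.0
    charge: Optional[int] = None
    source: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    def residue_mass(self, position: int) -> float:
        aa = self.residues[position - 1]
        if aa == "X":
            raise UnresolvableMassError(
                f"residue X at position {position} has no defined mass"
            )
        try:
            base = RESIDUE_MASSES[aa]
        except KeyError:
            raise UnresolvableMassError(f"unknown residue {aa!r}")
        return base + self.residue_mods.get(position, 0.0)

    def span_mass(self, start: int, end: int) -> float:
        return sum(self.residue_mass(i) for i in range(start, end + 1))

    def neutral_mass(self) -> float:
        return (self.span_mass(1, len(self)) + CONSTANTS.water
                + self.nterm_mod + self.cterm_mod)


_ALLOWED_RESIDUES = set(RESIDUE_FORMULAS) | {"X"}
_UNSUPPORTED_MOD_MARKERS = ("#", "|", "Formula:", "GNO:", "Glycan:", "XLMOD:")


def _resolve_mod(token: str) -> float:
    if any(marker in token for marker in _UNSUPPORTED_MOD_MARKERS):
        raise ProformaError(
            f"unsupported modification construct [{token}]", "unsupported"
        )
    stripped = token
    for prefix in ("U:", "UNIMOD:"):
        if stripped.startswith(prefix):
            stripped = stripped[len(prefix):]
            break
    if re.fullmatch(r"[+-]\d+(\.\d+)?", stripped):
        return float(stripped)
    mass = _UNIMOD_LOWER.get(stripped.lower())
    if mass is None:
        raise ProformaError(
            f"unresolvable modification name [{token}]", "unresolvable-mod"
        )
    return mass


def parse_proforma_subset(s: str) -> Peptidoform:
    """Parse the supported ProForma subset: a bare sequence, bracketed mass
    deltas (``[+79.966]``), bracketed Unimod names resolved via the bundled
    table, ``-``-separated terminal modifications, and an optional trailing
    ``/z`` charge.  Unsupported constructs raise rather than dropping mass.
    """
    if not s:
        raise ProformaError("empty peptidoform string")
    source = s
    charge = None
    m = re.search(r"/(\d+)$", s)
    if m:
        charge = int(m.group(1))
        s = s[:m.start()]

    def take_bracket(text: str, pos: int) -> tuple[str, int]:
        # pos is at '['; returns (content, index past ']')
        depth = 0
        for i in range(pos, len(text)):
            if text[i] == "[":
                depth += 1
            elif text[i] == "]":
                depth -= 1
                if depth == 0:
                    return text[pos + 1:i], i + 1
        raise ProformaError(f"unbalanced brackets in {source!r}")

    nterm = 0.0
    pos = 0
    if s.startswith("["):
        content, after = take_bracket(s, 0)
        if after < len(s) and s[after] == "-":
            nterm = _resolve_mod(content)
            pos = after + 1

    residues: list[str] = []
    mods: dict[int, float] = {}
    cterm = 0.0
    while pos < len(s):
        ch = s[pos]
        if ch == "-":
            if pos + 1 < len(s) and s[pos + 1] == "[":
                content, after = take_bracket(s, pos + 1)
                if after != len(s):
                    raise ProformaError(
                        f"trailing characters after C-terminal modification in {source!r}"
                    )
                cterm = _resolve_mod(content)
                pos = after
                continue
            raise ProformaError(f"stray '-' at offset {pos} in {source!r}")
        if ch == "[":
            if not residues:
                raise ProformaError(
                    f"modification before any residue in {source!r} "
                    "(N-terminal mods use the '[mod]-' form)"
                )
            content, after = take_bracket(s, pos)
            position = len(residues)
            mods[position] = mods.get(position, 0.0) + _resolve_mod(content)
            pos = after
            continue
        if ch in _ALLOWED_RESIDUES:
            residues.append(ch)
            pos += 1
            continue
        if ch == "]":
            raise ProformaError(f"unbalanced brackets in {source!r}")
        raise ProformaError(f"unsupported character {ch!r} at offset {pos} in {source!r}")
    if not residues:
        raise ProformaError(f"no residues in {source!r}")
    return Peptidoform("".join(residues), mods, nterm, cterm, charge, source)


# ---------------------------------------------------------------------------
# Fragment masses


def fragment_neutral_mass(p: Peptidoform, ion) -> float:
    """Neutral monoisotopic mass of a backbone fragment of peptidoform ``p``.

    Terminal modifications attach only to the series that retains their
    terminus; positional modifications attach iff the position lies inside
    the fragment span.
    """
    c = CONSTANTS
    L = len(p)
    if isinstance(ion, Series):
        n = ion.ordinal
        if n > L - 1:
            raise ValueError(
                f"series ordinal {n} out of bounds for length-{L} peptidoform"
            )
        if ion.series in "abc":
            base = p.span_mass(1, n) + p.nterm_mod
            if ion.series == "a":
                return base - c.co
            if ion.series == "c":
                return base + c.ammonia
            return base
        base = p.span_mass(L - n + 1, L) + c.water + p.cterm_mod
        if ion.series == "x":
            return base + c.co - 2 * c.hydrogen
        if ion.series == "z":  # radical z-dot
            return base - c.ammonia + c.hydrogen
        return base  # y
    if isinstance(ion, Internal):
        if ion.end > L:
            raise ValueError(
                f"internal ion end {ion.end} out of bounds for length-{L} peptidoform"
            )
        return p.span_mass(ion.start, ion.end)
    if isinstance(ion, Precursor):
        return p.neutral_mass()
    if isinstance(ion, Immonium):
        base = RESIDUE_MASSES.get(ion.residue)
        if base is None:
            raise UnresolvableMassError(f"residue {ion.residue!r} has no mass")
        if ion.modification:
            base += _resolve_mod(ion.modification)
        return base - c.co
    raise TypeError(f"no neutral-mass rule for ion {ion!r}")


_SERIES_OFFSETS = {
    # offset added to the residue-span sum, in terms of (water, ammonia, CO, H)
    "b": (0, 0, 0, 0), "a": (0, 0, -1, 0), "c": (0, 1, 0, 0),
    "y": (1, 0, 0, 0), "x": (1, 0, 1, -2), "z": (1, -1, 0, 1),
}


def _series_offset(series: str) -> float:
    w, n, co, h = _SERIES_OFFSETS[series]
    c = CONSTANTS
    return w * c.water + n * c.ammonia + co * c.co + h * c.hydrogen


def _context_fragment_mass(a: IonAnnotation) -> Optional[float]:
    # A series ion whose sequence context covers the full fragment span
    # (e.g. 0@y2{TK}) is computable without an analyte.
    if (isinstance(a.ion, Series) and a.sequence_context
            and len(a.sequence_context) == a.ion.ordinal):
        stub = Peptidoform(a.sequence_context)
        return stub.span_mass(1, len(stub)) + _series_offset(a.ion.series)
    return None


def _carrier_mass(species: str) -> float:
    sign = 1 if species[0] == "+" else -1
    return sign * parse_formula(species[1:]).mass()


def ion_neutral_mass(a: IonAnnotation, p: Optional[Peptidoform]) -> float:
    """Neutral mass of the annotated ion variant, before deltas/carriers."""
    ion = a.ion
    if isinstance(ion, Immonium):  # independent of any analyte
        return fragment_neutral_mass(Peptidoform(ion.residue), ion)
    if isinstance(ion, (Series, Internal, Precursor)):
        if p is None:
            context = _context_fragment_mass(a)
            if context is not None:
                return context
            raise UnresolvableMassError(
                "annotation requires an analyte peptidoform"
            )
        return fragment_neutral_mass(p, ion)
    if isinstance(ion, Formula):
        return parse_formula(ion.formula).mass()
    if isinstance(ion, Reference):
        try:
            mz1 = REFERENCE_IONS[ion.name]
        except KeyError:
            raise UnresolvableMassError(f"unknown reference ion {ion.name!r}")
        # table stores the singly protonated m/z
        return mz1 - CONSTANTS.proton
    if isinstance(ion, (Named, Smiles, Unknown)):
        raise UnresolvableMassError(
            f"{type(ion).__name__} ions are not mass-resolvable"
        )
    raise TypeError(f"not an ion variant: {ion!r}")


def annotation_mz(p: Optional[Peptidoform], a: IonAnnotation) -> float:
    """Theoretical m/z of an annotation against peptidoform ``p``.

    Charge carriers default to ``z`` protons (H atoms minus their electrons)
    and are replaced wholesale by the adduct list when one is present.
    """
    c = CONSTANTS
    z = a.charge
    neutral = ion_neutral_mass(a, p)
    neutral += sum(delta_mass(d) for d in a.neutral_deltas)
    neutral += a.isotope * c.isotope_spacing
    if a.adducts:
        net = sum(1 if s[0] == "+" else -1 for s in a.adducts)
        if net != z:
            raise ValueError(
                f"adduct list {list(a.adducts)} carries net count {net} "
                f"but the annotation charge is {z}"
            )
        carriers = sum(_carrier_mass(s) for s in a.adducts)
    else:
        # Default carriers are z protons; express them as proton + electron
        # so the electron subtraction below cancels exactly and
        # mz(z=k) == (mz(z=1) + (k-1)*proton)/k holds to float precision.
        carriers = z * (c.proton + c.electron)
    electron = z * c.electron if c.include_electron_mass else 0.0
    return (neutral + carriers - electron) / z


def mass_error(observed_mz: float, theoretical_mz: float, unit: str = "mz") -> float:
    """Signed mass error, always measured minus computed."""
    if theoretical_mz <= 0:
        raise ValueError("theoretical m/z must be positive")
    diff = observed_mz - theoretical_mz
    if unit == "mz":
        return diff
    if unit == "ppm":
        return diff / theoretical_mz * 1e6
    raise ValueError(f"unknown mass-error unit {unit!r}")


def check_smiles_syntax(smiles: str) -> bool:
    """Syntax-check a SMILES string; uses RDKit when available, else a
    charset-level check."""
    try:  # pragma: no cover - depends on optional extra
        from rdkit import Chem, RDLogger

        RDLogger.DisableLog("rdApp.error")
        return Chem.MolFromSmiles(smiles) is not None
    except ImportError:
        return bool(re.fullmatch(r"[A-Za-z0-9@+\-\[\]()=#$/\\%.*:]+", smiles))


# ---------------------------------------------------------------------------
# Spectrum-level verification


def _implied_theoretical(peak_mz: float, me) -> float:
    if me is None:
        return peak_mz
    if me.unit == "mz":
        return peak_mz - me.value
    return peak_mz / (1.0 + me.value * 1e-6)


def verify_spectrum(
    peaks: list[tuple[float, float, PeakAnnotationSet]],
    analytes: dict[int, Peptidoform],
    tol_ppm: float = 10.0,
    context: str = "",
) -> list[ValidationIssue]:
    """Recompute every resolvable annotation's theoretical m/z and compare it
    with the value the peak implies (peak m/z corrected by the stated mass
    error, falling back to the raw peak m/z).

    Returns error issues for disagreements beyond ``tol_ppm`` and for
    dangling analyte references; annotations that cannot be mass-resolved
    (named compounds, SMILES, unknown reference ions, X residues) yield
    warnings only.  When an annotation states a mass error, a disagreement
    is additionally cross-checked against the raw peak m/z so both readings
    of the stated delta (informational vs normative) are reported.
    """
    issues: list[ValidationIssue] = []
    for peak_index, (peak_mz, _intensity, annset) in enumerate(peaks):
        where = f"{context}/Peak={peak_index}" if context else f"Peak={peak_index}"
        for a in annset:
            if isinstance(a.ion, Unknown):
                continue
            peptidoform = analytes.get(a.analyte_ref)
            if peptidoform is None and a.analyte_ref != 0:
                issues.append(ValidationIssue(
                    "error", where,
                    f"annotation references missing analyte {a.analyte_ref}",
                ))
                continue
            try:
                theoretical = annotation_mz(peptidoform, a)
            except (UnresolvableMassError, UnsupportedFeatureError) as exc:
                issues.append(ValidationIssue(
                    "warning", where, f"unverifiable annotation: {exc}"
                ))
                continue
            except ValueError as exc:
                issues.append(ValidationIssue("error", where, str(exc)))
                continue
            implied = _implied_theoretical(peak_mz, a.mass_error)
            err_ppm = mass_error(implied, theoretical, "ppm")
            if abs(err_ppm) > tol_ppm:
                raw_ppm = mass_error(peak_mz, theoretical, "ppm")
                issues.append(ValidationIssue(
                    "error", where,
                    f"annotation {mzpaf.serialize_annotation(a)} implies "
                    f"theoretical m/z {implied:.6f} but recomputation gives "
                    f"{theoretical:.6f} ({err_ppm:+.2f} ppm vs stated delta, "
                    f"{raw_ppm:+.2f} ppm vs raw peak)",
                ))
    return issues
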