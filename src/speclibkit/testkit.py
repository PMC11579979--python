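"""Seeded synthetic-fixture generator.

Builds small but structurally complete libraries from scratch: random
tryptic-like peptides (length 7-20, C-terminal K/R), theoretical b/y
fragment peaks with Gaussian m/z jitter, compact peak annotations carrying
the true measured-minus-computed deltas, a stated fraction of unidentified
spectra, and an MSP twin rendering.  Everything is driven by one seeded
generator, so a given seed always yields byte-identical output.

The generator emulates centroided, annotated DDA library entries.  It does
not emulate chimeric spectra, noise peaks beyond m/z jitter, intensity
models, isotope envelopes, or real modification chemistry — properties
proven on fixtures speak to the format machinery, not to any biological
claim.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .cv import Attribute, TermValue
from .masses import CONSTANTS, Peptidoform, annotation_mz, fragment_neutral_mass
from .model import Analyte, Cluster, Interpretation, Library, Peak, Spectrum
from .msp import write_msp
from .mzpaf import (
    UNKNOWN_PEAK, Formula, Immonium, Internal, IonAnnotation, MassError,
    Named, NeutralDelta, PeakAnnotationSet, Precursor, Reference, Series,
    Smiles, Unknown,
)

__all__ = ["FixtureSpec", "generate_fixture", "generate_fixture_msp",
           "random_tryptic_peptide", "random_annotation",
           "random_annotation_set"]

_RESIDUE_POOL = "ACDEFGHILMNPQSTVWY"  # internal positions; K/R close the peptide


@dataclass(frozen=True)
class FixtureSpec:
    n_spectra: int = 5
    peptides_per_spectrum: int = 1
    peaks_per_spectrum: int = 12
    fraction_annotated: float = 1.0
    fraction_unidentified: float = 0.0
    mz_sigma: float = 0.002  # Da, Gaussian jitter on observed peak m/z
    seed: int = 0

    def __post_init__(self):
        for name in ("fraction_annotated", "fraction_unidentified"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.n_spectra < 0 or self.peaks_per_spectrum < 1:
            raise ValueError("n_spectra must be >= 0 and peaks_per_spectrum >= 1")


def random_tryptic_peptide(rng: random.Random) -> str:
    length = rng.randint(7, 20)
    body = "".join(rng.choice(_RESIDUE_POOL) for _ in range(length - 1))
    return body + rng.choice("KR")


def _fragment_ions(length: int) -> list[Series]:
    ions = [Series("b", n) for n in range(2, length)]
    ions += [Series("y", n) for n in range(1, length)]
    return ions


def generate_fixture(spec: FixtureSpec) -> Library:
    """Generate a deterministic, validation-clean library."""
    rng = random.Random(spec.seed)
    lib = Library(header_attributes=[
        Attribute("MS:1003186", "library format version", "1.0"),
        Attribute("MS:1003188", "library name", f"synthetic-fixture-{spec.seed}"),
        Attribute("MS:1003059", "number of spectra", spec.n_spectra),
    ])
    lib.attribute_sets["Spectrum"] = {
        "all": [Attribute("MS:1001456", "analysis software", "speclibkit-testkit")],
    }
    n_unidentified = round(spec.n_spectra * spec.fraction_unidentified)
    for key in range(1, spec.n_spectra + 1):
        unidentified = key > spec.n_spectra - n_unidentified
        spectrum = Spectrum(key)
        if unidentified:
            spectrum.attributes.append(Attribute(
                "MS:1003065", "spectrum aggregation type",
                TermValue("MS:1003066", "singleton spectrum"),
            ))
            for _ in range(spec.peaks_per_spectrum):
                mz = round(rng.uniform(150.0, 1500.0), 4)
                intensity = round(rng.uniform(10.0, 10000.0), 1)
                spectrum.peaks.append(Peak(mz, intensity, UNKNOWN_PEAK))
            spectrum.peaks.sort(key=lambda p: p.mz)
            lib.spectra.append(spectrum)
            continue
        for analyte_id in range(1, spec.peptides_per_spectrum + 1):
            peptide = random_tryptic_peptide(rng)
            charge = rng.choice((2, 3))
            p = Peptidoform(peptide)
            precursor_mz = (p.neutral_mass() + charge * CONSTANTS.proton) / charge
            analyte = Analyte(analyte_id, [
                Attribute("MS:1003169", "proforma peptidoform sequence", peptide),
                Attribute("MS:1000041", "charge state", charge),
                Attribute("MS:1003053", "theoretical monoisotopic m/z",
                          round(precursor_mz, 6)),
            ])
            spectrum.analytes[analyte_id] = analyte
            interp = spectrum.interpretations.setdefault(1, Interpretation(1))
            interp.members[analyte_id] = []
            if analyte_id == 1:
                spectrum.attributes.extend([
                    Attribute("MS:1003061", "library spectrum name",
                              f"{peptide}/{charge}"),
                    Attribute("MS:1000744", "selected ion m/z",
                              round(precursor_mz, 4)),
                ])
                spectrum.attributes.append(Attribute(
                    "MS:1003065", "spectrum aggregation type",
                    TermValue("MS:1003067", "consensus spectrum"),
                ))
        first = spectrum.analytes[1]
        peptide = str(first.attributes[0].value)
        p = Peptidoform(peptide)
        candidates = _fragment_ions(len(peptide))
        rng.shuffle(candidates)
        chosen = candidates[:spec.peaks_per_spectrum]
        for ion in chosen:
            annotation = IonAnnotation(ion, analyte_ref=1)
            theoretical = annotation_mz(p, annotation)
            observed = theoretical + rng.gauss(0.0, spec.mz_sigma)
            observed = round(observed, 6)
            intensity = round(rng.uniform(10.0, 10000.0), 1)
            if rng.random() < spec.fraction_annotated:
                delta = round(observed - theoretical, 6)
                annset = PeakAnnotationSet((IonAnnotation(
                    ion, analyte_ref=1, mass_error=MassError(delta, "mz"),
                ),))
            else:
                annset = UNKNOWN_PEAK
            spectrum.peaks.append(Peak(observed, intensity, annset))
        spectrum.peaks.sort(key=lambda peak: peak.mz)
        lib.spectra.append(spectrum)

    identified = [s.key for s in lib.spectra if s.analytes]
    if len(identified) >= 2:
        lib.clusters.append(Cluster(1, [
            Attribute("MS:1003267", "cluster member spectrum keys",
                      " ".join(str(k) for k in identified[:2])),
        ]))
    return lib


_DELTA_FORMULAS = ("H2O", "NH3", "H3PO4", "CO", "CH4OS", "C2H4O2")
_DELTA_NAMES = ("Hex", "HexNAc", "Phospho", "Oxidation")
_REFERENCE_NAMES = ("TMT126", "TMT127N", "iTRAQ114", "NotInTable")
_SMILES = ("CN=C=O", "c1ccccc1", "CC(=O)O")
_NAMED = ("Adenine", "Guanine", "Urocanic acid")
_CARRIERS = ("Na", "K", "H", "NH4")


def random_annotation(rng: random.Random) -> IonAnnotation:
    """One random, well-formed annotation spanning the whole grammar."""
    kind = rng.randrange(9)
    sequence_context = None
    if kind == 0:
        ion = Series(rng.choice("abcxyz"), rng.randint(1, 30))
        if rng.random() < 0.2:
            sequence_context = "".join(
                rng.choice(_RESIDUE_POOL) for _ in range(rng.randint(1, 4))
            )
    elif kind == 1:
        start = rng.randint(1, 12)
        ion = Internal(start, start + rng.randint(1, 10))
    elif kind == 2:
        ion = Precursor()
    elif kind == 3:
        ion = Immonium(rng.choice("ACDEFGHIKLMNPQRSTVWY"),
                       rng.choice((None, "Oxidation", "Phospho")))
    elif kind == 4:
        ion = Reference(rng.choice(_REFERENCE_NAMES))
    elif kind == 5:
        ion = Formula(rng.choice(("C13H9", "C6H12O6", "CH3NO", "C2H5N2O")))
    elif kind == 6:
        ion = Smiles(rng.choice(_SMILES))
    elif kind == 7:
        ion = Named(rng.choice(_NAMED))
    else:
        ion = Unknown(rng.randint(1, 99) if rng.random() < 0.3 else None)

    deltas = []
    for _ in range(rng.randrange(3)):
        if rng.random() < 0.3:
            deltas.append(NeutralDelta(
                rng.choice((1, -1)), rng.choice(_DELTA_NAMES),
                rng.randint(1, 3), bracketed=True,
            ))
        else:
            deltas.append(NeutralDelta(
                rng.choice((1, -1)), rng.choice(_DELTA_FORMULAS),
                rng.randint(1, 3),
            ))
    charge = rng.randint(1, 4)
    adducts = None
    if rng.random() < 0.25:
        adducts = tuple(
            "+" + rng.choice(_CARRIERS) for _ in range(charge)
        )
    mass_error = None
    if rng.random() < 0.5:
        value = round(rng.uniform(-25.0, 25.0), 4) or 0.0001
        mass_error = MassError(value, rng.choice(("mz", "ppm")))
    return IonAnnotation(
        ion=ion,
        analyte_ref=rng.choice((0, 1, 1, 1, 2)),
        is_auxiliary=rng.random() < 0.15,
        sequence_context=sequence_context,
        neutral_deltas=tuple(deltas),
        isotope=rng.choice((0, 0, 0, 1, 2, -1)),
        adducts=adducts,
        charge=charge,
        mass_error=mass_error,
        confidence=round(rng.random(), 3) if rng.random() < 0.3 else None,
    )


def random_annotation_set(rng: random.Random) -> PeakAnnotationSet:
    n = 1 + (rng.random() < 0.25)
    return PeakAnnotationSet(tuple(random_annotation(rng) for _ in range(n)))


def generate_fixture_msp(spec: FixtureSpec) -> str:
    """The twin MSP rendering of the generated library (single-analyte
    spectra only; multi-analyte fixtures cannot be expressed in MSP)."""
    if spec.peptides_per_spectrum != 1:
        raise ValueError("MSP twin requires peptides_per_spectrum == 1")
    lib = generate_fixture(spec)
    lib.header_attributes = []  # MSP has no header; avoid a spurious warning
    return write_msp(lib)
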