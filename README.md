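# speclibkit

A toolkit for standardized mass-spectral libraries and fragment-ion peak
annotations in proteomics.

Spectral libraries are curated collections of reference MS2 spectra, each
tied (when known) to the analyte — typically a charged peptidoform — that
produced it. Historically they have been shipped in ad hoc text formats
(NIST MSP, sptxt, assorted TSVs) whose metadata live in undocumented
comment-line keys and whose peak-annotation strings drifted between tools.
`speclibkit` implements the standardized alternative end to end:

- **A six-component data model** — library metadata, spectrum clusters,
  spectra, analytes, peaks, and per-peak annotations — in which every
  metadata statement is a controlled-vocabulary attribute
  (`MS:1000744|selected ion m/z=504.27`). Shared metadata can be declared
  once in named *attribute sets* and cascade onto entries like
  configuration, with entry-level values overriding set-level ones.
- **Two lossless serializations** of that model: a human-readable
  sectioned text dialect (`.mzlib.txt`) and a JSON form (`.mzlib.json`),
  interconvertible without loss (any conversion path yields the same
  canonical rendering).
- **A compact peak-annotation grammar** covering the Roepstorff/Biemann
  ion series (`a b c x y z`), internal (`m2:15`), precursor (`p`),
  immonium (`IL`), reference/reporter (`r[TMT127N]`), formula (`f{C13H9}`),
  SMILES (`s{...}`), named-compound (`_{Adenine}`) and unknown (`?`) ions,
  with neutral losses/gains, isotope peaks, non-proton charge carriers,
  charge, measured-minus-computed mass deltas (m/z or ppm) and a
  confidence in [0, 1] — e.g. `y16-H3PO4^2/0.001` or
  `m2:15+2i[M+2Na]^2/-20ppm`. A state-machine parser, a canonical
  serializer and a JSON object model are included.
- **Theoretical m/z computation and verification.** For a peptidoform with
  residue masses Σres, the neutral fragment masses are
  `b=Σres`, `a=b−CO`, `c=b+NH3`, `y=Σres+H2O`, `x=y+CO−H2`, `z•=y−NH3+H`,
  and an ion of charge z with carriers c₁..c_z (protons by default) has
  `m/z = (neutral + Σdeltas + isotope·1.003355 + Σm(cᵢ) − z·mₑ)/z`.
  Every resolvable annotation in a spectrum can be recomputed and checked
  against its peak at a ppm tolerance.
- **A legacy MSP converter** that collapses the many historical comment
  keys (eight spellings of precursor m/z, `HCD` ≡ `CE`, `Nreps=27/31` →
  replicate-count terms plus a grouped peak-aggregation declaration, ...)
  onto CV terms, preserves everything unmapped verbatim, and writes MSP
  back out for single-analyte libraries.

## Worked example

```python
from speclibkit import (parse_annotations, parse_proforma_subset,
                        annotation_mz, mass_error, serialize_annotations)
from speclibkit.mzpaf import Series, IonAnnotation, MassError, PeakAnnotationSet

p = parse_proforma_subset("EM[+15.995]EVEES[+79.966]PEK")
theo = annotation_mz(p, IonAnnotation(Series("y", 4)))
print(f"theoretical y4 m/z : {theo:.5f}")
obs = 540.20720
err = mass_error(obs, theo, "ppm")
print(f"observed {obs} -> delta {err:+.2f} ppm")
ann = IonAnnotation(Series("y", 4), mass_error=MassError(round(err, 2), "ppm"))
print("annotation:", serialize_annotations(PeakAnnotationSet((ann,))))
```

prints

```
theoretical y4 m/z : 540.20619
observed 540.2072 -> delta +1.87 ppm
annotation: y4/1.87ppm
```

The y4 ion of this phosphopeptide spans `S[+79.966]PEK`, so its neutral
mass is the four residue masses plus the phospho shift plus water; adding
a proton gives 540.20619, and the observed peak sits 1.87 ppm above it —
which is exactly what the emitted annotation records (deltas are always
measured minus computed).

The same machinery drives the `speclib-tool` CLI:

```sh
$ speclib-tool convert -i fixture.msp -o fixture.mzlib.txt
$ speclib-tool describe -i fixture.mzlib.txt
spectra: 2
analytes: 2
clusters: 0
peaks: 24
annotated_peak_fraction: 1.0
$ speclib-tool validate -i fixture.mzlib.txt --check-masses --tol-ppm 10
WARNING [Library] header lacks a library name
0 errors, 1 warnings
```

(`validate` exits 0 when there are no errors; `--strict` promotes
warnings.) A seeded fixture generator (`speclibkit.testkit`) produces
synthetic tryptic-peptide libraries and twin MSP renderings so everything
is testable without downloads.

## Layout

```
src/speclibkit/
  cv.py           controlled-vocabulary attributes + bundled PSI-MS subset
  mzpaf.py        peak-annotation AST, parser, serializer, JSON model
  masses.py       peptidoforms, fragment masses, verification
  model.py        the six-component library model, cascade, merge/subset
  serializers.py  text + JSON readers/writers, schema check, conversion
  msp.py          legacy MSP reader/mapper/writer
  testkit.py      seeded synthetic fixtures and random annotation ASTs
  cli.py          speclib-tool convert | validate | describe
  assets/         element masses, Unimod subset, reference ions,
                  MSP key map, PSI-MS subset, JSON schema (all TSV/JSON)
```

See `docs/methods.md` for the modelling choices, conventions and known
limitations.
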