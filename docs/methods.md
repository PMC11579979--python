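# Methods

## The data model and its serializations

A library is modelled as six nested components: library-level metadata,
optional spectrum clusters, spectra, per-spectrum analytes, the peak list,
and per-peak annotations. All metadata, at every level, are
controlled-vocabulary attributes — `accession|name=value` statements,
optionally tied together by a `[n]` group prefix (e.g. a value and its
unit, or a peak-attribute declaration and the term it declares). The model
is serialization-independent; the package ships a sectioned text dialect
and a JSON form and guarantees they are interconvertible without loss.

Two canonicalization rules make that guarantee checkable as byte equality:

1. **Writers are canonical.** Attribute lines carry no padding around `=`,
   floats use shortest round-trip formatting, peaks are written sorted by
   m/z with an explicit annotation column, and sections appear in a fixed
   order (header, attribute sets, clusters, spectra). Two writes of the
   same in-memory library are byte-identical, and converting a document
   along any path through {text, json} yields the same canonical text.
   Raw input text is still retained at the single-attribute level, so
   `format_attribute(parse_attribute_line(s)) == s` byte-for-byte even for
   padded input; the document writer deliberately does not reuse raw
   tokens, because the JSON path cannot carry them and the two paths must
   agree.
2. **The `?` shorthand** in the peak table denotes exactly the default
   unknown annotation; any decorated unknown (`?17`, `?^2`) is written in
   full.

Attribute sets cascade like configuration: the scope's implicit `all` set
applies first, then named sets in reference order, then the entity's own
attributes. Later sources override earlier ones per accession, grouped
attributes move as whole groups, and a small allowlist of inherently
multi-valued terms (analysis software, constituent spectrum files,
other-attribute name/value pairs, cluster member lists) accumulates
instead of overriding. Group ids in the resolved view are renumbered
sequentially so ids arriving from different sources cannot collide.

Merging two libraries shifts the second library's spectrum and cluster
keys past the maxima of the first and rewrites intra-library cluster
references accordingly; attribute sets whose names collide with
differently valued sets are inlined into the affected spectra rather than
silently redefined. Subsetting keeps referenced attribute sets, drops
clusters whose members are all removed, and flags partially emptied
clusters with a warning. Unidentified spectra (zero analytes, zero
interpretations) are valid throughout. Cluster members that are not
integer keys are treated as external, USI-shaped references and are not
resolved.

## The annotation grammar

One annotation is serialized in a fixed component order: analyte
reference (`1@`, elided when 1; `0@` marks an unspecified contaminant),
ambiguity bracket, ion body, sequence context (`{TK}`), neutral deltas,
isotope token (`+2i`), adduct list (`[M+2Na]`), charge (`^z`, elided when
1), mass delta (`/0.001`, `/-20ppm`), confidence (`*0.97`). On input the
isotope and adduct tokens are accepted in either order; everything else
is positional. The parser is a hand-written cursor state machine: errors
carry a column offset, trailing unconsumed characters are an error (no
silent truncation), and element-specific isotope tokens (`+i13C`) are
reserved — they raise an unsupported-feature error rather than
mis-parsing. Internal-ion coordinates are 1-based inclusive positions
counted from the N terminus. An unknown ion may carry a numeric label
(`?17`) to co-index recurring unknown series across spectra. Ambiguity
brackets accept both a bracketed group (`[y4,y4+i]`) and per-annotation
brackets; the serializer always emits per-annotation brackets.

The JSON object model spells each component out as an explicit field
(`ion_type`, `ordinal`, `neutral_deltas`, `mass_error`, ...) rather than
embedding the compact string, and validation errors name the offending
path (`annotations[0].ion_type`).

## Mass conventions

Monoisotopic element masses (IUPAC/CODATA, ≥6 decimals) live in a TSV
asset; residue masses are derived from elemental compositions at import
time. The fragment chemistry is the Roepstorff/Biemann table given in the
README; the choices that are genuinely conventions, not facts, are:

- **z ions are the radical z• species** (`y − NH3 + H`), the form
  observed in ETD spectra; the even-electron z is written with an
  explicit `-H` delta. The offsets live in one table for easy override.
- **Internal ions use b/y-type chemistry** (no water); a-type internal
  ions are written with an explicit `-CO` delta.
- **Electron mass is included**: m/z subtracts z·mₑ, with charge carriers
  modelled as neutral species. Default proton carriers are expressed as
  proton + electron so the subtraction cancels exactly and the
  charge-state identity `mz(k) = (mz(1) + (k−1)·proton)/k` holds to float
  precision. The inclusion is a single toggleable constant.
- **Isotope spacing** uses the 13C−12C difference (1.003355 Da)
  uniformly; averaged isotopologue spacing is out of scope.
- **Adduct lists replace the proton carriers wholesale** (`[M+2Na]` means
  two sodiums, not sodiums in addition to protons), and their net count
  must equal the charge.
- **Reference ions** resolve against a bundled TSV of reporter-ion m/z
  values (the table stores the singly charged m/z); unknown names parse
  but verify as unresolvable. Named compounds and SMILES ions are never
  mass-resolved — SMILES strings are syntax-checked only (via RDKit when
  installed, else a charset check).

Peptidoforms are parsed from a deliberately bounded notation subset: bare
sequences over the 20 canonical residues plus U, O and X (X poisons mass
computation), bracketed numeric mass deltas, bracketed modification names
resolved through a bundled ~45-entry Unimod-subset TSV, `-`-separated
terminal modifications, and an optional trailing `/charge`. Anything
outside the subset — localization scores, cross-linkers, formula
modifications, unknown names — raises; mass is never silently dropped.

Spectrum verification recomputes each resolvable annotation's theoretical
m/z and compares it with the value the peak implies: the peak m/z
corrected by the stated delta when one is present, else the raw peak m/z.
Because the stated delta could be read as informational or normative,
disagreement reports include the discrepancy under both readings. A
series annotation whose sequence context covers its full span (e.g.
`0@y2{TK}`) is verifiable even without an analyte; other unresolvable
annotations yield warnings, not errors.

## The MSP converter

The key-mapping table is a TSV asset covering the synonym families found
across MSP dialects (eight spellings of precursor m/z, six of scan
polarity, eight of collision energy, with `HCD` and `CE` mapping to the
same term). `Nreps=a/b` splits on the slash (falling back to a single
used-count), yields both replicate-count terms, and registers the grouped
peak-attribute declaration for observation frequency. `Mods=` is parsed
for the common `n(pos,aa,Name)` and `n/pos,aa,Name` dialects with 0-based
positions; anything else leaves the bare sequence plus a warning. Every
unmapped key is preserved as a grouped name/value attribute pair, so the
forward conversion is lossless by construction. On the reverse path,
attributes without an MSP synonym are written as
`MzSpecLib_<accession>=value` comment keys (analyte-context attributes as
`MzSpecLib_Analyte_...`) which the reader recognizes and restores —
making MSP → model → MSP a fixed point after the first conversion.
Multi-analyte or multi-interpretation spectra are rejected on MSP output
(the format cannot express them), and library headers are dropped with a
warning. Legacy peak-annotation strings are translated only where the
dialects genuinely coincide; a trailing occurrence suffix (`2/2`) is
stripped, and anything else becomes an unknown annotation that preserves
the raw text in a non-serialized field — components are never fabricated.

## Synthetic fixtures

The fixture generator emulates small centroided, annotated DDA library
entries: tryptic-like peptides of length 7–20 ending in K or R, precursor
charges 2–3, b/y fragment peaks at their theoretical m/z plus Gaussian
jitter (σ = 0.002 Da by default, a typical high-resolution instrument
scale), annotations carrying the true measured-minus-computed deltas,
uniform random intensities, a configurable fraction of unidentified
spectra (uniform random peaks, all `?`), one attribute set and one
cluster. A given seed yields byte-identical output. It does **not**
emulate chimeric spectra, noise peaks, isotope envelopes,
intensity models, or real modification chemistry — fixture-based tests
therefore demonstrate the format and verification machinery, not
biological fidelity, and passing them says nothing about search-engine
performance on real data.

Problem sizes used by the default test run and the acceptance script —
10,000 random annotation ASTs, 50 fixture libraries for the serialization
commuting square, 100 random peptides for the chemistry identities, and a
5-spectrum pipeline fixture — were chosen to exercise every grammar
production and code path many times over while keeping the whole suite
in the seconds range.

## Known limitations

- The bundled PSI-MS subset is a static snapshot (~30 terms); unknown
  accessions validate as warnings so current-CV libraries remain usable,
  and the TSV can be swapped for a fresh psi-ms.obo extract. Where a
  convenience term was needed that the printed sources do not pin down
  (cluster membership, attribute-set references, other-attribute pairs),
  the subset fixes one accession; the registry, writers and validator are
  mutually consistent by construction.
- Term names are treated as authoritative alongside accessions: a name
  that contradicts the bundled registry is an error. A policy where the
  accession silently wins would hide transcription mistakes.
- Glycan-, cross-link- and lipid-specific annotation extensions, binary
  or indexed serializations, spectrum clustering itself, FDR estimation
  and spectrum prediction are out of scope (only their *encodings* are
  supported).
- Average masses and fine isotope structure are not computed.
- The NIST annotation dialect has drifted over decades; the translator is
  intentionally conservative and preserves rather than guesses.
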