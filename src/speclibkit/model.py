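"""The spectral-library data model.

A library is six nested components: library-level metadata, optional spectrum
clusters, spectra, the analytes proposed for each spectrum, the peak list,
and per-peak annotations.  All metadata are CV attributes
(:mod:`speclibkit.cv`); shared metadata can be declared once in named
*attribute sets* in the header and referenced by many entries, cascading like
configuration: the implicit ``all`` set of a scope applies first, then named
sets in reference order, then the entity's own attributes, later sources
overriding earlier ones accession-by-accession (grouped attributes move as
whole groups; a small allowlist of inherently multi-valued terms accumulates
instead of overriding).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Optional, Union

from .cv import Attribute, CvTerm, ValidationIssue, validate_attributes
from .mzpaf import PeakAnnotationSet, UNKNOWN_PEAK

__all__ = [
    "Library", "Spectrum", "Analyte", "Interpretation", "Peak", "Cluster",
    "resolve_attributes", "validate_library", "merge_libraries",
    "subset_library",
    "PEPTIDOFORM_ACCESSIONS", "ACCUMULATING_ACCESSIONS",
]

# Accessions that legitimately occur many times in one context and therefore
# accumulate through the attribute-set cascade instead of overriding.
ACCUMULATING_ACCESSIONS = {
    "MS:1001456",  # analysis software
    "MS:1003203",  # constituent spectrum file
    "MS:1003275",  # other attribute name
    "MS:1003276",  # other attribute value
    "MS:1003267",  # cluster member spectrum keys
}

PEPTIDOFORM_ACCESSIONS = {"MS:1003169"}  # proforma peptidoform sequence
ATTRIBUTE_SET_REF_ACCESSION = "MS:1003212"  # library attribute set name
FORMAT_VERSION_ACCESSION = "MS:1003186"
LIBRARY_NAME_ACCESSION = "MS:1003188"
SCOPES = ("Spectrum", "Analyte", "Interpretation", "Cluster")


@dataclass
class Analyte:
    id: int
    attributes: list[Attribute] = field(default_factory=list)

    def peptidoform_string(self) -> Optional[str]:
        for attr in self.attributes:
            if attr.accession in PEPTIDOFORM_ACCESSIONS:
                return str(attr.value)
        return None


@dataclass
class Interpretation:
    id: int
    attributes: list[Attribute] = field(default_factory=list)
    # analyte id -> member-level attributes
    members: dict[int, list[Attribute]] = field(default_factory=dict)


@dataclass
class Peak:
    mz: float
    intensity: float
    annotations: PeakAnnotationSet = UNKNOWN_PEAK
    aggregations: list[Union[str, float]] = field(default_factory=list)
    # retained raw column text for byte-stable re-serialization
    raw_columns: Optional[tuple[str, ...]] = field(default=None, compare=False)


@dataclass
class Spectrum:
    key: int
    attributes: list[Attribute] = field(default_factory=list)
    attribute_set_refs: list[str] = field(default_factory=list)
    analytes: dict[int, Analyte] = field(default_factory=dict)
    interpretations: dict[int, Interpretation] = field(default_factory=dict)
    peaks: list[Peak] = field(default_factory=list)
    was_sorted: bool = True

    def sorted_peaks(self) -> list[Peak]:
        return sorted(self.peaks, key=lambda p: p.mz)


@dataclass
class Cluster:
    key: int
    attributes: list[Attribute] = field(default_factory=list)

    def member_keys(self) -> tuple[list[int], list[str]]:
        """Split member references into in-library integer keys and
        external (USI-shaped string) references."""
        internal: list[int] = []
        external: list[str] = []
        for attr in self.attributes:
            if attr.accession != "MS:1003267":
                continue
            for token in str(attr.value).split():
                if token.isdigit():
                    internal.append(int(token))
                else:
                    external.append(token)
        return internal, external


@dataclass
class Library:
    header_attributes: list[Attribute] = field(default_factory=list)
    # scope -> set name -> attributes
    attribute_sets: dict[str, dict[str, list[Attribute]]] = field(
        default_factory=dict
    )
    clusters: list[Cluster] = field(default_factory=list)
    spectra: list[Spectrum] = field(default_factory=list)

    def spectrum_by_key(self, key: int) -> Spectrum:
        for s in self.spectra:
            if s.key == key:
                return s
        raise KeyError(f"no spectrum with key {key}")


# ---------------------------------------------------------------------------
# Attribute-set cascade


def _override(effective: list[Attribute], incoming: list[Attribute]) -> list[Attribute]:
    """Apply one source on top of the current effective list.

    Same-accession attributes are replaced (whole groups move together)
    unless the accession accumulates.
    """
    incoming_accessions = {
        a.accession for a in incoming
        if a.accession not in ACCUMULATING_ACCESSIONS
    }
    # groups to drop: any group containing a replaced accession
    doomed_groups = {
        a.group_id for a in effective
        if a.group_id is not None and a.accession in incoming_accessions
    }
    kept = [
        a for a in effective
        if a.accession not in incoming_accessions and a.group_id not in doomed_groups
    ]
    return kept + list(incoming)


def _renumber_groups(attrs: list[Attribute]) -> list[Attribute]:
    """Renumber group ids sequentially in first-seen order so ids from
    different cascade sources cannot collide in the effective list."""
    seen: dict[int, int] = {}
    out = []
    for a in attrs:
        if a.group_id is None:
            out.append(a)
        else:
            if a.group_id not in seen:
                seen[a.group_id] = len(seen) + 1
            out.append(replace(a, group_id=seen[a.group_id], raw=None))
    return out


def resolve_attributes(
    entity: Union[Spectrum, Analyte, Interpretation, Cluster],
    library: Library,
) -> list[Attribute]:
    """Effective attributes of an entity after the attribute-set cascade.

    Sources, in order: the scope's implicit ``all`` set, the entity's named
    set references (Spectrum entities only), then the entity's own
    attributes; later sources override earlier ones.  Idempotent and
    order-stable.
    """
    scope = type(entity).__name__
    if scope not in SCOPES:
        raise TypeError(f"{scope} entities carry no attribute sets")
    sets = library.attribute_sets.get(scope, {})
    effective: list[Attribute] = []
    if "all" in sets:
        effective = _override(effective, sets["all"])
    for name in getattr(entity, "attribute_set_refs", []):
        if name == "all":
            continue
        if name not in sets:
            raise KeyError(f"unknown {scope} attribute set {name!r}")
        effective = _override(effective, sets[name])
    own = [a for a in entity.attributes if a.accession != ATTRIBUTE_SET_REF_ACCESSION]
    effective = _override(effective, own)
    return _renumber_groups(effective)


# ---------------------------------------------------------------------------
# Validation


def validate_library(
    lib: Library,
    registry: Optional[dict[str, CvTerm]] = None,
) -> list[ValidationIssue]:
    """Structural validation of a whole library: key uniqueness, reference
    integrity, header completeness, peak ordering, CV conformance of every
    attribute context (when a registry is given)."""
    issues: list[ValidationIssue] = []

    def check_attrs(attrs: list[Attribute], context: str):
        if registry is not None:
            issues.extend(validate_attributes(attrs, registry, context))

    header_accessions = {a.accession for a in lib.header_attributes}
    if FORMAT_VERSION_ACCESSION not in header_accessions:
        issues.append(ValidationIssue(
            "warning", "Library", "header lacks a library format version"
        ))
    if LIBRARY_NAME_ACCESSION not in header_accessions:
        issues.append(ValidationIssue(
            "warning", "Library", "header lacks a library name"
        ))
    check_attrs(lib.header_attributes, "Library")

    for scope, sets in lib.attribute_sets.items():
        if scope not in SCOPES:
            issues.append(ValidationIssue(
                "error", "Library", f"unknown attribute-set scope {scope!r}"
            ))
        for name, attrs in sets.items():
            check_attrs(attrs, f"AttributeSet {scope}={name}")

    spectrum_keys = set()
    for spectrum in lib.spectra:
        ctx = f"Spectrum={spectrum.key}"
        if spectrum.key in spectrum_keys:
            issues.append(ValidationIssue(
                "error", ctx, f"duplicate spectrum key {spectrum.key}"
            ))
        spectrum_keys.add(spectrum.key)
        check_attrs(spectrum.attributes, ctx)
        for name in spectrum.attribute_set_refs:
            if name != "all" and name not in lib.attribute_sets.get("Spectrum", {}):
                issues.append(ValidationIssue(
                    "error", ctx, f"references unknown attribute set {name!r}"
                ))
        peptidoform_counts = {}
        for analyte in spectrum.analytes.values():
            actx = f"{ctx}/Analyte={analyte.id}"
            check_attrs(analyte.attributes, actx)
            n = sum(1 for a in analyte.attributes
                    if a.accession in PEPTIDOFORM_ACCESSIONS)
            if n > 1:
                issues.append(ValidationIssue(
                    "error", actx, "multiple peptidoform attributes on one analyte"
                ))
            peptidoform_counts[analyte.id] = n
        for interp in spectrum.interpretations.values():
            ictx = f"{ctx}/Interpretation={interp.id}"
            check_attrs(interp.attributes, ictx)
            for member_id, member_attrs in interp.members.items():
                if member_id not in spectrum.analytes:
                    issues.append(ValidationIssue(
                        "error", ictx,
                        f"member references missing analyte {member_id}",
                    ))
                check_attrs(member_attrs, f"{ictx}/Member={member_id}")
            if spectrum.analytes and not interp.members:
                issues.append(ValidationIssue(
                    "warning", ictx, "interpretation lists no members"
                ))
        if not spectrum.was_sorted:
            issues.append(ValidationIssue(
                "warning", ctx, "peaks were not sorted by m/z in the source"
            ))
        mzs = [p.mz for p in spectrum.peaks]
        if any(b < a for a, b in zip(mzs, mzs[1:])):
            issues.append(ValidationIssue(
                "warning", ctx, "peaks out of m/z order in memory"
            ))

    cluster_keys = set()
    for cluster in lib.clusters:
        ctx = f"Cluster={cluster.key}"
        if cluster.key in cluster_keys:
            issues.append(ValidationIssue(
                "error", ctx, f"duplicate cluster key {cluster.key}"
            ))
        cluster_keys.add(cluster.key)
        check_attrs(cluster.attributes, ctx)
        internal, _external = cluster.member_keys()
        for key in internal:
            if key not in spectrum_keys:
                issues.append(ValidationIssue(
                    "error", ctx, f"member references missing spectrum {key}"
                ))
    return issues


# ---------------------------------------------------------------------------
# Merge / subset


def _shift_cluster_members(cluster: Cluster, offset: int) -> Cluster:
    out = copy.deepcopy(cluster)
    for i, attr in enumerate(out.attributes):
        if attr.accession != "MS:1003267":
            continue
        tokens = [
            str(int(t) + offset) if t.isdigit() else t
            for t in str(attr.value).split()
        ]
        out.attributes[i] = replace(attr, value=" ".join(tokens), raw=None)
    return out


def merge_libraries(a: Library, b: Library) -> Library:
    """Merge two libraries.

    Spectrum and cluster keys of ``b`` are shifted past the maxima of ``a``
    so merged keys never collide; intra-library cluster references follow.
    Attribute sets of ``b`` whose names collide with differently valued sets
    of ``a`` are materialized (inlined) into the affected spectra of ``b``
    rather than silently redefined.
    """
    out = copy.deepcopy(a)
    b = copy.deepcopy(b)

    spectrum_offset = max((s.key for s in a.spectra), default=0)
    cluster_offset = max((c.key for c in a.clusters), default=0)

    # attribute sets: keep equal ones, inline colliding-but-different ones
    inlined: dict[str, set[str]] = {}
    for scope, sets in b.attribute_sets.items():
        for name, attrs in sets.items():
            ours = out.attribute_sets.get(scope, {}).get(name)
            theirs_norm = [x.without_raw() for x in attrs]
            if ours is None:
                out.attribute_sets.setdefault(scope, {})[name] = attrs
            elif [x.without_raw() for x in ours] != theirs_norm:
                inlined.setdefault(scope, set()).add(name)

    for spectrum in b.spectra:
        spectrum.key += spectrum_offset
        doomed = inlined.get("Spectrum", set())
        if doomed & set(spectrum.attribute_set_refs):
            extra: list[Attribute] = []
            for name in spectrum.attribute_set_refs:
                if name in doomed:
                    extra = _override(extra, b.attribute_sets["Spectrum"][name])
            spectrum.attribute_set_refs = [
                n for n in spectrum.attribute_set_refs if n not in doomed
            ]
            spectrum.attributes = _override(extra, spectrum.attributes)
        out.spectra.append(spectrum)
    for cluster in b.clusters:
        shifted = _shift_cluster_members(cluster, spectrum_offset)
        shifted.key += cluster_offset
        out.clusters.append(shifted)
    return out


def subset_library(lib: Library, keys: list[int]) -> tuple[Library, list[ValidationIssue]]:
    """Keep only the spectra with the given keys.

    Referenced attribute sets are retained; clusters whose members are all
    removed are dropped, and partially emptied clusters are retained with a
    warning issue.
    """
    wanted = set(keys)
    out = Library(
        header_attributes=copy.deepcopy(lib.header_attributes),
        attribute_sets={},
        clusters=[],
        spectra=[copy.deepcopy(s) for s in lib.spectra if s.key in wanted],
    )
    issues: list[ValidationIssue] = []

    referenced: dict[str, set[str]] = {scope: {"all"} for scope in SCOPES}
    for spectrum in out.spectra:
        referenced["Spectrum"].update(spectrum.attribute_set_refs)
    for scope, sets in lib.attribute_sets.items():
        kept = {
            name: copy.deepcopy(attrs) for name, attrs in sets.items()
            if name in referenced.get(scope, {"all"}) or scope != "Spectrum"
        }
        if kept:
            out.attribute_sets[scope] = kept

    for cluster in lib.clusters:
        internal, external = cluster.member_keys()
        surviving = [k for k in internal if k in wanted]
        if not surviving and not external:
            continue
        out.clusters.append(copy.deepcopy(cluster))
        if len(surviving) < len(internal):
            issues.append(ValidationIssue(
                "warning", f"Cluster={cluster.key}",
                f"subset removed {len(internal) - len(surviving)} of "
                f"{len(internal)} member spectra",
            ))
    return out, issues
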