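"""The Namespace abstraction and platform-annotation consistency curation.

A *namespace* is any source of (name, mature sequence) pairs: a
species-scoped repository release, or a vendor profiling platform.  Both
reduce to the same bidirectional lookup structure, which is what makes
all four pairwise translation directions (platform↔platform,
platform↔release, release↔release) a single code path downstream.

Within one namespace a name must map to exactly one sequence; the reverse
is not true — paralogous precursors can yield byte-identical matures, so a
sequence legitimately carries several names (reported downstream with the
"multiple" status).  A name claiming two different sequences is a data
defect (typically a vendor design or annotation error) and is surfaced as
a curation finding rather than silently resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotation_model import Platform, Release, normalize_sequence
from .errors import UnknownNamespaceError

__all__ = [
    "Namespace",
    "CurationFinding",
    "build_namespace_from_release",
    "build_namespace_from_platform",
    "namespace_for_version",
    "curate_platform",
    "lookup_names",
]


@dataclass
class Namespace:
    """Bidirectional (name ↔ normalized mature sequence) lookup.

    ``seq_to_names`` values are lexicographically sorted for deterministic
    output.  ``seq_to_accessions`` and ``dead_ids`` are populated only for
    release-backed namespaces (vendor files rarely carry MIMAT accessions);
    they are what allows the "dead" status to be distinguished from plain
    "missing" downstream.
    """

    label: str
    kind: str  # "release" | "platform"
    name_to_seq: dict[str, str] = field(default_factory=dict)
    seq_to_names: dict[str, tuple[str, ...]] = field(default_factory=dict)
    seq_to_accessions: dict[str, frozenset[str]] = field(default_factory=dict)
    dead_ids: frozenset[str] = frozenset()
    source_version: str = "unknown"
    warnings: tuple[str, ...] = ()
    conflicts: tuple["CurationFinding", ...] = ()

    def __len__(self) -> int:
        return len(self.name_to_seq)

    @property
    def sequences(self) -> frozenset[str]:
        return frozenset(self.seq_to_names)


@dataclass(frozen=True)
class CurationFinding:
    """One probe-level inconsistency found while curating a platform."""

    probe_id: str
    finding_kind: str  # name_sequence_mismatch | unknown_name | duplicate_probe_name | control_excluded
    detail: str
    expected_sequence: str = ""
    observed_sequence: str = ""


def build_namespace_from_release(release: Release, species: str) -> Namespace:
    """Species-scoped namespace over one release's mature records.

    An absent species yields an empty namespace carrying a warning rather
    than an error: downstream callers treat it as "nothing to translate".
    """
    label = f"mirbase:{release.version_label}:{species}"
    ns = Namespace(label=label, kind="release", source_version=release.version_label,
                   dead_ids=release.dead_ids)
    if species not in release.species_set:
        ns.warnings = (f"species {species!r} absent from release {release.version_label}",)
        return ns
    seq_names: dict[str, set[str]] = {}
    seq_accs: dict[str, set[str]] = {}
    for rec in release.records:
        if rec.species != species:
            continue
        ns.name_to_seq[rec.name] = rec.sequence
        seq_names.setdefault(rec.sequence, set()).add(rec.name)
        seq_accs.setdefault(rec.sequence, set()).add(rec.mimat_id)
    ns.seq_to_names = {s: tuple(sorted(n)) for s, n in seq_names.items()}
    ns.seq_to_accessions = {s: frozenset(a) for s, a in seq_accs.items()}
    return ns


def namespace_for_version(index, version_label: str, species: str) -> Namespace:
    """Resolve a namespace by version label within a loaded release series."""
    try:
        release = index.get(version_label)
    except KeyError:
        raise UnknownNamespaceError(
            f"version {version_label!r} not loaded (have {list(index.labels)})"
        ) from None
    return build_namespace_from_release(release, species)


def build_namespace_from_platform(platform: Platform) -> Namespace:
    """Namespace over a platform's non-control probes.

    Duplicate (name, sequence) probes collapse to one entry.  A name carried
    by probes with *different* sequences is contradictory — a name cannot
    denote two matures — so neither entry is kept and the contradiction is
    recorded in ``conflicts``.
    """
    ns = Namespace(
        label=f"platform:{platform.platform_id}",
        kind="platform",
        source_version=platform.design_version,
    )
    name_seqs: dict[str, dict[str, list[str]]] = {}  # name -> seq -> probe_ids
    for p in platform.probes:
        if p.is_control:
            continue
        seq = normalize_sequence(p.target_sequence)
        name_seqs.setdefault(p.reported_name, {}).setdefault(seq, []).append(p.probe_id)
    conflicts: list[CurationFinding] = []
    seq_names: dict[str, set[str]] = {}
    for name, seqs in name_seqs.items():
        if len(seqs) > 1:
            for seq, probe_ids in sorted(seqs.items()):
                for pid in probe_ids:
                    conflicts.append(
                        CurationFinding(
                            probe_id=pid,
                            finding_kind="duplicate_probe_name",
                            detail=f"name {name!r} maps to {len(seqs)} distinct sequences",
                            observed_sequence=seq,
                        )
                    )
            continue
        (seq,) = seqs
        ns.name_to_seq[name] = seq
        seq_names.setdefault(seq, set()).add(name)
    ns.seq_to_names = {s: tuple(sorted(n)) for s, n in seq_names.items()}
    ns.conflicts = tuple(conflicts)
    return ns


def curate_platform(platform: Platform, reference: Namespace) -> list[CurationFinding]:
    """Check name↔sequence consistency of a platform against its design release.

    For each non-control probe the reported name is looked up in the
    reference release namespace:

    * found, equal sequence → consistent, no finding;
    * found, different sequence → ``name_sequence_mismatch`` (a design or
      annotation error: the probe does not detect what its name claims);
    * not found → ``unknown_name``;
    * the same name on probes with different sequences →
      ``duplicate_probe_name``;
    * control probes → ``control_excluded`` (bookkeeping, not a defect).
    """
    if reference.kind != "release":
        raise ValueError("curation reference must be a release namespace")
    findings: list[CurationFinding] = []
    name_seqs: dict[str, set[str]] = {}
    for p in platform.probes:
        if not p.is_control:
            name_seqs.setdefault(p.reported_name, set()).add(
                normalize_sequence(p.target_sequence)
            )
    for p in platform.probes:
        if p.is_control:
            findings.append(
                CurationFinding(
                    probe_id=p.probe_id,
                    finding_kind="control_excluded",
                    detail=f"control probe {p.reported_name!r} excluded from mapping",
                )
            )
            continue
        observed = normalize_sequence(p.target_sequence)
        if len(name_seqs[p.reported_name]) > 1:
            findings.append(
                CurationFinding(
                    probe_id=p.probe_id,
                    finding_kind="duplicate_probe_name",
                    detail=f"name {p.reported_name!r} borne by probes with differing sequences",
                    observed_sequence=observed,
                )
            )
            continue
        expected = reference.name_to_seq.get(p.reported_name)
        if expected is None:
            findings.append(
                CurationFinding(
                    probe_id=p.probe_id,
                    finding_kind="unknown_name",
                    detail=f"name {p.reported_name!r} absent from {reference.label}",
                    observed_sequence=observed,
                )
            )
        elif expected != observed:
            findings.append(
                CurationFinding(
                    probe_id=p.probe_id,
                    finding_kind="name_sequence_mismatch",
                    detail=f"probe sequence disagrees with {reference.label} for {p.reported_name!r}",
                    expected_sequence=expected,
                    observed_sequence=observed,
                )
            )
    return findings


def lookup_names(ns: Namespace, sequence: str) -> tuple[str, ...]:
    """All names the namespace attaches to a mature sequence (sorted, possibly empty)."""
    return ns.seq_to_names.get(normalize_sequence(sequence), ())
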