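"""Domain model for miRBase-style release snapshots and profiling platforms.

A *mature* miRNA — the short processed RNA actually detected by microarray
and RT-qPCR probes — is the unit of identity throughout this package.  Each
mature entry carries a stable MIMAT accession, a (species-prefixed) name, a
mature sequence over {A,C,G,U}, and one or more hairpin precursor (MI)
accessions.  Names drift between repository releases while the sequence is
the reproducible handle, so all cross-release and cross-platform mapping
downstream is keyed on the normalized full-length mature sequence.

Validation is deliberately split from construction: :func:`validate_release`
returns violation descriptors as data, so that defective vendor or release
files can be inspected rather than aborting the load.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import InvalidSequenceError

__all__ = [
    "MatureRecord",
    "Release",
    "VersionIndex",
    "Probe",
    "Platform",
    "Violation",
    "normalize_sequence",
    "validate_release",
    "derive_arm",
    "species_from_name",
]

_RNA_ALPHABET = set("ACGU")
_INPUT_ALPHABET = set("ACGUTacgut \t\r\n")
_MIMAT_RE = re.compile(r"^MIMAT\d+$")
_MI_RE = re.compile(r"^MI\d+$")
_SPECIES_RE = re.compile(r"^([a-z]{3,4})-")


def normalize_sequence(raw: str) -> str:
    """Normalize a mature sequence to uppercase RNA.

    Uppercases, converts the DNA alphabet (T) to RNA (U) and strips all
    whitespace.  Vendor annotation files frequently ship probe targets in
    DNA; release files ship RNA.  Idempotent by construction.

    Raises
    ------
    InvalidSequenceError
        If any character falls outside {A,C,G,U,T} (case-insensitive)
        or whitespace.
    """
    for ch in raw:
        if ch not in _INPUT_ALPHABET:
            raise InvalidSequenceError(
                f"invalid character {ch!r} in sequence {raw.strip()!r}"
            )
    seq = "".join(raw.split()).upper().replace("T", "U")
    if not seq:
        raise InvalidSequenceError("empty sequence after normalization")
    return seq


def derive_arm(name: str) -> str:
    """Arm of the hairpin the mature derives from, read off the name suffix.

    Returns ``"5p"``, ``"3p"`` or ``"unspecified"``.  Pre-v17 miRBase names
    frequently lack an arm suffix, hence the third value.
    """
    if name.endswith("-5p"):
        return "5p"
    if name.endswith("-3p"):
        return "3p"
    return "unspecified"


def species_from_name(name: str) -> str | None:
    """Three/four-letter organism prefix of a miRNA name, or None."""
    m = _SPECIES_RE.match(name)
    return m.group(1) if m else None


@dataclass(frozen=True)
class MatureRecord:
    """One mature miRNA in one release snapshot."""

    mimat_id: str
    name: str
    sequence: str
    species: str
    precursor_ids: frozenset[str] = frozenset()
    arm: str = "unspecified"
    length: int = 0

    @classmethod
    def create(
        cls,
        mimat_id: str,
        name: str,
        sequence: str,
        species: str | None = None,
        precursor_ids=(),
    ) -> "MatureRecord":
        """Build a record, normalizing the sequence and deriving arm/length/species."""
        seq = normalize_sequence(sequence)
        sp = species or species_from_name(name)
        if sp is None:
            raise ValueError(f"cannot derive species for unprefixed name {name!r}")
        return cls(
            mimat_id=mimat_id,
            name=name,
            sequence=seq,
            species=sp,
            precursor_ids=frozenset(precursor_ids),
            arm=derive_arm(name),
            length=len(seq),
        )


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_release`."""

    record_id: str
    rule: str
    message: str


@dataclass
class Release:
    """A single release snapshot: live mature records plus retired accessions."""

    version_label: str
    records: tuple[MatureRecord, ...]
    dead_ids: frozenset[str] = frozenset()

    @property
    def species_set(self) -> frozenset[str]:
        return frozenset(r.species for r in self.records)

    def by_accession(self) -> dict[str, MatureRecord]:
        return {r.mimat_id: r for r in self.records}


@dataclass
class VersionIndex:
    """An ordered series of release snapshots, oldest first.

    Version labels are opaque strings; ordering is the explicit list order,
    never numeric parsing (miRBase labels mix "10.1" and "21").
    """

    releases: tuple[Release, ...]

    def __post_init__(self) -> None:
        labels = [r.version_label for r in self.releases]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate version labels in index: {labels}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(r.version_label for r in self.releases)

    def __iter__(self):
        return iter(self.releases)

    def __len__(self) -> int:
        return len(self.releases)

    def get(self, version_label: str) -> Release:
        for r in self.releases:
            if r.version_label == version_label:
                return r
        raise KeyError(version_label)

    def position(self, version_label: str) -> int:
        for i, r in enumerate(self.releases):
            if r.version_label == version_label:
                return i
        raise KeyError(version_label)


@dataclass(frozen=True)
class Probe:
    """One vendor probe: platform-local id, reported name, target sequence."""

    probe_id: str
    reported_name: str
    target_sequence: str
    is_control: bool = False


@dataclass
class Platform:
    """A commercial detection probe set referencing some annotation release.

    ``design_version`` is the release label the vendor annotation referenced;
    vendors often do not state it, in which case it is ``"unknown"``.
    Control/housekeeping probes are carried but excluded from all
    sequence-keyed mapping.
    """

    platform_id: str
    vendor: str
    probes: tuple[Probe, ...]
    design_version: str = "unknown"
    species_scope: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        ids = [p.probe_id for p in self.probes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate probe_id within platform: {dupes}")
        if not self.species_scope:
            scope = set()
            for p in self.probes:
                if not p.is_control:
                    sp = species_from_name(p.reported_name)
                    if sp:
                        scope.add(sp)
            self.species_scope = frozenset(scope)


def validate_release(release: Release) -> list[Violation]:
    """Check every release and per-record invariant; empty list means valid.

    Violations are data, not exceptions: a report identifies the offending
    record (by accession) and the rule it breaks.
    """
    out: list[Violation] = []
    seen_mimat: set[str] = set()
    seen_name: set[tuple[str, str]] = set()
    for rec in release.records:
        rid = rec.mimat_id
        if not _MIMAT_RE.match(rid):
            out.append(Violation(rid, "accession_pattern", f"bad MIMAT accession {rid!r}"))
        if rid in seen_mimat:
            out.append(Violation(rid, "mimat_unique", f"duplicate accession {rid!r}"))
        seen_mimat.add(rid)
        if rid in release.dead_ids:
            out.append(Violation(rid, "dead_conflict", f"{rid!r} both live and dead"))
        key = (rec.species, rec.name)
        if key in seen_name:
            out.append(Violation(rid, "name_unique", f"duplicate (species, name) {key!r}"))
        seen_name.add(key)
        if set(rec.sequence) - _RNA_ALPHABET:
            out.append(Violation(rid, "alphabet", f"non-RNA characters in {rec.sequence!r}"))
        if rec.length != len(rec.sequence):
            out.append(
                Violation(
                    rid,
                    "length",
                    f"length field {rec.length} != sequence length {len(rec.sequence)}",
                )
            )
        prefix = species_from_name(rec.name)
        if prefix is not None and prefix != rec.species:
            out.append(
                Violation(rid, "species_prefix", f"name prefix {prefix!r} != species {rec.species!r}")
            )
        expected_arm = derive_arm(rec.name)
        if rec.arm != expected_arm:
            out.append(Violation(rid, "arm", f"arm {rec.arm!r}, name implies {expected_arm!r}"))
        for mi in rec.precursor_ids:
            if not _MI_RE.match(mi):
                out.append(Violation(rid, "precursor_pattern", f"bad MI accession {mi!r}"))
    return out
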