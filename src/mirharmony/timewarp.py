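"""Name-history reconstruction across an ordered series of releases.

Unlike the sequence-keyed translation machinery, history is keyed on the
MIMAT accession: names *and* sequences both change between releases, and
the accession is the repository's stable handle for "the same entry".

For each accession ever observed, a :class:`Track` records introduction,
renames, sequence revisions, deletion, and possible reinstatement, in
release order, plus the name it bore at every loaded release.  Queries can
be stringent (exact whole-name equality against any name the entry ever
bore) or relaxed (case-insensitive substring containment), optionally
scoped to one species and to a starting release.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotation_model import Platform, VersionIndex, normalize_sequence
from .errors import UnknownVersionError

__all__ = [
    "HistoryEvent",
    "Track",
    "build_history",
    "time_warp_query",
    "detecting_platforms",
]


@dataclass(frozen=True)
class HistoryEvent:
    """One change to one accession at one release."""

    version_label: str
    kind: str  # introduced | renamed | deleted | sequence_changed
    old_name: str = ""
    new_name: str = ""
    sequence_at_version: str = ""


@dataclass
class Track:
    """Full name history of one accession across the loaded series.

    ``pre_series`` marks entries already alive in the earliest loaded
    release: their ``introduced`` event is relative to the series, not to
    the repository's actual first appearance.  ``current_name`` is empty
    iff the entry is deleted and never reinstated; ``name_by_version``
    holds the name at each loaded release, ``None`` before introduction or
    while dead.
    """

    mimat_id: str
    mi_ids: frozenset[str]
    species: str
    events: list[HistoryEvent] = field(default_factory=list)
    current_name: str = ""
    current_sequence: str = ""
    arm: str = "unspecified"
    length: int = 0
    pre_series: bool = False
    name_by_version: dict[str, str | None] = field(default_factory=dict)

    @property
    def alive(self) -> bool:
        return bool(self.current_name)

    def names_ever(self, versions: tuple[str, ...] | None = None) -> set[str]:
        """All names borne at the given releases (default: all loaded)."""
        if versions is None:
            versions = tuple(self.name_by_version)
        return {
            n for v in versions
            if (n := self.name_by_version.get(v)) is not None
        }


def build_history(index: VersionIndex, species: str = "all") -> dict[str, Track]:
    """Reconstruct a Track for every accession ever observed in the series.

    Renames are detected as same accession / different name between
    consecutive loaded releases, sequence revisions as same accession /
    different sequence, deletions as presence → absence (or dead-list
    membership).  An accession absent from an intermediate release but
    present later is deleted-then-reinstated — two events reflecting what
    the loaded snapshots literally say — with a note-worthy second
    ``introduced`` event rather than a silent gap.
    """
    tracks: dict[str, Track] = {}
    prev_alive: dict[str, tuple[str, str]] = {}  # acc -> (name, seq) in previous release
    for pos, release in enumerate(index):
        cur: dict[str, tuple[str, str]] = {}
        for rec in release.records:
            if species != "all" and rec.species != species:
                continue
            cur[rec.mimat_id] = (rec.name, rec.sequence)
            tr = tracks.get(rec.mimat_id)
            if tr is None:
                tr = Track(
                    mimat_id=rec.mimat_id,
                    mi_ids=rec.precursor_ids,
                    species=rec.species,
                    pre_series=(pos == 0),
                )
                tracks[rec.mimat_id] = tr
            tr.mi_ids = tr.mi_ids | rec.precursor_ids
            if rec.mimat_id not in prev_alive:
                tr.events.append(
                    HistoryEvent(release.version_label, "introduced",
                                 new_name=rec.name, sequence_at_version=rec.sequence)
                )
            else:
                old_name, old_seq = prev_alive[rec.mimat_id]
                if rec.name != old_name:
                    tr.events.append(
                        HistoryEvent(release.version_label, "renamed",
                                     old_name=old_name, new_name=rec.name,
                                     sequence_at_version=rec.sequence)
                    )
                if rec.sequence != old_seq:
                    tr.events.append(
                        HistoryEvent(release.version_label, "sequence_changed",
                                     old_name=old_name, new_name=rec.name,
                                     sequence_at_version=rec.sequence)
                    )
            tr.current_name = rec.name
            tr.current_sequence = rec.sequence
            tr.arm = rec.arm
            tr.length = rec.length
        # deletions: alive previously, absent (or dead-listed) now
        for acc, (old_name, _old_seq) in prev_alive.items():
            if acc not in cur:
                tracks[acc].events.append(
                    HistoryEvent(release.version_label, "deleted", old_name=old_name)
                )
        # record per-version names
        for acc, tr in tracks.items():
            tr.name_by_version[release.version_label] = (
                cur[acc][0] if acc in cur else None
            )
        prev_alive = cur
    # an entry dead at the end of the series has no current name
    for acc, tr in tracks.items():
        if acc not in prev_alive:
            tr.current_name = ""
    return tracks


def time_warp_query(
    index: VersionIndex,
    query: str,
    stringent: bool = True,
    species: str = "all",
    start_version: str | None = None,
    history: dict[str, Track] | None = None,
) -> list[Track]:
    """Find tracks whose names (at or after ``start_version``) match the query.

    Stringent mode requires exact whole-name equality against any name the
    entry ever bore in the considered window; an unprefixed query (e.g.
    "miR-21") matches with the selected species' prefix injected, or with
    any prefix when ``species == "all"``.  Relaxed mode retrieves every
    name containing the query string, case-insensitively.
    """
    if start_version is not None:
        try:
            start = index.position(start_version)
        except KeyError:
            raise UnknownVersionError(
                f"version {start_version!r} not in loaded series {list(index.labels)}"
            ) from None
    else:
        start = 0
    window = index.labels[start:]
    if history is None:
        history = build_history(index, species="all")
    needle = query.strip()
    out: list[Track] = []
    for acc in sorted(history):
        tr = history[acc]
        if species != "all" and tr.species != species:
            continue
        names = tr.names_ever(window)
        if not names:
            continue
        if stringent:
            hit = needle in names
            if not hit and not needle.startswith(f"{tr.species}-"):
                # unprefixed query: inject the selected species' prefix,
                # or strip any prefix when searching all species
                if species != "all":
                    hit = f"{species}-{needle}" in names
                else:
                    hit = any(n.split("-", 1)[-1] == needle for n in names)
        else:
            low = needle.lower()
            hit = any(low in n.lower() for n in names)
        if hit:
            out.append(tr)
    return out


def detecting_platforms(track: Track, registry: list[Platform]) -> tuple[list[str], str]:
    """Platform ids whose probes target the track's current mature sequence.

    Matching is exact on the normalized sequence, control probes excluded,
    and species-respecting (a platform scoped to other species is skipped).
    Returns (sorted platform ids, note); a deleted track detects nothing.
    """
    if not track.alive:
        return [], f"{track.mimat_id} is deleted; no current sequence to detect"
    hits: list[str] = []
    for platform in registry:
        if platform.species_scope and track.species not in platform.species_scope:
            continue
        for p in platform.probes:
            if p.is_control:
                continue
            if normalize_sequence(p.target_sequence) == track.current_sequence:
                hits.append(platform.platform_id)
                break
    return sorted(hits), ""
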