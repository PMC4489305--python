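"""Deterministic synthetic fixtures: release series, platforms, matrices.

The generator emits an ordered series of release snapshots together with
the *scripted event log* that produced it — the ground truth that history
reconstruction and translation are tested against.  Synthetic sequences
are uniform random over {A,C,G,U} with lengths 19–25 nt (the length range
of mature miRNAs); sequence collisions — distinct accessions bearing an
identical mature — are constructed by copying, never left to chance, since
chance collisions among random 22-mers are negligible and tests need
scripted ones.

The synthetic species code is "syn" so fixtures can never be mistaken for
real annotation.  All generators are byte-stable under a fixed seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .annotation_model import MatureRecord, Platform, Probe, Release, VersionIndex
from .errors import FixtureSpecError
from .namespace_engine import Namespace
from .rosetta import ExpressionMatrix

__all__ = [
    "ScriptedEvent",
    "FixtureSpec",
    "PlatformSpec",
    "generate_series",
    "apply_events",
    "derive_platform",
    "generate_matrix",
    "toy3",
]

_DEFAULT_RATES = {"rename": 0.12, "delete": 0.06, "add": 0.12, "sequence_change": 0.04}


@dataclass(frozen=True)
class ScriptedEvent:
    """Ground-truth record of one change the generator applied."""

    version_label: str
    kind: str  # add | rename | delete | sequence_change | collide
    accession: str
    old_name: str = ""
    new_name: str = ""
    sequence: str = ""
    precursor_id: str = ""  # populated for add/collide so replay is exact


@dataclass(frozen=True)
class PlatformSpec:
    """Recipe for one synthetic platform derived from a release."""

    platform_id: str
    design_version: str
    n_probes: int
    n_injected_mismatches: int = 0
    n_controls: int = 0
    vendor: str = "SynVendor"


@dataclass
class FixtureSpec:
    """Recipe for a synthetic release series.

    ``event_rates`` are per-record probabilities applied independently at
    each version step (``add`` is the per-slot probability of a new entry,
    with as many slots as initial records).  ``n_collisions`` scripted
    sequence collisions are injected into the final release.
    """

    seed: int = 0
    n_versions: int = 2
    n_initial_records: int = 10
    event_rates: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_RATES))
    n_collisions: int = 0
    species: str = "syn"
    platform_specs: list[PlatformSpec] = field(default_factory=list)

    def validate(self) -> None:
        if self.n_versions < 1:
            raise FixtureSpecError("n_versions must be >= 1")
        if self.n_initial_records < 1:
            raise FixtureSpecError("n_initial_records must be >= 1")
        if self.n_collisions < 0:
            raise FixtureSpecError("n_collisions must be >= 0")
        for kind, p in self.event_rates.items():
            if kind not in _DEFAULT_RATES:
                raise FixtureSpecError(f"unknown event kind {kind!r}")
            if not 0.0 <= p <= 1.0:
                raise FixtureSpecError(f"rate for {kind!r} out of [0,1]: {p}")
        if self.n_collisions > self.n_initial_records:
            raise FixtureSpecError(
                "cannot script more collisions than initial records to copy from"
            )


def _random_sequence(rng: random.Random) -> str:
    return "".join(rng.choice("ACGU") for _ in range(rng.randint(19, 25)))


def _new_name(species: str, idx: int, rng: random.Random) -> str:
    arm = rng.choice(("-5p", "-3p", ""))
    return f"{species}-miR-{idx}{arm}"


def _renamed(name: str) -> str:
    """Bump a name's paralog letter, e.g. syn-miR-2-3p → syn-miR-2b-3p."""
    parts = name.split("-")
    # parts like ["syn","miR","2","3p"] or ["syn","miR","2"]
    core = parts[2]
    digits = core.rstrip("abcdefgh")
    letter = core[len(digits):]
    nxt = "b" if not letter else chr(ord(letter[-1]) + 1)
    parts[2] = digits + nxt
    return "-".join(parts)


class _SeriesBuilder:
    def __init__(self, species: str, rng: random.Random) -> None:
        self.species = species
        self._rng = rng
        self.alive: dict[str, MatureRecord] = {}
        self.dead: set[str] = set()
        self.next_acc = 1
        self.next_mi = 1
        self.next_idx = 1
        self.releases: list[Release] = []
        self.events: list[ScriptedEvent] = []

    def fresh_accession(self) -> str:
        acc = f"MIMAT{self.next_acc:07d}"
        self.next_acc += 1
        return acc

    def fresh_precursor(self) -> str:
        mi = f"MI{self.next_mi:07d}"
        self.next_mi += 1
        return mi

    def add(self, version: str, sequence: str, name: str | None = None,
            kind: str = "add") -> MatureRecord:
        if name is None:
            name = _new_name(self.species, self.next_idx, self._rng)
            self.next_idx += 1
        acc = self.fresh_accession()
        mi = self.fresh_precursor()
        rec = MatureRecord.create(acc, name, sequence, species=self.species,
                                  precursor_ids=(mi,))
        self.alive[acc] = rec
        self.events.append(ScriptedEvent(version, kind, acc, new_name=name,
                                         sequence=rec.sequence, precursor_id=mi))
        return rec

    def rename(self, version: str, acc: str) -> None:
        old = self.alive[acc]
        new_name = _renamed(old.name)
        taken = {r.name for r in self.alive.values()}
        while new_name in taken:
            new_name = _renamed(new_name)
        self.alive[acc] = MatureRecord.create(
            acc, new_name, old.sequence, species=old.species,
            precursor_ids=old.precursor_ids,
        )
        self.events.append(ScriptedEvent(version, "rename", acc,
                                         old_name=old.name, new_name=new_name,
                                         sequence=old.sequence))

    def delete(self, version: str, acc: str) -> None:
        old = self.alive.pop(acc)
        self.dead.add(acc)
        self.events.append(ScriptedEvent(version, "delete", acc, old_name=old.name))

    def change_sequence(self, version: str, acc: str, sequence: str) -> None:
        old = self.alive[acc]
        self.alive[acc] = MatureRecord.create(
            acc, old.name, sequence, species=old.species,
            precursor_ids=old.precursor_ids,
        )
        self.events.append(ScriptedEvent(version, "sequence_change", acc,
                                         old_name=old.name, new_name=old.name,
                                         sequence=self.alive[acc].sequence))

    def collide(self, version: str, source_acc: str) -> MatureRecord:
        """Add a new accession copying an existing record's mature sequence."""
        src = self.alive[source_acc]
        name = _renamed(src.name)
        taken = {r.name for r in self.alive.values()}
        while name in taken:
            name = _renamed(name)
        acc = self.fresh_accession()
        mi = self.fresh_precursor()
        rec = MatureRecord.create(acc, name, src.sequence, species=self.species,
                                  precursor_ids=(mi,))
        self.alive[acc] = rec
        self.events.append(ScriptedEvent(version, "collide", acc, new_name=name,
                                         sequence=src.sequence, precursor_id=mi))
        return rec

    def snapshot(self, version: str) -> None:
        records = tuple(sorted(self.alive.values(), key=lambda r: r.mimat_id))
        self.releases.append(
            Release(version_label=version, records=records,
                    dead_ids=frozenset(self.dead))
        )


def generate_series(spec: FixtureSpec) -> tuple[VersionIndex, list[ScriptedEvent]]:
    """Generate an ordered release series plus its ground-truth event log.

    The log describes exactly the differences between consecutive releases
    (initial records are logged as ``add`` events at the first release);
    replaying it with :func:`apply_events` reproduces each snapshot.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    b = _SeriesBuilder(spec.species, rng)
    labels = [f"v{i + 1}" for i in range(spec.n_versions)]

    for _ in range(spec.n_initial_records):
        b.add(labels[0], _random_sequence(rng))
    b.snapshot(labels[0])

    rates = {**_DEFAULT_RATES, **spec.event_rates}
    for label in labels[1:]:
        for acc in sorted(b.alive):
            r = rng.random()
            if r < rates["rename"]:
                b.rename(label, acc)
            elif r < rates["rename"] + rates["delete"]:
                if len(b.alive) > 1:  # never empty the release
                    b.delete(label, acc)
            elif r < rates["rename"] + rates["delete"] + rates["sequence_change"]:
                b.change_sequence(label, acc, _random_sequence(rng))
        for _ in range(spec.n_initial_records):
            if rng.random() < rates["add"]:
                b.add(label, _random_sequence(rng))
        if label == labels[-1]:
            sources = sorted(b.alive)
            if spec.n_collisions > len(sources):
                raise FixtureSpecError("not enough live records to collide with")
            for acc in rng.sample(sources, spec.n_collisions):
                b.collide(label, acc)
        b.snapshot(label)

    return VersionIndex(tuple(b.releases)), b.events


def apply_events(release: Release, events: list[ScriptedEvent],
                 version_label: str) -> Release:
    """Replay one version step's events on a snapshot (self-consistency check)."""
    alive = dict(release.by_accession())
    dead = set(release.dead_ids)
    for ev in events:
        if ev.version_label != version_label:
            continue
        if ev.kind in ("add", "collide"):
            alive[ev.accession] = MatureRecord.create(
                ev.accession, ev.new_name, ev.sequence,
                precursor_ids=(ev.precursor_id,) if ev.precursor_id else (),
            )
        elif ev.kind == "rename":
            old = alive[ev.accession]
            alive[ev.accession] = MatureRecord.create(
                ev.accession, ev.new_name, old.sequence, species=old.species,
                precursor_ids=old.precursor_ids,
            )
        elif ev.kind == "sequence_change":
            old = alive[ev.accession]
            alive[ev.accession] = MatureRecord.create(
                ev.accession, old.name, ev.sequence, species=old.species,
                precursor_ids=old.precursor_ids,
            )
        elif ev.kind == "delete":
            del alive[ev.accession]
            dead.add(ev.accession)
    records = tuple(sorted(alive.values(), key=lambda r: r.mimat_id))
    return Release(version_label=version_label, records=records,
                   dead_ids=frozenset(dead))


def derive_platform(
    release: Release, spec: PlatformSpec, seed: int
) -> tuple[Platform, list[tuple[str, str, str]]]:
    """Derive a synthetic platform from a release, with optional injected defects.

    Probes sample the release's (name, sequence) pairs verbatim; then
    ``n_injected_mismatches`` probes get the sequence of a *different*
    record swapped in (emulating vendor design/annotation errors), and
    ``n_controls`` control probes with non-miRNA names are appended.

    Returns the platform and the injection manifest: a list of
    ``(probe_id, expected_sequence, observed_wrong_sequence)`` tuples —
    the oracle that consistency curation is checked against.
    """
    rng = random.Random(seed)
    records = sorted(release.records, key=lambda r: r.mimat_id)
    if spec.n_probes > len(records):
        raise FixtureSpecError(
            f"platform wants {spec.n_probes} probes but release has {len(records)} records"
        )
    if spec.n_injected_mismatches > spec.n_probes:
        raise FixtureSpecError("cannot inject more mismatches than probes")
    chosen = rng.sample(records, spec.n_probes)
    probes: list[Probe] = []
    for i, rec in enumerate(chosen, start=1):
        probes.append(Probe(probe_id=f"{spec.platform_id}-{i:04d}",
                            reported_name=rec.name,
                            target_sequence=rec.sequence))
    manifest: list[tuple[str, str, str]] = []
    if spec.n_injected_mismatches:
        # need a donor sequence different from the victim's own
        victims = rng.sample(range(len(probes)), spec.n_injected_mismatches)
        for vi in victims:
            victim = probes[vi]
            donors = [r for r in records if r.sequence != victim.target_sequence]
            if not donors:
                raise FixtureSpecError("no donor sequence available for mismatch injection")
            wrong = rng.choice(donors).sequence
            manifest.append((victim.probe_id, victim.target_sequence, wrong))
            probes[vi] = Probe(probe_id=victim.probe_id,
                               reported_name=victim.reported_name,
                               target_sequence=wrong)
    for i in range(1, spec.n_controls + 1):
        probes.append(Probe(probe_id=f"{spec.platform_id}-ctrl-{i:02d}",
                            reported_name=f"spike-in-ctrl-{i}",
                            target_sequence=_random_sequence(rng),
                            is_control=True))
    platform = Platform(platform_id=spec.platform_id, vendor=spec.vendor,
                        probes=tuple(probes), design_version=spec.design_version)
    return platform, manifest


def generate_matrix(
    ns: Namespace, n_samples: int, seed: int, mu: float = 5.0, sigma: float = 1.0
) -> ExpressionMatrix:
    """Log-normal expression matrix over a namespace's names (one row each).

    Values are drawn from LogNormal(mu, sigma) — the canonical shape of
    hybridization intensities — reproducibly for a fixed seed.  Rows are
    the namespace's names in lexicographic order.
    """
    if not ns.name_to_seq:
        raise FixtureSpecError(f"namespace {ns.label} is empty; nothing to simulate")
    rng = random.Random(seed)
    names = sorted(ns.name_to_seq)
    samples = [f"S{i + 1}" for i in range(n_samples)]
    values = [
        [round(rng.lognormvariate(mu, sigma), 4) for _ in samples] for _ in names
    ]
    return ExpressionMatrix(row_names=names, sample_ids=samples, values=values)


def toy3() -> tuple[VersionIndex, list[ScriptedEvent]]:
    """The hand-scripted two-release mini series used throughout the tests.

    v1 holds three records (syn-miR-1-5p, syn-miR-2-3p, syn-miR-3); v2
    renames syn-miR-2-3p to syn-miR-2b-3p, retires syn-miR-3, and adds the
    scripted collision pair syn-miR-5a / syn-miR-5b sharing one mature
    sequence.
    """
    rng = random.Random(42)
    b = _SeriesBuilder("syn", rng)
    s1, s2, s3, s5 = (_random_sequence(rng) for _ in range(4))
    for name, seq in (("syn-miR-1-5p", s1), ("syn-miR-2-3p", s2), ("syn-miR-3", s3)):
        b.add("v1", seq, name=name)
    b.snapshot("v1")
    b.rename("v2", "MIMAT0000002")
    b.delete("v2", "MIMAT0000003")
    b.add("v2", s5, name="syn-miR-5a")
    acc_5a = max(b.alive)  # the accession just added
    b.collide("v2", acc_5a)
    b.snapshot("v2")
    return VersionIndex(tuple(b.releases)), b.events
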