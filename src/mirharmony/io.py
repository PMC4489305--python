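"""File formats: canonical release TSV, mature FASTA, platform CSV, matrices.

All tabular writers are byte-stable for a fixed input (no timestamps in
data files), and every reader/writer pair round-trips losslessly — the
fixture generator writes through these same functions, so the loaders are
exercised on every synthetic artifact.

Delimiters are sniffed from the extension: ``.csv`` comma, ``.tsv`` /
``.txt`` tab.  Version labels are opaque strings ordered by
``Config.version_order``; they are never parsed numerically because real
release labels mix forms like "10.1" and "21".
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .annotation_model import (
    MatureRecord,
    Platform,
    Probe,
    Release,
    VersionIndex,
    normalize_sequence,
)
from .errors import FormatError, InvalidSequenceError
from .rosetta import ExpressionMatrix, IntersectionResult, UpdatedMatrix, TranslationRow
from .timewarp import Track

__all__ = [
    "Config",
    "read_release_tsv",
    "write_release_tsv",
    "read_mature_fasta",
    "write_mature_fasta",
    "read_platform_csv",
    "write_platform_csv",
    "read_matrix",
    "write_matrix",
    "read_name_list",
    "write_translation_csv",
    "write_result",
    "write_overlap_csv",
    "write_intersection_csv",
    "write_tracks",
    "write_curation_csv",
    "load_version_dir",
]

#: miRBase release labels in chronological order (mixed label styles are
#: why ordering is explicit rather than numeric).
DEFAULT_VERSION_ORDER = (
    "10.0", "10.1", "11.0", "12.0", "13.0", "14.0",
    "15", "16", "17", "18", "19", "20", "21",
)

_RESULT_HEADER = [
    "input_name", "matched_sequence", "status",
    "output_names", "output_accessions", "note",
]

_RELEASE_COLUMNS = ["version", "species", "mi_ids", "mimat_id", "name", "sequence", "dead"]
_PLATFORM_COLUMNS = [
    "platform_id", "vendor", "design_version",
    "probe_id", "reported_name", "target_sequence", "is_control",
]
_MIMAT_TOKEN = re.compile(r"MIMAT\d+")


@dataclass
class Config:
    """User-tunable behaviour shared by the CLI and the writers."""

    version_order: tuple[str, ...] = DEFAULT_VERSION_ORDER
    default_species: str = "hsa"  # Homo sapiens, the default query species
    multi_name_delimiter: str = ";"
    failures_last: bool = False
    case_rescue: bool = True

    def __post_init__(self) -> None:
        if len(set(self.version_order)) != len(self.version_order):
            raise ValueError("version_order labels must be unique")


def _delimiter_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


# ---------------------------------------------------------------------------
# canonical release TSV

def read_release_tsv(path: str | Path) -> Release:
    """Read a release snapshot from the canonical tab-separated format.

    Columns: version, species, mi_ids (comma-joined), mimat_id, name,
    sequence, dead (0/1).  Rows flagged dead populate the retired-accession
    set and carry no live record.
    """
    path = Path(path)
    records: list[MatureRecord] = []
    dead: set[str] = set()
    version = ""
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [c for c in _RELEASE_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise FormatError(f"{path}: missing column(s) {missing}")
        for lineno, row in enumerate(reader, start=2):
            version = row["version"] or version
            if row["dead"].strip() == "1":
                dead.add(row["mimat_id"].strip())
                continue
            try:
                rec = MatureRecord.create(
                    row["mimat_id"].strip(),
                    row["name"].strip(),
                    row["sequence"],
                    species=row["species"].strip() or None,
                    precursor_ids=[m for m in row["mi_ids"].split(",") if m],
                )
            except InvalidSequenceError as exc:
                raise InvalidSequenceError(f"{path}:{lineno}: {exc}") from None
            records.append(rec)
    return Release(version_label=version or path.stem, records=tuple(records),
                   dead_ids=frozenset(dead))


def write_release_tsv(path: str | Path, release: Release) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_RELEASE_COLUMNS)
        for rec in sorted(release.records, key=lambda r: r.mimat_id):
            w.writerow([
                release.version_label, rec.species,
                ",".join(sorted(rec.precursor_ids)),
                rec.mimat_id, rec.name, rec.sequence, "0",
            ])
        for acc in sorted(release.dead_ids):
            w.writerow([release.version_label, "", "", acc, "", "", "1"])


def load_version_dir(directory: str | Path,
                     order: tuple[str, ...] | None = None) -> VersionIndex:
    """Load every ``<label>.tsv`` release in a directory into an ordered index.

    Files whose stem appears in ``order`` are sorted by that explicit
    ordering; any others follow in name order (covers synthetic labels
    like "v1", "v2").
    """
    directory = Path(directory)
    paths = sorted(directory.glob("*.tsv"))
    if order:
        rank = {label: i for i, label in enumerate(order)}
        paths.sort(key=lambda p: (rank.get(p.stem, len(rank)), p.stem))
    return VersionIndex(tuple(read_release_tsv(p) for p in paths))


# ---------------------------------------------------------------------------
# mature FASTA (official release dialect)

def read_mature_fasta(path: str | Path, version_label: str) -> Release:
    """Read mature records from the official FASTA dialect.

    Headers look like ``>hsa-miR-21-5p MIMAT0000076 Homo sapiens miR-21-5p``:
    name first, then the MIMAT accession; species is derived from the name
    prefix.  Only live records can be represented — dead lists travel
    separately — so the returned release has an empty retired set.
    """
    path = Path(path)
    # map record index -> header line number, for error reporting
    header_lines = [
        i for i, line in enumerate(path.read_text().splitlines(), start=1)
        if line.startswith(">")
    ]
    records: list[MatureRecord] = []
    for idx, entry in enumerate(SeqIO.parse(str(path), "fasta")):
        m = _MIMAT_TOKEN.search(entry.description)
        if not m:
            lineno = header_lines[idx] if idx < len(header_lines) else "?"
            raise FormatError(
                f"{path}:{lineno}: header {entry.description!r} lacks a MIMAT accession"
            )
        name = entry.id
        records.append(
            MatureRecord.create(m.group(0), name, str(entry.seq))
        )
    return Release(version_label=version_label, records=tuple(records))


def write_mature_fasta(path: str | Path, release: Release) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in sorted(release.records, key=lambda r: r.mimat_id):
            fh.write(f">{rec.name} {rec.mimat_id} synthetic organism {rec.name}\n")
            fh.write(rec.sequence + "\n")


# ---------------------------------------------------------------------------
# platform CSV

def read_platform_csv(path: str | Path) -> Platform:
    """Read a platform annotation table (probe id, reported name, target sequence).

    Target sequences may use the DNA alphabet (T is normalized to U);
    ``is_control`` accepts 0/1 or true/false.
    """
    path = Path(path)
    probes: list[Probe] = []
    platform_id = vendor = design_version = ""
    seen: set[str] = set()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in _PLATFORM_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise FormatError(f"{path}: missing column(s) {missing}")
        for lineno, row in enumerate(reader, start=2):
            platform_id = row["platform_id"] or platform_id
            vendor = row["vendor"] or vendor
            design_version = row["design_version"] or design_version
            pid = row["probe_id"].strip()
            if pid in seen:
                raise FormatError(f"{path}:{lineno}: duplicate probe_id {pid!r}")
            seen.add(pid)
            is_control = row["is_control"].strip().lower() in ("1", "true", "yes")
            try:
                seq = normalize_sequence(row["target_sequence"])
            except InvalidSequenceError as exc:
                raise InvalidSequenceError(f"{path}:{lineno}: {exc}") from None
            probes.append(Probe(probe_id=pid, reported_name=row["reported_name"].strip(),
                                target_sequence=seq, is_control=is_control))
    return Platform(platform_id=platform_id or path.stem, vendor=vendor,
                    probes=tuple(probes),
                    design_version=design_version or "unknown")


def write_platform_csv(path: str | Path, platform: Platform) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(_PLATFORM_COLUMNS)
        for p in platform.probes:
            w.writerow([
                platform.platform_id, platform.vendor, platform.design_version,
                p.probe_id, p.reported_name, p.target_sequence,
                "1" if p.is_control else "0",
            ])


# ---------------------------------------------------------------------------
# expression matrices and name lists

def read_matrix(path: str | Path) -> ExpressionMatrix:
    """Read an expression matrix: first column miRNA names, header row sample ids."""
    path = Path(path)
    delim = _delimiter_for(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh, delimiter=delim))
    if not rows:
        raise FormatError(f"{path}: empty file")
    header = rows[0]
    sample_ids = [c.strip() for c in header[1:]]
    names: list[str] = []
    values: list[list[float | None]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) != len(header):
            raise FormatError(
                f"{path}:{lineno}: row has {len(row)} fields, header has {len(header)}"
            )
        names.append(row[0].strip())
        parsed: list[float | None] = []
        for cell in row[1:]:
            cell = cell.strip()
            if not cell or cell.upper() in ("NA", "NAN"):
                parsed.append(None)
            else:
                try:
                    parsed.append(float(cell))
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: non-numeric cell {cell!r}"
                    ) from None
        values.append(parsed)
    return ExpressionMatrix(row_names=names, sample_ids=sample_ids, values=values)


def _fmt(v: float | None) -> str:
    if v is None:
        return ""
    return repr(v) if isinstance(v, float) else str(v)


def write_matrix(path: str | Path, m: ExpressionMatrix) -> None:
    path = Path(path)
    delim = _delimiter_for(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter=delim, lineterminator="\n")
        w.writerow(["miRNA"] + list(m.sample_ids))
        for name, row in zip(m.row_names, m.values):
            w.writerow([name] + [_fmt(v) for v in row])


def read_name_list(path: str | Path) -> list[str]:
    """Read a query name list: names separated by spaces and/or newlines."""
    return Path(path).read_text().split()


# ---------------------------------------------------------------------------
# result writers (column layout is a frozen contract)

def _translation_fields(tr: TranslationRow, cfg: Config) -> list[str]:
    return [
        tr.input_name,
        tr.matched_sequence,
        tr.status,
        cfg.multi_name_delimiter.join(tr.output_names),
        cfg.multi_name_delimiter.join(sorted(tr.output_accessions)),
        tr.note,
    ]


def write_translation_csv(path, rows: list[TranslationRow],
                          cfg: Config | None = None) -> None:
    cfg = cfg or Config()
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(_RESULT_HEADER)
        for tr in rows:
            w.writerow(_translation_fields(tr, cfg))


def write_result(path, updated: UpdatedMatrix, cfg: Config | None = None) -> None:
    """Write an updated matrix: translation columns, then one column per sample."""
    cfg = cfg or Config()
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(_RESULT_HEADER + list(updated.sample_ids))
        for rec in updated.records:
            w.writerow(_translation_fields(rec.translation, cfg)
                       + [_fmt(v) for v in rec.values])


def write_overlap_csv(path, entries, cfg: Config | None = None) -> None:
    cfg = cfg or Config()
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["sequence", "names_a", "names_b"])
        for e in entries:
            w.writerow([
                e.sequence,
                cfg.multi_name_delimiter.join(e.names_a),
                cfg.multi_name_delimiter.join(e.names_b),
            ])


def write_intersection_csv(path, result: IntersectionResult,
                           cfg: Config | None = None) -> None:
    cfg = cfg or Config()
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["sequence", "output_names", "names_a", "names_b"]
                   + list(result.sample_ids))
        for row in result.rows:
            w.writerow([
                row.sequence,
                cfg.multi_name_delimiter.join(row.output_names),
                cfg.multi_name_delimiter.join(row.names_a),
                cfg.multi_name_delimiter.join(row.names_b),
            ] + [_fmt(v) for v in row.values_a + row.values_b])


def write_curation_csv(path, findings) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["probe_id", "finding_kind", "detail",
                    "expected_sequence", "observed_sequence"])
        for f in findings:
            w.writerow([f.probe_id, f.finding_kind, f.detail,
                        f.expected_sequence, f.observed_sequence])


def write_tracks(path, tracks: list[Track], index: VersionIndex) -> None:
    """Write track histories: one column per release holding the name then
    borne, "-" before introduction, "DEAD" while retired."""
    labels = list(index.labels)
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["mimat_id", "mi_ids", "species", "current_name",
                    "current_sequence", "arm", "length"] + labels)
        for tr in tracks:
            cells = []
            introduced = False
            for label in labels:
                name = tr.name_by_version.get(label)
                if name is not None:
                    introduced = True
                    cells.append(name)
                else:
                    cells.append("DEAD" if introduced else "-")
            w.writerow([
                tr.mimat_id, ",".join(sorted(tr.mi_ids)), tr.species,
                tr.current_name, tr.current_sequence, tr.arm, str(tr.length),
            ] + cells)
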