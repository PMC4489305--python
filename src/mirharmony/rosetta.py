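"""Sequence-keyed translation of miRNA name lists and expression matrices.

Four operations, all keyed on the normalized full-length mature sequence:

* :func:`translate_names` — rewrite a name list from a source namespace
  (platform or release) into a destination namespace;
* :func:`overlap_namespaces` — the mature sequences two namespaces share,
  regardless of what either side calls them;
* :func:`update_matrix` — re-annotate an expression matrix's row names,
  carrying every expression value over unchanged;
* :func:`intersect_matrices` — join two expression matrices on shared
  mature sequences, annotated with destination names.

Every per-name outcome carries exactly one status:

==============  ======================================================
stable          the destination uses the same name
renamed         one destination name, different from the input
multiple        the sequence bears ≥2 names in the destination
dead            the accession was retired before the destination release
missing         sequence absent from destination, retirement not proven
unrecognized    input name unknown to the source namespace (typically a
                control probe or non-miRNA annotation)
==============  ======================================================

"dead" requires accession continuity: when the source namespace has no
MIMAT accessions (a vendor platform), an absent sequence is reported
"missing", never "dead" — retirement is never over-claimed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotation_model import normalize_sequence
from .errors import ConfigurationError
from .namespace_engine import Namespace

__all__ = [
    "TranslationRow",
    "ExpressionMatrix",
    "OverlapEntry",
    "UpdatedRecord",
    "UpdatedMatrix",
    "IntersectionRow",
    "IntersectionResult",
    "STATUSES",
    "translate_names",
    "overlap_namespaces",
    "update_matrix",
    "intersect_matrices",
]

STATUSES = ("stable", "renamed", "multiple", "dead", "missing", "unrecognized")


@dataclass(frozen=True)
class TranslationRow:
    """Harmonization outcome for one input name."""

    input_name: str
    matched_sequence: str
    output_names: tuple[str, ...]
    output_accessions: frozenset[str]
    status: str
    note: str = ""


@dataclass
class ExpressionMatrix:
    """miRNA rows × sample columns; ``None`` marks a missing cell."""

    row_names: list[str]
    sample_ids: list[str]
    values: list[list[float | None]]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.row_names):
            raise ValueError(
                f"{len(self.row_names)} row names but {len(self.values)} value rows"
            )
        for i, row in enumerate(self.values):
            if len(row) != len(self.sample_ids):
                raise ValueError(
                    f"row {i} ({self.row_names[i]!r}) has {len(row)} cells, "
                    f"expected {len(self.sample_ids)}"
                )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids not unique")

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.row_names), len(self.sample_ids))


@dataclass(frozen=True)
class OverlapEntry:
    """One mature sequence present in both namespaces, with each side's names."""

    sequence: str
    names_a: tuple[str, ...]
    names_b: tuple[str, ...]


def _resolve_in_source(name: str, src: Namespace, case_rescue: bool) -> tuple[str | None, str]:
    """Find a name's sequence in the source namespace.

    Matching is case-sensitive after whitespace trimming; when that fails
    and ``case_rescue`` is on, a case-insensitive match is attempted and
    accepted only if unique (vendor files differ in capitalization, e.g.
    "hsa-miR" vs "hsa-mir", but silent folding would mask genuine
    precursor-vs-mature distinctions).  Returns (sequence or None, note).
    """
    seq = src.name_to_seq.get(name)
    if seq is not None:
        return seq, ""
    if case_rescue:
        folded = name.lower()
        hits = [n for n in src.name_to_seq if n.lower() == folded]
        if len(hits) == 1:
            return src.name_to_seq[hits[0]], f"case-insensitive match of {hits[0]!r}"
    return None, ""


def _classify(name: str, seq: str, src: Namespace, dst: Namespace, note: str) -> TranslationRow:
    out_names = dst.seq_to_names.get(seq, ())
    out_accs = dst.seq_to_accessions.get(seq, frozenset())
    if out_names:
        if out_names == (name,):
            status = "stable"
        elif len(out_names) == 1:
            status = "renamed"
        else:
            status = "multiple"
        return TranslationRow(name, seq, out_names, frozenset(out_accs), status, note)
    src_accs = src.seq_to_accessions.get(seq, frozenset())
    if src_accs & dst.dead_ids:
        dead = sorted(src_accs & dst.dead_ids)
        extra = f"accession {','.join(dead)} retired in {dst.label}"
        return TranslationRow(name, seq, (), frozenset(), "dead",
                              f"{note}; {extra}" if note else extra)
    return TranslationRow(name, seq, (), frozenset(), "missing", note)


def translate_names(
    names: list[str],
    src: Namespace,
    dst: Namespace,
    case_rescue: bool = True,
) -> list[TranslationRow]:
    """Translate a name list from ``src`` into ``dst`` by mature sequence.

    One output row per input name, same order; duplicated inputs each get
    their own row.  Names unknown to the source (control probes, endogenous
    controls, typos) come back ``unrecognized``.
    """
    rows: list[TranslationRow] = []
    for raw in names:
        name = raw.strip()
        seq, note = _resolve_in_source(name, src, case_rescue)
        if seq is None:
            rows.append(
                TranslationRow(
                    name, "", (), frozenset(), "unrecognized",
                    f"name not found in {src.label}",
                )
            )
            continue
        rows.append(_classify(name, seq, src, dst, note))
    return rows


def overlap_namespaces(a: Namespace, b: Namespace) -> list[OverlapEntry]:
    """Mature sequences present in both namespaces, sorted by sequence."""
    shared = sorted(a.sequences & b.sequences)
    return [
        OverlapEntry(seq, a.seq_to_names[seq], b.seq_to_names[seq]) for seq in shared
    ]


@dataclass(frozen=True)
class UpdatedRecord:
    """One re-annotated matrix row: its translation plus the carried values."""

    translation: TranslationRow
    values: tuple[float | None, ...]


@dataclass
class UpdatedMatrix:
    """Result of :func:`update_matrix`: per-row translation with data carryover."""

    sample_ids: list[str]
    records: list[UpdatedRecord]


def update_matrix(
    m: ExpressionMatrix,
    src: Namespace,
    dst: Namespace,
    case_rescue: bool = True,
    failures_last: bool = False,
) -> UpdatedMatrix:
    """Re-annotate a matrix's row names from ``src`` to ``dst``.

    Exactly one output record per input row; expression values are carried
    over bit-identically.  Untranslatable rows are retained with their
    status; with ``failures_last`` they are stably sorted to the bottom
    (translated rows first), otherwise input order is kept.
    """
    rows = translate_names(m.row_names, src, dst, case_rescue=case_rescue)
    records = [
        UpdatedRecord(tr, tuple(vals)) for tr, vals in zip(rows, m.values)
    ]
    if failures_last:
        # stable: translated rows keep input order, failures follow in input order
        records.sort(key=lambda r: 0 if r.translation.output_names else 1)
    return UpdatedMatrix(sample_ids=list(m.sample_ids), records=records)


@dataclass(frozen=True)
class IntersectionRow:
    """One shared mature sequence with both matrices' values side by side."""

    sequence: str
    output_names: tuple[str, ...]
    names_a: tuple[str, ...]
    names_b: tuple[str, ...]
    values_a: tuple[float | None, ...]
    values_b: tuple[float | None, ...]


@dataclass
class IntersectionResult:
    sample_ids: list[str]  # samples of A then samples of B
    rows: list[IntersectionRow]
    side_report: list[TranslationRow]


def intersect_matrices(
    m_a: ExpressionMatrix,
    ns_a: Namespace,
    m_b: ExpressionMatrix,
    ns_b: Namespace,
    dst: Namespace,
    prefix_a: str = "",
    prefix_b: str = "",
    case_rescue: bool = True,
) -> IntersectionResult:
    """Join two expression matrices on the mature sequences they share.

    Each matrix's row names are resolved through its own namespace; rows
    whose sequences occur in both matrices are emitted with destination
    names and the values of both sides (columns: samples of A, then B).
    Rows that do not resolve, are not shared, or repeat a sequence already
    seen within their matrix go to the side report with a translation-style
    status.
    """
    ids_a = [prefix_a + s for s in m_a.sample_ids]
    ids_b = [prefix_b + s for s in m_b.sample_ids]
    if set(ids_a) & set(ids_b):
        clash = sorted(set(ids_a) & set(ids_b))
        raise ConfigurationError(
            f"sample ids {clash} occur in both matrices; supply prefixes"
        )

    def resolve(m: ExpressionMatrix, ns: Namespace, side: str):
        seq_row: dict[str, tuple[str, tuple]] = {}
        unresolved: list[TranslationRow] = []
        for name, vals in zip(m.row_names, m.values):
            stripped = name.strip()
            seq, note = _resolve_in_source(stripped, ns, case_rescue)
            if seq is None:
                unresolved.append(
                    TranslationRow(stripped, "", (), frozenset(), "unrecognized",
                                   f"[{side}] name not found in {ns.label}")
                )
            elif seq in seq_row:
                unresolved.append(
                    TranslationRow(stripped, seq, (), frozenset(), "unrecognized",
                                   f"[{side}] duplicate sequence of row "
                                   f"{seq_row[seq][0]!r}; first occurrence kept")
                )
            else:
                seq_row[seq] = (stripped, tuple(vals))
        return seq_row, unresolved

    rows_a, report = resolve(m_a, ns_a, "A")
    rows_b, rep_b = resolve(m_b, ns_b, "B")
    report.extend(rep_b)

    shared = sorted(set(rows_a) & set(rows_b))
    out: list[IntersectionRow] = []
    for seq in shared:
        name_a, vals_a = rows_a[seq]
        name_b, vals_b = rows_b[seq]
        out.append(
            IntersectionRow(
                sequence=seq,
                output_names=dst.seq_to_names.get(seq, ()),
                names_a=ns_a.seq_to_names.get(seq, (name_a,)),
                names_b=ns_b.seq_to_names.get(seq, (name_b,)),
                values_a=vals_a,
                values_b=vals_b,
            )
        )
    for side, rows, ns, other in (
        ("A", rows_a, ns_a, rows_b),
        ("B", rows_b, ns_b, rows_a),
    ):
        for seq, (name, _vals) in rows.items():
            if seq in other:
                continue
            tr = _classify(name, seq, ns, dst, "")
            note = f"[{side}] not shared between the two data sets"
            if tr.note:
                note = f"{note}; {tr.note}"
            report.append(
                TranslationRow(name, seq, tr.output_names, tr.output_accessions,
                               tr.status, note)
            )
    return IntersectionResult(sample_ids=ids_a + ids_b, rows=out, side_report=report)
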