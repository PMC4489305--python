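import random

import pytest

from mirharmony import fixtures as fx
from mirharmony.errors import ConfigurationError
from mirharmony.namespace_engine import (
    Namespace,
    build_namespace_from_platform,
    build_namespace_from_release,
)
from mirharmony.rosetta import (
    ExpressionMatrix,
    intersect_matrices,
    overlap_namespaces,
    translate_names,
    update_matrix,
)


def brute_force_translate(name, src, dst):
    """Independent oracle: quadratic join of the two namespace tables."""
    if name not in src.name_to_seq:
        return ((), "unrecognized")
    seq = src.name_to_seq[name]
    outs = tuple(sorted(n for n, s in dst.name_to_seq.items() if s == seq))
    if outs == (name,):
        return (outs, "stable")
    if len(outs) == 1:
        return (outs, "renamed")
    if len(outs) >= 2:
        return (outs, "multiple")
    if src.seq_to_accessions.get(seq, frozenset()) & dst.dead_ids:
        return ((), "dead")
    return ((), "missing")


@pytest.mark.parametrize(
    "name, expected_status, expected_outputs",
    [
        ("syn-miR-2-3p", "renamed", ("syn-miR-2b-3p",)),  # scripted rename
        ("syn-miR-3", "dead", ()),  # scripted deletion, accession retired
        ("syn-miR-1-5p", "stable", ("syn-miR-1-5p",)),
        ("spike-in-ctrl-1", "unrecognized", ()),  # control probe name, not a miRNA
    ],
)
def test_translate_statuses_v1_to_v2(ns_v1, ns_v2, name, expected_status, expected_outputs):
    (row,) = translate_names([name], ns_v1, ns_v2)
    assert row.status == expected_status
    assert row.output_names == expected_outputs


def test_translate_collision_reports_multiple(ns_v2):
    (row,) = translate_names(["syn-miR-5a"], ns_v2, ns_v2)
    assert row.status == "multiple"
    assert row.output_names == ("syn-miR-5a", "syn-miR-5b")


def test_translate_self_is_stable_for_unambiguous_names(ns_v1):
    rows = translate_names(sorted(ns_v1.name_to_seq), ns_v1, ns_v1)
    assert all(r.status == "stable" for r in rows)


def test_translate_preserves_order_and_duplicates(ns_v1, ns_v2):
    rows = translate_names(["syn-miR-3", "syn-miR-3"], ns_v1, ns_v2)
    assert len(rows) == 2 and rows[0] == rows[1]


def test_translate_case_rescue_annotates_note(ns_v1, ns_v2):
    (row,) = translate_names(["SYN-MIR-2-3P"], ns_v1, ns_v2)
    assert row.status == "renamed"
    assert "case-insensitive" in row.note
    (strict,) = translate_names(["SYN-MIR-2-3P"], ns_v1, ns_v2, case_rescue=False)
    assert strict.status == "unrecognized"


def test_missing_not_dead_without_accessions(platform_p1, ns_v1, ns_v2):
    """A platform source carries no MIMATs, so retirement is never claimed."""
    pns = build_namespace_from_platform(platform_p1)
    # the same name, translated from the release, is provably dead ...
    (from_release,) = translate_names(["syn-miR-3"], ns_v1, ns_v2)
    assert from_release.status == "dead"
    # ... but from the accession-less platform it can only be "missing"
    (from_platform,) = translate_names(["syn-miR-3"], pns, ns_v2)
    assert from_platform.status == "missing"


def test_status_partition_invariants(ns_v1, ns_v2):
    names = sorted(ns_v1.name_to_seq) + ["nonsense", "syn-miR-5a"]
    for row in translate_names(names, ns_v1, ns_v2):
        if row.status == "stable":
            assert row.output_names == (row.input_name,)
        elif row.status == "renamed":
            assert len(row.output_names) == 1
            assert row.output_names[0] != row.input_name
        elif row.status == "multiple":
            assert len(row.output_names) >= 2
        else:
            assert row.status in ("dead", "missing", "unrecognized")
            assert row.output_names == ()


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_translate_matches_brute_force_join(seed):
    index, _ = fx.generate_series(
        fx.FixtureSpec(seed=seed, n_versions=3, n_initial_records=40, n_collisions=2)
    )
    src = build_namespace_from_release(index.releases[0], "syn")
    dst = build_namespace_from_release(index.releases[-1], "syn")
    rng = random.Random(seed)
    queries = sorted(src.name_to_seq) + ["bogus-1", "spike-in"]
    rng.shuffle(queries)
    for row in translate_names(queries, src, dst, case_rescue=False):
        outs, status = brute_force_translate(row.input_name, src, dst)
        assert (row.output_names, row.status) == (outs, status)


def test_overlap_self_covers_every_sequence(ns_v1):
    entries = overlap_namespaces(ns_v1, ns_v1)
    assert {e.sequence for e in entries} == ns_v1.sequences
    assert all(e.names_a == e.names_b for e in entries)


def test_overlap_with_empty_namespace(ns_v1):
    assert overlap_namespaces(ns_v1, Namespace("e", "release")) == []


def test_overlap_platforms_sharing_one_sequence(toy3_index):
    release = toy3_index.get("v1")
    records = sorted(release.records, key=lambda r: r.mimat_id)
    from mirharmony.annotation_model import Platform, Probe
    p1 = Platform("P1", "V", probes=(
        Probe("a1", records[0].name, records[0].sequence),
        Probe("a2", records[1].name, records[1].sequence),
    ))
    p2 = Platform("P2", "V", probes=(
        Probe("b1", records[1].name, records[1].sequence),
        Probe("b2", records[2].name, records[2].sequence),
    ))
    entries = overlap_namespaces(
        build_namespace_from_platform(p1), build_namespace_from_platform(p2)
    )
    # exhaustive pairwise comparison of probe sequences finds one shared mature
    assert [e.sequence for e in entries] == [records[1].sequence]


def test_overlap_is_sequence_symmetric(ns_v1, ns_v2):
    ab = {e.sequence for e in overlap_namespaces(ns_v1, ns_v2)}
    ba = {e.sequence for e in overlap_namespaces(ns_v2, ns_v1)}
    assert ab == ba


def test_update_matrix_carries_values_and_rename(ns_v1, ns_v2):
    m = ExpressionMatrix(
        row_names=["syn-miR-1-5p", "syn-miR-2-3p", "syn-miR-3"],
        sample_ids=["s1", "s2"],
        values=[[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
    )
    out = update_matrix(m, ns_v1, ns_v2)
    assert len(out.records) == 3
    statuses = [r.translation.status for r in out.records]
    assert statuses == ["stable", "renamed", "dead"]
    assert out.records[1].translation.output_names == ("syn-miR-2b-3p",)
    assert [list(r.values) for r in out.records] == m.values


def test_update_identity_and_empty(ns_v1):
    m = ExpressionMatrix(sorted(ns_v1.name_to_seq), ["s1"], [[1.0], [2.0], [3.0]])
    out = update_matrix(m, ns_v1, ns_v1)
    assert all(r.translation.status == "stable" for r in out.records)
    empty = ExpressionMatrix([], ["s1", "s2"], [])
    assert update_matrix(empty, ns_v1, ns_v1).records == []


def test_update_failures_last_is_stable_sort(ns_v1, ns_v2):
    m = ExpressionMatrix(
        ["syn-miR-3", "syn-miR-1-5p", "syn-miR-2-3p"],
        ["s1"], [[1.0], [2.0], [3.0]],
    )
    out = update_matrix(m, ns_v1, ns_v2, failures_last=True)
    assert [r.translation.input_name for r in out.records] == [
        "syn-miR-1-5p", "syn-miR-2-3p", "syn-miR-3"
    ]


@pytest.mark.parametrize("seed", range(5))
def test_update_conservation_property(seed):
    """Row count and the multiset of carried values are preserved exactly."""
    index, _ = fx.generate_series(
        fx.FixtureSpec(seed=seed, n_versions=2, n_initial_records=25)
    )
    src = build_namespace_from_release(index.releases[0], "syn")
    dst = build_namespace_from_release(index.releases[-1], "syn")
    m = fx.generate_matrix(src, n_samples=3, seed=seed)
    out = update_matrix(m, src, dst)
    assert len(out.records) == len(m.row_names)
    carried = sorted(v for r in out.records for v in r.values)
    original = sorted(v for row in m.values for v in row)
    assert carried == original


@pytest.mark.parametrize("seed", range(5))
def test_stable_and_renamed_rows_round_trip(seed):
    index, _ = fx.generate_series(
        fx.FixtureSpec(seed=seed, n_versions=3, n_initial_records=30)
    )
    src = build_namespace_from_release(index.releases[0], "syn")
    dst = build_namespace_from_release(index.releases[-1], "syn")
    for row in translate_names(sorted(src.name_to_seq), src, dst, case_rescue=False):
        if row.status in ("stable", "renamed"):
            (back,) = translate_names([row.output_names[0]], dst, src)
            assert row.input_name in back.output_names


def test_intersect_joins_renamed_rows(ns_v1, ns_v2):
    m_a = ExpressionMatrix(["syn-miR-1-5p", "syn-miR-2-3p"], ["a1"], [[1.0], [2.0]])
    m_b = ExpressionMatrix(["syn-miR-1-5p", "syn-miR-2b-3p"], ["b1"], [[7.0], [8.0]])
    res = intersect_matrices(m_a, ns_v1, m_b, ns_v2, ns_v2)
    assert len(res.rows) == 2
    assert res.sample_ids == ["a1", "b1"]
    by_seq = {r.sequence: r for r in res.rows}
    seq2 = ns_v1.name_to_seq["syn-miR-2-3p"]
    assert by_seq[seq2].output_names == ("syn-miR-2b-3p",)
    assert by_seq[seq2].values_a == (2.0,) and by_seq[seq2].values_b == (8.0,)


def test_intersect_disjoint_reports_everything(ns_v1, ns_v2):
    m_a = ExpressionMatrix(["syn-miR-1-5p"], ["a1"], [[1.0]])
    m_b = ExpressionMatrix(["syn-miR-5a"], ["b1"], [[2.0]])
    res = intersect_matrices(m_a, ns_v1, m_b, ns_v2, ns_v2)
    assert res.rows == []
    assert {r.input_name for r in res.side_report} == {"syn-miR-1-5p", "syn-miR-5a"}


def test_intersect_self_with_prefixes(ns_v1, ns_v2):
    m = ExpressionMatrix(["syn-miR-1-5p", "syn-miR-2-3p"], ["s1"], [[1.0], [2.0]])
    res = intersect_matrices(m, ns_v1, m, ns_v1, ns_v2, prefix_a="A_", prefix_b="B_")
    assert res.sample_ids == ["A_s1", "B_s1"]
    assert len(res.rows) == 2
    assert all(r.values_a == r.values_b for r in res.rows)


def test_intersect_sample_clash_without_prefix_errors(ns_v1, ns_v2):
    m = ExpressionMatrix(["syn-miR-1-5p"], ["s1"], [[1.0]])
    with pytest.raises(ConfigurationError):
        intersect_matrices(m, ns_v1, m, ns_v1, ns_v2)
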