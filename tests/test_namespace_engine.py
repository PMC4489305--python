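import random

import pytest

from mirharmony import fixtures as fx
from mirharmony.annotation_model import Platform, Probe
from mirharmony.errors import InvalidSequenceError, UnknownNamespaceError
from mirharmony.namespace_engine import (
    build_namespace_from_platform,
    build_namespace_from_release,
    curate_platform,
    lookup_names,
    namespace_for_version,
)


def test_release_namespace_counts(ns_v1):
    assert len(ns_v1.name_to_seq) == 3
    assert len(ns_v1.seq_to_names) == 3
    assert all(ns_v1.seq_to_accessions.values())


def test_release_namespace_absent_species_warns(toy3_index):
    ns = build_namespace_from_release(toy3_index.get("v1"), "xyz")
    assert len(ns) == 0
    assert ns.warnings and "xyz" in ns.warnings[0]


def test_release_namespace_collision_shares_sequence_key(ns_v2):
    # v2 carries the scripted collision: two accessions, one mature sequence
    assert len(ns_v2.name_to_seq) == 4
    assert len(ns_v2.seq_to_names) == 3
    collided = [names for names in ns_v2.seq_to_names.values() if len(names) > 1]
    assert collided == [("syn-miR-5a", "syn-miR-5b")]


def test_unknown_version_label_raises(toy3_index):
    with pytest.raises(UnknownNamespaceError):
        namespace_for_version(toy3_index, "v99", "syn")


def test_platform_namespace_excludes_controls(platform_p1):
    ns = build_namespace_from_platform(platform_p1)
    assert len(ns) == 3  # 4 probes, 1 control
    assert ns.seq_to_accessions == {}


def test_platform_name_with_two_sequences_is_a_conflict_not_an_entry():
    platform = Platform(
        platform_id="PX", vendor="V",
        probes=(
            Probe("p1", "syn-miR-1-5p", "ACGUACGUACGUACGUACG"),
            Probe("p2", "syn-miR-1-5p", "GGGGACGUACGUACGUACG"),
        ),
    )
    ns = build_namespace_from_platform(platform)
    assert "syn-miR-1-5p" not in ns.name_to_seq
    assert ns.seq_to_names == {}
    assert sorted(f.probe_id for f in ns.conflicts) == ["p1", "p2"]
    assert all(f.finding_kind == "duplicate_probe_name" for f in ns.conflicts)


def test_empty_platform_gives_empty_namespace():
    ns = build_namespace_from_platform(Platform("PE", "V", probes=()))
    assert len(ns) == 0 and ns.conflicts == ()


def test_curate_verbatim_platform_only_excludes_controls(platform_p1, ns_v1):
    findings = curate_platform(platform_p1, ns_v1)
    assert [f.finding_kind for f in findings] == ["control_excluded"]


def test_curate_recovers_injected_mismatch(platform_p_err, ns_v1):
    platform, manifest = platform_p_err
    findings = [f for f in curate_platform(platform, ns_v1)
                if f.finding_kind == "name_sequence_mismatch"]
    assert {(f.probe_id, f.expected_sequence, f.observed_sequence) for f in findings} \
        == {(pid, exp, obs) for pid, exp, obs in manifest}


def test_curate_flags_unknown_name(ns_v1):
    platform = Platform(
        "PU", "V",
        probes=(Probe("p1", "syn-miR-404-5p", "ACGUACGUACGUACGUACG"),),
    )
    (finding,) = curate_platform(platform, ns_v1)
    assert finding.finding_kind == "unknown_name"


def test_curate_requires_release_reference(platform_p1):
    ns = build_namespace_from_platform(platform_p1)
    with pytest.raises(ValueError):
        curate_platform(platform_p1, ns)


def test_lookup_names_collision_and_normalization(ns_v1, ns_v2):
    collided_seq = next(s for s, n in ns_v2.seq_to_names.items() if len(n) > 1)
    assert lookup_names(ns_v2, collided_seq) == ("syn-miR-5a", "syn-miR-5b")
    assert lookup_names(ns_v1, "A" * 22) == ()
    seq1 = ns_v1.name_to_seq["syn-miR-1-5p"]
    assert lookup_names(ns_v1, seq1.lower()) == ("syn-miR-1-5p",)
    with pytest.raises(InvalidSequenceError):
        lookup_names(ns_v1, "NOTASEQ!")


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_namespace_mutual_consistency_on_generated_releases(seed):
    index, _ = fx.generate_series(fx.FixtureSpec(seed=seed, n_versions=3,
                                                 n_initial_records=30,
                                                 n_collisions=2))
    for release in index:
        ns = build_namespace_from_release(release, "syn")
        assert len(ns.name_to_seq) >= len(ns.seq_to_names)
        for name, seq in ns.name_to_seq.items():
            assert name in ns.seq_to_names[seq]
        for seq, names in ns.seq_to_names.items():
            for name in names:
                assert ns.name_to_seq[name] == seq


@pytest.mark.parametrize("seed", [3, 4])
def test_lookup_agrees_with_linear_scan(seed):
    """lookup_names must equal a brute-force scan of the source table."""
    index, _ = fx.generate_series(fx.FixtureSpec(seed=seed, n_versions=2,
                                                 n_initial_records=60,
                                                 n_collisions=3))
    release = index.releases[-1]
    ns = build_namespace_from_release(release, "syn")
    rng = random.Random(seed)
    pool = [r.sequence for r in release.records] + [
        "".join(rng.choice("ACGU") for _ in range(22)) for _ in range(50)
    ]
    for seq in rng.sample(pool, 80):
        expected = tuple(sorted(r.name for r in release.records if r.sequence == seq))
        assert lookup_names(ns, seq) == expected


@pytest.mark.parametrize("seed", [0, 5])
def test_curation_clean_on_derived_platform_any_seed(seed):
    index, _ = fx.generate_series(fx.FixtureSpec(seed=seed, n_versions=2,
                                                 n_initial_records=25))
    release = index.releases[-1]
    spec = fx.PlatformSpec("PD", release.version_label, n_probes=20, n_controls=2)
    platform, _ = fx.derive_platform(release, spec, seed=seed)
    ns = build_namespace_from_release(release, "syn")
    kinds = {f.finding_kind for f in curate_platform(platform, ns)}
    assert kinds <= {"control_excluded"}
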