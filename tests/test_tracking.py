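import dataclasses
import random

import numpy as np
import pytest

from scfvtools.align import revcomp
from scfvtools.annotate import annotate_many, annotate_read
from scfvtools.fixture import RELATED_READS, read_name
from scfvtools.mutations import apply_mutations, parse_mutation
from scfvtools.simulate import ReadErrorModel, simulate_reads
from scfvtools.tracking import (
    TrackedRead,
    classify_identity,
    classify_provenance,
    clonotype_key,
    extract_diffs,
    localize_all,
    localize_mutation,
    rank_associations,
    run_tracking,
    signature_of,
    track_by_alignment,
    track_by_characteristics,
)


@dataclasses.dataclass
class StubDomain:
    v_call: str
    j_call: str
    junction_aa: str


@dataclasses.dataclass
class StubAnn:
    read_id: str
    layout: str
    domain1: StubDomain
    domain2: StubDomain


def _stub(rid, v1="IGHV1-1*01", j1="IGHJ4*01", aa1="CARW", v2="IGKV1-1*01",
          j2="IGKJ1*01", aa2="CQQF", layout="VH-VL"):
    return StubAnn(rid, layout, StubDomain(v1, j1, aa1), StubDomain(v2, j2, aa2))


def test_clonotype_key_equality():
    assert clonotype_key(_stub("a")) == clonotype_key(_stub("b"))


def test_clonotype_key_layout_aware():
    a = _stub("a")
    b = StubAnn("b", "VL-VH", a.domain2, a.domain1)
    assert clonotype_key(a) != clonotype_key(b)


def test_clonotype_key_untyped_errors():
    bad = _stub("x")
    bad.domain2 = StubDomain("IGKV1-1*01", "IGKJ1*01", "")
    with pytest.raises(ValueError, match="untyped"):
        clonotype_key(bad)


def test_silent_substitution_same_key(refdir, tracking_fixture):
    fx = tracking_fixture
    base = annotate_read("base", fx.reference_insert, fx.refdir)
    # substitution in the 5' flank: outside both junctions
    variant_seq = apply_mutations(
        fx.reference_insert,
        [f"{fx.reference_insert[30].lower()}31>"
         f"{'a' if fx.reference_insert[30] != 'A' else 'g'}"],
    )
    variant = annotate_read("var", variant_seq, fx.refdir)
    assert clonotype_key(base) == clonotype_key(variant)


def test_rank_tie_rule():
    anns = (
        [_stub(f"a{i}") for i in range(5)]
        + [_stub(f"b{i}", aa1="CBBW") for i in range(3)]
        + [_stub(f"c{i}", aa1="CCCW") for i in range(3)]
    )
    table = rank_associations(anns)
    assert list(table["count"]) == [5, 3, 3]
    assert list(table["rank"]) == [1, 2, 2]


def test_rank_single_clone():
    table = rank_associations([_stub("only")])
    assert len(table) == 1
    assert table.iloc[0]["frequency"] == 1.0


def test_rank_stability_under_duplication():
    anns = [_stub(f"a{i}") for i in range(4)] + [_stub("b", aa1="CBBW")]
    base = rank_associations(anns)
    doubled = rank_associations(anns + [dataclasses.replace(a, read_id=a.read_id + "x") for a in anns])
    assert list(base["rank"]) == list(doubled["rank"])


def test_track_by_characteristics():
    reference = clonotype_key(_stub("ref"))
    anns = [_stub("m1"), _stub("m2"), _stub("x", aa2="CDIFFERENTF")]
    assert track_by_characteristics(reference, anns) == {"m1", "m2"}
    assert track_by_characteristics(reference, []) == set()


def test_track_by_alignment_diff_counts(tracking_fixture):
    fx = tracking_fixture
    scfv = fx.reference_scfv
    lo = fx.geometry.scfv_span[0]
    exact = ("exact", fx.reference_insert)
    four = ("four", apply_mutations(fx.reference_insert,
                                    ["a545>g", "g686>a", "a757>g", "c838>g"]))
    rng = random.Random(1)
    positions = rng.sample(range(lo + 10, lo + 700), 21)
    many = fx.reference_insert
    muts = []
    for pos in sorted(positions):
        base = fx.reference_insert[pos - 1].lower()
        alt = {"a": "g", "g": "a", "c": "t", "t": "c"}[base]
        muts.append(f"{base}{pos}>{alt}")
    many = apply_mutations(fx.reference_insert, muts)
    retained, stats = track_by_alignment(scfv, [exact, four, ("many", many)])
    assert retained == {"exact", "four"}
    by_id = {s.read_id: s for s in stats}
    assert by_id["exact"].diff_count == 0
    assert by_id["four"].diff_count == 4
    assert by_id["many"].diff_count == 21
    assert by_id["four"].coverage == 1.0


def test_track_by_alignment_short_reference():
    with pytest.raises(ValueError, match="100 nt"):
        track_by_alignment("ACGT" * 10, [])


def test_classify_identity_classes(tracking_fixture):
    fx = tracking_fixture
    geo = fx.geometry
    cls, diffs = classify_identity(fx.reference_insert, fx.reference_insert, geo)
    assert cls == "identical_full" and diffs == []
    cls, diffs = classify_identity(
        apply_mutations(fx.reference_insert, ["a942>del"]), fx.reference_insert, geo
    )
    assert cls == "identical_core"
    assert [d.nomenclature for d in diffs] == ["a942>del"]
    cls, diffs = classify_identity(
        apply_mutations(fx.reference_insert, ["a545>g"]), fx.reference_insert, geo
    )
    assert cls == "related"
    assert [d.nomenclature for d in diffs] == ["a545>g"]


def test_extract_diffs_round_trip(tracking_fixture):
    fx = tracking_fixture
    for number, (_, _, mutations) in RELATED_READS.items():
        if number in (9, 84):  # insertion descriptions have co-optimal encodings
            continue
        mutated = apply_mutations(fx.reference_insert, mutations)
        recovered = {d.nomenclature for d in extract_diffs(mutated, fx.reference_insert)}
        assert recovered == set(mutations), number


def test_extract_diffs_orientation_via_runner(tracking_fixture):
    fx = tracking_fixture
    mutated = revcomp(apply_mutations(fx.reference_insert, ["a545>g"]))
    from scfvtools.tracking import orient_to_reference

    oriented = orient_to_reference(mutated, fx.reference_insert)
    assert [d.nomenclature for d in extract_diffs(oriented, fx.reference_insert)] == ["a545>g"]


@pytest.mark.parametrize(
    "position,expected",
    [
        (2, "fwd_primer_end"),
        (956, "rev_primer_vicinity"),
        (942, "rev_primer_vicinity"),
        (975, "rev_primer_end"),
        (495, "insert_linker"),
        (242, "insert_VH"),
        (545, "insert_VL"),
        (50, "insert_flank"),
        (900, "insert_flank"),
    ],
)
def test_localize_mutation(tracking_fixture, position, expected):
    fx = tracking_fixture
    base = fx.reference_insert[position - 1].lower()
    record = parse_mutation(f"{base}{position}>del")
    assert localize_mutation(record, fx.geometry) == expected


def test_signature_excludes_primer_and_terminal(tracking_fixture):
    fx = tracking_fixture
    mutations = ["a545>g", "g686>a", "a757>g", "c838>g", "a886-a977>del (92 nt)"]
    diffs = localize_all([parse_mutation(m) for m in mutations], fx.geometry)
    assert signature_of(diffs, fx.geometry) == ("a545>g", "a757>g", "c838>g", "g686>a")


def test_provenance_same_sample_is_category_b(tracking_fixture):
    fx = tracking_fixture
    diffs = tuple(localize_all([parse_mutation("a545>g")], fx.geometry))
    reads = [
        TrackedRead("r1", "s1", 1, "related", diffs),
        TrackedRead("r2", "s1", 2, "related", diffs),
    ]
    groups = classify_provenance(reads, fx.geometry)
    assert [g.category for g in groups] == ["B"]
    assert groups[0].provenance == "unassigned"
    # the looser >=2-cells rule promotes the same pair to category A
    groups = classify_provenance(reads, fx.geometry, rule="smrt_cells")
    assert [g.category for g in groups] == ["A"]


def test_provenance_singleton_insertion(tracking_fixture):
    fx = tracking_fixture
    diffs = tuple(localize_all([parse_mutation("209^210>ins^a")], fx.geometry))
    groups = classify_provenance(
        [TrackedRead("r1", "s2", 5, "related", diffs)], fx.geometry
    )
    assert groups[0].category == "B"
    assert groups[0].provenance == "putative_sequencing_error"


def test_fixture_tracking_partition(tracking_fixture):
    fx = tracking_fixture
    report = run_tracking(
        fx.reads, fx.metadata, fx.reference_insert, fx.reference_scfv, fx.geometry
    )
    assert report.n_tracked == 85
    assert (report.n_identical_full, report.n_identical_core, report.n_related) == (53, 7, 25)
    assert report.category_read_counts() == {"A": 15, "B": 10}


def test_union_consistency_with_characteristics(tracking_fixture):
    fx = tracking_fixture
    annotations = annotate_many(fx.reads, fx.refdir)
    reference_ann = annotate_read("ref", fx.reference_insert, fx.refdir)
    reference_key = clonotype_key(reference_ann)
    by_chars = track_by_characteristics(reference_key, annotations)
    by_aln, _ = track_by_alignment(fx.reference_scfv, fx.reads)
    assert by_aln == {rid for rid, _ in fx.reads}  # all 85 within 20 diffs
    assert by_chars <= by_aln
    assert len(by_chars | by_aln) == 85
    # reads identical over the insert must share the reference key
    identical_ids = {read_name(n) for n in range(1, 86)
                     if not fx.mutation_lists[read_name(n)]}
    assert identical_ids <= by_chars


def test_provenance_soundness_simulated(tracking_fixture):
    """Error-model singletons are never category A; replicated spikes are."""
    fx = tracking_fixture
    rng = np.random.default_rng(77)
    model = ReadErrorModel(per_base_error=0.003)
    for trial in range(8):
        reads = []
        metadata = {}
        # spiked library variant: 3 copies across 2 samples
        variant = apply_mutations(fx.reference_insert, ["a545>g"])
        for i, (sample, cell) in enumerate((("s1", 1), ("s2", 4), ("s3", 9))):
            rid = f"spike{i}"
            reads.append((rid, variant))
            metadata[rid] = (sample, cell)
        # error-model reads (one per batch)
        from scfvtools.simulate import _apply_errors

        for i in range(6):
            seq, _ = _apply_errors(fx.reference_insert, model, rng)
            rid = f"err{i}"
            reads.append((rid, seq))
            metadata[rid] = (f"s{i % 4 + 1}", i + 1)
        report = run_tracking(reads, metadata, fx.reference_insert,
                              fx.reference_scfv, fx.geometry)
        for group in report.groups:
            if any(r.startswith("spike") for r in group.read_ids):
                assert group.category == "A"
            elif len(group.read_ids) == 1:
                assert group.category == "B"
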