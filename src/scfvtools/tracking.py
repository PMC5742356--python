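"""Reference-clone tracking, identity classes, and mutation provenance.

Two complementary tracking routes are implemented: by clonotype key (same V
and J alleles and amino-acid junctions for both domains, layout-aware) and by
alignment against the reference scFv nucleotide sequence (full-reference
coverage, bounded mismatch+indel count).  Tracked reads are then classified
against the full reference insert as ``identical_full`` (byte-identical),
``identical_core`` (identical over the core span, all differences outside
it), or ``related``; differences are localized on the insert geometry and
grouped into mutation-signature groups whose replication across independent
PCR samples determines library provenance (category A) versus undetermined
singletons (category B).
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from typing import Iterable, Optional, Sequence

import pandas as pd

from . import align
from .geometry import InsertGeometry
from .mutations import MutationRecord, format_mutation, parse_mutation  # noqa: F401 (re-export)

_GLOBAL = align.make_aligner("global")
_GLOCAL = align.make_glocal_aligner()
_LOCAL = align.make_aligner("local")

PRIMER_CLASSES = frozenset({"fwd_primer_end", "rev_primer_end", "rev_primer_vicinity"})


@dataclasses.dataclass(frozen=True)
class ClonotypeKey:
    layout: str
    domain1: tuple[str, str, str]  # (v_call, j_call, junction_aa)
    domain2: tuple[str, str, str]


def clonotype_key(ann) -> ClonotypeKey:
    """Association identity of one annotated scFv read."""
    for domain in (ann.domain1, ann.domain2):
        if (
            domain is None
            or not domain.v_call
            or not domain.j_call
            or not domain.junction_aa
        ):
            raise ValueError(f"untyped domain in read {ann.read_id!r}")
    return ClonotypeKey(
        layout=ann.layout,
        domain1=(ann.domain1.v_call, ann.domain1.j_call, ann.domain1.junction_aa),
        domain2=(ann.domain2.v_call, ann.domain2.j_call, ann.domain2.junction_aa),
    )


EXPECTED_LAYOUTS = ("VH-VL", "VL-VH")


def rank_associations(passed_annotations: Sequence) -> pd.DataFrame:
    """Ranked table of expected-layout clonotype associations.

    Descending by read count; ties share the minimum rank; frequency is the
    count over all expected-layout reads.
    """
    expected = [a for a in passed_annotations if a.layout in EXPECTED_LAYOUTS]
    counts: dict[ClonotypeKey, int] = defaultdict(int)
    for ann in expected:
        counts[clonotype_key(ann)] += 1
    total = len(expected)
    rows = sorted(
        counts.items(), key=lambda kv: (-kv[1], kv[0].layout, kv[0].domain1, kv[0].domain2)
    )
    out = []
    rank = 0
    prev_count = None
    for index, (key, count) in enumerate(rows, start=1):
        if count != prev_count:
            rank = index
            prev_count = count
        out.append(
            {
                "rank": rank,
                "count": count,
                "frequency": count / total if total else 0.0,
                "layout": key.layout,
                "d1_v_call": key.domain1[0],
                "d1_j_call": key.domain1[1],
                "d1_junction_aa": key.domain1[2],
                "d2_v_call": key.domain2[0],
                "d2_j_call": key.domain2[1],
                "d2_junction_aa": key.domain2[2],
            }
        )
    return pd.DataFrame(
        out,
        columns=[
            "rank",
            "count",
            "frequency",
            "layout",
            "d1_v_call",
            "d1_j_call",
            "d1_junction_aa",
            "d2_v_call",
            "d2_j_call",
            "d2_junction_aa",
        ],
    )


def track_by_characteristics(reference_key: ClonotypeKey, annotations: Sequence) -> set[str]:
    """Read ids whose clonotype key equals the reference key."""
    matched = set()
    for ann in annotations:
        try:
            key = clonotype_key(ann)
        except ValueError:
            continue
        if key == reference_key:
            matched.add(ann.read_id)
    return matched


@dataclasses.dataclass(frozen=True)
class AlignmentTrackStats:
    read_id: str
    retained: bool
    coverage: float
    identity: float
    diff_count: int
    strand: str


def _count_glocal_diffs(reference: str, read: str) -> tuple[int, int, int]:
    """(mismatches+indel nt, aligned reference nt, matches) for a
    full-reference glocal alignment of ``reference`` inside ``read``."""
    aln = _GLOCAL.align(read, reference)[0]
    mismatches = 0
    matches = 0
    indel_nt = 0
    for t, q in align.iter_columns(aln):
        if t is not None and q is not None:
            if read[t].upper() == reference[q].upper():
                matches += 1
            else:
                mismatches += 1
        elif q is not None:
            indel_nt += 1  # reference base deleted from the read
        # read-only columns are handled below (internal insertions only)
    # insertions: read bases between aligned reference columns
    coords = aln.coordinates
    for k in range(coords.shape[1] - 1):
        t0, q0 = int(coords[0, k]), int(coords[1, k])
        t1, q1 = int(coords[0, k + 1]), int(coords[1, k + 1])
        if t1 > t0 and q1 == q0 and 0 < q0 < len(reference):
            indel_nt += t1 - t0
    return mismatches + indel_nt, matches + mismatches, matches


def track_by_alignment(
    reference_seq: str,
    reads: Iterable[tuple[str, str]],
    max_diffs: int = 20,
) -> tuple[set[str], list[AlignmentTrackStats]]:
    """Track reads by alignment against the reference scFv sequence.

    A read is retained iff the alignment covers the full reference and the
    number of mismatches plus inserted plus deleted nucleotides is at most
    ``max_diffs``.  Both read orientations are considered.
    """
    if len(reference_seq) < 100:
        raise ValueError("reference sequence shorter than 100 nt")
    retained = set()
    stats = []
    for read_id, seq in reads:
        best = None
        for strand, oriented in (("forward", seq), ("reverse", align.revcomp(seq))):
            score = _GLOCAL.score(oriented, reference_seq)
            if best is None or score > best[0]:
                best = (score, strand, oriented)
        _, strand, oriented = best
        diffs, aligned_cols, matches = _count_glocal_diffs(reference_seq, oriented)
        coverage = aligned_cols / len(reference_seq)
        identity = matches / aligned_cols if aligned_cols else 0.0
        ok = diffs <= max_diffs
        stats.append(
            AlignmentTrackStats(read_id, ok, coverage, identity, diffs, strand)
        )
        if ok:
            retained.add(read_id)
    return retained, stats


def orient_to_reference(read: str, reference: str) -> str:
    """Return the read orientation that aligns best to the reference."""
    fwd_score = _LOCAL.score(read, reference)
    rc = align.revcomp(read)
    rev_score = _LOCAL.score(rc, reference)
    return rc if rev_score > fwd_score else read


def _normalize_right(records: list[MutationRecord], reference: str) -> list[MutationRecord]:
    """Shift indels to their 3'-most equivalent placement."""
    out: list[MutationRecord] = []
    boundaries = sorted(r.position for r in records)
    for rec in records:
        if rec.kind in ("deletion", "range_deletion"):
            start, end = rec.position, rec.end or rec.position
            limit = min(
                [b for b in boundaries if b > end] + [len(reference) + 1]
            )
            while end + 1 < limit and end < len(reference) and reference[end] == reference[start - 1]:
                start += 1
                end += 1
            ref_bases = (
                reference[start - 1].lower()
                if start == end
                else reference[start - 1].lower() + reference[end - 1].lower()
            )
            if start == end:
                out.append(dataclasses.replace(rec, kind="deletion", position=start, ref_bases=ref_bases, end=None))
            else:
                out.append(dataclasses.replace(rec, position=start, ref_bases=ref_bases, end=end))
        elif rec.kind == "insertion":
            pos, bases = rec.position, rec.alt_bases
            limit = min([b for b in boundaries if b > pos] + [len(reference) + 1])
            while pos + 1 < limit and pos < len(reference) and reference[pos].upper() == bases[0].upper():
                bases = bases[1:] + bases[0]
                pos += 1
            out.append(dataclasses.replace(rec, position=pos, alt_bases=bases.lower()))
        else:
            out.append(rec)
    return sorted(out, key=lambda r: (r.position, r.kind))


def extract_diffs(read: str, reference: str) -> list[MutationRecord]:
    """Differences of ``read`` vs ``reference`` in reference coordinates.

    Uses a global alignment (end gaps penalised), merges gap runs into single
    or range deletions / multi-base insertions, and right-normalises indels
    within homopolymer runs.
    """
    if read == reference:
        return []
    aln = _GLOBAL.align(read, reference)[0]
    records: list[MutationRecord] = []
    pending_del: list[int] = []
    pending_ins: Optional[tuple[int, list[str]]] = None
    last_q = None

    def flush_del() -> None:
        if not pending_del:
            return
        start, end = pending_del[0], pending_del[-1]
        if start == end:
            records.append(MutationRecord("deletion", start, reference[start - 1].lower()))
        else:
            records.append(
                MutationRecord(
                    "range_deletion",
                    start,
                    reference[start - 1].lower() + reference[end - 1].lower(),
                    end=end,
                )
            )
        pending_del.clear()

    def flush_ins() -> None:
        nonlocal pending_ins
        if pending_ins is not None:
            pos, bases = pending_ins
            records.append(MutationRecord("insertion", pos, alt_bases="".join(bases)))
            pending_ins = None

    for t, q in align.iter_columns(aln):
        if t is not None and q is not None:
            flush_del()
            flush_ins()
            if read[t].upper() != reference[q].upper():
                records.append(
                    MutationRecord(
                        "substitution", q + 1, reference[q].lower(), read[t].lower()
                    )
                )
            last_q = q
        elif q is not None:
            flush_ins()
            pending_del.append(q + 1)
            last_q = q
        else:
            flush_del()
            pos = (last_q + 1) if last_q is not None else 0
            if pending_ins is None:
                pending_ins = (pos, [])
            pending_ins[1].append(read[t].lower())
    flush_del()
    flush_ins()
    return _normalize_right(records, reference)


def localize_mutation(
    mutation: MutationRecord,
    geometry: InsertGeometry,
    domain_spans: Optional[dict[str, tuple[int, int]]] = None,
) -> str:
    """Localization label for a mutation on the insert geometry.

    ``domain_spans`` may override the VH/VL spans (e.g. from an annotation);
    by default the scFv segments flanking the linker are used.
    """
    pos = mutation.position

    def within(span: tuple[int, int]) -> bool:
        return span[0] <= pos <= span[1]

    if within(geometry.fwd_primer_span):
        return "fwd_primer_end"
    if within(geometry.rev_primer_span):
        return "rev_primer_end"
    if geometry.core_span[1] < pos < geometry.rev_primer_span[0]:
        return "rev_primer_vicinity"
    vh_span = (domain_spans or {}).get("VH", geometry.vh_like_span)
    vl_span = (domain_spans or {}).get("VL", geometry.vl_like_span)
    if within(vh_span):
        return "insert_VH"
    if within(geometry.linker_span):
        return "insert_linker"
    if within(vl_span):
        return "insert_VL"
    return "insert_flank"


def localize_all(
    mutations: Iterable[MutationRecord],
    geometry: InsertGeometry,
    domain_spans: Optional[dict[str, tuple[int, int]]] = None,
) -> list[MutationRecord]:
    return [
        m.with_localization(localize_mutation(m, geometry, domain_spans))
        for m in mutations
    ]


def classify_identity(
    read: str, reference_insert: str, geometry: InsertGeometry
) -> tuple[str, list[MutationRecord]]:
    """Identity class of a tracked read vs the full reference insert.

    Returns ``(class, localized differences)`` with class in
    ``{identical_full, identical_core, related}``.
    """
    if read.upper() == reference_insert.upper():
        return "identical_full", []
    diffs = localize_all(extract_diffs(read, reference_insert), geometry)
    lo, hi = geometry.core_span
    for diff in diffs:
        if diff.kind == "insertion":
            # inserted bases sit between position and position+1
            if diff.position + 1 > lo and diff.position < hi:
                return "related", diffs
        else:
            start, end = diff.span
            if start <= hi and end >= lo:
                return "related", diffs
    return "identical_core", diffs


def _is_terminal_range_deletion(m: MutationRecord, geometry: InsertGeometry) -> bool:
    return m.kind == "range_deletion" and (
        m.position == 1 or (m.end or m.position) == geometry.total_len
    )


def signature_of(diffs: Sequence[MutationRecord], geometry: InsertGeometry) -> tuple[str, ...]:
    """Grouping signature: insert-localized mutations, excluding primer-end /
    primer-vicinity changes and terminal range deletions."""
    kept = [
        m
        for m in diffs
        if m.localization not in PRIMER_CLASSES
        and not _is_terminal_range_deletion(m, geometry)
    ]
    return tuple(sorted(m.nomenclature for m in kept))


@dataclasses.dataclass(frozen=True)
class TrackedRead:
    read_id: str
    pcr_sample_id: str
    smrt_cell_id: int
    identity_class: str
    diffs: tuple[MutationRecord, ...]


@dataclasses.dataclass(frozen=True)
class SignatureGroup:
    signature: tuple[str, ...]
    read_ids: tuple[str, ...]
    pcr_samples: tuple[str, ...]
    smrt_cells: tuple[int, ...]
    category: str  # A | B
    provenance: str


def classify_provenance(
    related_reads: Sequence[TrackedRead],
    geometry: InsertGeometry,
    rule: str = "pcr_samples",
) -> list[SignatureGroup]:
    """Group related reads by mutation signature and assign categories.

    Category A (library provenance) requires a signature replicated in >= 2
    reads spanning >= 2 distinct PCR samples (``rule="pcr_samples"``) or
    >= 2 distinct SMRT cells (``rule="smrt_cells"``).  Everything else is
    category B: singletons carrying any indel are flagged
    ``putative_sequencing_error``, substitution-only singletons
    ``putative_pcr_or_library``, replicated-but-unconfirmed groups
    ``unassigned``.
    """
    if rule not in ("pcr_samples", "smrt_cells"):
        raise ValueError(f"unknown provenance rule {rule!r}")
    by_signature: dict[tuple[str, ...], list[TrackedRead]] = defaultdict(list)
    for read in related_reads:
        by_signature[signature_of(read.diffs, geometry)].append(read)
    groups = []
    for signature in sorted(by_signature):
        members = sorted(by_signature[signature], key=lambda r: r.read_id)
        samples = sorted({r.pcr_sample_id for r in members})
        cells = sorted({r.smrt_cell_id for r in members})
        replicates = len(samples) if rule == "pcr_samples" else len(cells)
        if len(members) >= 2 and replicates >= 2:
            category, provenance = "A", "library"
        else:
            category = "B"
            if len(members) == 1:
                has_indel = any(m.is_indel for m in members[0].diffs)
                provenance = (
                    "putative_sequencing_error" if has_indel else "putative_pcr_or_library"
                )
            else:
                provenance = "unassigned"
        groups.append(
            SignatureGroup(
                signature=signature,
                read_ids=tuple(r.read_id for r in members),
                pcr_samples=tuple(samples),
                smrt_cells=tuple(cells),
                category=category,
                provenance=provenance,
            )
        )
    return groups


@dataclasses.dataclass
class TrackingReport:
    reference_id: str
    n_identical_full: int
    n_identical_core: int
    n_related: int
    reads: list[TrackedRead]
    groups: list[SignatureGroup]
    alignment_stats: list[AlignmentTrackStats]

    @property
    def n_tracked(self) -> int:
        return self.n_identical_full + self.n_identical_core + self.n_related

    def provenance_of(self, read_id: str) -> Optional[str]:
        for group in self.groups:
            if read_id in group.read_ids:
                return group.provenance
        return None

    def category_read_counts(self) -> dict[str, int]:
        counts = {"A": 0, "B": 0}
        for group in self.groups:
            counts[group.category] += len(group.read_ids)
        return counts

    def reads_frame(self) -> pd.DataFrame:
        rows = []
        for read in self.reads:
            rows.append(
                {
                    "read_id": read.read_id,
                    "pcr_sample_id": read.pcr_sample_id,
                    "smrt_cell_id": read.smrt_cell_id,
                    "identity_class": read.identity_class,
                    "mutations": ";".join(m.nomenclature for m in read.diffs),
                    "localizations": ";".join(m.localization or "" for m in read.diffs),
                    "provenance": self.provenance_of(read.read_id) or "",
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "read_id",
                "pcr_sample_id",
                "smrt_cell_id",
                "identity_class",
                "mutations",
                "localizations",
                "provenance",
            ],
        )

    def groups_frame(self) -> pd.DataFrame:
        rows = []
        for group in self.groups:
            rows.append(
                {
                    "category": group.category,
                    "n_reads": len(group.read_ids),
                    "read_ids": ",".join(group.read_ids),
                    "pcr_samples": ",".join(group.pcr_samples),
                    "smrt_cells": ",".join(str(c) for c in group.smrt_cells),
                    "signature": ";".join(group.signature),
                    "provenance": group.provenance,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "category",
                "n_reads",
                "read_ids",
                "pcr_samples",
                "smrt_cells",
                "signature",
                "provenance",
            ],
        )


def run_tracking(
    reads: Sequence[tuple[str, str]],
    metadata: dict[str, tuple[str, int]],
    reference_insert: str,
    reference_scfv: str,
    geometry: InsertGeometry,
    annotations: Optional[Sequence] = None,
    reference_key: Optional[ClonotypeKey] = None,
    max_diffs: int = 20,
    rule: str = "pcr_samples",
    reference_id: str = "reference",
) -> TrackingReport:
    """Run both tracking approaches and the full classification chain."""
    by_alignment, stats = track_by_alignment(reference_scfv, reads, max_diffs)
    tracked_ids = set(by_alignment)
    if annotations is not None and reference_key is not None:
        tracked_ids |= track_by_characteristics(reference_key, annotations)

    seq_by_id = dict(reads)
    tracked: list[TrackedRead] = []
    counts = {"identical_full": 0, "identical_core": 0, "related": 0}
    for read_id in sorted(tracked_ids):
        oriented = orient_to_reference(seq_by_id[read_id].upper(), reference_insert)
        identity_class, diffs = classify_identity(oriented, reference_insert, geometry)
        counts[identity_class] += 1
        sample, cell = metadata.get(read_id, ("", -1))
        tracked.append(
            TrackedRead(read_id, sample, int(cell), identity_class, tuple(diffs))
        )
    related = [r for r in tracked if r.identity_class == "related"]
    groups = classify_provenance(related, geometry, rule=rule)
    return TrackingReport(
        reference_id=reference_id,
        n_identical_full=counts["identical_full"],
        n_identical_core=counts["identical_core"],
        n_related=counts["related"],
        reads=tracked,
        groups=groups,
        alignment_stats=stats,
    )
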