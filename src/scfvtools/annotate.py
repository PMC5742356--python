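"""Dual V-domain detection and germline annotation of long amplicon reads.

Each read is oriented so its best V-allele hit lies on the forward strand,
then up to two non-overlapping V-domain hits are retained and annotated:
closest germline V and J alleles, V-REGION percent identity (gap columns in
the denominator), junction extraction between the V 2nd-CYS and J-TRP/J-PHE
anchor codons, frame determination, and enumeration of differences against
the germline V.  Domain-level mutations are expressed in germline V allele
coordinates.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

from Bio.Seq import Seq

from . import align
from .germline import GermlineAllele, ReferenceDirectory
from .mutations import MutationRecord
from .filtering import round2

MIN_DOMAIN_SCORE = 60
MIN_J_SCORE = 30
WINDOW_PAD = 60
J_WINDOW = 170
D_MIN_CORE = 5

_LOCAL = align.make_aligner("local")


@dataclasses.dataclass(frozen=True)
class DomainHit:
    allele_name: str
    chain_kind: str
    score: float
    read_span: tuple[int, int]  # 0-based half-open on the oriented read


@dataclasses.dataclass(frozen=True)
class DomainAnnotation:
    domain_kind: str  # VH | VL
    strand: str  # forward | reverse (strand of the original read)
    read_span: tuple[int, int]  # 1-based inclusive on the oriented read
    v_call: str
    j_call: Optional[str]
    d_call: str
    v_identity_pct: float
    junction_nt: str
    junction_aa: str
    in_frame: bool
    mutations: tuple[MutationRecord, ...]


@dataclasses.dataclass(frozen=True)
class ScFvAnnotation:
    read_id: str
    layout: str
    domain1: Optional[DomainAnnotation]
    domain2: Optional[DomainAnnotation]
    linker_span: Optional[tuple[int, int]]
    is_scfv_candidate: bool
    strand: str
    oriented_sequence: str


def orient_read(read: str, refdir: ReferenceDirectory, k: int = 13) -> tuple[str, str]:
    """Return ``(oriented_sequence, strand)`` for a read.

    Orientation is chosen by exact k-mer votes against the V-allele set, with
    a full alignment-score comparison as fallback on ties.
    """
    seq = read.upper()
    fwd_kmers, rev_kmers = refdir.v_kmers(k)
    fwd_votes = 0
    rev_votes = 0
    for i in range(0, len(seq) - k + 1):
        kmer = seq[i : i + k]
        if kmer in fwd_kmers:
            fwd_votes += 1
        if kmer in rev_kmers:
            rev_votes += 1
    if fwd_votes > rev_votes:
        return seq, "forward"
    if rev_votes > fwd_votes:
        return align.revcomp(seq), "reverse"
    rc = align.revcomp(seq)
    best_fwd = max((_LOCAL.score(seq, a.sequence) for a in refdir.v_alleles()), default=0)
    best_rev = max((_LOCAL.score(rc, a.sequence) for a in refdir.v_alleles()), default=0)
    if best_rev > best_fwd:
        return rc, "reverse"
    return seq, "forward"


def _kmer_shortlist(
    segment: str, refdir: ReferenceDirectory, top: int, k: int = 13
) -> list:
    """V alleles ranked by shared exact k-mers with ``segment``.

    Falls back to the full allele list when nothing seeds (deep divergence).
    """
    seg_kmers = {segment[i : i + k] for i in range(len(segment) - k + 1)}
    counts = []
    for name, kmers in refdir.v_kmers_by_allele(k).items():
        counts.append((len(seg_kmers & kmers), name))
    counts.sort(key=lambda pair: (-pair[0], pair[1]))
    if not counts or counts[0][0] == 0:
        return refdir.v_alleles()
    return [refdir[name] for hits, name in counts[:top] if hits > 0]


def _best_segment_hit(
    segment: str,
    offset: int,
    refdir: ReferenceDirectory,
) -> Optional[DomainHit]:
    if len(segment) < 20:
        return None
    best: Optional[tuple[float, str]] = None
    for allele in _kmer_shortlist(segment, refdir, top=3):
        score = _LOCAL.score(segment, allele.sequence)
        if best is None or score > best[0] or (score == best[0] and allele.allele_name < best[1]):
            best = (score, allele.allele_name)
    if best is None or best[0] <= 0:
        return None
    allele = refdir[best[1]]
    alignment = _LOCAL.align(segment, allele.sequence)[0]
    t0, t1 = align.aligned_target_range(alignment)
    return DomainHit(
        allele_name=allele.allele_name,
        chain_kind=allele.chain_kind,
        score=float(best[0]),
        read_span=(offset + t0, offset + t1),
    )


def detect_v_domains(
    read: str,
    refdir: ReferenceDirectory,
    min_score: float = MIN_DOMAIN_SCORE,
) -> tuple[str, str, list[DomainHit]]:
    """Detect up to two non-overlapping V-domain hits.

    Returns ``(oriented_read, strand, hits)`` with hits ordered 5'->3' on the
    oriented read.  The second hit is searched outside the span of the first
    and must reach ``min_score``.
    """
    oriented, strand = orient_read(read, refdir)
    first = _best_segment_hit(oriented, 0, refdir)
    if first is None or first.score < min_score:
        return oriented, strand, []
    hits = [first]
    s, e = first.read_span
    candidates = [
        _best_segment_hit(oriented[:s], 0, refdir),
        _best_segment_hit(oriented[e:], e, refdir),
    ]
    second = None
    for hit in candidates:
        if hit is None or hit.score < min_score:
            continue
        if second is None or hit.score > second.score:
            second = hit
    if second is not None:
        hits.append(second)
    hits.sort(key=lambda h: h.read_span[0])
    return oriented, strand, hits


def _v_region_seq(allele: GermlineAllele) -> str:
    lo, hi = allele.v_region_span
    return allele.sequence[lo - 1 : hi]


def _enumerate_v_mutations(alignment, window: str, allele: GermlineAllele) -> tuple[MutationRecord, ...]:
    """Differences vs the germline V, in germline allele coordinates."""
    lo, hi = allele.v_region_span
    records: list[MutationRecord] = []
    pending_del: list[int] = []
    pending_ins: tuple[int, list[str]] | None = None

    def flush_del() -> None:
        if not pending_del:
            return
        start, end = pending_del[0], pending_del[-1]
        if start == end:
            records.append(
                MutationRecord("deletion", start, allele.sequence[start - 1].lower())
            )
        else:
            records.append(
                MutationRecord(
                    "range_deletion",
                    start,
                    allele.sequence[start - 1].lower() + allele.sequence[end - 1].lower(),
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

    last_q = None
    for t, q in align.iter_columns(alignment):
        if q is not None and not (lo - 1 <= q <= hi - 1):
            last_q = q
            continue
        if t is not None and q is not None:
            flush_del()
            flush_ins()
            if window[t].upper() != allele.sequence[q].upper():
                records.append(
                    MutationRecord(
                        "substitution",
                        q + 1,
                        allele.sequence[q].lower(),
                        window[t].lower(),
                    )
                )
            last_q = q
        elif q is not None:  # germline base missing from the read
            flush_ins()
            pending_del.append(q + 1)
            last_q = q
        else:  # extra read base
            flush_del()
            pos = (last_q + 1) if last_q is not None else 0
            if pending_ins is None:
                pending_ins = (pos, [])
            pending_ins[1].append(window[t].lower())
    flush_del()
    flush_ins()
    return tuple(records)


def _translate(junction_nt: str) -> str:
    usable = len(junction_nt) - len(junction_nt) % 3
    return str(Seq(junction_nt[:usable]).translate()) if usable else ""


def _longest_common_exact(a: str, b: str) -> int:
    best = 0
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def annotate_domain(
    oriented: str,
    hit: DomainHit,
    refdir: ReferenceDirectory,
    strand: str = "forward",
) -> DomainAnnotation:
    """Full germline annotation of one detected V-domain hit."""
    s, e = hit.read_span
    w0 = max(0, s - WINDOW_PAD)
    w1 = min(len(oriented), e + WINDOW_PAD)
    window = oriented[w0:w1]

    # Shortlist closest-allele candidates by alignment score, then rank the
    # shortlist by canonical identity.  A coverage floor (half the V-REGION)
    # keeps short spurious cross-chain alignments from winning on identity.
    scored = sorted(
        (
            (_LOCAL.score(window, _v_region_seq(a)), a)
            for a in _kmer_shortlist(window, refdir, top=4)
        ),
        key=lambda pair: (-pair[0], pair[1].allele_name),
    )
    shortlist = [
        allele
        for score, allele in scored[:4]
        if score >= scored[0][0] - 40 and score > 0
    ]
    best_key = None
    best_allele = None
    best_stats = (0, 0, 0)
    for allele in shortlist:
        region = _v_region_seq(allele)
        score, matches, columns = align.local_identity(window, region)
        if columns < 0.5 * len(region):
            continue
        identity = matches / columns
        key = (-identity, -columns, allele.allele_name)
        if best_key is None or key < best_key:
            best_key = key
            best_allele = allele
            best_stats = (score, matches, columns)
    if best_allele is None:  # degenerate hit: fall back to the score ranking
        best_allele = scored[0][1]
        best_stats = align.local_identity(window, _v_region_seq(best_allele))
        if best_stats[2] == 0:
            raise ValueError("domain hit has no alignable V allele")
    v = best_allele
    _, matches, columns = best_stats
    v_identity_pct = float(round2(100.0 * matches / columns))

    v_aln = _LOCAL.align(window, v.sequence)[0]
    vt0, vt1 = align.aligned_target_range(v_aln)
    read_start = w0 + vt0
    read_end = w0 + vt1  # half-open

    mutations = _enumerate_v_mutations(v_aln, window, v)

    # J assignment downstream of the V hit
    j_seg_start = read_end
    j_segment = oriented[j_seg_start : j_seg_start + J_WINDOW]
    j_call: Optional[str] = None
    j_aln = None
    j_allele = None
    if j_segment:
        best_j = None
        for allele in refdir.j_alleles(v.chain_kind):
            score = _LOCAL.score(j_segment, allele.sequence)
            if best_j is None or score > best_j[0] or (
                score == best_j[0] and allele.allele_name < best_j[1]
            ):
                best_j = (score, allele.allele_name)
        if best_j is not None and best_j[0] >= MIN_J_SCORE:
            j_allele = refdir[best_j[1]]
            j_call = j_allele.allele_name
            j_aln = _LOCAL.align(j_segment, j_allele.sequence)[0]

    junction_nt = ""
    junction_aa = ""
    in_frame = False
    span_end = read_end
    if j_aln is not None:
        v_anchor_read = align.map_query_to_target(v_aln, v.anchor_pos - 1)
        j_anchor_read = align.map_query_to_target(j_aln, j_allele.anchor_pos + 1)
        jt0, jt1 = align.aligned_target_range(j_aln)
        span_end = j_seg_start + jt1
        if v_anchor_read is not None and j_anchor_read is not None:
            jstart = w0 + v_anchor_read
            jend = j_seg_start + j_anchor_read
            if jend > jstart:
                junction_nt = oriented[jstart : jend + 1]
                junction_aa = _translate(junction_nt)
                in_frame = len(junction_nt) % 3 == 0

    domain_kind = "VH" if v.chain_kind == "heavy" else "VL"
    d_call = "not assigned"
    if domain_kind == "VH" and junction_nt:
        best_d = None
        for allele in refdir.d_alleles("heavy"):
            core = _longest_common_exact(junction_nt.upper(), allele.sequence)
            if core >= D_MIN_CORE and (
                best_d is None
                or core > best_d[0]
                or (core == best_d[0] and allele.allele_name < best_d[1])
            ):
                best_d = (core, allele.allele_name)
        if best_d is not None:
            d_call = best_d[1]

    return DomainAnnotation(
        domain_kind=domain_kind,
        strand=strand,
        read_span=(read_start + 1, span_end),
        v_call=v.allele_name,
        j_call=j_call,
        d_call=d_call,
        v_identity_pct=v_identity_pct,
        junction_nt=junction_nt,
        junction_aa=junction_aa,
        in_frame=in_frame,
        mutations=mutations,
    )


def classify_layout(
    domain1: Optional[DomainAnnotation], domain2: Optional[DomainAnnotation]
) -> str:
    if domain1 is None or domain2 is None:
        return "incomplete"
    return f"{domain1.domain_kind}-{domain2.domain_kind}"


def locate_linker(
    ann: ScFvAnnotation,
    linker_seq: str,
    max_mismatch: int = 5,
) -> Optional[tuple[int, int]]:
    """Best approximate linker occurrence between the two domain spans."""
    if ann.domain1 is None or ann.domain2 is None:
        return None
    seg_start = ann.domain1.read_span[1]  # 0-based index just past domain 1
    seg_end = ann.domain2.read_span[0] - 1
    segment = ann.oriented_sequence[seg_start:seg_end]
    if not segment:
        return None
    distance, lo, hi = align.edit_distance_infix(linker_seq.upper(), segment.upper())
    if distance > max_mismatch:
        return None
    return (seg_start + lo + 1, seg_start + hi)


def annotate_read(
    read_id: str,
    sequence: str,
    refdir: ReferenceDirectory,
    linker_seq: Optional[str] = None,
    min_score: float = MIN_DOMAIN_SCORE,
    max_linker_mismatch: int = 5,
) -> ScFvAnnotation:
    """End-to-end annotation of one read."""
    oriented, strand, hits = detect_v_domains(sequence, refdir, min_score)
    domains = [annotate_domain(oriented, hit, refdir, strand) for hit in hits]
    domain1 = domains[0] if domains else None
    domain2 = domains[1] if len(domains) > 1 else None
    ann = ScFvAnnotation(
        read_id=read_id,
        layout=classify_layout(domain1, domain2),
        domain1=domain1,
        domain2=domain2,
        linker_span=None,
        is_scfv_candidate=domain1 is not None and domain2 is not None,
        strand=strand,
        oriented_sequence=oriented,
    )
    if linker_seq and ann.is_scfv_candidate:
        ann = dataclasses.replace(
            ann, linker_span=locate_linker(ann, linker_seq, max_linker_mismatch)
        )
    return ann


def annotate_many(
    reads: Sequence[tuple[str, str]],
    refdir: ReferenceDirectory,
    linker_seq: Optional[str] = None,
    min_score: float = MIN_DOMAIN_SCORE,
) -> list[ScFvAnnotation]:
    return [
        annotate_read(read_id, seq, refdir, linker_seq=linker_seq, min_score=min_score)
        for read_id, seq in reads
    ]
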