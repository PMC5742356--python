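"""Pairwise alignment primitives shared across the package.

Two engines cooperate here:

* Biopython's :class:`Bio.Align.PairwiseAligner` (C implementation) is used
  wherever an explicit alignment path is needed: hit detection, anchor
  mapping, and difference extraction.
* :func:`local_identity` is an int64 numpy affine-gap Smith-Waterman that
  reports the identity of the *canonical* optimal local alignment.  When
  several alignments share the optimal score, the one with the most matched
  columns is chosen, and among those the one with the fewest alignment
  columns.  This makes "percent identity of the best local alignment" a
  well-defined, order-independent statistic.

Scoring is the package-wide nucleotide scheme: match +2, mismatch -3,
gap open -6 (first gap column), gap extend -1.
"""

from __future__ import annotations

from typing import Iterator, Optional

import numpy as np
from Bio import Align

MATCH_SCORE = 2
MISMATCH_SCORE = -3
GAP_OPEN = -6
GAP_EXTEND = -1

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

# Composite encoding: value = SCORE_W * score + MATCH_W * matches - columns.
# MATCH_W exceeds any possible column count and SCORE_W exceeds any possible
# |MATCH_W * matches - columns|, so maximising the composite maximises
# (score, matches, -columns) lexicographically.  Bounds assume sequences of
# at most ~100 kb, far beyond any amplicon handled here.
_MATCH_W = 1 << 18
_SCORE_W = 1 << 38


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def make_aligner(mode: str = "local") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def make_glocal_aligner() -> Align.PairwiseAligner:
    """Global on the query, free end gaps on the target.

    Used to force full coverage of a reference (query) inside a longer read
    (target) while still penalising internal indels.
    """
    aligner = make_aligner("global")
    # Read (target) overhangs beyond the reference are free; the reference
    # (query) must align end to end.  Attribute names changed across
    # Biopython releases.
    try:
        aligner.open_end_deletion_score = 0
        aligner.extend_end_deletion_score = 0
    except AttributeError:  # pragma: no cover - older Biopython
        aligner.query_end_open_gap_score = 0
        aligner.query_end_extend_gap_score = 0
    return aligner


def local_identity(target: str, query: str) -> tuple[int, int, int]:
    """Canonical local alignment statistics for ``target`` vs ``query``.

    Returns ``(score, matches, columns)`` of the optimal-score local
    alignment, tie-broken to maximise matches and then minimise columns.
    ``columns`` counts aligned pairs plus internal gap columns.  An empty
    optimal alignment returns ``(0, 0, 0)``.
    """
    if not target or not query:
        return (0, 0, 0)
    if len(target) < len(query):  # iterate over the shorter axis; statistics
        target, query = query, target  # are symmetric under transposition
    t = np.frombuffer(target.upper().encode(), dtype=np.uint8)
    q = np.frombuffer(query.upper().encode(), dtype=np.uint8)
    n = q.size

    # Per-column composite contributions.
    match_step = MATCH_SCORE * _SCORE_W + _MATCH_W - 1
    mismatch_step = MISMATCH_SCORE * _SCORE_W - 1
    open_step = GAP_OPEN * _SCORE_W - 1
    extend_step = GAP_EXTEND * _SCORE_W - 1

    neg_inf = np.int64(-(1 << 60))
    h_prev = np.zeros(n + 1, dtype=np.int64)   # best ending in aligned pair
    x_prev = np.full(n + 1, neg_inf, dtype=np.int64)  # gap in query (vertical)
    best = np.int64(0)

    for i in range(t.size):
        sub = np.where(q == t[i], match_step, mismatch_step)
        # H[i][j]: fresh start allowed (local), from diag of any state.
        diag = np.maximum(np.maximum(h_prev[:-1], x_prev[:-1]), 0)
        h_cur = np.empty(n + 1, dtype=np.int64)
        h_cur[0] = neg_inf
        h_cur[1:] = diag + sub
        # X (vertical gap) from previous row.
        x_cur = np.maximum(h_prev + open_step, x_prev + extend_step)
        # Y (horizontal gap) via prefix-max scan over the current H row:
        # Y[j] = max_{k<j} H[k] + open + (j-1-k)*extend.
        idx = np.arange(n + 1, dtype=np.int64)
        scan = np.maximum.accumulate(h_cur - idx * extend_step)
        y_cur = np.full(n + 1, neg_inf, dtype=np.int64)
        if n >= 1:
            y_cur[1:] = scan[:-1] + (idx[1:] - 1) * extend_step + open_step
        # Local alignments never profitably end in a gap column, but a gap
        # may be followed by aligned pairs; fold Y into the diag source for
        # the *next* row by merging into h candidates via x/y storage.
        h_cur = np.maximum(h_cur, neg_inf)
        best = max(best, np.int64(h_cur.max()))
        # Next row's diag can come from H, X or Y of this row.
        h_prev = np.maximum(h_cur, y_cur)
        x_prev = x_cur

    composite = int(best)
    if composite <= 0:
        return (0, 0, 0)
    score = composite // _SCORE_W
    rem = composite - score * _SCORE_W
    if rem < 0:  # score was rounded up past the remainder
        score -= 1
        rem = composite - score * _SCORE_W
    matches = (rem + _MATCH_W - 1) // _MATCH_W
    columns = _MATCH_W * matches - rem
    return (int(score), int(matches), int(columns))


def identity_pct(target: str, query: str) -> float:
    """Percent identity of the canonical best local alignment (0-100)."""
    _, matches, columns = local_identity(target, query)
    if columns == 0:
        return 0.0
    return 100.0 * matches / columns


def iter_columns(alignment: Align.Alignment) -> Iterator[tuple[Optional[int], Optional[int]]]:
    """Yield one ``(target_index, query_index)`` pair per alignment column.

    Gap columns carry ``None`` on the gapped side.  End gaps of global
    alignments are included.
    """
    coords = alignment.coordinates
    for k in range(coords.shape[1] - 1):
        t0, q0 = int(coords[0, k]), int(coords[1, k])
        t1, q1 = int(coords[0, k + 1]), int(coords[1, k + 1])
        if t1 > t0 and q1 > q0:
            for d in range(t1 - t0):
                yield (t0 + d, q0 + d)
        elif t1 > t0:
            for d in range(t1 - t0):
                yield (t0 + d, None)
        else:
            for d in range(q1 - q0):
                yield (None, q0 + d)


def map_query_to_target(alignment: Align.Alignment, query_index: int) -> Optional[int]:
    """Target index aligned to ``query_index``, or None if in a gap."""
    coords = alignment.coordinates
    for k in range(coords.shape[1] - 1):
        t0, q0 = int(coords[0, k]), int(coords[1, k])
        t1, q1 = int(coords[0, k + 1]), int(coords[1, k + 1])
        if q0 <= query_index < q1:
            if t1 > t0 and q1 > q0:
                return t0 + (query_index - q0)
            return None
    return None


def aligned_query_range(alignment: Align.Alignment) -> tuple[int, int]:
    """Half-open query interval covered by aligned (non-gap) columns."""
    blocks = alignment.aligned[1]
    if len(blocks) == 0:
        return (0, 0)
    return (int(blocks[0][0]), int(blocks[-1][1]))


def aligned_target_range(alignment: Align.Alignment) -> tuple[int, int]:
    blocks = alignment.aligned[0]
    if len(blocks) == 0:
        return (0, 0)
    return (int(blocks[0][0]), int(blocks[-1][1]))


def edit_distance_infix(needle: str, haystack: str) -> tuple[int, int, int]:
    """Best approximate occurrence of ``needle`` inside ``haystack``.

    Plain Sellers DP (unit costs, free leading/trailing haystack).  Returns
    ``(distance, start, end)`` with a 0-based half-open haystack interval of
    the best match; ties resolve to the leftmost end, then longest match.
    """
    m, n = len(needle), len(haystack)
    if m == 0:
        return (0, 0, 0)
    prev = np.zeros(n + 1, dtype=np.int32)
    starts = np.arange(n + 1, dtype=np.int32)
    prev_start = starts.copy()
    for i in range(1, m + 1):
        cur = np.empty(n + 1, dtype=np.int32)
        cur_start = np.empty(n + 1, dtype=np.int32)
        cur[0] = i
        cur_start[0] = 0
        for j in range(1, n + 1):
            sub = prev[j - 1] + (needle[i - 1] != haystack[j - 1])
            dele = prev[j] + 1
            ins = cur[j - 1] + 1
            best = min(sub, dele, ins)
            cur[j] = best
            if best == sub:
                cur_start[j] = prev_start[j - 1]
            elif best == dele:
                cur_start[j] = prev_start[j]
            else:
                cur_start[j] = cur_start[j - 1]
        prev, prev_start = cur, cur_start
    end = int(np.argmin(prev))
    return (int(prev[end]), int(prev_start[end]), end)
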