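"""Independent brute-force oracles used by the test suite only.

These deliberately avoid the production code paths: plain-Python tuple DPs
and exhaustive searches, kept simple enough to be obviously correct.
"""

from __future__ import annotations

MATCH = 2
MISMATCH = -3
OPEN = -6
EXTEND = -1

NEG = (-(10**9), 0, 0)
ZERO = (0, 0, 0)


def _add(value: tuple[int, int, int], step: tuple[int, int, int]) -> tuple[int, int, int]:
    return (value[0] + step[0], value[1] + step[1], value[2] + step[2])


def oracle_local_identity(a: str, b: str) -> tuple[int, int, int]:
    """(score, matches, columns) of the canonical best local alignment.

    Tuple-lexicographic DP over (score, matches, -columns): maximise score,
    then matches, then minimise columns.  Same alignment model as the
    production aligner: affine gaps (open -6 covering the first gap column,
    extend -1), horizontal gaps open from aligned columns only.
    """
    a, b = a.upper(), b.upper()
    if len(a) < len(b):
        a, b = b, a
    m, n = len(a), len(b)
    match_step = (MATCH, 1, -1)
    mismatch_step = (MISMATCH, 0, -1)
    open_step = (OPEN, 0, -1)
    extend_step = (EXTEND, 0, -1)

    h_prev = [ZERO] * (n + 1)
    x_prev = [NEG] * (n + 1)
    best = ZERO
    for i in range(1, m + 1):
        h_cur = [NEG] * (n + 1)
        for j in range(1, n + 1):
            step = match_step if a[i - 1] == b[j - 1] else mismatch_step
            h_cur[j] = _add(max(h_prev[j - 1], x_prev[j - 1], ZERO), step)
        x_cur = [
            max(_add(h_prev[j], open_step), _add(x_prev[j], extend_step))
            for j in range(n + 1)
        ]
        y_cur = [NEG] * (n + 1)
        for j in range(1, n + 1):
            y_cur[j] = max(_add(h_cur[j - 1], open_step), _add(y_cur[j - 1], extend_step))
        best = max(best, max(h_cur))
        h_prev = [max(h, y) for h, y in zip(h_cur, y_cur)]
        x_prev = x_cur
    if best <= ZERO:
        return (0, 0, 0)
    score, matches, neg_columns = best
    return (score, matches, -neg_columns)


def oracle_edit_distance(a: str, b: str) -> int:
    """Plain Levenshtein distance."""
    prev = list(range(len(b) + 1))
    for i in range(1, len(a) + 1):
        cur = [i]
        for j in range(1, len(b) + 1):
            cur.append(
                min(
                    prev[j - 1] + (a[i - 1] != b[j - 1]),
                    prev[j] + 1,
                    cur[j - 1] + 1,
                )
            )
        prev = cur
    return prev[-1]


def oracle_best_infix_distance(needle: str, haystack: str) -> int:
    """Minimum edit distance of needle against any haystack substring."""
    best = len(needle)
    for start in range(len(haystack) + 1):
        tail = haystack[start:]
        # needle vs every prefix of tail: one DP, min over the last row
        prev = list(range(len(needle) + 1))
        best = min(best, prev[-1])
        for j in range(1, len(tail) + 1):
            cur = [0] * (len(needle) + 1)
            cur[0] = j
            for i in range(1, len(needle) + 1):
                cur[i] = min(
                    prev[i - 1] + (needle[i - 1] != tail[j - 1]),
                    prev[i] + 1,
                    cur[i - 1] + 1,
                )
            prev = cur
            best = min(best, prev[-1])
    return best
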