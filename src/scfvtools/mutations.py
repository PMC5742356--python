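"""Mutation records, nomenclature, and sequence editing.

Nomenclature follows the compact immunogenetics style used throughout the
package outputs, with lowercase bases and 1-based positions:

* substitution      ``c322>t``
* single deletion   ``a942>del``
* range deletion    ``a886-a977>del (92 nt)``
* insertion         ``658^659>ins^cc`` (bases inserted between 658 and 659)

``parse_mutation(format_mutation(m)) == m`` for every kind.
"""

from __future__ import annotations

import dataclasses
import re
from typing import Iterable, Optional, Sequence

KINDS = ("substitution", "deletion", "insertion", "range_deletion")

_SUB_RE = re.compile(r"^([acgt])(\d+)>([acgt])$")
_DEL_RE = re.compile(r"^([acgt])(\d+)>del$")
_RANGE_DEL_RE = re.compile(r"^([acgt])(\d+)-([acgt])(\d+)>del \((\d+) nt\)$")
_INS_RE = re.compile(r"^(\d+)\^(\d+)>ins\^([acgt]+)$")


class MutationError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class MutationRecord:
    """One difference against a reference sequence.

    ``position`` is the 1-based start on the reference.  For insertions the
    bases sit between ``position`` and ``position + 1``.  ``ref_bases`` holds
    the affected reference bases (first and last suffice for range
    deletions); ``alt_bases`` the replacement/inserted bases.  Localization
    and provenance are filled in downstream of extraction.
    """

    kind: str
    position: int
    ref_bases: str = ""
    alt_bases: str = ""
    end: Optional[int] = None
    localization: Optional[str] = None
    provenance: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise MutationError(f"unknown mutation kind {self.kind!r}")
        if self.kind == "range_deletion" and self.end is None:
            raise MutationError("range_deletion requires an end position")

    @property
    def span(self) -> tuple[int, int]:
        """Reference interval touched by this mutation (1-based inclusive)."""
        if self.kind == "range_deletion":
            return (self.position, self.end)
        if self.kind == "insertion":
            return (self.position, self.position + 1)
        return (self.position, self.position)

    @property
    def is_indel(self) -> bool:
        return self.kind != "substitution"

    @property
    def nomenclature(self) -> str:
        return format_mutation(
            self.kind, self.position, self.ref_bases, self.alt_bases, self.end
        )

    def with_localization(self, localization: str) -> "MutationRecord":
        return dataclasses.replace(self, localization=localization)


def format_mutation(
    kind: str,
    position: int,
    ref_bases: str = "",
    alt_bases: str = "",
    end: Optional[int] = None,
) -> str:
    """Render one mutation in the package nomenclature (lowercase bases)."""
    ref = ref_bases.lower()
    alt = alt_bases.lower()
    if kind == "substitution":
        return f"{ref[0]}{position}>{alt[0]}"
    if kind == "deletion":
        return f"{ref[0]}{position}>del"
    if kind == "range_deletion":
        n = end - position + 1
        return f"{ref[0]}{position}-{ref[-1]}{end}>del ({n} nt)"
    if kind == "insertion":
        return f"{position}^{position + 1}>ins^{alt}"
    raise MutationError(f"unknown mutation kind {kind!r}")


def parse_mutation(text: str) -> MutationRecord:
    """Parse a nomenclature string back into a :class:`MutationRecord`."""
    text = text.strip()
    m = _SUB_RE.match(text)
    if m:
        return MutationRecord("substitution", int(m.group(2)), m.group(1), m.group(3))
    m = _DEL_RE.match(text)
    if m:
        return MutationRecord("deletion", int(m.group(2)), m.group(1))
    m = _RANGE_DEL_RE.match(text)
    if m:
        start, end = int(m.group(2)), int(m.group(4))
        if end - start + 1 != int(m.group(5)):
            raise MutationError(f"inconsistent range length in {text!r}")
        return MutationRecord(
            "range_deletion", start, m.group(1) + m.group(3), end=end
        )
    m = _INS_RE.match(text)
    if m:
        left, right = int(m.group(1)), int(m.group(2))
        if right != left + 1:
            raise MutationError(f"insertion anchors not adjacent in {text!r}")
        return MutationRecord("insertion", left, alt_bases=m.group(3))
    raise MutationError(f"unparseable mutation {text!r}")


def _check_ref(reference: str, pos: int, expected: str) -> None:
    actual = reference[pos - 1].lower()
    if expected and actual != expected.lower():
        raise MutationError(
            f"reference base at {pos} is {actual!r}, mutation says {expected.lower()!r}"
        )


def apply_mutations(reference: str, mutations: Iterable[MutationRecord | str]) -> str:
    """Apply mutations (records or nomenclature strings) to ``reference``.

    Positions refer to the unmodified reference; overlapping mutations that
    contradict each other raise :class:`MutationError`.  Substitutions may
    share positions with an insertion boundary but not with deletions.
    """
    records = [parse_mutation(m) if isinstance(m, str) else m for m in mutations]
    for rec in records:
        lo, hi = rec.span
        if not (1 <= lo <= len(reference)) or hi > len(reference) + (
            1 if rec.kind == "insertion" else 0
        ):
            raise MutationError(f"{rec.nomenclature}: position outside reference")
        if rec.kind == "substitution":
            _check_ref(reference, rec.position, rec.ref_bases)
        elif rec.kind == "deletion":
            _check_ref(reference, rec.position, rec.ref_bases)
        elif rec.kind == "range_deletion":
            if rec.ref_bases:
                _check_ref(reference, rec.position, rec.ref_bases[0])
                _check_ref(reference, rec.end, rec.ref_bases[-1])
    _check_consistent(records)
    out = list(reference)
    insertions: dict[int, str] = {}
    for rec in records:
        if rec.kind == "substitution":
            out[rec.position - 1] = rec.alt_bases.upper()
        elif rec.kind == "deletion":
            out[rec.position - 1] = ""
        elif rec.kind == "range_deletion":
            for pos in range(rec.position, rec.end + 1):
                out[pos - 1] = ""
        elif rec.kind == "insertion":
            insertions[rec.position] = insertions.get(rec.position, "") + rec.alt_bases.upper()
    for pos, bases in insertions.items():
        index = pos - 1
        out[index] = out[index] + bases
    return "".join(out)


def _check_consistent(records: Sequence[MutationRecord]) -> None:
    touched: dict[int, MutationRecord] = {}
    for rec in records:
        if rec.kind == "insertion":
            continue
        lo, hi = rec.span
        for pos in range(lo, hi + 1):
            other = touched.get(pos)
            if other is not None and other.nomenclature != rec.nomenclature:
                raise MutationError(
                    f"contradictory mutations at position {pos}: "
                    f"{other.nomenclature} vs {rec.nomenclature}"
                )
            touched[pos] = rec
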