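"""Amplicon coordinate maps.

All spans are 1-based inclusive ``(start, end)`` tuples on the
forward-oriented insert.  The five outer spans (forward primer, 5' flank,
scFv, 3' flank, reverse primer) tile ``[1, total_len]``; the linker and core
spans are sub-intervals (the scFv contains the linker, and the core region
excludes the primer-artifact-prone termini).
"""

from __future__ import annotations

import dataclasses
import json
from typing import Optional

Span = tuple[int, int]

# Default core region: drop the first 2 nt and the last 36 nt (reverse primer
# plus its immediate vicinity), which for a 977-nt insert gives 3..941.
CORE_HEAD_TRIM = 2
CORE_TAIL_TRIM = 36


def default_core_span(total_len: int) -> Span:
    return (CORE_HEAD_TRIM + 1, total_len - CORE_TAIL_TRIM)


@dataclasses.dataclass(frozen=True)
class InsertGeometry:
    total_len: int
    fwd_primer_span: Span
    five_flank_span: Span
    scfv_span: Span
    linker_span: Span
    three_flank_span: Span
    rev_primer_span: Span
    core_span: Span

    def __post_init__(self) -> None:
        tiling = [
            self.fwd_primer_span,
            self.five_flank_span,
            self.scfv_span,
            self.three_flank_span,
            self.rev_primer_span,
        ]
        expected_start = 1
        for span in tiling:
            lo, hi = span
            if lo != expected_start or hi < lo:
                raise ValueError(f"spans do not tile [1,{self.total_len}]: {tiling}")
            expected_start = hi + 1
        if expected_start != self.total_len + 1:
            raise ValueError(f"spans do not tile [1,{self.total_len}]: {tiling}")
        for name, inner, outer in (
            ("linker_span", self.linker_span, self.scfv_span),
            ("core_span", self.core_span, (1, self.total_len)),
        ):
            if not (outer[0] <= inner[0] <= inner[1] <= outer[1]):
                raise ValueError(f"{name} {inner} not within {outer}")

    @property
    def vh_like_span(self) -> Span:
        """scFv segment 5' of the linker (first domain on the insert)."""
        return (self.scfv_span[0], self.linker_span[0] - 1)

    @property
    def vl_like_span(self) -> Span:
        """scFv segment 3' of the linker (second domain on the insert)."""
        return (self.linker_span[1] + 1, self.scfv_span[1])

    def to_dict(self) -> dict:
        return {k: list(v) if isinstance(v, tuple) else v for k, v in dataclasses.asdict(self).items()}

    @classmethod
    def from_dict(cls, data: dict) -> "InsertGeometry":
        kwargs = {}
        for field in dataclasses.fields(cls):
            value = data[field.name]
            kwargs[field.name] = tuple(value) if isinstance(value, (list, tuple)) else value
        return cls(**kwargs)

    def to_json(self, path) -> None:
        with open(path, "w") as handle:
            json.dump(self.to_dict(), handle, indent=2, sort_keys=True)
            handle.write("\n")

    @classmethod
    def from_json(cls, path) -> "InsertGeometry":
        with open(path) as handle:
            return cls.from_dict(json.load(handle))


def build_geometry(
    fwd_primer_len: int,
    five_flank_len: int,
    vh_len: int,
    linker_len: int,
    vl_len: int,
    three_flank_len: int,
    rev_primer_len: int,
    core_span: Optional[Span] = None,
) -> InsertGeometry:
    """Assemble a geometry from consecutive segment lengths."""
    pos = 1

    def take(length: int) -> Span:
        nonlocal pos
        span = (pos, pos + length - 1)
        pos += length
        return span

    fwd = take(fwd_primer_len)
    flank5 = take(five_flank_len)
    scfv_start = pos
    take(vh_len)
    linker = take(linker_len)
    take(vl_len)
    scfv = (scfv_start, pos - 1)
    flank3 = take(three_flank_len)
    rev = take(rev_primer_len)
    total = pos - 1
    return InsertGeometry(
        total_len=total,
        fwd_primer_span=fwd,
        five_flank_span=flank5,
        scfv_span=scfv,
        linker_span=linker,
        three_flank_span=flank3,
        rev_primer_span=rev,
        core_span=core_span if core_span is not None else default_core_span(total),
    )
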