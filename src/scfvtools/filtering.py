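"""Dual-domain filtering and per-batch coverage summaries.

A candidate read (two V regions detected) passes the filter iff *both*
domains have V-REGION identity strictly above the threshold (default 85%)
and an in-frame junction.  Percentages are rounded half away from zero to
two decimals.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence


def round2(value) -> Decimal:
    """Round to 2 decimals, half away from zero."""
    return Decimal(str(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)


def pct(numerator: int, denominator: int) -> Decimal:
    if denominator == 0:
        raise ZeroDivisionError("empty denominator in percentage")
    return (Decimal(100) * Decimal(numerator) / Decimal(denominator)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    )


@dataclasses.dataclass(frozen=True)
class BatchSummary:
    pcr_sample_id: str
    smrt_cell_id: Optional[int]
    n_analyzed: int
    n_candidates: int
    n_filtered_in: int

    def __post_init__(self) -> None:
        if not (self.n_filtered_in <= self.n_candidates <= self.n_analyzed):
            raise ValueError(
                f"inconsistent counts: filtered {self.n_filtered_in} <= "
                f"candidates {self.n_candidates} <= analyzed {self.n_analyzed} violated"
            )
        if self.n_analyzed == 0:
            raise ValueError("empty batch")

    @property
    def pct_candidates(self) -> Decimal:
        return pct(self.n_candidates, self.n_analyzed)

    @property
    def pct_scfv_of_filtered(self) -> Decimal:
        return pct(self.n_filtered_in, self.n_candidates)

    @property
    def pct_scfv_of_analyzed(self) -> Decimal:
        return pct(self.n_filtered_in, self.n_analyzed)

    def as_row(self) -> dict:
        return {
            "pcr_sample_id": self.pcr_sample_id,
            "smrt_cell_id": self.smrt_cell_id if self.smrt_cell_id is not None else "total",
            "n_analyzed": self.n_analyzed,
            "n_candidates": self.n_candidates,
            "pct_candidates": float(self.pct_candidates),
            "n_filtered_in": self.n_filtered_in,
            "pct_scfv_of_filtered": float(self.pct_scfv_of_filtered),
            "pct_scfv_of_analyzed": float(self.pct_scfv_of_analyzed),
        }


@dataclasses.dataclass(frozen=True)
class FilterVerdict:
    read_id: str
    passed: bool
    reasons: tuple[str, ...]


def _domain_reasons(index: int, domain, threshold: float, require_in_frame: bool) -> list[str]:
    reasons = []
    if domain.v_identity_pct <= threshold:
        reasons.append(f"domain{index} identity <= {threshold:g}")
    if require_in_frame and not domain.in_frame:
        reasons.append(f"domain{index} out-of-frame junction")
    return reasons


def filter_scfv(
    annotations: Sequence,
    identity_threshold_pct: float = 85.0,
    require_in_frame: bool = True,
) -> tuple[list, list[tuple[object, FilterVerdict]]]:
    """Split candidate annotations into (passed, failed-with-reasons).

    The identity comparison is strict (``> threshold``), per the standard
    repertoire filter; every violated criterion is reported per domain.
    """
    passed = []
    failed = []
    for ann in annotations:
        if not ann.is_scfv_candidate:
            failed.append((ann, FilterVerdict(ann.read_id, False, ("not a candidate",))))
            continue
        reasons = _domain_reasons(1, ann.domain1, identity_threshold_pct, require_in_frame)
        reasons += _domain_reasons(2, ann.domain2, identity_threshold_pct, require_in_frame)
        if reasons:
            failed.append((ann, FilterVerdict(ann.read_id, False, tuple(reasons))))
        else:
            passed.append(ann)
    return passed, failed


def summarize_batch(read_rows: Iterable[dict]) -> list[BatchSummary]:
    """Per-(PCR sample, SMRT cell) summaries plus a grand-total row.

    ``read_rows`` need keys ``pcr_sample_id, smrt_cell_id, is_candidate,
    passed``.  One summary per batch (sorted) and a final total row with
    ``smrt_cell_id=None``.
    """
    groups: dict[tuple[str, int], list[dict]] = {}
    for row in read_rows:
        key = (str(row["pcr_sample_id"]), int(row["smrt_cell_id"]))
        groups.setdefault(key, []).append(row)
    if not groups:
        raise ValueError("no reads to summarize")
    summaries = []
    totals = [0, 0, 0]
    for sample, cell in sorted(groups):
        rows = groups[(sample, cell)]
        n_analyzed = len(rows)
        n_candidates = sum(bool(r["is_candidate"]) for r in rows)
        n_filtered = sum(bool(r["passed"]) for r in rows)
        summaries.append(BatchSummary(sample, cell, n_analyzed, n_candidates, n_filtered))
        totals[0] += n_analyzed
        totals[1] += n_candidates
        totals[2] += n_filtered
    summaries.append(BatchSummary("total", None, *totals))
    return summaries


def summarize_counts(
    n_analyzed: int,
    n_candidates: int,
    n_filtered_in: int,
    pcr_sample_id: str = "batch",
    smrt_cell_id: Optional[int] = None,
) -> BatchSummary:
    """Summary percentages straight from externally supplied counts."""
    return BatchSummary(pcr_sample_id, smrt_cell_id, n_analyzed, n_candidates, n_filtered_in)


def tally_layouts(passed_annotations: Sequence) -> Counter:
    """Counts of passed reads per layout label."""
    return Counter(ann.layout for ann in passed_annotations)


def expected_layout_counts(n_total: int, n_vh_vh: int, n_vl_vl: int) -> tuple[int, int]:
    """(expected-layout count, off-type count) from a filtered total and the
    two off-type layout counts."""
    off_type = n_vh_vh + n_vl_vl
    return n_total - off_type, off_type
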