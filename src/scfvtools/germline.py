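"""Germline V/(D)/J reference directories.

A reference directory is an ungapped nucleotide FASTA plus a sidecar TSV
(``allele_name, segment_kind, chain_kind, v_region_start, v_region_end,
anchor_pos``) giving region boundaries and the CDR3 anchor positions:
the 2nd-CYS codon start for V alleles, the J-TRP/J-PHE codon start for J
alleles.  Coordinates are 1-based inclusive throughout.

A deterministic miniature fixture directory is generated by
:func:`build_fixture_reference` so every pipeline stage can be exercised
without external downloads.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

SEGMENT_KINDS = ("V", "D", "J")
CHAIN_KINDS = ("heavy", "kappa", "lambda")
_ALPHABET = frozenset("ACGT")

METADATA_COLUMNS = [
    "allele_name",
    "segment_kind",
    "chain_kind",
    "v_region_start",
    "v_region_end",
    "anchor_pos",
]


class ReferenceError(ValueError):
    """Raised for invalid reference directories."""


@dataclasses.dataclass(frozen=True)
class GermlineAllele:
    """One germline allele with its anchors.

    ``anchor_pos`` is the 1-based position of the first nucleotide of the
    2nd-CYS codon (V) or of the J-TRP/J-PHE codon (J); ``None`` for D.
    """

    allele_name: str
    segment_kind: str
    chain_kind: str
    sequence: str
    v_region_span: Optional[tuple[int, int]] = None
    anchor_pos: Optional[int] = None

    @property
    def gene_name(self) -> str:
        return self.allele_name.split("*")[0]

    def validate(self) -> None:
        if self.segment_kind not in SEGMENT_KINDS:
            raise ReferenceError(
                f"{self.allele_name}: unknown segment_kind {self.segment_kind!r}"
            )
        if self.chain_kind not in CHAIN_KINDS:
            raise ReferenceError(
                f"{self.allele_name}: unknown chain_kind {self.chain_kind!r}"
            )
        if not self.sequence:
            raise ReferenceError(f"{self.allele_name}: empty sequence")
        for i, base in enumerate(self.sequence):
            if base not in _ALPHABET:
                raise ReferenceError(
                    f"{self.allele_name}: invalid base {base!r} at position {i + 1}"
                )
        n = len(self.sequence)
        if self.segment_kind == "V":
            if self.v_region_span is None:
                raise ReferenceError(f"{self.allele_name}: V allele lacks v_region_span")
            lo, hi = self.v_region_span
            if not (1 <= lo <= hi <= n):
                raise ReferenceError(
                    f"{self.allele_name}: v_region_span {self.v_region_span} "
                    f"outside sequence of length {n}"
                )
            if self.anchor_pos is None or not (lo <= self.anchor_pos <= hi - 2):
                raise ReferenceError(
                    f"{self.allele_name}: anchor_pos {self.anchor_pos} outside "
                    f"v_region_span {self.v_region_span}"
                )
        elif self.segment_kind == "J":
            if self.anchor_pos is None or not (1 <= self.anchor_pos <= n - 2):
                raise ReferenceError(
                    f"{self.allele_name}: anchor_pos {self.anchor_pos} outside "
                    f"sequence of length {n}"
                )


class ReferenceDirectory:
    """Validated collection of germline alleles, indexed by kind and chain."""

    def __init__(self, alleles: Iterable[GermlineAllele], release_tag: str = "fixture"):
        self.release_tag = release_tag
        self.alleles: dict[str, GermlineAllele] = {}
        for allele in alleles:
            allele.validate()
            if allele.allele_name in self.alleles:
                raise ReferenceError(f"duplicate allele_name {allele.allele_name!r}")
            self.alleles[allele.allele_name] = allele
        if not self.alleles:
            raise ReferenceError("no alleles in reference directory")
        for chain in CHAIN_KINDS:
            if self._any(chain):
                if not self.select("V", chain):
                    raise ReferenceError(f"chain {chain!r} has no V allele")
                if not self.select("J", chain):
                    raise ReferenceError(f"chain {chain!r} has no J allele")
        self._kmer_cache: dict = {}

    def _any(self, chain: str) -> bool:
        return any(a.chain_kind == chain for a in self.alleles.values())

    def select(self, segment_kind: str, chain_kind: Optional[str] = None) -> list[GermlineAllele]:
        out = [
            a
            for a in self.alleles.values()
            if a.segment_kind == segment_kind
            and (chain_kind is None or a.chain_kind == chain_kind)
        ]
        return sorted(out, key=lambda a: a.allele_name)

    def v_alleles(self, chain_kind: Optional[str] = None) -> list[GermlineAllele]:
        return self.select("V", chain_kind)

    def j_alleles(self, chain_kind: Optional[str] = None) -> list[GermlineAllele]:
        return self.select("J", chain_kind)

    def d_alleles(self, chain_kind: Optional[str] = None) -> list[GermlineAllele]:
        return self.select("D", chain_kind)

    def __getitem__(self, allele_name: str) -> GermlineAllele:
        return self.alleles[allele_name]

    def __len__(self) -> int:
        return len(self.alleles)

    def v_kmers(self, k: int = 13) -> tuple[frozenset, frozenset]:
        """Cached (forward, reverse-complement) k-mer sets over V alleles."""
        key = ("strand", k)
        if key not in self._kmer_cache:
            from .align import revcomp

            fwd: set[str] = set()
            rev: set[str] = set()
            for allele in self.v_alleles():
                seq = allele.sequence
                rc = revcomp(seq)
                for i in range(len(seq) - k + 1):
                    fwd.add(seq[i : i + k])
                    rev.add(rc[i : i + k])
            self._kmer_cache[key] = (frozenset(fwd), frozenset(rev))
        return self._kmer_cache[key]

    def v_kmers_by_allele(self, k: int = 13) -> dict[str, frozenset]:
        """Cached per-allele forward k-mer sets over V alleles."""
        key = ("allele", k)
        if key not in self._kmer_cache:
            table = {}
            for allele in self.v_alleles():
                seq = allele.sequence
                table[allele.allele_name] = frozenset(
                    seq[i : i + k] for i in range(len(seq) - k + 1)
                )
            self._kmer_cache[key] = table
        return self._kmer_cache[key]


def load_reference(fasta_path, metadata_path, release_tag: Optional[str] = None) -> ReferenceDirectory:
    """Load and validate a FASTA + TSV-sidecar reference directory."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ReferenceError(f"no alleles in {fasta_path}")
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str, comment="#")
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ReferenceError(f"metadata missing columns: {missing_cols}")
    meta_by_name = {}
    for row in meta.itertuples(index=False):
        meta_by_name[row.allele_name] = row
    alleles = []
    for rec in records:
        if rec.id not in meta_by_name:
            raise ReferenceError(f"missing metadata row for FASTA record {rec.id!r}")
        row = meta_by_name[rec.id]

        def _opt(value) -> Optional[int]:
            return None if pd.isna(value) or value in ("", ".") else int(value)

        span = None
        if _opt(row.v_region_start) is not None:
            span = (_opt(row.v_region_start), _opt(row.v_region_end))
        alleles.append(
            GermlineAllele(
                allele_name=rec.id,
                segment_kind=row.segment_kind,
                chain_kind=row.chain_kind,
                sequence=str(rec.seq).upper(),
                v_region_span=span,
                anchor_pos=_opt(row.anchor_pos),
            )
        )
    tag = release_tag if release_tag is not None else "user"
    return ReferenceDirectory(alleles, release_tag=tag)


def write_reference(refdir: ReferenceDirectory, fasta_path, metadata_path) -> None:
    """Write the FASTA + metadata sidecar pair (round-trips load_reference)."""
    ordered = sorted(refdir.alleles.values(), key=lambda a: a.allele_name)
    records = [
        SeqRecord(Seq(a.sequence), id=a.allele_name, description="") for a in ordered
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = []
    for a in ordered:
        rows.append(
            {
                "allele_name": a.allele_name,
                "segment_kind": a.segment_kind,
                "chain_kind": a.chain_kind,
                "v_region_start": a.v_region_span[0] if a.v_region_span else "",
                "v_region_end": a.v_region_span[1] if a.v_region_span else "",
                "anchor_pos": a.anchor_pos if a.anchor_pos is not None else "",
            }
        )
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(
        metadata_path, sep="\t", index=False
    )


# Fixture geometry: V alleles end in a TGT (Cys) anchor codon; heavy J carry
# TGG (Trp) at 25-27, light J carry TTC (Phe) at 19-21.  Both J anchor starts
# are ≡ 1 (mod 3) so junctions built with N-insert lengths divisible by 3 are
# in frame.
V_LEN_HEAVY = 322
V_LEN_LIGHT = 301
J_LEN_HEAVY = 39
J_LEN_LIGHT = 37
J_ANCHOR_HEAVY = 25
J_ANCHOR_LIGHT = 19


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _with_codon(seq: str, pos: int, codon: str) -> str:
    return seq[: pos - 1] + codon + seq[pos + 2 :]


def _sibling(seq: str, rng: np.random.Generator, positions=(50, 150, 250)) -> str:
    """Derive a *02 allele: 3 fixed-position substitutions off the *01."""
    out = list(seq)
    for pos in positions:
        current = out[pos]
        choices = [b for b in "ACGT" if b != current]
        out[pos] = choices[int(rng.integers(0, 3))]
    return "".join(out)


def build_fixture_reference(seed: int = 0) -> ReferenceDirectory:
    """Deterministic miniature reference directory for tests and simulation."""
    rng = np.random.default_rng(seed)
    alleles: list[GermlineAllele] = []

    def add_v(name: str, chain: str) -> str:
        length = V_LEN_HEAVY if chain == "heavy" else V_LEN_LIGHT
        anchor = length - 2
        seq = _with_codon(_random_seq(rng, length), anchor, "TGT")
        alleles.append(
            GermlineAllele(name, "V", chain, seq, v_region_span=(1, length), anchor_pos=anchor)
        )
        return seq

    def add_v_sibling(name: str, chain: str, base_seq: str) -> None:
        length = len(base_seq)
        alleles.append(
            GermlineAllele(
                name,
                "V",
                chain,
                _sibling(base_seq, rng),
                v_region_span=(1, length),
                anchor_pos=length - 2,
            )
        )

    def add_j(name: str, chain: str) -> None:
        if chain == "heavy":
            length, anchor, codon = J_LEN_HEAVY, J_ANCHOR_HEAVY, "TGG"
        else:
            length, anchor, codon = J_LEN_LIGHT, J_ANCHOR_LIGHT, "TTC"
        seq = _with_codon(_random_seq(rng, length), anchor, codon)
        alleles.append(GermlineAllele(name, "J", chain, seq, anchor_pos=anchor))

    hv1 = add_v("IGHV1-1*01", "heavy")
    add_v_sibling("IGHV1-1*02", "heavy", hv1)
    add_v("IGHV2-1*01", "heavy")
    add_v("IGHV3-1*01", "heavy")
    kv1 = add_v("IGKV1-1*01", "kappa")
    add_v_sibling("IGKV1-1*02", "kappa", kv1)
    add_v("IGKV2-1*01", "kappa")
    add_v("IGLV1-1*01", "lambda")
    add_v("IGLV2-1*01", "lambda")

    add_j("IGHJ4*01", "heavy")
    add_j("IGHJ6*01", "heavy")
    add_j("IGKJ1*01", "kappa")
    add_j("IGKJ2*01", "kappa")
    add_j("IGLJ2*01", "lambda")
    add_j("IGLJ3*01", "lambda")

    for name in ("IGHD2-2*01", "IGHD3-1*01"):
        alleles.append(GermlineAllele(name, "D", "heavy", _random_seq(rng, 20)))

    return ReferenceDirectory(alleles, release_tag=f"fixture-{seed}")
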