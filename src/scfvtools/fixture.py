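"""Deterministic reconstruction of the reference-clone tracking dataset.

Builds a synthetic 977-nt amplicon insert with the documented geometry
(23-mer forward primer, 74-nt 5' flank, 370-nt VH, 53-nt linker, 344-nt VL,
93-nt 3' flank, reverse complement of the 20-mer reverse primer; scFv =
positions 98-864; core region 3-941) and emits the 85-read tracking set:
53 reads identical over the full insert, 7 reads identical over the core
with primer-terminal artifacts, and 25 related reads carrying the replicated
or singleton mutation signatures, each with its PCR-sample / SMRT-cell
provenance.

The reference base at every mutated position (and the homopolymer context
around every indel site) is pinned so that alignment-based difference
extraction reproduces the listed coordinates exactly.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .align import revcomp
from .geometry import InsertGeometry, build_geometry
from .germline import ReferenceDirectory, build_fixture_reference
from .mutations import apply_mutations
from .simulate import (
    DEFAULT_LINKER,
    FWD_PRIMER,
    REV_PRIMER,
    LibrarySimConfig,
    vector_flanks,
)

VH_V_ALLELE = "IGHV1-1*01"
VH_J_ALLELE = "IGHJ4*01"
VL_V_ALLELE = "IGKV1-1*01"
VL_J_ALLELE = "IGKJ1*01"
VH_N_LEN = 9
VL_N_LEN = 6

# Reads identical over the whole 977-nt insert: read number -> (sample, cell).
IDENTICAL_FULL_READS: dict[int, tuple[str, int]] = {
    **{i: ("s1", 1) for i in (1, 2, 3, 4, 6, 8)},
    **{i: ("s1", 2) for i in (10, 30)},
    **{i: ("s1", 3) for i in (16, 17, 19)},
    **{i: ("s2", 4) for i in (32, 33)},
    36: ("s2", 5),
    **{i: ("s2", 6) for i in (37, 38, 39)},
    **{i: ("s2", 7) for i in (20, 41, 44, 45, 46, 47, 48)},
    **{i: ("s3", 8) for i in (49, 50, 51, 52, 53, 54)},
    **{i: ("s3", 9) for i in (56, 57, 59, 60)},
    **{i: ("s3", 10) for i in (63, 65, 66)},
    68: ("s3", 11),
    **{i: ("s4", 12) for i in (70, 72, 73)},
    **{i: ("s4", 13) for i in (75, 76)},
    **{i: ("s4", 14) for i in (21, 80, 83)},
    **{i: ("s4", 15) for i in (23, 24, 25, 26, 27, 28, 29)},
}

# Reads identical over the core (3-941) with primer-terminal artifacts:
# read number -> (sample, cell, mutations).
IDENTICAL_CORE_READS: dict[int, tuple[str, int, tuple[str, ...]]] = {
    13: ("s1", 2, ("g2>del",)),
    11: ("s1", 2, ("t975>del", "a977>del")),
    15: ("s1", 3, ("c956>t",)),
    12: ("s1", 2, ("a942>del",)),
    35: ("s2", 5, ("a942>del",)),
    71: ("s4", 12, ("a942>del",)),
    64: ("s3", 10, ("a942>del", "t975>del")),
}

# Related reads: read number -> (sample, cell, mutations).
RELATED_READS: dict[int, tuple[str, int, tuple[str, ...]]] = {
    # replicated four-substitution signature (6 reads + 1 with terminal deletion)
    7: ("s1", 1, ("a545>g", "g686>a", "a757>g", "c838>g")),
    18: ("s1", 3, ("a545>g", "g686>a", "a757>g", "c838>g")),
    43: ("s2", 7, ("a545>g", "g686>a", "a757>g", "c838>g")),
    67: ("s3", 11, ("a545>g", "g686>a", "a757>g", "c838>g")),
    69: ("s4", 12, ("a545>g", "g686>a", "a757>g", "c838>g")),
    79: ("s4", 14, ("a545>g", "g686>a", "a757>g", "c838>g")),
    58: ("s3", 9, ("a545>g", "g686>a", "a757>g", "c838>g", "a886-a977>del (92 nt)")),
    # replicated second four-substitution signature (1 read + 1 with primer deletion)
    61: ("s3", 9, ("c741>t", "g837>a", "c838>g", "g843>t")),
    74: ("s4", 13, ("c741>t", "g837>a", "c838>g", "g843>t", "a977>del")),
    # replicated two-substitution signature
    5: ("s1", 1, ("c720>t", "t744>c")),
    14: ("s1", 2, ("c720>t", "t744>c")),
    31: ("s2", 4, ("c720>t", "t744>c")),
    34: ("s2", 7, ("c720>t", "t744>c")),
    42: ("s4", 14, ("c720>t", "t744>c")),
    82: ("s4", 14, ("c720>t", "t744>c")),
    # singletons
    85: ("s2", 4, ("c242>del",)),
    40: ("s2", 6, ("g600>del",)),
    77: ("s4", 13, ("g495>a",)),
    22: ("s4", 14, ("t624>c",)),
    55: ("s3", 9, ("a627>g",)),
    62: ("s3", 10, ("g736>a",)),
    78: ("s4", 13, ("t599>g", "t975-a977>del (3 nt)")),
    81: ("s4", 14, ("g2>del", "a715>g", "c959-a977>del (19 nt)")),
    84: ("s2", 5, ("209^210>ins^a", "762^763>ins^t")),
    9: ("s1", 2, ("c322>t", "658^659>ins^cc", "c659>t", "t660>a")),
}

# Pinned reference bases (1-based insert position -> base): the reference base
# printed in each mutation plus homopolymer-context bases around indel sites
# so right-normalized indel extraction lands on the listed coordinates.
REFERENCE_BASE_PINS: dict[int, str] = {
    208: "T", 209: "C", 210: "G",
    241: "A", 242: "C", 243: "G",
    322: "C",
    545: "A",
    599: "T", 600: "G", 601: "A",
    624: "T",
    627: "A",
    658: "G", 659: "C", 660: "T",
    686: "G",
    715: "A",
    720: "C",
    736: "G",
    741: "C",
    744: "T",
    757: "A",
    762: "C", 763: "G",
    837: "G", 838: "C", 843: "G",
    886: "A",
    941: "T", 942: "A", 943: "G",
    956: "C",
}

# Anchor codons that annotation depends on; pins must never touch them.
_ANCHOR_SPANS = ((417, 419), (453, 455), (819, 821), (846, 848))


@dataclasses.dataclass
class TrackingFixture:
    refdir: ReferenceDirectory
    config: LibrarySimConfig
    geometry: InsertGeometry
    reference_insert: str
    reference_scfv: str
    reads: list[tuple[str, str]]
    metadata: dict[str, tuple[str, int]]
    mutation_lists: dict[str, tuple[str, ...]]

    @property
    def read_ids(self) -> list[str]:
        return [read_id for read_id, _ in self.reads]


def read_name(number: int) -> str:
    return f"P3-{number:02d}"


def build_reference_insert(seed: int = 0) -> tuple[ReferenceDirectory, LibrarySimConfig, InsertGeometry, str]:
    """Assemble the 977-nt reference insert from the fixture germline set."""
    refdir = build_fixture_reference(seed)
    config = LibrarySimConfig(seed=seed)
    rng = np.random.default_rng([seed, 0xF1F1])
    bases = np.array(list("ACGT"))

    def n_insert(length: int) -> str:
        return "".join(bases[rng.integers(0, 4, size=length)])

    vh = (
        refdir[VH_V_ALLELE].sequence
        + n_insert(VH_N_LEN)
        + refdir[VH_J_ALLELE].sequence
    )
    vl = (
        refdir[VL_V_ALLELE].sequence
        + n_insert(VL_N_LEN)
        + refdir[VL_J_ALLELE].sequence
    )
    five_flank, three_flank = vector_flanks(config)
    insert = (
        FWD_PRIMER + five_flank + vh + DEFAULT_LINKER + vl + three_flank + revcomp(REV_PRIMER)
    )
    geometry = build_geometry(
        len(FWD_PRIMER), len(five_flank), len(vh), len(DEFAULT_LINKER), len(vl),
        len(three_flank), len(REV_PRIMER),
    )
    out = list(insert)
    for pos, base in REFERENCE_BASE_PINS.items():
        for lo, hi in _ANCHOR_SPANS:
            if lo <= pos <= hi:
                raise AssertionError(f"pin {pos} collides with anchor span {(lo, hi)}")
        out[pos - 1] = base
    return refdir, config, geometry, "".join(out)


def build_tracking_fixture(seed: int = 0) -> TrackingFixture:
    """Emit the full 85-read tracking dataset with metadata and truth."""
    refdir, config, geometry, insert = build_reference_insert(seed)
    scfv_lo, scfv_hi = geometry.scfv_span
    reads: list[tuple[str, str]] = []
    metadata: dict[str, tuple[str, int]] = {}
    mutation_lists: dict[str, tuple[str, ...]] = {}
    for number in range(1, 86):
        if number in IDENTICAL_FULL_READS:
            sample, cell = IDENTICAL_FULL_READS[number]
            mutations: tuple[str, ...] = ()
        elif number in IDENTICAL_CORE_READS:
            sample, cell, mutations = IDENTICAL_CORE_READS[number]
        else:
            sample, cell, mutations = RELATED_READS[number]
        sequence = apply_mutations(insert, mutations) if mutations else insert
        if number % 3 == 0:  # exercise strand handling downstream
            sequence = revcomp(sequence)
        read_id = read_name(number)
        reads.append((read_id, sequence))
        metadata[read_id] = (sample, cell)
        mutation_lists[read_id] = mutations
    return TrackingFixture(
        refdir=refdir,
        config=config,
        geometry=geometry,
        reference_insert=insert,
        reference_scfv=insert[scfv_lo - 1 : scfv_hi],
        reads=reads,
        metadata=metadata,
        mutation_lists=mutation_lists,
    )
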