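"""Synthetic scFv amplicon library and CCS-style read simulator.

Clones are assembled as ``FWD_PRIMER + 5'flank + domain1 + linker + domain2 +
3'flank + revcomp(REV_PRIMER)``; each domain is a germline V allele, an
N-diversity insert, and a germline J allele, with library substitutions drawn
per configured per-domain rates.  Reads are sampled from clone frequencies per
(PCR sample, SMRT cell) batch, strand-flipped 50/50, and corrupted by a
residual consensus-error model with a deletion boost near the amplicon ends.
Every read carries a ground-truth record.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .align import revcomp
from .geometry import InsertGeometry, build_geometry
from .germline import GermlineAllele, ReferenceDirectory
from .mutations import MutationRecord, apply_mutations, format_mutation, parse_mutation

FWD_PRIMER = "TGCAAATTCTATTTCAAGGAGAC"
REV_PRIMER = "TCACGTGCAAAAGCAGCGGC"

# 53 nt, (G4S)-style, with EcoRI (GAATTC) and XbaI (TCTAGA) sites.
DEFAULT_LINKER = "GAATTCGGTGGAGGCGGTTCAGGCGGAGGTGGCTCTAGAGGTGGTGGATCAGG"
assert len(DEFAULT_LINKER) == 53 and "GAATTC" in DEFAULT_LINKER and "TCTAGA" in DEFAULT_LINKER

FIVE_FLANK_LEN = 74
THREE_FLANK_LEN = 93

LAYOUTS = ("VH-VL", "VL-VH", "VH-VH", "VL-VL")
DEFAULT_LAYOUT_MIX = (0.60, 0.395, 0.0005, 0.0045)

_BASES = np.array(list("ACGT"))


@dataclasses.dataclass(frozen=True)
class ReadErrorModel:
    """Residual consensus error model with primer-end deletion artifacts."""

    per_base_error: float = 0.001
    sub_frac: float = 0.4
    ins_frac: float = 0.3
    del_frac: float = 0.3
    primer_end_del_boost: float = 20.0
    end_window: int = 3

    def __post_init__(self) -> None:
        total = self.sub_frac + self.ins_frac + self.del_frac
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"error-kind mixture sums to {total}, expected 1")
        for name in ("per_base_error", "sub_frac", "ins_frac", "del_frac"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name}={value} outside [0,1]")


@dataclasses.dataclass(frozen=True)
class LibrarySimConfig:
    n_clones: int = 50
    zipf_exponent: float = 1.5
    frequencies: Optional[tuple[float, ...]] = None
    layout_mix: tuple[float, float, float, float] = DEFAULT_LAYOUT_MIX
    vh_mutation_rate: float = 1.0
    vl_mutation_rate: float = 4.0
    linker_seq: str = DEFAULT_LINKER
    fwd_primer: str = FWD_PRIMER
    rev_primer: str = REV_PRIMER
    junction_insertion_range: tuple[int, int] = (0, 12)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.layout_mix) - 1.0) > 1e-9:
            raise ValueError(f"layout_mix sums to {sum(self.layout_mix)}, expected 1")
        if self.vh_mutation_rate < 0 or self.vl_mutation_rate < 0:
            raise ValueError("mutation rates must be >= 0")
        if "GAATTC" not in self.linker_seq or "TCTAGA" not in self.linker_seq:
            raise ValueError("linker must contain EcoRI (GAATTC) and XbaI (TCTAGA) sites")

    def clone_frequencies(self) -> np.ndarray:
        if self.frequencies is not None:
            freqs = np.asarray(self.frequencies, dtype=float)
            if abs(freqs.sum() - 1.0) > 1e-9:
                raise ValueError("explicit frequencies must sum to 1")
            return freqs
        ranks = np.arange(1, self.n_clones + 1, dtype=float)
        weights = ranks ** (-self.zipf_exponent)
        return weights / weights.sum()


@dataclasses.dataclass(frozen=True)
class SimDomain:
    kind: str  # VH | VL
    chain_kind: str
    v_allele: str
    j_allele: str
    junction_nt: str
    junction_aa: str
    span: tuple[int, int]  # 1-based inclusive on the clone insert


@dataclasses.dataclass
class SimClone:
    clone_id: str
    sequence: str
    layout: str
    geometry: InsertGeometry
    domains: tuple[SimDomain, ...]
    library_mutations: tuple[str, ...] = ()
    forced_batches: tuple[tuple[str, int, int], ...] = ()  # (sample, cell, copies)


def vector_flanks(config: LibrarySimConfig) -> tuple[str, str]:
    """Deterministic phagemid flank sequences shared by every clone."""
    rng = np.random.default_rng([config.seed, 0xF1A2])
    five = "".join(_BASES[rng.integers(0, 4, size=FIVE_FLANK_LEN)])
    three = "".join(_BASES[rng.integers(0, 4, size=THREE_FLANK_LEN)])
    return five, three


def _translate(junction_nt: str) -> str:
    usable = len(junction_nt) - len(junction_nt) % 3
    return str(Seq(junction_nt[:usable]).translate())


def _draw_domain(
    refdir: ReferenceDirectory,
    kind: str,
    config: LibrarySimConfig,
    rng: np.random.Generator,
) -> tuple[str, str, str, GermlineAllele, int]:
    """Return (sequence, chain, n-insert, V allele, junction start offset)."""
    if kind == "VH":
        chain = "heavy"
    else:
        lights = [c for c in ("kappa", "lambda") if refdir.v_alleles(c)]
        if not lights:
            raise ValueError("no light-chain V alleles available for VL domain")
        chain = lights[int(rng.integers(0, len(lights)))]
    v_pool = refdir.v_alleles(chain)
    j_pool = refdir.j_alleles(chain)
    if not v_pool or not j_pool:
        raise ValueError(f"chain {chain!r} lacks V or J alleles for layout")
    v = v_pool[int(rng.integers(0, len(v_pool)))]
    j = j_pool[int(rng.integers(0, len(j_pool)))]
    lo, hi = config.junction_insertion_range
    n_len = int(rng.integers(lo // 3, hi // 3 + 1)) * 3  # keep junctions in frame
    n_seq = "".join(_BASES[rng.integers(0, 4, size=n_len)]) if n_len else ""
    seq = v.sequence + n_seq + j.sequence
    return seq, chain, n_seq, v, len(v.sequence) + n_len


def simulate_clone(
    refdir: ReferenceDirectory,
    config: LibrarySimConfig,
    rng: np.random.Generator,
    clone_id: str = "clone1",
    layout: Optional[str] = None,
) -> SimClone:
    """Simulate one recombined clone consensus with ground truth."""
    if layout is None:
        layout = LAYOUTS[int(rng.choice(len(LAYOUTS), p=np.asarray(config.layout_mix)))]
    if layout not in LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}")
    kinds = layout.split("-")
    five_flank, three_flank = vector_flanks(config)

    parts: list[str] = [config.fwd_primer, five_flank]
    pos = len(config.fwd_primer) + len(five_flank)
    domains: list[SimDomain] = []
    mutation_notes: list[str] = []
    domain_lengths: list[int] = []

    for index, kind in enumerate(kinds):
        seq, chain, _n_seq, v, j_start = _draw_domain(refdir, kind, config, rng)
        j_allele = _matching_j(refdir, chain, seq, j_start)
        rate = config.vh_mutation_rate if kind == "VH" else config.vl_mutation_rate
        n_mut = int(rng.poisson(rate))
        v_anchor0 = v.anchor_pos - 1
        j_anchor0 = j_start + j_allele.anchor_pos - 1
        mutated = list(seq)
        # protect the V 2nd-CYS and J anchor codons so annotation stays exact
        protected = set(range(v_anchor0, v_anchor0 + 3))
        protected |= set(range(j_anchor0, j_anchor0 + 3))
        candidates = [i for i in range(len(seq)) if i not in protected]
        if n_mut > 0 and candidates:
            chosen = rng.choice(len(candidates), size=min(n_mut, len(candidates)), replace=False)
            for c in sorted(int(x) for x in chosen):
                i = candidates[c]
                current = mutated[i]
                options = [b for b in "ACGT" if b != current]
                mutated[i] = options[int(rng.integers(0, 3))]
                mutation_notes.append(
                    format_mutation("substitution", pos + i + 1, current, mutated[i])
                )
        domain_seq = "".join(mutated)
        junction_nt = domain_seq[v_anchor0 : j_anchor0 + 3]
        domains.append(
            SimDomain(
                kind=kind,
                chain_kind=chain,
                v_allele=v.allele_name,
                j_allele=j_allele.allele_name,
                junction_nt=junction_nt,
                junction_aa=_translate(junction_nt),
                span=(pos + 1, pos + len(domain_seq)),
            )
        )
        parts.append(domain_seq)
        pos += len(domain_seq)
        domain_lengths.append(len(domain_seq))
        if index == 0:
            parts.append(config.linker_seq)
            pos += len(config.linker_seq)

    parts.append(three_flank)
    parts.append(revcomp(config.rev_primer))
    sequence = "".join(parts)
    geometry = build_geometry(
        len(config.fwd_primer),
        len(five_flank),
        domain_lengths[0],
        len(config.linker_seq),
        domain_lengths[1],
        len(three_flank),
        len(config.rev_primer),
    )
    return SimClone(
        clone_id=clone_id,
        sequence=sequence,
        layout=layout,
        geometry=geometry,
        domains=tuple(domains),
        library_mutations=tuple(mutation_notes),
    )


def _matching_j(refdir: ReferenceDirectory, chain: str, seq: str, j_start: int) -> GermlineAllele:
    """Identify which J allele occupies ``seq[j_start:]`` (exact by construction)."""
    tail = seq[j_start:]
    for allele in refdir.j_alleles(chain):
        if allele.sequence == tail:
            return allele
    raise ValueError("domain tail does not match any J allele")


def simulate_library(refdir: ReferenceDirectory, config: LibrarySimConfig) -> tuple[list[SimClone], np.ndarray]:
    """Simulate ``config.n_clones`` clones and their abundance distribution."""
    rng = np.random.default_rng([config.seed, 0xC10E])
    clones = [
        simulate_clone(refdir, config, rng, clone_id=f"clone{i + 1:04d}")
        for i in range(config.n_clones)
    ]
    return clones, config.clone_frequencies()


def spike_reference_clone(
    clones: Sequence[SimClone],
    reference: SimClone,
    spec: Sequence[dict],
) -> list[SimClone]:
    """Add a reference clone and mutation-signature variants with forced reads.

    Each ``spec`` entry is a mapping with keys ``mutations`` (list of
    nomenclature strings, possibly empty) and ``batches`` (list of
    ``(pcr_sample_id, smrt_cell_id, copies)``).  Contradictory mutations at
    one position raise.  Returns a new clone list.
    """
    out = list(clones)
    for index, entry in enumerate(spec):
        mutations = [
            parse_mutation(m) if isinstance(m, str) else m for m in entry["mutations"]
        ]
        sequence = apply_mutations(reference.sequence, mutations)
        out.append(
            SimClone(
                clone_id=f"{reference.clone_id}.v{index}" if mutations else reference.clone_id,
                sequence=sequence,
                layout=reference.layout,
                geometry=reference.geometry,
                domains=reference.domains,
                library_mutations=tuple(m.nomenclature for m in mutations),
                forced_batches=tuple(
                    (str(s), int(c), int(n)) for s, c, n in entry["batches"]
                ),
            )
        )
    return out


def _apply_errors(
    sequence: str,
    model: ReadErrorModel,
    rng: np.random.Generator,
) -> tuple[str, list[MutationRecord]]:
    """Corrupt one read; returns (read, error records vs the clone consensus)."""
    n = len(sequence)
    if model.per_base_error <= 0:
        return sequence, []
    p = model.per_base_error
    del_boost = np.ones(n)
    w = model.end_window
    if w > 0:
        del_boost[:w] = model.primer_end_del_boost
        del_boost[n - w :] = model.primer_end_del_boost
    p_sub = p * model.sub_frac
    p_ins = p * model.ins_frac
    p_del = p * model.del_frac * del_boost
    p_total = p_sub + p_ins + p_del
    u = rng.random(n)
    hits = np.nonzero(u < p_total)[0]
    if hits.size == 0:
        return sequence, []
    records: list[MutationRecord] = []
    pieces: list[str] = []
    prev = 0
    for i in hits:
        i = int(i)
        # conditional error kind at this position
        u_kind = u[i] / p_total[i]
        ref_base = sequence[i]
        pieces.append(sequence[prev:i])
        if u_kind < p_sub / p_total[i]:
            options = [b for b in "ACGT" if b != ref_base]
            alt = options[int(rng.integers(0, 3))]
            pieces.append(alt)
            records.append(MutationRecord("substitution", i + 1, ref_base, alt))
        elif u_kind < (p_sub + p_ins) / p_total[i]:
            ins = str(_BASES[int(rng.integers(0, 4))])
            pieces.append(ref_base + ins)
            records.append(MutationRecord("insertion", i + 1, alt_bases=ins))
        else:
            records.append(MutationRecord("deletion", i + 1, ref_base))
        prev = i + 1
    pieces.append(sequence[prev:])
    return "".join(pieces), records


@dataclasses.dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str
    quality_char: str = "?"  # constant Q30 (Sanger Phred+33)

    def fastq_block(self) -> str:
        return (
            f"@{self.read_id}\n{self.sequence}\n+\n"
            f"{self.quality_char * len(self.sequence)}\n"
        )


def batch_plan(n_pcr_samples: int, cells_per_sample: int) -> list[tuple[str, int]]:
    """Batches as (pcr_sample_id, smrt_cell_id) with globally numbered cells."""
    plan = []
    cell = 1
    for s in range(1, n_pcr_samples + 1):
        for _ in range(cells_per_sample):
            plan.append((f"s{s}", cell))
            cell += 1
    return plan


def simulate_reads(
    clones: Sequence[SimClone],
    frequencies: Optional[np.ndarray],
    error_model: ReadErrorModel,
    n_reads: int,
    n_pcr_samples: int = 4,
    cells_per_sample: int = 4,
    seed: int = 0,
) -> tuple[list[SimulatedRead], pd.DataFrame]:
    """Draw reads per batch, apply errors, and return reads plus truth table.

    Random reads are drawn i.i.d. from ``frequencies`` and split evenly over
    the batches; clones with ``forced_batches`` additionally emit exact copy
    counts into their designated batches.  Deterministic for a fixed seed.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be > 0")
    rng = np.random.default_rng([seed, 0x5EED])
    batches = batch_plan(n_pcr_samples, cells_per_sample)
    valid_batches = set(batches)

    random_pool = [i for i, c in enumerate(clones) if not c.forced_batches]
    if random_pool:
        if frequencies is None:
            freqs = np.full(len(random_pool), 1.0 / len(random_pool))
        else:
            freqs = np.asarray(frequencies, dtype=float)
            if freqs.size != len(random_pool):
                raise ValueError(
                    f"{freqs.size} frequencies for {len(random_pool)} random clones"
                )
            if abs(freqs.sum() - 1.0) > 1e-9:
                raise ValueError("frequencies must sum to 1")

    jobs: list[tuple[SimClone, str, int]] = []
    for clone in clones:
        for sample, cell, copies in clone.forced_batches:
            if (sample, cell) not in valid_batches:
                raise ValueError(f"forced batch ({sample}, {cell}) not in batch plan")
            jobs.extend((clone, sample, cell) for _ in range(copies))
    if random_pool:
        per_batch = np.full(len(batches), n_reads // len(batches), dtype=int)
        per_batch[: n_reads % len(batches)] += 1
        for b, (sample, cell) in enumerate(batches):
            picks = rng.choice(len(random_pool), size=int(per_batch[b]), p=freqs)
            jobs.extend((clones[random_pool[int(k)]], sample, cell) for k in picks)

    reads: list[SimulatedRead] = []
    truth_rows: list[dict] = []
    for number, (clone, sample, cell) in enumerate(jobs, start=1):
        read_id = f"r{number:06d}"
        seq, errors = _apply_errors(clone.sequence, error_model, rng)
        strand = "forward" if rng.random() < 0.5 else "reverse"
        emitted = seq if strand == "forward" else revcomp(seq)
        reads.append(SimulatedRead(read_id, emitted))
        d1, d2 = clone.domains
        truth_rows.append(
            {
                "read_id": read_id,
                "clone_id": clone.clone_id,
                "pcr_sample_id": sample,
                "smrt_cell_id": cell,
                "layout": clone.layout,
                "strand": strand,
                "true_mutations": ";".join(e.nomenclature for e in errors),
                "n_sub": sum(e.kind == "substitution" for e in errors),
                "n_ins": sum(e.kind == "insertion" for e in errors),
                "n_del": sum(e.kind == "deletion" for e in errors),
                "d1_v_call": d1.v_allele,
                "d1_j_call": d1.j_allele,
                "d1_junction_aa": d1.junction_aa,
                "d2_v_call": d2.v_allele,
                "d2_j_call": d2.j_allele,
                "d2_junction_aa": d2.junction_aa,
            }
        )
    truth = pd.DataFrame(truth_rows)
    return reads, truth


def write_fastq(reads: Sequence[SimulatedRead], path) -> None:
    with open(path, "w") as handle:
        for read in reads:
            handle.write(read.fastq_block())
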