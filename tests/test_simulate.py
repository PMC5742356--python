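import numpy as np
import pytest

from scfvtools.align import revcomp
from scfvtools.mutations import MutationError
from scfvtools.simulate import (
    DEFAULT_LINKER,
    FWD_PRIMER,
    REV_PRIMER,
    LibrarySimConfig,
    ReadErrorModel,
    simulate_clone,
    simulate_library,
    simulate_reads,
    spike_reference_clone,
)


def test_config_validation():
    with pytest.raises(ValueError, match="layout_mix"):
        LibrarySimConfig(layout_mix=(0.5, 0.5, 0.5, 0.0))
    with pytest.raises(ValueError, match="rates"):
        LibrarySimConfig(vl_mutation_rate=-1)
    with pytest.raises(ValueError, match="linker"):
        LibrarySimConfig(linker_seq="AAAAAA" * 9)
    with pytest.raises(ValueError, match="mixture"):
        ReadErrorModel(sub_frac=0.9, ins_frac=0.2, del_frac=0.2)


def test_clone_structure(refdir):
    config = LibrarySimConfig(seed=11, vh_mutation_rate=0, vl_mutation_rate=0)
    rng = np.random.default_rng(4)
    clone = simulate_clone(refdir, config, rng, layout="VH-VL")
    assert clone.sequence.startswith(FWD_PRIMER)
    assert clone.sequence.endswith(revcomp(REV_PRIMER))
    assert DEFAULT_LINKER in clone.sequence
    assert clone.geometry.total_len == len(clone.sequence)
    # zero mutation rates: domains exactly germline V + N + J
    d1 = clone.domains[0]
    v = refdir[d1.v_call] if hasattr(refdir, "v_call") else refdir[d1.v_allele]
    assert v.sequence in clone.sequence
    assert clone.library_mutations == ()


def test_clone_layout_vl_vl(refdir):
    config = LibrarySimConfig(seed=11)
    rng = np.random.default_rng(4)
    clone = simulate_clone(refdir, config, rng, layout="VL-VL")
    assert [d.kind for d in clone.domains] == ["VL", "VL"]
    assert all(d.chain_kind in ("kappa", "lambda") for d in clone.domains)


def test_clone_junctions_in_frame(refdir):
    config = LibrarySimConfig(seed=2)
    rng = np.random.default_rng(9)
    for _ in range(10):
        clone = simulate_clone(refdir, config, rng)
        for domain in clone.domains:
            assert len(domain.junction_nt) % 3 == 0
            assert domain.junction_aa.startswith("C")
            assert domain.junction_aa[-1] in ("W", "F")


def test_vl_mutation_rate_monte_carlo(refdir):
    rate = 4.0
    config = LibrarySimConfig(seed=5, vh_mutation_rate=1.0, vl_mutation_rate=rate)
    rng = np.random.default_rng(13)
    counts = []
    for _ in range(400):
        clone = simulate_clone(refdir, config, rng, layout="VH-VL")
        vl = clone.domains[1]
        n_vl = sum(
            1
            for m in clone.library_mutations
            if vl.span[0] <= int("".join(ch for ch in m.split(">")[0] if ch.isdigit())) <= vl.span[1]
        )
        counts.append(n_vl)
    mean = np.mean(counts)
    se = np.sqrt(rate / len(counts))
    assert abs(mean - rate) < 3 * se + 0.05


def test_reads_error_free_match_clone(refdir, small_library):
    _, clones, freqs = small_library
    reads, truth = simulate_reads(
        clones, freqs, ReadErrorModel(per_base_error=0.0), 40, 2, 2, seed=8
    )
    by_id = {c.clone_id: c for c in clones}
    for read, row in zip(reads, truth.itertuples(index=False)):
        clone = by_id[row.clone_id]
        expected = clone.sequence if row.strand == "forward" else revcomp(clone.sequence)
        assert read.sequence == expected


def test_reads_deterministic(refdir, small_library):
    _, clones, freqs = small_library
    model = ReadErrorModel()
    a, _ = simulate_reads(clones, freqs, model, 50, 2, 2, seed=21)
    b, _ = simulate_reads(clones, freqs, model, 50, 2, 2, seed=21)
    assert [r.fastq_block() for r in a] == [r.fastq_block() for r in b]
    c, _ = simulate_reads(clones, freqs, model, 50, 2, 2, seed=22)
    assert [r.sequence for r in a] != [r.sequence for r in c]


def test_geometry_conservation_without_indels(refdir, small_library):
    _, clones, freqs = small_library
    model = ReadErrorModel(per_base_error=0.002, sub_frac=1.0, ins_frac=0.0, del_frac=0.0)
    reads, truth = simulate_reads(clones, freqs, model, 60, 2, 2, seed=3)
    by_id = {c.clone_id: c for c in clones}
    for read, row in zip(reads, truth.itertuples(index=False)):
        assert len(read.sequence) == len(by_id[row.clone_id].sequence)


def test_mean_errors_per_read(refdir, small_library):
    _, clones, freqs = small_library
    model = ReadErrorModel(per_base_error=0.001, primer_end_del_boost=1.0)
    n = 4000
    reads, truth = simulate_reads(clones, freqs, model, n, 2, 2, seed=17)
    errors = (truth.n_sub + truth.n_ins + truth.n_del).to_numpy()
    lengths = np.array([len(c.sequence) for c in clones])
    expected = 0.001 * lengths.mean()  # clones near-equal length
    se = np.sqrt(expected / n)
    assert abs(errors.mean() - expected) < 4 * se


def test_error_mixture_calibration(refdir, small_library):
    _, clones, freqs = small_library
    model = ReadErrorModel(per_base_error=0.02, primer_end_del_boost=1.0)
    reads, truth = simulate_reads(clones, freqs, model, 5200, 2, 2, seed=19)
    n_sub, n_ins, n_del = truth.n_sub.sum(), truth.n_ins.sum(), truth.n_del.sum()
    total = n_sub + n_ins + n_del
    assert total > 100_000
    for observed, expected in ((n_sub, 0.4), (n_ins, 0.3), (n_del, 0.3)):
        se = np.sqrt(expected * (1 - expected) / total)
        assert abs(observed / total - expected) < 3 * se


def test_primer_end_deletion_boost(refdir, small_library):
    _, clones, freqs = small_library
    model = ReadErrorModel(per_base_error=0.01, sub_frac=0.0, ins_frac=0.0,
                           del_frac=1.0, primer_end_del_boost=20.0, end_window=3)
    reads, truth = simulate_reads(clones, freqs, model, 1500, 2, 2, seed=23)
    lengths = {c.clone_id: len(c.sequence) for c in clones}
    end_hits = interior_hits = 0
    end_positions = interior_positions = 0
    for row in truth.itertuples(index=False):
        n = lengths[row.clone_id]
        end_positions += 6
        interior_positions += n - 6
        if not row.true_mutations or str(row.true_mutations) == "nan":
            continue
        for text in str(row.true_mutations).split(";"):
            if not text:
                continue
            pos = int("".join(ch for ch in text.split(">")[0] if ch.isdigit()))
            if pos <= 3 or pos >= n - 2:
                end_hits += 1
            else:
                interior_hits += 1
    rate_ratio = (end_hits / end_positions) / (interior_hits / interior_positions)
    assert 14 < rate_ratio < 28  # configured boost is x20


def test_frequency_recovery(refdir):
    config = LibrarySimConfig(n_clones=12, seed=31)
    clones, freqs = simulate_library(refdir, config)
    n = 6000
    reads, truth = simulate_reads(
        clones, freqs, ReadErrorModel(per_base_error=0.0), n, 2, 2, seed=37
    )
    counts = truth.clone_id.value_counts()
    for clone, freq in zip(clones, freqs):
        expected = n * freq
        if expected < 20:
            continue
        se = np.sqrt(n * freq * (1 - freq))
        assert abs(counts.get(clone.clone_id, 0) - expected) <= 3 * se


def test_spike_reference_clone(refdir, small_library):
    _, clones, freqs = small_library
    reference = clones[0]
    spec = [
        {"mutations": [], "batches": [("s1", 1, 3)]},
        {"mutations": ["%s545>%s" % (reference.sequence[544].lower(), "g" if reference.sequence[544] != "G" else "a")],
         "batches": [("s1", 1, 1)]},
    ]
    augmented = spike_reference_clone(clones, reference, spec)
    assert len(augmented) == len(clones) + 2
    assert spike_reference_clone(clones, reference, []) == list(clones)
    reads, truth = simulate_reads(
        augmented, freqs, ReadErrorModel(per_base_error=0.0), 10, 2, 2, seed=2
    )
    variant_id = f"{reference.clone_id}.v1"
    assert (truth.clone_id == variant_id).sum() == 1  # singleton spike
    assert (truth.clone_id == reference.clone_id).sum() >= 3  # forced + random


def test_spike_contradictory_mutations(refdir, small_library):
    _, clones, _ = small_library
    reference = clones[0]
    base = reference.sequence[99].lower()
    alts = [b for b in "acgt" if b != base]
    spec = [{"mutations": [f"{base}100>{alts[0]}", f"{base}100>{alts[1]}"],
             "batches": [("s1", 1, 1)]}]
    with pytest.raises(MutationError, match="contradictory"):
        spike_reference_clone(clones, reference, spec)


def test_n_reads_validation(refdir, small_library):
    _, clones, freqs = small_library
    with pytest.raises(ValueError, match="n_reads"):
        simulate_reads(clones, freqs, ReadErrorModel(), 0, 2, 2, seed=1)
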