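"""Output writers with reproducibility headers, and read-file loading."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from Bio import SeqIO

from . import __version__


def config_hash(params: dict) -> str:
    canonical = json.dumps(params, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def header_lines(params: dict, seed: Optional[int]) -> str:
    return (
        f"# scfvtools {__version__}\n"
        f"# config_hash={config_hash(params)}\n"
        f"# seed={seed if seed is not None else 'none'}\n"
    )


def write_table(frame: pd.DataFrame, path, params: dict, seed: Optional[int]) -> None:
    """TSV with a reproducibility header comment block."""
    path = Path(path)
    with open(path, "w") as handle:
        handle.write(header_lines(params, seed))
        frame.to_csv(handle, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def load_reads(path) -> list[tuple[str, str]]:
    """Load (id, sequence) pairs from FASTA or FASTQ (qualities ignored)."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), fmt)]


def write_fasta(records: Sequence[tuple[str, str]], path, width: int = 70) -> None:
    with open(path, "w") as handle:
        for name, seq in records:
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")
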