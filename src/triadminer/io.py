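"""Standard-format readers and writers (FASTA, Newick, TSV tables).

Readers tolerate wrapped FASTA lines, CRLF line endings and gzip
compression; writers emit canonical forms so that write-then-read is the
identity on canonical files.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable

import pandas as pd


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a plain or gzipped FASTA file."""
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for sid, seq in records:
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_label_map(path: str | Path) -> dict[str, str]:
    """Leaf -> class map from a two-column tab-separated file."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            out[parts[0]] = parts[1]
    return out


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
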