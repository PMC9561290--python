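"""Small shared sequence utilities."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO

import numpy as np

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")

BASES = "ACGT"
_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement (DNA alphabet; U treated as T)."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_alphabet(seq: str) -> str:
    """Uppercase and map U -> T so RNA and DNA inputs are interchangeable."""
    return seq.upper().replace("U", "T")


def seq_to_array(seq: str) -> np.ndarray:
    """Encode a sequence as a uint8 array of ASCII codes."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    """Open a possibly gzip-compressed text file by suffix."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def write_fasta(path: str | Path, records, line_width: int = 0) -> None:
    """Write ``(name, sequence)`` or ``(name, description, sequence)`` records.

    ``line_width == 0`` writes each sequence on a single line, which keeps
    output byte-identical across runs regardless of wrapping conventions.
    """
    with open_text(path, "wt") as fh:
        for rec in records:
            if len(rec) == 3:
                name, desc, seq = rec
                header = f">{name} {desc}" if desc else f">{name}"
            else:
                name, seq = rec
                header = f">{name}"
            fh.write(header + "\n")
            if line_width and line_width > 0:
                for i in range(0, len(seq), line_width):
                    fh.write(seq[i : i + line_width] + "\n")
            else:
                fh.write(seq + "\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Minimal FASTA reader returning ``(id, sequence)`` pairs in file order."""
    records: list[tuple[str, str]] = []
    name = None
    chunks: list[str] = []
    with open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    records.append((name, "".join(chunks)))
                name = line[1:].split()[0] if len(line) > 1 else ""
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        records.append((name, "".join(chunks)))
    return records
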