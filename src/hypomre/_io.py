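"""FASTQ/FASTA helpers built on Biopython's fast parsers."""
from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

PHRED_OFFSET = 33


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def iter_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality string) records; plain or gzipped input."""
    with _open_text(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield title.split()[0], seq, qual


def write_fastq(path, records: Iterable[tuple[str, str, str]]) -> int:
    """Write (id, seq, qual) records as Sanger/Phred+33 FASTQ; returns count."""
    n = 0
    with _open_text(path, "wt") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def quals_to_str(quals: np.ndarray) -> str:
    return (quals.astype(np.uint8) + PHRED_OFFSET).tobytes().decode("ascii")


def str_to_quals(qual: str) -> np.ndarray:
    return np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int32) - PHRED_OFFSET


def read_fasta(path) -> dict[str, str]:
    """Load a (small) FASTA file as an ordered id -> sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_fasta_with_desc(path) -> list[tuple[str, str, str]]:
    """FASTA records as (id, description, sequence) triples."""
    return [
        (rec.id, rec.description, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 80) -> int:
    """Write (id_or_header, seq) records; header may contain a description."""
    n = 0
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
            n += 1
    return n


def sha256_file(path) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
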