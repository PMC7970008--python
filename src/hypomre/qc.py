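"""Read quality filtering and alignment-free contamination screening.

Quality filtering trims leading/trailing N runs and sub-Q30 3' tails, then
rejects mates shorter than 50 bp or with a high ambiguous-base fraction; a
pair is dropped when either mate fails. Contamination screening classifies
each high-quality read against labelled reference sets (phiX, repeats,
rRNA, chloroplast, mitochondrion) by canonical k-mer containment: the read
is assigned to the class holding the largest fraction of its k-mers, when
that fraction reaches ``min_frac``; ties fall to a fixed class order with
the phiX control first.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._io import PHRED_OFFSET, iter_fastq, read_fasta_with_desc, write_fastq
from ._kmer import canonical_kmers, canonical_kmer_matrix, encode, group_by_length, isin_sorted

log = logging.getLogger(__name__)

#: fixed tie-break order; phiX first so control spikes never land on organelles
CLASS_ORDER = ("phix", "repetitive", "ribosomal", "chloroplast", "mitochondrion")
CLEAN = "clean"


class MalformedReadError(ValueError):
    """Sequence/quality length mismatch, naming the offending read."""


@dataclass
class ReadPair:
    id: str
    seq1: str
    qual1: str  # Phred+33 string; same length as seq1
    seq2: str
    qual2: str

    def __post_init__(self):
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise MalformedReadError(
                f"read {self.id}: sequence/quality length mismatch"
            )


@dataclass
class Rejection:
    id: str
    reason: str  # short | ambiguous


def _trim_mate(seq: str, qual: str, min_q: int) -> tuple[str, str]:
    """N-end stripping and 3' quality trimming, iterated to a fixed point."""
    thr = chr(min_q + PHRED_OFFSET)
    while True:
        n0 = len(seq)
        lead = len(seq) - len(seq.lstrip("N"))
        trail = len(seq) - len(seq.rstrip("N"))
        end = len(seq) - trail
        seq, qual = seq[lead:end], qual[lead:end]
        i = len(qual)
        while i > 0 and qual[i - 1] < thr:
            i -= 1
        seq, qual = seq[:i], qual[:i]
        if len(seq) == n0:
            return seq, qual


def quality_filter(
    pair: ReadPair, min_q: int = 30, min_len: int = 50, max_n_frac: float = 0.1
) -> ReadPair | Rejection:
    """Trim a pair and accept it, or reject it with a reason.

    Surviving pairs keep their id and are unchanged apart from trimming.
    """
    mates = []
    for seq, qual in ((pair.seq1, pair.qual1), (pair.seq2, pair.qual2)):
        seq, qual = _trim_mate(seq, qual, min_q)
        if len(seq) < min_len:
            return Rejection(pair.id, "short")
        if seq.count("N") / len(seq) > max_n_frac:
            return Rejection(pair.id, "ambiguous")
        mates.append((seq, qual))
    (s1, q1), (s2, q2) = mates
    return replace(pair, seq1=s1, qual1=q1, seq2=s2, qual2=q2)


# ---------------------------------------------------------------------------
# contaminant screen


class ContaminantIndex:
    """Canonical k-mer sets per contaminant class."""

    def __init__(self, class_kmers: dict[str, np.ndarray], k: int = 31):
        self.k = k
        self.class_kmers = {c: np.sort(np.unique(a)) for c, a in class_kmers.items()}
        # union of all classes: cheap prefilter so the per-class pass only
        # touches reads that hit the index at all
        arrays = [a for a in self.class_kmers.values() if a.size]
        self.all_kmers = (
            np.unique(np.concatenate(arrays)) if arrays else np.empty(0, dtype=np.uint64)
        )

    @classmethod
    def from_sequences(cls, class_seqs: dict[str, list[str] | str], k: int = 31):
        kmers = {}
        for name, seqs in class_seqs.items():
            if isinstance(seqs, str):
                seqs = [seqs]
            parts = []
            for s in seqs:
                canon, _, valid = canonical_kmers(encode(s), k)
                parts.append(canon[valid])
            kmers[name] = (
                np.concatenate(parts) if parts else np.empty(0, dtype=np.uint64)
            )
        return cls(kmers, k)

    @classmethod
    def from_fasta(cls, path, k: int = 31):
        """Build from a multi-FASTA whose descriptions carry `class=<name>`."""
        class_seqs: dict[str, list[str]] = {}
        for rid, desc, seq in read_fasta_with_desc(path):
            label = None
            for tok in desc.split():
                if tok.startswith("class="):
                    label = tok[len("class="):]
            if label is None:
                raise ValueError(f"FASTA record {rid} lacks a class= token")
            class_seqs.setdefault(label, []).append(seq)
        return cls.from_sequences(class_seqs, k)

    def classify(self, seq: str, min_frac: float = 0.5) -> str:
        return self.classify_batch([seq], min_frac)[0]

    #: prefilter samples every 4th window; a read must carry >= min_frac
    #: (default 50%) contaminant k-mers to classify, so sampling cannot miss
    #: a classifiable read, and final fractions use every k-mer of the read
    SAMPLE_STRIDE = 4

    def _best_class(self, frac_by_class: dict[str, np.ndarray], min_frac: float) -> list[str]:
        """Highest-fraction class per row; ties fall to the fixed order."""
        n = len(next(iter(frac_by_class.values())))
        best_frac = np.zeros(n)
        best_cls = np.full(n, -1, dtype=np.int64)
        for ci, cname in enumerate(CLASS_ORDER):
            frac = frac_by_class.get(cname)
            if frac is None:
                continue
            better = frac > best_frac + 1e-12  # ties keep the earlier class
            best_frac[better] = frac[better]
            best_cls[better] = ci
        return [
            CLASS_ORDER[c] if c >= 0 and f >= min_frac else CLEAN
            for c, f in zip(best_cls, best_frac)
        ]

    def classify_batch(self, seqs: list[str], min_frac: float = 0.5) -> list[str]:
        """Class label per read; reads shorter than k are clean (no evidence)."""
        k = self.k
        labels = [CLEAN] * len(seqs)
        if not seqs or self.all_kmers.size == 0:
            return labels
        groups, odd = group_by_length(seqs)
        for L in sorted(groups):
            idxs, mat = groups[L]
            if L < k:
                log.debug("%d reads shorter than k=%d left clean", len(idxs), k)
                continue
            kmers = canonical_kmer_matrix(mat, k)
            samp = np.ascontiguousarray(kmers[:, :: self.SAMPLE_STRIDE])
            hit_any = (
                isin_sorted(samp.ravel(), self.all_kmers).reshape(samp.shape).any(axis=1)
            )
            rows = np.nonzero(hit_any)[0]
            if rows.size == 0:
                continue
            sub = kmers[rows]
            m = sub.shape[1]
            fracs = {
                cname: isin_sorted(sub.ravel(), arr).reshape(sub.shape).sum(axis=1) / m
                for cname, arr in self.class_kmers.items()
                if arr.size
            }
            for r, label in zip(rows, self._best_class(fracs, min_frac)):
                labels[idxs[r]] = label
        # reads containing ambiguous bases: masked 1-D path, no prefilter
        for i in odd:
            if len(seqs[i]) < k:
                continue
            canon, _, valid = canonical_kmers(encode(seqs[i]), k)
            canon = canon[valid]
            if canon.size == 0:
                continue
            fracs = {
                cname: np.array([isin_sorted(canon, arr).sum() / canon.size])
                for cname, arr in self.class_kmers.items()
                if arr.size
            }
            labels[i] = self._best_class(fracs, min_frac)[0]
        return labels


# ---------------------------------------------------------------------------
# accounting and driver


@dataclass
class QCStats:
    """Per-direction read accounting (one Filtering-results table row)."""

    accession: str
    direction: str  # R1 | R2
    total: int = 0
    hq: int = 0
    contaminants: dict[str, int] = field(default_factory=dict)

    @property
    def filtered_hq(self) -> int:
        return self.hq - sum(self.contaminants.values())


def run_qc(
    r1_path,
    r2_path,
    index: ContaminantIndex | None,
    out_r1,
    out_r2,
    accession: str = "sample",
    min_q: int = 30,
    min_len: int = 50,
    max_n_frac: float = 0.1,
    min_frac: float = 0.5,
    rejected_path=None,
    batch_size: int = 20_000,
) -> tuple[QCStats, QCStats]:
    """Filter one accession's paired FASTQ; write surviving clean pairs.

    A pair survives when both mates pass quality filtering and both mates
    are classified clean. Counts are kept per direction.
    """
    s1 = QCStats(accession, "R1")
    s2 = QCStats(accession, "R2")
    kept1: list[tuple[str, str, str]] = []
    kept2: list[tuple[str, str, str]] = []
    rejected: list[tuple[str, str, str]] = []

    batch: list[ReadPair] = []

    def flush():
        if not batch:
            return
        if index is not None:
            lab1 = index.classify_batch([p.seq1 for p in batch], min_frac)
            lab2 = index.classify_batch([p.seq2 for p in batch], min_frac)
        else:
            lab1 = [CLEAN] * len(batch)
            lab2 = [CLEAN] * len(batch)
        for p, l1, l2 in zip(batch, lab1, lab2):
            if l1 != CLEAN:
                s1.contaminants[l1] = s1.contaminants.get(l1, 0) + 1
            if l2 != CLEAN:
                s2.contaminants[l2] = s2.contaminants.get(l2, 0) + 1
            if l1 == CLEAN and l2 == CLEAN:
                kept1.append((p.id, p.seq1, p.qual1))
                kept2.append((p.id, p.seq2, p.qual2))
            elif rejected_path is not None:
                reason = l1 if l1 != CLEAN else l2
                rejected.append((f"{p.id} {reason}", p.seq1, p.qual1))
        batch.clear()

    for (id1, sq1, ql1), (id2, sq2, ql2) in zip(iter_fastq(r1_path), iter_fastq(r2_path)):
        s1.total += 1
        s2.total += 1
        res = quality_filter(ReadPair(id1, sq1, ql1, sq2, ql2), min_q, min_len, max_n_frac)
        if isinstance(res, Rejection):
            if rejected_path is not None:
                rejected.append((f"{res.id} {res.reason}", sq1, ql1))
            continue
        s1.hq += 1
        s2.hq += 1
        batch.append(res)
        if len(batch) >= batch_size:
            flush()
    flush()

    write_fastq(out_r1, kept1)
    write_fastq(out_r2, kept2)
    if rejected_path is not None:
        write_fastq(rejected_path, rejected)
    return s1, s2


def qc_report(stats: list[QCStats]) -> pd.DataFrame:
    """Filtering-results table: counts plus percentages of total (1 decimal)."""
    rows = []
    for s in stats:
        total = s.total

        def pct(n):
            return round(100.0 * n / total, 1) if total else 0.0

        row = {
            "accession": s.accession,
            "direction": s.direction,
            "total": total,
            "hq": s.hq,
            "hq_pct": pct(s.hq),
        }
        for cls in CLASS_ORDER:
            n = s.contaminants.get(cls, 0)
            row[cls] = n
            row[f"{cls}_pct"] = pct(n)
        row["filtered_hq"] = s.filtered_hq
        row["filtered_hq_pct"] = pct(s.filtered_hq)
        rows.append(row)
    return pd.DataFrame(rows)
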