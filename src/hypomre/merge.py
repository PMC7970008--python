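"""Overlap-merging of mate pairs into single fragments.

Mate 2 is reverse-complemented and every innie overlap length L from
``min_overlap`` up to min(len1, len2) is scored by mismatch density; the
lowest-density overlap is accepted when its density is at most
``max_mismatch_density``, ties going to the larger overlap. Following the
conventional fast merger semantics, overlaps longer than ``max_overlap``
remain candidates, with the density denominator capped at ``max_overlap``.
Consensus bases come from the higher-quality mate; consensus quality is the
maximum of the two.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._io import iter_fastq
from ._kmer import revcomp


@dataclass
class MergedRead:
    id: str
    seq: str
    qual: str
    overlap_len: int
    source: str  # pair id

    def __post_init__(self):
        assert len(self.seq) == len(self.qual)


def _merge_group(
    seqs1: list[str],
    quals1: list[str],
    seqs2_rc: list[str],
    quals2_rev: list[str],
    min_overlap: int,
    max_overlap: int,
    max_mismatch_density: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Best overlap per pair for a group of identical (len1, len2).

    Returns (best_L, best_density); best_L is 0 where no candidate exists.
    """
    n1 = len(seqs1[0])
    n2 = len(seqs2_rc[0])
    A = np.frombuffer("".join(seqs1).encode(), dtype=np.uint8).reshape(-1, n1)
    B = np.frombuffer("".join(seqs2_rc).encode(), dtype=np.uint8).reshape(-1, n2)
    n = A.shape[0]
    best_L = np.zeros(n, dtype=np.int64)
    best_d = np.full(n, np.inf)
    for L in range(min_overlap, min(n1, n2) + 1):
        mm = np.count_nonzero(A[:, n1 - L :] != B[:, :L], axis=1)
        d = mm / min(L, max_overlap)
        upd = d <= best_d  # ascending L: <= prefers the larger overlap on ties
        best_d[upd] = d[upd]
        best_L[upd] = L
    best_L[best_d > max_mismatch_density] = 0
    return best_L, best_d


def _consensus(
    seq1: str, qual1: str, seq2_rc: str, qual2_rev: str, L: int
) -> tuple[str, str]:
    n1 = len(seq1)
    a = np.frombuffer(seq1[n1 - L :].encode(), dtype=np.uint8)
    b = np.frombuffer(seq2_rc[:L].encode(), dtype=np.uint8)
    qa = np.frombuffer(qual1[n1 - L :].encode(), dtype=np.uint8)
    qb = np.frombuffer(qual2_rev[:L].encode(), dtype=np.uint8)
    take_a = qa >= qb  # ties fall to mate 1
    cons = np.where(take_a, a, b).tobytes().decode()
    consq = np.maximum(qa, qb).tobytes().decode()
    return seq1[: n1 - L] + cons + seq2_rc[L:], qual1[: n1 - L] + consq + qual2_rev[L:]


def merge_pairs(
    pairs: list[tuple[str, str, str, str, str]],
    min_overlap: int = 10,
    max_overlap: int = 250,
    max_mismatch_density: float = 0.25,
) -> tuple[list[MergedRead], list[tuple[str, str, str, str, str]]]:
    """Merge (id, seq1, qual1, seq2, qual2) pairs; returns (merged, unmerged).

    Input order is preserved within each output list.
    """
    groups: dict[tuple[int, int], list[int]] = {}
    for i, (_, s1, _, s2, _) in enumerate(pairs):
        groups.setdefault((len(s1), len(s2)), []).append(i)

    merged_at: dict[int, MergedRead] = {}
    for (n1, n2), idxs in groups.items():
        if min(n1, n2) < min_overlap or min(n1, n2) == 0:
            continue  # overlap search window empty -> all unmerged
        seqs1 = [pairs[i][1] for i in idxs]
        quals1 = [pairs[i][2] for i in idxs]
        seqs2_rc = [revcomp(pairs[i][3]) for i in idxs]
        quals2_rev = [pairs[i][4][::-1] for i in idxs]
        best_L, _ = _merge_group(
            seqs1, quals1, seqs2_rc, quals2_rev, min_overlap, max_overlap, max_mismatch_density
        )
        for j, i in enumerate(idxs):
            L = int(best_L[j])
            if L == 0:
                continue
            seq, qual = _consensus(seqs1[j], quals1[j], seqs2_rc[j], quals2_rev[j], L)
            pid = pairs[i][0]
            merged_at[i] = MergedRead(pid, seq, qual, L, pid)

    merged = [merged_at[i] for i in sorted(merged_at)]
    unmerged = [pairs[i] for i in range(len(pairs)) if i not in merged_at]
    return merged, unmerged


def merge_pair(
    pair: tuple[str, str, str, str, str],
    min_overlap: int = 10,
    max_overlap: int = 250,
    max_mismatch_density: float = 0.25,
) -> MergedRead | None:
    """Single-pair convenience wrapper around :func:`merge_pairs`."""
    merged, _ = merge_pairs([pair], min_overlap, max_overlap, max_mismatch_density)
    return merged[0] if merged else None


def run_merge(
    r1_path,
    r2_path,
    out_merged,
    out_unmerged=None,
    accession: str = "sample",
    min_overlap: int = 10,
    max_overlap: int = 250,
    max_mismatch_density: float = 0.25,
    batch_size: int = 50_000,
) -> dict:
    """Merge a filtered FASTQ pair of files; returns per-accession stats."""
    n_pairs = 0
    n_merged = 0
    merged_out = open(out_merged, "w")
    unmerged_out = open(out_unmerged, "w") if out_unmerged else None
    try:
        batch: list[tuple[str, str, str, str, str]] = []

        def flush():
            nonlocal n_merged
            if not batch:
                return
            merged, unmerged = merge_pairs(
                batch, min_overlap, max_overlap, max_mismatch_density
            )
            n_merged += len(merged)
            for m in merged:
                merged_out.write(f"@{m.id}\n{m.seq}\n+\n{m.qual}\n")
            if unmerged_out is not None:
                for pid, s1, q1, s2, q2 in unmerged:
                    unmerged_out.write(f"@{pid}/1\n{s1}\n+\n{q1}\n")
                    unmerged_out.write(f"@{pid}/2\n{s2}\n+\n{q2}\n")
            batch.clear()

        for (id1, s1, q1), (_, s2, q2) in zip(iter_fastq(r1_path), iter_fastq(r2_path)):
            n_pairs += 1
            batch.append((id1, s1, q1, s2, q2))
            if len(batch) >= batch_size:
                flush()
        flush()
    finally:
        merged_out.close()
        if unmerged_out is not None:
            unmerged_out.close()
    return {
        "accession": accession,
        "pairs": n_pairs,
        "merged": n_merged,
        "merged_pct": round(100.0 * n_merged / n_pairs, 1) if n_pairs else 0.0,
    }


def merge_stats_table(stats: list[dict]) -> pd.DataFrame:
    """Overlap statistics table (pairs, merged, %) per accession."""
    return pd.DataFrame(stats, columns=["accession", "pairs", "merged", "merged_pct"])
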