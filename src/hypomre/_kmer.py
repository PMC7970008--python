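"""2-bit k-mer encoding shared by the assembler, mapper and contaminant screen.

K-mers with k <= 31 are packed into uint64, most significant base first,
with A,C,G,T -> 0,1,2,3. The canonical form of a k-mer is the lexicographic
minimum of its forward code and the code of its reverse complement, which
collapses the two strands onto a single key.
"""
from __future__ import annotations

import numpy as np

#: byte -> 2-bit code; anything that is not ACGT (upper or lower case) maps to 255
ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    ENCODE[_b] = _i
    ENCODE[_b + 32] = _i

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)

_RC_TRANS = bytes.maketrans(b"ACGTacgtNn", b"TGCAtgcaNn")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N is preserved)."""
    return seq.encode().translate(_RC_TRANS)[::-1].decode()


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a sequence to uint8 codes (255 for non-ACGT)."""
    if isinstance(seq, str):
        seq = seq.encode()
    return ENCODE[np.frombuffer(seq, dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode an array of 2-bit codes (values 0..3) back to a string."""
    return _DECODE[codes].tobytes().decode()


def _weights(k: int) -> np.ndarray:
    return 4 ** np.arange(k - 1, -1, -1, dtype=np.uint64)


def _valid_windows(codes: np.ndarray, k: int) -> np.ndarray:
    bad = np.concatenate(([0], np.cumsum(codes > 3, dtype=np.int64)))
    return (bad[k:] - bad[:-k]) == 0


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Forward k-mer codes of a code array plus a validity mask.

    A window is invalid when it covers any non-ACGT position; invalid
    windows carry arbitrary code values and must be masked by the caller.
    Packing accumulates k shifted passes over flat arrays, avoiding any
    (n, k) window materialization.
    """
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    m = n - k + 1
    c64 = codes.astype(np.uint64)
    fwd = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | (c64[j : j + m] & np.uint64(3))
    return fwd, _valid_windows(codes, k)


def canonical_kmers(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Canonical k-mer codes, forward-is-canonical flags and validity mask."""
    n = codes.size
    if n < k:
        e = np.empty(0, dtype=np.uint64)
        return e, np.empty(0, dtype=bool), np.empty(0, dtype=bool)
    m = n - k + 1
    c64 = (codes & np.uint8(3)).astype(np.uint64)
    comp = np.uint64(3) - c64
    fwd = np.zeros(m, dtype=np.uint64)
    rc = np.zeros(m, dtype=np.uint64)
    two = np.uint64(2)
    for j in range(k):
        np.left_shift(fwd, two, out=fwd)
        np.bitwise_or(fwd, c64[j : j + m], out=fwd)
        np.left_shift(rc, two, out=rc)
        np.bitwise_or(rc, comp[k - 1 - j : k - 1 - j + m], out=rc)
    valid = _valid_windows(codes, k)
    canon = np.minimum(fwd, rc)
    return canon, fwd <= rc, valid


def canonical_kmer_matrix(codes: np.ndarray, k: int) -> np.ndarray:
    """Canonical k-mers of equal-length reads, vectorized across reads.

    ``codes`` is an (N, L) uint8 matrix with values 0..3 only (callers route
    reads containing N through the 1-D path). A rolling recurrence walks the
    L columns once, so the cost is ~2 passes over the matrix regardless of k.
    Returns an (N, L-k+1) uint64 matrix.
    """
    n, L = codes.shape
    m = L - k + 1
    if m <= 0:
        return np.empty((n, 0), dtype=np.uint64)
    # transpose so each column step touches a contiguous row
    c64 = np.ascontiguousarray(codes.T).astype(np.uint64)
    comp = np.uint64(3) - c64
    mask = np.uint64((1 << (2 * k)) - 1)
    top = np.uint64(2 * (k - 1))
    two = np.uint64(2)
    out_f = np.empty((m, n), dtype=np.uint64)
    out_r = np.empty((m, n), dtype=np.uint64)
    f = np.zeros(n, dtype=np.uint64)
    r = np.zeros(n, dtype=np.uint64)
    for i in range(L):
        f = ((f << two) | c64[i]) & mask
        r = (r >> two) | (comp[i] << top)
        if i >= k - 1:
            out_f[i - k + 1] = f
            out_r[i - k + 1] = r
    np.minimum(out_f, out_r, out=out_f)
    return out_f.T


def group_by_length(seqs) -> tuple[dict[int, tuple[list[int], np.ndarray]], list[int]]:
    """Pack ACGT-only sequences into per-length uint8 matrices.

    Returns ({length: (original indices, (N, L) code matrix)}, odd_indices)
    where odd_indices lists sequences containing non-ACGT characters (to be
    handled by the 1-D masked path).
    """
    buckets: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        buckets.setdefault(len(s), []).append(i)
    groups: dict[int, tuple[list[int], np.ndarray]] = {}
    odd: list[int] = []
    for L, idxs in buckets.items():
        mat = ENCODE[
            np.frombuffer("".join(seqs[i] for i in idxs).encode(), dtype=np.uint8)
        ].reshape(len(idxs), L)
        bad = (mat > 3).any(axis=1)
        if bad.any():
            clean = [i for i, b in zip(idxs, bad) if not b]
            odd.extend(i for i, b in zip(idxs, bad) if b)
            if clean:
                groups[L] = (clean, mat[~bad])
        else:
            groups[L] = (idxs, mat)
    return groups, odd


def rc_code(code: int, k: int) -> int:
    """Reverse-complement a single packed k-mer code (scalar, python int)."""
    out = 0
    for _ in range(k):
        out = (out << 2) | (3 - (code & 3))
        code >>= 2
    return out


def code_to_seq(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code & 3])
        code >>= 2
    return "".join(reversed(out))


def count_canonical_kmers(seqs, k: int, chunk_bases: int = 16_000_000) -> tuple[np.ndarray, np.ndarray]:
    """Count canonical k-mers over an iterable of sequences.

    Equal-length ACGT-only reads go through the vectorized matrix path in
    row chunks; reads with ambiguous bases fall back to the masked 1-D path.

    Returns (unique_codes, counts), both sorted by code.
    """
    seq_list = seqs if isinstance(seqs, list) else list(seqs)
    groups, odd = group_by_length(seq_list)
    collected: list[np.ndarray] = []
    for L in sorted(groups):
        if L < k:
            continue
        _, mat = groups[L]
        step = max(1, chunk_bases // L)
        for lo in range(0, mat.shape[0], step):
            collected.append(canonical_kmer_matrix(mat[lo : lo + step], k).ravel())
    for i in odd:
        if len(seq_list[i]) < k:
            continue
        canon, _, valid = canonical_kmers(encode(seq_list[i]), k)
        collected.append(canon[valid])
    if not collected:
        e = np.empty(0, dtype=np.uint64)
        return e, e.astype(np.int64)
    allk = np.concatenate(collected)
    return np.unique(allk, return_counts=True)


def isin_sorted(values: np.ndarray, sorted_array: np.ndarray) -> np.ndarray:
    """Membership of `values` in a sorted unique uint64 array."""
    if sorted_array.size == 0:
        return np.zeros(values.shape, dtype=bool)
    idx = np.searchsorted(sorted_array, values)
    idx[idx == sorted_array.size] = 0
    return sorted_array[idx] == values
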