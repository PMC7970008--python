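"""De novo assembly of merged reads, read-back mapping and pileups.

The assembler is a minimal de Bruijn unitig assembler over canonical
(strand-collapsed) k-mers: k-mers below a count threshold are dropped as
noise, unitigs are the maximal non-branching paths of the remaining graph,
and contigs shorter than ``min_contig_len`` are discarded. Contig
orientation is normalized to the lexicographically smaller strand and
contigs are emitted in sorted-sequence order, so the output is fully
deterministic. The mapper is gapless: exact seed k-mers propose placements
which are verified by Hamming comparison, and the best placement is
reported when its identity reaches ``min_identity``. Pileups count bases
{A,C,G,T,gap} per contig position per accession; the gapless mapper never
emits gap evidence itself (the category exists for the variant-score
contract downstream).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._kmer import canonical_kmers, count_canonical_kmers, encode, revcomp

log = logging.getLogger(__name__)

BASE_COLS = ("A", "C", "G", "T", "gap")


@dataclass
class Contig:
    contig_id: str
    seq: str
    source: str = "reference"  # accession id or "reference"
    n_supporting_reads: int = 0
    mean_depth: float = 0.0

    def __len__(self):
        return len(self.seq)


@dataclass
class Alignment:
    read_id: str
    contig_id: str
    start: int  # 0-based on the stored contig orientation
    strand: str  # + | -
    matches: int
    length: int  # aligned span; shorter than the read when end-clipped
    read_start: int = 0  # offset of the aligned span on the oriented read

    @property
    def identity(self) -> float:
        return self.matches / self.length if self.length else 0.0


class IntegrityError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# assembly


def _norm_contig(seq: str) -> str:
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def auto_kmer_threshold(counts: np.ndarray, cap: int = 15) -> int:
    """Coverage-adaptive solid-k-mer cutoff: first valley of the count histogram.

    Error k-mers form a decaying peak at low counts while genuine sequence
    sits near the locus coverage; the first local minimum separates the two.
    Falls back to 2 when the histogram is monotone (low-depth data), and is
    capped so shallow loci are never discarded wholesale.
    """
    if counts.size == 0:
        return 2
    hist = np.bincount(np.minimum(counts, 1000).astype(np.int64))
    # box-smooth to dodge empty-bin jitter
    if hist.size > 4:
        sm = np.convolve(hist, np.ones(3) / 3.0, mode="same")
    else:
        sm = hist.astype(float)
    for c in range(2, min(sm.size - 1, cap + 1)):
        if sm[c] <= sm[c + 1]:
            return max(2, c)
    return max(2, min(cap, sm.size - 1))


def assemble(
    merged_reads,
    k: int = 31,
    min_kmer_count: int | str = 2,
    min_contig_len: int = 100,
    source: str = "reference",
) -> list[Contig]:
    """Unitigs of the canonical de Bruijn graph of the merged reads.

    ``merged_reads`` is an iterable of sequences (or objects with a ``seq``
    attribute). k must be odd (a canonical k-mer must not be its own
    reverse complement) and smaller than the reads. ``min_kmer_count`` may
    be the string ``"auto"`` to pick the threshold from the k-mer count
    histogram (recommended at high coverage, where recurrent sequencing
    errors exceed any fixed small cutoff).
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    seqs = (r if isinstance(r, str) else r.seq for r in merged_reads)
    uniq, counts = count_canonical_kmers(seqs, k)
    if min_kmer_count == "auto":
        min_kmer_count = auto_kmer_threshold(counts)
        log.info("auto k-mer count threshold: %d", min_kmer_count)
    solid = {int(c) for c, n in zip(uniq, counts) if n >= min_kmer_count}
    if not solid:
        log.warning("no k-mer above count threshold %d: empty assembly", min_kmer_count)
        return []

    mask = (1 << (2 * k)) - 1
    shift = 2 * (k - 1)

    def canon_pairs(fwd: int, rc: int) -> int:
        return fwd if fwd <= rc else rc

    def out_edges(fwd: int, rc: int):
        """Successor oriented k-mers of (fwd, rc); rc is revcomp of fwd."""
        out = []
        for b in range(4):
            nf = ((fwd << 2) | b) & mask
            nr = (rc >> 2) | ((3 - b) << shift)
            if canon_pairs(nf, nr) in solid:
                out.append((nf, nr))
        return out

    # a canonical node is "linear" iff it has exactly one successor in each
    # orientation (one out-edge forward, one out-edge backward)
    def degree(fwd: int, rc: int) -> int:
        return len(out_edges(fwd, rc))

    # precompute rc for every solid k-mer once, vectorized
    solid_arr = np.fromiter(solid, dtype=np.uint64, count=len(solid))
    solid_arr.sort()
    rc_arr = _rc_codes(solid_arr, k)
    rc_of = {int(c): int(r) for c, r in zip(solid_arr, rc_arr)}

    visited: set[int] = set()
    unitigs: list[str] = []

    def walk(fwd: int, rc: int) -> list[int]:
        """Extend from oriented node while the path stays non-branching."""
        path = [fwd & 3]
        cur = (fwd, rc)
        while True:
            nxt = out_edges(*cur)
            if len(nxt) != 1:
                break
            nf, nr = nxt[0]
            canon = canon_pairs(nf, nr)
            # the successor must have exactly one predecessor (= one out-edge
            # of its reverse orientation) and must be unvisited and linear
            if degree(nr, nf) != 1:
                break
            if canon in visited:
                break
            visited.add(canon)
            path.append(nf & 3)
            cur = (nf, nr)
        return path

    def emit(start_fwd: int, start_rc: int):
        canon = canon_pairs(start_fwd, start_rc)
        visited.add(canon)
        ext = walk(start_fwd, start_rc)
        # seed sequence = the starting k-mer, then one base per extension step
        seq = _code_seq(start_fwd, k) + "".join("ACGT"[b] for b in ext[1:])
        unitigs.append(_norm_contig(seq))

    # pass 1: start unitigs at branch points / tips, in deterministic order
    for c in map(int, solid_arr):
        if c in visited:
            continue
        rc = rc_of[c]
        for fwd, bwd in ((c, rc), (rc, c)):
            # start in orientation `fwd` when the node has no unique
            # predecessor in that orientation (tip or branch behind it)
            preds = out_edges(bwd, fwd)
            if len(preds) != 1 or degree(preds[0][1], preds[0][0]) != 1:
                if c not in visited:
                    emit(fwd, bwd)
                break

    # pass 2: remaining nodes belong to simple cycles
    for c in map(int, solid_arr):
        if c not in visited:
            emit(c, rc_of[c])

    contigs = sorted(set(u for u in unitigs if len(u) >= min_contig_len))
    return [
        Contig(f"ctg{i:06d}", seq, source=source) for i, seq in enumerate(contigs)
    ]


def _rc_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Vectorized reverse complement of packed k-mer codes."""
    rev2 = np.zeros(256, dtype=np.uint8)
    for b in range(256):
        v, x = 0, b
        for _ in range(4):
            v = (v << 2) | (3 - (x & 3))
            x >>= 2
        rev2[b] = v
    by = codes.view(np.uint8).reshape(-1, 8)
    out = rev2[by][:, ::-1].copy().view(np.uint64).ravel()
    return out >> np.uint64(64 - 2 * k)


def _code_seq(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code & 3])
        code >>= 2
    return "".join(reversed(out))


# ---------------------------------------------------------------------------
# mapping


class ContigIndex:
    """Exact seed k-mer index over a contig set, for gapless mapping."""

    MAX_POSTINGS = 8  # k-mers placed in more positions are skipped as seeds

    def __init__(self, contigs: list[Contig], seed_k: int = 31):
        self.contigs = contigs
        self.seed_k = seed_k
        self.codes = [encode(c.seq) for c in contigs]
        self.index: dict[int, list[tuple[int, int, bool]]] = {}
        banned: set[int] = set()  # over-represented k-mers: ambiguous seeds
        for ci, c in enumerate(contigs):
            canon, fwd_is_canon, valid = canonical_kmers(self.codes[ci], seed_k)
            for pos in np.nonzero(valid)[0]:
                key = int(canon[pos])
                if key in banned:
                    continue
                postings = self.index.get(key)
                if postings is None:
                    self.index[key] = [(ci, int(pos), bool(fwd_is_canon[pos]))]
                elif len(postings) >= self.MAX_POSTINGS:
                    del self.index[key]
                    banned.add(key)
                else:
                    postings.append((ci, int(pos), bool(fwd_is_canon[pos])))


def map_read(
    read_id: str,
    seq: str,
    index: ContigIndex,
    min_identity: float = 0.9,
    seed_stride: int = 37,
) -> Alignment | None:
    k = index.seed_k
    n = len(seq)
    if n < k:
        return None
    codes_f = encode(seq)
    canon, fwd_is_canon, valid = canonical_kmers(codes_f, k)
    offsets = list(range(0, n - k, seed_stride)) + [n - k]
    votes: dict[tuple[int, int, str], int] = {}
    for off in offsets:
        if not valid[off]:
            continue
        postings = index.index.get(int(canon[off]))
        if not postings:
            continue
        for ci, pos, ctg_fwd in postings:
            if bool(fwd_is_canon[off]) == ctg_fwd:
                key = (ci, pos - off, "+")
            else:
                key = (ci, pos - (n - k - off), "-")
            votes[key] = votes.get(key, 0) + 1
    if not votes:
        return None
    cands = sorted(votes, key=lambda c: (-votes[c], c[0], c[1], c[2] == "-"))[:3]
    # (matches, aligned_len, ci, astart, strand, read_start)
    best: tuple[int, int, int, int, str, int] | None = None
    rc_codes = None
    for ci, start, strand in cands:
        ctg = index.codes[ci]
        # reads may overhang contig ends; the aligned span is clipped to the
        # contig and must still hold at least one full seed k-mer
        astart = max(0, start)
        aend = min(ctg.size, start + n)
        alen = aend - astart
        if alen < k:
            continue
        if strand == "+":
            rcodes = codes_f
        else:
            if rc_codes is None:
                rc_codes = encode(revcomp(seq))
            rcodes = rc_codes
        rs = astart - start
        matches = alen - int(
            np.count_nonzero(ctg[astart:aend] != rcodes[rs : rs + alen])
        )
        key = (-matches, ci, astart, strand == "-")
        if best is None or key < (-best[0], best[2], best[3], best[4] == "-"):
            best = (matches, alen, ci, astart, strand, rs)
    if best is None or best[0] / best[1] < min_identity:
        return None
    matches, alen, ci, astart, strand, rs = best
    return Alignment(
        read_id, index.contigs[ci].contig_id, astart, strand, matches, alen, rs
    )


def map_reads(
    reads,
    contigs: list[Contig] | ContigIndex,
    seed_k: int = 31,
    min_identity: float = 0.9,
) -> tuple[list[Alignment], list[str]]:
    """Map (read_id, seq) pairs to contigs; returns (alignments, unmapped ids)."""
    index = contigs if isinstance(contigs, ContigIndex) else ContigIndex(contigs, seed_k)
    alignments = []
    unmapped = []
    for read_id, seq in reads:
        aln = map_read(read_id, seq, index, min_identity)
        if aln is None:
            unmapped.append(read_id)
        else:
            alignments.append(aln)
    return alignments, unmapped


def retain_contigs(
    contigs: list[Contig], alignments: list[Alignment], min_reads: int = 5
) -> list[Contig]:
    """Keep contigs supported by at least ``min_reads`` distinct mapped reads."""
    readsets: dict[str, set[str]] = {}
    lengths: dict[str, int] = {}
    for aln in alignments:
        readsets.setdefault(aln.contig_id, set()).add(aln.read_id)
        lengths[aln.contig_id] = lengths.get(aln.contig_id, 0) + aln.length
    kept = []
    for c in contigs:  # assembly order is already deterministic
        n = len(readsets.get(c.contig_id, ()))
        if n >= min_reads:
            kept.append(
                Contig(
                    c.contig_id,
                    c.seq,
                    source=c.source,
                    n_supporting_reads=n,
                    mean_depth=lengths.get(c.contig_id, 0) / len(c.seq),
                )
            )
    return kept


def build_reference_hypomethylome(
    per_accession_reads: dict[str, list[tuple[str, str]]],
    k: int = 31,
    min_kmer_count: int = 2,
    min_contig_len: int = 100,
    min_reads: int = 5,
    seed_k: int = 31,
    min_identity: float = 0.9,
) -> tuple[list[Contig], dict[str, list[Alignment]], pd.DataFrame]:
    """Pooled assembly across accessions plus per-accession read inclusion.

    Assembles the pooled merged reads, retains contigs by pooled distinct-read
    support, then re-maps each accession's reads to the retained set.
    Returns (contigs, per-accession alignments, stats table).
    """
    if len(per_accession_reads) < 2:
        raise ValueError("need at least two accessions for a reference hypomethylome")
    accs = sorted(per_accession_reads)
    pooled = (seq for a in accs for _, seq in per_accession_reads[a])
    contigs = assemble(pooled, k, min_kmer_count, min_contig_len, source="reference")
    index = ContigIndex(contigs, seed_k)
    per_acc_aln: dict[str, list[Alignment]] = {}
    for a in accs:
        per_acc_aln[a], _ = map_reads(per_accession_reads[a], index, seed_k, min_identity)
    pooled_aln = [aln for a in accs for aln in per_acc_aln[a]]
    retained = retain_contigs(contigs, pooled_aln, min_reads)
    kept_ids = {c.contig_id for c in retained}
    for a in accs:
        per_acc_aln[a] = [aln for aln in per_acc_aln[a] if aln.contig_id in kept_ids]
    stats = assembly_stats(
        retained,
        {a: (per_acc_aln[a], len(per_accession_reads[a])) for a in accs},
    )
    return retained, per_acc_aln, stats


def assembly_stats(
    contigs: list[Contig], per_source: dict[str, tuple[list[Alignment], int]]
) -> pd.DataFrame:
    """Assembly summary: contigs, % reads included, reads/contig, mean length."""
    n_contigs = len(contigs)
    mean_len = float(np.mean([len(c.seq) for c in contigs])) if contigs else 0.0
    rows = []
    for src in sorted(per_source):
        alns, n_reads = per_source[src]
        included = len({a.read_id for a in alns})
        rows.append(
            {
                "source": src,
                "contigs": n_contigs,
                "reads": n_reads,
                "reads_included_pct": round(100.0 * included / n_reads, 1) if n_reads else 0.0,
                "avg_reads_per_contig": round(included / n_contigs, 1) if n_contigs else 0.0,
                "avg_contig_len": round(mean_len, 1),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pileup


def pileup(
    alignments: list[Alignment],
    contigs: list[Contig],
    reads: dict[str, str],
) -> dict[str, np.ndarray]:
    """Per-contig base-count matrices of shape (length, 5) over A,C,G,T,gap.

    Reads on the minus strand contribute their reverse complement. Every
    position of every contig is represented (zero rows where uncovered),
    which the coverage-based DMR logic relies on.
    """
    arrays = {c.contig_id: np.zeros((len(c.seq), 5), dtype=np.int32) for c in contigs}
    for aln in alignments:
        arr = arrays.get(aln.contig_id)
        if arr is None or aln.start < 0 or aln.start + aln.length > arr.shape[0]:
            raise IntegrityError(
                f"alignment of {aln.read_id} outside contig {aln.contig_id}"
            )
        seq = reads[aln.read_id]
        if aln.strand == "-":
            seq = revcomp(seq)
        codes = encode(seq)[aln.read_start : aln.read_start + aln.length]
        ok = codes <= 3
        pos = aln.start + np.nonzero(ok)[0]
        arr[pos, codes[ok]] += 1
    return arrays


def pileup_to_frame(arrays: dict[str, np.ndarray]) -> pd.DataFrame:
    """Sparse TSV form of a pileup: rows only where depth > 0."""
    frames = []
    for cid in sorted(arrays):
        arr = arrays[cid]
        depth = arr.sum(axis=1)
        idx = np.nonzero(depth)[0]
        if idx.size == 0:
            continue
        df = pd.DataFrame(arr[idx], columns=list(BASE_COLS))
        df.insert(0, "pos", idx)
        df.insert(0, "contig", cid)
        df["depth"] = depth[idx]
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["contig", "pos", *BASE_COLS, "depth"])
    return pd.concat(frames, ignore_index=True)


def frame_to_pileup(df: pd.DataFrame, contig_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """Inverse of :func:`pileup_to_frame` given the contig universe."""
    arrays = {cid: np.zeros((L, 5), dtype=np.int32) for cid, L in contig_lengths.items()}
    for cid, sub in df.groupby("contig"):
        arr = arrays[str(cid)]
        arr[sub["pos"].to_numpy()] = sub[list(BASE_COLS)].to_numpy()
    return arrays


def alignments_to_frame(alignments: list[Alignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (a.read_id, a.contig_id, a.start, a.strand, a.matches, a.length, a.read_start)
            for a in alignments
        ],
        columns=["read_id", "contig_id", "start", "strand", "matches", "length", "read_start"],
    )
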