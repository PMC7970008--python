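"""Coverage-normalized difference-score variant calling between accessions.

Per contig position, the base counts of each accession form a vector over
{A,C,G,T,gap}; each vector is normalized by its coverage to percentages
(summing to 100), and the difference score of two accessions is the L1
distance of their normalized vectors. The score ranges from 0 (identical
composition) to 200 (disjoint composition). A position is called a variant
for a pair when both accessions reach ``min_cov`` (default 10) reads and
the score is strictly greater than ``score_threshold`` (default 180).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CATEGORIES = ("A", "C", "G", "T", "gap")
ACGT = ("A", "C", "G", "T")


class UndefinedPositionError(ValueError):
    """Normalization requested for a zero-depth vector."""


def _as_tuple(v: Mapping[str, float] | Sequence[float], categories) -> tuple[float, ...]:
    if isinstance(v, Mapping):
        unknown = set(v) - set(categories)
        if unknown:
            raise ValueError(f"unknown base categories {sorted(unknown)}")
        return tuple(float(v.get(c, 0)) for c in categories)
    return tuple(float(x) for x in v)


def normalize(
    counts: Mapping[str, float] | Sequence[float],
    categories: tuple[str, ...] = CATEGORIES,
) -> dict[str, float]:
    """Scale a base-count vector by its coverage to percentages summing to 100."""
    vec = _as_tuple(counts, categories)
    depth = sum(vec)
    if depth <= 0:
        raise UndefinedPositionError("cannot normalize a zero-depth vector")
    return {c: 100.0 * x / depth for c, x in zip(categories, vec)}


def difference_score(
    counts_i: Mapping[str, float] | Sequence[float],
    counts_j: Mapping[str, float] | Sequence[float],
    categories: tuple[str, ...] = CATEGORIES,
) -> float:
    """Sum of absolute differences of the normalized vectors; in [0, 200].

    For integer counts the score is computed by cross-multiplication,
    100 * sum|c_i*d_j - c_j*d_i| / (d_i*d_j), so the bounds 0 and 200 are
    attained exactly rather than up to floating-point dust.
    """
    vi = _as_tuple(counts_i, categories)
    vj = _as_tuple(counts_j, categories)
    di, dj = sum(vi), sum(vj)
    if di <= 0 or dj <= 0:
        raise UndefinedPositionError("difference score needs depth > 0 on both sides")
    if all(float(x).is_integer() for x in (*vi, *vj)):
        num = sum(abs(int(a) * int(dj) - int(b) * int(di)) for a, b in zip(vi, vj))
        return 100.0 * num / (int(di) * int(dj))
    return sum(abs(100.0 * a / di - 100.0 * b / dj) for a, b in zip(vi, vj))


@dataclass
class Variant:
    contig_id: str
    pos: int  # 0-based internally; exports convert to 1-based
    pair: tuple[str, str]
    score: float
    depth_i: int
    depth_j: int
    vector_i: dict[str, float]
    vector_j: dict[str, float]
    major_allele_i: str
    major_allele_j: str


def _category_slice(bases: str) -> list[int]:
    """Column indices of the pileup matrix for the active category set."""
    if bases == "ACGT":
        return [0, 1, 2, 3]
    if bases in ("ACGTgap", "ACGTGAP", "ACGT+gap"):
        return [0, 1, 2, 3, 4]
    raise ValueError("bases must be 'ACGT' or 'ACGTgap'")


def call_pairwise_variants(
    pileup_i: dict[str, np.ndarray],
    pileup_j: dict[str, np.ndarray],
    pair: tuple[str, str],
    min_cov: int = 10,
    score_threshold: float = 180.0,
    bases: str = "ACGTgap",
    all_scores: bool = False,
) -> list[Variant]:
    """Scored positions for one accession pair, vectorized per contig.

    With ``all_scores`` every position passing the coverage gate is returned
    regardless of score (the unthresholded analysis); otherwise only strict
    score > threshold calls. Output sorted by (contig, pos).
    """
    if set(pileup_i) != set(pileup_j):
        from .assembly import IntegrityError

        raise IntegrityError("pileups computed against different references")
    cols = _category_slice(bases)
    cats = tuple(CATEGORIES[c] for c in cols)
    out: list[Variant] = []
    for cid in sorted(pileup_i):
        ai = pileup_i[cid][:, cols].astype(np.float64)
        aj = pileup_j[cid][:, cols].astype(np.float64)
        di = ai.sum(axis=1)
        dj = aj.sum(axis=1)
        ok = (di >= min_cov) & (dj >= min_cov)
        if not ok.any():
            continue
        idx = np.nonzero(ok)[0]
        fi = 100.0 * ai[idx] / di[idx, None]
        fj = 100.0 * aj[idx] / dj[idx, None]
        # round off float dust so the strict >threshold gate is not tripped
        # by representation error at exact-boundary compositions
        scores = np.round(np.abs(fi - fj).sum(axis=1), 9)
        take = slice(None) if all_scores else scores > score_threshold
        sel = np.arange(idx.size)[take]
        for s in sel:
            p = int(idx[s])
            out.append(
                Variant(
                    cid,
                    p,
                    pair,
                    float(scores[s]),
                    int(di[p]),
                    int(dj[p]),
                    dict(zip(cats, fi[s])),
                    dict(zip(cats, fj[s])),
                    cats[int(np.argmax(ai[p]))],
                    cats[int(np.argmax(aj[p]))],
                )
            )
    return out


def call_all_pairs(
    pileups: dict[str, dict[str, np.ndarray]],
    min_cov: int = 10,
    score_threshold: float = 180.0,
    bases: str = "ACGTgap",
    all_scores: bool = False,
) -> dict[tuple[str, str], list[Variant]]:
    """Variants for every unordered accession pair."""
    accs = sorted(pileups)
    calls = {}
    for i, a in enumerate(accs):
        for b in accs[i + 1 :]:
            calls[(a, b)] = call_pairwise_variants(
                pileups[a], pileups[b], (a, b), min_cov, score_threshold, bases, all_scores
            )
    return calls


def pairwise_difference_table(calls: dict[tuple[str, str], list[Variant]]) -> pd.DataFrame:
    """Symmetric matrix of called-variant counts per accession pair."""
    accs = sorted({a for pair in calls for a in pair})
    mat = pd.DataFrame(0, index=accs, columns=accs)
    for (a, b), vs in calls.items():
        mat.loc[a, b] = len(vs)
        mat.loc[b, a] = len(vs)
    return mat


def variants_to_frame(calls: dict[tuple[str, str], list[Variant]]) -> pd.DataFrame:
    rows = []
    for pair in sorted(calls):
        for v in calls[pair]:
            rows.append(
                {
                    "contig": v.contig_id,
                    "pos": v.pos,
                    "first": v.pair[0],
                    "second": v.pair[1],
                    "score": round(v.score, 4),
                    "depth_first": v.depth_i,
                    "depth_second": v.depth_j,
                    "major_first": v.major_allele_i,
                    "major_second": v.major_allele_j,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "contig", "pos", "first", "second", "score",
            "depth_first", "depth_second", "major_first", "major_second",
        ],
    )
    return df.sort_values(["contig", "pos", "first", "second"], ignore_index=True)


def write_vcf(
    calls: dict[tuple[str, str], list[Variant]],
    contig_seqs: dict[str, str],
    path,
) -> None:
    """Minimal VCF 4.2 export (positions converted to 1-based).

    REF is the reference-hypomethylome contig base; ALT is the major allele
    of whichever accession differs from it ('.' when neither does, e.g. a
    pure frequency shift).
    """
    rows = []
    for pair in sorted(calls):
        for v in calls[pair]:
            ref = contig_seqs[v.contig_id][v.pos]
            alt = "."
            for cand in (v.major_allele_i, v.major_allele_j):
                if cand != ref and cand in ACGT:
                    alt = cand
                    break
            rows.append(
                (
                    v.contig_id,
                    v.pos + 1,
                    ref,
                    alt,
                    f"PAIR={v.pair[0]}|{v.pair[1]};SCORE={v.score:.2f};"
                    f"DPI={v.depth_i};DPJ={v.depth_j}",
                )
            )
    rows.sort()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=PAIR,Number=1,Type=String,Description="Accession pair">\n')
        fh.write('##INFO=<ID=SCORE,Number=1,Type=Float,Description="Difference score">\n')
        fh.write('##INFO=<ID=DPI,Number=1,Type=Integer,Description="Depth first">\n')
        fh.write('##INFO=<ID=DPJ,Number=1,Type=Integer,Description="Depth second">\n')
        for cid in sorted(contig_seqs):
            fh.write(f"##contig=<ID={cid},length={len(contig_seqs[cid])}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for cid, pos, ref, alt, info in rows:
            fh.write(f"{cid}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\n")
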