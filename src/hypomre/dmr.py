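"""Coverage-defined differentially methylated regions.

A locus of the reference hypomethylome is sequenced in an accession only if
it was unmethylated (and hence released by the enzyme) there, so read
coverage is the methylation proxy: two strategies are applied, (1) pairwise
— covered intervals of one accession minus the covered intervals of a
second, and (2) unique — positions covered in exactly one accession.
Regions shorter than ``min_region_len`` (default 50 bp) are discarded.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assembly import IntegrityError


@dataclass
class Region:
    contig_id: str
    start: int
    end: int  # 0-based half-open
    owner: str  # accession the coverage belongs to
    comparison: str  # "first|second" accession pair, or "unique"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CoverageMap:
    """Covered intervals per contig plus the contig universe they live on."""

    intervals: dict[str, list[tuple[int, int]]]
    lengths: dict[str, int]  # every contig of the shared reference

    def total_covered(self) -> int:
        return sum(e - s for ivs in self.intervals.values() for s, e in ivs)


def covered_intervals(depth: np.ndarray, min_cov: int = 1) -> list[tuple[int, int]]:
    """Maximal runs of positions with depth >= min_cov, half-open."""
    mask = np.asarray(depth) >= min_cov
    if mask.size == 0:
        return []
    edges = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return [(int(s), int(e)) for s, e in zip(starts, ends)]


def coverage_from_pileup(
    pileups: dict[str, np.ndarray], min_cov: int = 1
) -> CoverageMap:
    """CoverageMap of one accession's pileup against the reference."""
    intervals = {}
    lengths = {}
    for cid, arr in pileups.items():
        lengths[cid] = arr.shape[0]
        ivs = covered_intervals(arr.sum(axis=1), min_cov)
        if ivs:
            intervals[cid] = ivs
    return CoverageMap(intervals, lengths)


def _subtract(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Interval set difference a \\ b for sorted non-overlapping intervals."""
    out = []
    bi = 0
    for s, e in a:
        cur = s
        while bi < len(b) and b[bi][1] <= cur:
            bi += 1
        j = bi
        while j < len(b) and b[j][0] < e:
            bs, be = b[j]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if be >= e:
                break
            j += 1
        if cur < e:
            out.append((cur, e))
    return out


def _check_universe(a: CoverageMap, b: CoverageMap) -> None:
    if set(a.lengths) != set(b.lengths):
        raise IntegrityError("coverage maps computed against different references")


def pairwise_dmr(
    cov_first: CoverageMap,
    cov_second: CoverageMap,
    first: str,
    second: str,
    min_region_len: int = 50,
) -> list[Region]:
    """Regions covered by `first` but not by `second` (ordered comparison)."""
    _check_universe(cov_first, cov_second)
    regions = []
    for cid in sorted(cov_first.intervals):
        diff = _subtract(cov_first.intervals[cid], cov_second.intervals.get(cid, []))
        for s, e in diff:
            if e - s >= min_region_len:
                regions.append(Region(cid, s, e, first, f"{first}|{second}"))
    return regions


def unique_regions(
    coverages: dict[str, CoverageMap], min_region_len: int = 50
) -> dict[str, list[Region]]:
    """Intervals covered in exactly one accession, per owning accession."""
    accs = sorted(coverages)
    if len(accs) < 2:
        raise ValueError("unique regions need at least two accessions")
    base = coverages[accs[0]]
    for a in accs[1:]:
        _check_universe(base, coverages[a])
    out: dict[str, list[Region]] = {a: [] for a in accs}
    for cid in sorted(base.lengths):
        L = base.lengths[cid]
        count = np.zeros(L, dtype=np.int16)
        owner = np.zeros(L, dtype=np.int16)
        for ai, a in enumerate(accs):
            for s, e in coverages[a].intervals.get(cid, []):
                count[s:e] += 1
                owner[s:e] = ai
        single = count == 1
        for ai, a in enumerate(accs):
            for s, e in covered_intervals(single & (owner == ai), min_cov=1):
                if e - s >= min_region_len:
                    out[a].append(Region(cid, s, e, a, "unique"))
    return out


def dmr_summary(pairwise: dict[tuple[str, str], list[Region]]) -> pd.DataFrame:
    """Directed region counts per accession pair (both directions per row)."""
    pairs = sorted({tuple(sorted(k)) for k in pairwise})
    rows = []
    for a, b in pairs:
        rows.append(
            {
                "first": a,
                "second": b,
                "regions_in_first": len(pairwise.get((a, b), [])),
                "regions_in_second": len(pairwise.get((b, a), [])),
            }
        )
    return pd.DataFrame(rows, columns=["first", "second", "regions_in_first", "regions_in_second"])


def unique_summary(uniq: dict[str, list[Region]]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"accession": a, "unique_regions": len(rs)} for a, rs in sorted(uniq.items())]
    )


def regions_to_bed(regions: list[Region]) -> pd.DataFrame:
    """BED form: contig, start, end, name=owner|comparison, score=length."""
    rows = [
        (r.contig_id, r.start, r.end, f"{r.owner}|{r.comparison}", r.length)
        for r in sorted(regions, key=lambda r: (r.contig_id, r.start, r.end, r.owner))
    ]
    return pd.DataFrame(rows, columns=["contig", "start", "end", "name", "score"])
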