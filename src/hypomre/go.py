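"""Polymorphism counts per Gene Ontology term and their clustering.

Called variant positions are attributed to every accession participating in
at least one passing pairwise comparison at that position; attributed
positions on GO-annotated contigs are counted per accession both as
(position, GO) incidences and as distinct positions, with and without the
difference-score threshold. The most polymorphic terms form a GO x
accession matrix that is hierarchically clustered on both axes.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, leaves_list, linkage
from scipy.spatial.distance import pdist

from .variants import Variant

log = logging.getLogger(__name__)

_GO_RE = re.compile(r"^GO:\d{7}$")


def load_annotation(path) -> dict[str, frozenset[str]]:
    """contig_id TAB comma-separated GO ids -> {contig: {terms}}.

    A header line starting with 'contig' is tolerated; malformed term ids
    raise. Contigs without terms are omitted.
    """
    out: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "contig", "gene_id")):
                continue
            cid, _, terms = line.partition("\t")
            terms = [t for t in terms.split(",") if t and t != "-"]
            for t in terms:
                if not _GO_RE.match(t):
                    raise ValueError(f"invalid GO term id {t!r} for {cid}")
            if terms:
                out[cid] = frozenset(terms)
    return out


def attribute_variants(
    calls: dict[tuple[str, str], list[Variant]]
) -> dict[str, set[tuple[str, int]]]:
    """Positions per accession: X gets every position with a passing pair
    in which X participates (a position may belong to several accessions)."""
    out: dict[str, set[tuple[str, int]]] = {}
    for a, b in calls:  # every accession appears, even with no passing pair
        out.setdefault(a, set())
        out.setdefault(b, set())
    for (a, b), vs in calls.items():
        for v in vs:
            key = (v.contig_id, v.pos)
            out.setdefault(a, set()).add(key)
            out.setdefault(b, set()).add(key)
    return out


@dataclass
class GOSummary:
    accession: str
    n_polymorphic_gos: int
    n_incidences: int  # (position, GO) pairs
    n_positions: int  # distinct annotated positions


def count_go_polymorphisms(
    attributed: dict[str, set[tuple[str, int]]],
    annotation: dict[str, frozenset[str]],
    known_contigs: set[str] | None = None,
) -> list[GOSummary]:
    """Per-accession polymorphic-GO summary over attributed positions."""
    if known_contigs is not None:
        unknown = set(annotation) - known_contigs
        if unknown:
            log.warning("annotation references %d unknown contigs; skipped", len(unknown))
            annotation = {c: t for c, t in annotation.items() if c in known_contigs}
    out = []
    for acc in sorted(attributed):
        gos: set[str] = set()
        incid = 0
        npos = 0
        for cid, _pos in attributed[acc]:
            terms = annotation.get(cid)
            if not terms:
                continue
            gos |= terms
            incid += len(terms)
            npos += 1
        out.append(GOSummary(acc, len(gos), incid, npos))
    return out


def go_summary_table(
    with_threshold: list[GOSummary], without_threshold: list[GOSummary]
) -> pd.DataFrame:
    """The dual (thresholded / unthresholded) polymorphic-GO table."""
    rows = {}
    for s in with_threshold:
        rows[s.accession] = {
            "accession": s.accession,
            "polymorphic_gos": s.n_polymorphic_gos,
            "incidences": s.n_incidences,
            "positions": s.n_positions,
        }
    for s in without_threshold:
        rows.setdefault(s.accession, {"accession": s.accession})
        rows[s.accession].update(
            {
                "polymorphic_gos_nothr": s.n_polymorphic_gos,
                "incidences_nothr": s.n_incidences,
                "positions_nothr": s.n_positions,
            }
        )
    return pd.DataFrame(sorted(rows.values(), key=lambda r: r["accession"])).fillna(0)


def go_count_matrix(
    attributed: dict[str, set[tuple[str, int]]],
    annotation: dict[str, frozenset[str]],
) -> pd.DataFrame:
    """GO x accession matrix of distinct attributed positions per term."""
    accs = sorted(attributed)
    counts: dict[str, dict[str, int]] = {}
    for acc in accs:
        for cid, _pos in attributed[acc]:
            for term in annotation.get(cid, ()):
                counts.setdefault(term, dict.fromkeys(accs, 0))
                counts[term][acc] += 1
    df = pd.DataFrame.from_dict(counts, orient="index", columns=accs).fillna(0)
    return df.sort_index().astype(int)


@dataclass
class GOMatrix:
    matrix: pd.DataFrame  # top-n GO x accession, in clustered order
    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None


def top_go_matrix(
    counts: pd.DataFrame,
    top_n: int = 50,
    method: str = "average",
    metric: str = "euclidean",
) -> GOMatrix:
    """Restrict to the top-n most polymorphic GOs and cluster both axes.

    Terms are ranked by total count across accessions, ties broken by GO id;
    rows (terms) and columns (accessions) are reordered by hierarchical
    clustering leaf order. Axes with < 2 elements keep their input order.
    """
    if counts.shape[1] < 2:
        raise ValueError("need counts for at least two accessions")
    if len(counts) > top_n:
        order = counts.assign(_tot=counts.sum(axis=1)).sort_values(
            ["_tot"], ascending=False, kind="stable"
        )
        # stable sort on the descending total preserves GO-id order for ties
        top = order.index[:top_n]
    else:
        if len(counts) < top_n:
            log.info("only %d GO terms available (top_n=%d)", len(counts), top_n)
        top = counts.index
    sub = counts.loc[top].sort_index()

    def _order(mat: np.ndarray, labels: list[str]):
        if len(labels) < 2:
            return labels, None
        lk = linkage(pdist(mat, metric=metric), method=method)
        return [labels[i] for i in leaves_list(lk)], lk

    row_order, row_lk = _order(sub.to_numpy(float), list(sub.index))
    col_order, col_lk = _order(sub.to_numpy(float).T, list(sub.columns))
    return GOMatrix(sub.loc[row_order, col_order], row_order, col_order, row_lk, col_lk)


def first_split_isolates(col_linkage: np.ndarray, col_order_input: list[str]) -> list[str]:
    """Members of the smaller cluster at the two-cluster cut of the accession axis."""
    cut = cut_tree(col_linkage, n_clusters=2).ravel()
    groups = [
        [c for c, g in zip(col_order_input, cut) if g == gid] for gid in (0, 1)
    ]
    return min(groups, key=len)


def plot_heatmap(gomatrix: GOMatrix, path) -> None:
    """Optional heatmap hook (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, max(4, 0.15 * len(gomatrix.matrix))))
    im = ax.imshow(gomatrix.matrix.to_numpy(float), aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(gomatrix.col_order)), gomatrix.col_order, rotation=90)
    ax.set_yticks(range(len(gomatrix.row_order)), gomatrix.row_order, fontsize=5)
    fig.colorbar(im, ax=ax, label="polymorphic positions")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
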