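"""Covariance PCA over per-accession allele-frequency vectors.

Accessions are pooled clonal samples, so each entry is the normalized
frequency (0-100) of the column's global major category rather than a
diploid genotype. Columns failing the coverage gate in any accession are
dropped (complete-case filtering; with a handful of samples imputation is
indefensible). PCA is the eigendecomposition of the accession-by-accession
covariance of the column-centered matrix, so with n accessions at most
n - 1 components carry variance.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variants import CATEGORIES, Variant

_EIG_TOL = 1e-12


@dataclass
class FrequencyMatrix:
    """Accession x variant-position major-allele frequency matrix."""

    values: pd.DataFrame  # rows = accessions, columns = "(contig, pos)" labels
    major: dict[str, str]  # column label -> global major category
    n_dropped: int  # columns removed by the coverage gate


@dataclass
class PCAResult:
    eigenvalues: np.ndarray  # non-increasing
    explained_pct: np.ndarray  # sums to 100 over nonzero components
    projections: pd.DataFrame  # accessions x components


def build_matrix(
    variant_positions,
    pileups: dict[str, dict[str, np.ndarray]],
    min_cov: int = 10,
) -> FrequencyMatrix:
    """Frequency matrix over the union of called variant positions.

    ``variant_positions`` is an iterable of (contig, pos) or Variant.
    The global major category of a column is the argmax of counts summed
    over accessions (ties broken in the order A < C < G < T < gap).
    """
    positions = set()
    for v in variant_positions:
        positions.add((v.contig_id, v.pos) if isinstance(v, Variant) else (v[0], int(v[1])))
    accs = sorted(pileups)
    cols: dict[str, list[float]] = {}
    majors: dict[str, str] = {}
    dropped = 0
    for cid, pos in sorted(positions):
        vecs = []
        ok = True
        for a in accs:
            arr = pileups[a].get(cid)
            if arr is None or pos >= arr.shape[0]:
                ok = False
                break
            v = arr[pos].astype(np.float64)
            if v.sum() < min_cov:
                ok = False
                break
            vecs.append(v)
        if not ok:
            dropped += 1
            continue
        total = np.sum(vecs, axis=0)
        major = int(np.argmax(total))  # argmax takes the first max: A<C<G<T<gap
        label = f"{cid}:{pos}"
        majors[label] = CATEGORIES[major]
        cols[label] = [100.0 * v[major] / v.sum() for v in vecs]
    values = pd.DataFrame(cols, index=accs)
    return FrequencyMatrix(values, majors, dropped)


def run_pca(matrix: FrequencyMatrix | pd.DataFrame) -> PCAResult:
    """Center columns, eigendecompose the accession covariance, project.

    Implemented through the SVD of the centered matrix (identical spectrum,
    numerically stabler than forming the covariance explicitly). All-rows-
    identical input is a defined degenerate case: zero eigenvalues,
    projections at the origin.
    """
    values = matrix.values if isinstance(matrix, FrequencyMatrix) else matrix
    if values.shape[1] == 0:
        raise ValueError("empty frequency matrix: no columns passed the coverage gate")
    X = values.to_numpy(float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least two accessions")
    Xc = X - X.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    eig = (s**2) / (n - 1)  # eigenvalues of the sample covariance
    eig[eig <= _EIG_TOL] = 0.0
    total = eig.sum()
    explained = 100.0 * eig / total if total > 0 else np.zeros_like(eig)
    proj = u * s  # component scores per accession
    proj[:, eig == 0.0] = 0.0
    comps = [f"PC{i + 1}" for i in range(len(eig))]
    return PCAResult(eig, explained, pd.DataFrame(proj, index=values.index, columns=comps))


def pca_tables(result: PCAResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(eigenvalue/explained-variance table, projection table) for export."""
    comps = list(result.projections.columns)
    ev = pd.DataFrame(
        {
            "component": comps,
            "eigenvalue": result.eigenvalues,
            "explained_pct": result.explained_pct,
        }
    )
    return ev, result.projections.reset_index(names="accession")


def plot_projection(result: PCAResult, path, components=(0, 1)) -> None:
    """Optional PC scatter hook (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    i, j = components
    fig, ax = plt.subplots(figsize=(5, 4))
    xs = result.projections.iloc[:, i]
    ys = result.projections.iloc[:, j] if result.projections.shape[1] > j else 0 * xs
    ax.scatter(xs, ys)
    for acc, x, y in zip(result.projections.index, xs, ys):
        ax.annotate(acc, (x, y), fontsize=8)
    ax.set_xlabel(f"PC{i + 1} ({result.explained_pct[i]:.1f}%)")
    if result.projections.shape[1] > j:
        ax.set_ylabel(f"PC{j + 1} ({result.explained_pct[j]:.1f}%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
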