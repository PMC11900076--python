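"""Gene-gene and gene-cell-type correlation screens plus UMAP atlases.

Gene-gene screens use plain Pearson r over cells on the expression view;
pairs above a signed threshold (default r > 0.8) are flagged as highly
correlated.  Gene-type association is the point-biserial correlation: the
Pearson r between a gene's expression and the 0/1 membership indicator of a
type.  The UMAP atlas works on any per-cell feature matrix — an expression
view or the reconstructed attribution matrix — and is deterministic under a
fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import LabeledExpressionMatrix

__all__ = ["CorrelationReport", "gene_correlation", "gene_type_correlation", "umap_atlas", "plot_atlas"]


@dataclass
class CorrelationReport:
    """Pairwise Pearson correlations and the pairs above the threshold."""

    matrix: pd.DataFrame  # symmetric, genes x genes
    high_pairs: list[tuple[str, str, float]]  # (g, h, r) with g < h and r > threshold
    threshold: float
    constant_genes: list[str]  # excluded: correlation undefined

    def to_csv(self, path) -> None:
        self.matrix.to_csv(path)


def _values_and_genes(matrix: LabeledExpressionMatrix | pd.DataFrame, genes=None):
    if isinstance(matrix, LabeledExpressionMatrix):
        genes = list(genes) if genes is not None else list(matrix.gene_ids)
        sub = matrix.subset_genes(genes)
        return sub.values, genes
    df = matrix if genes is None else matrix[list(genes)]
    return df.to_numpy(dtype=np.float64), [str(c) for c in df.columns]


def gene_correlation(
    matrix: LabeledExpressionMatrix | pd.DataFrame,
    genes=None,
    threshold: float = 0.8,
) -> CorrelationReport:
    """Pearson correlation of the selected genes across all cells.

    The threshold is applied to the signed r (not |r|), so strongly negative
    pairs are never flagged.  Constant genes are excluded with a warning
    since their correlation is undefined.
    """
    X, gene_list = _values_and_genes(matrix, genes)
    if X.shape[0] < 2:
        raise ValueError("correlation needs at least 2 cells")
    std = X.std(axis=0)
    constant = [g for g, s in zip(gene_list, std) if s == 0.0]
    if constant:
        warnings.warn(f"constant genes excluded from correlation: {constant}", stacklevel=2)
    keep = [g for g in gene_list if g not in set(constant)]
    idx = [gene_list.index(g) for g in keep]
    corr = np.corrcoef(X[:, idx], rowvar=False) if len(keep) > 1 else np.ones((len(keep), len(keep)))
    corr = np.atleast_2d(corr)
    np.fill_diagonal(corr, 1.0)
    mat = pd.DataFrame(corr, index=keep, columns=keep)
    high = [
        (keep[i], keep[j], float(corr[i, j]))
        for i in range(len(keep))
        for j in range(i + 1, len(keep))
        if corr[i, j] > threshold
    ]
    return CorrelationReport(matrix=mat, high_pairs=high, threshold=threshold, constant_genes=constant)


def gene_type_correlation(
    matrix: LabeledExpressionMatrix, genes=None
) -> pd.DataFrame:
    """Point-biserial correlation of each gene with each type's membership.

    Returns a genes x types DataFrame of Pearson r between expression and
    the 0/1 type indicator; constant genes get NaN (undefined) with a
    warning.
    """
    X, gene_list = _values_and_genes(matrix, genes)
    types = matrix.types
    if len(types) < 2:
        raise ValueError("gene-type correlation needs at least 2 types")
    y = matrix.labels.astype(str)
    Xc = X - X.mean(axis=0)
    xs = X.std(axis=0)
    constant = [g for g, s in zip(gene_list, xs) if s == 0.0]
    if constant:
        warnings.warn(f"constant genes have undefined correlation: {constant}", stacklevel=2)
    out = np.full((len(gene_list), len(types)), np.nan)
    n = X.shape[0]
    for tj, t in enumerate(types):
        ind = (y == t).astype(np.float64)
        ic = ind - ind.mean()
        is_ = ind.std()
        if is_ == 0.0:
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            out[:, tj] = (Xc.T @ ic) / n / (xs * is_)
    return pd.DataFrame(out, index=gene_list, columns=types)


def umap_atlas(
    features: LabeledExpressionMatrix | pd.DataFrame | np.ndarray,
    labels=None,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> pd.DataFrame:
    """2-D UMAP embedding of any per-cell feature matrix.

    Returns a DataFrame (cell, x, y, label).  Deterministic under a fixed
    seed; the neighbor count is capped at n_cells - 1 for tiny inputs.
    """
    import umap  # deferred: slow import

    if isinstance(features, LabeledExpressionMatrix):
        X = features.values
        ids = features.cell_ids
        labels = labels if labels is not None else features.labels
    elif isinstance(features, pd.DataFrame):
        X = features.to_numpy(dtype=np.float64)
        ids = [str(i) for i in features.index]
    else:
        X = np.asarray(features, dtype=np.float64)
        ids = [f"cell{i}" for i in range(X.shape[0])]
    n = X.shape[0]
    if n < 3:
        raise ValueError("UMAP atlas needs at least 3 rows")
    if labels is None:
        labels = np.array([""] * n, dtype=object)
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=min(n_neighbors, n - 1),
        min_dist=min_dist,
        random_state=seed,
        init="random" if n < 10 else "spectral",  # spectral needs n > k
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap warns that a fixed seed disables parallelism
        coords = reducer.fit_transform(X)
    return pd.DataFrame(
        {"cell": ids, "x": coords[:, 0], "y": coords[:, 1], "label": np.asarray(labels, dtype=object)}
    )


def plot_atlas(embedding: pd.DataFrame, path, title: str = "") -> None:
    """Scatter the embedding colored by label and save to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for lab, grp in embedding.groupby("label"):
        ax.scatter(grp.x, grp.y, s=4, label=str(lab))
    ax.set_xlabel("UMAP1")
    ax.set_ylabel("UMAP2")
    if title:
        ax.set_title(title)
    ax.legend(markerscale=3, fontsize=7, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
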