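"""Labeled expression matrices: container, MTX/TSV persistence, decile summary.

Matrices are cells-in-rows in memory.  On disk the counts are Matrix Market
(genes x cells, the 10x convention) alongside ``genes.tsv`` (one gene id per
line) and ``cells.tsv`` (cell id <tab> type label), and are transposed on load.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = ["LabeledExpressionMatrix", "DecileSummary", "load_matrix", "decile_expression_summary"]


class FormatError(ValueError):
    """Malformed or inconsistent on-disk matrix data."""


@dataclass
class LabeledExpressionMatrix:
    """A cells x genes expression matrix with one type label per cell.

    ``view`` records whether ``values`` holds raw counts or the log1p-CPM
    normalized transform, so downstream stages can assert which they consume.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    labels: np.ndarray
    view: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.labels = np.asarray(self.labels, dtype=object)
        n_cells, n_genes = self.values.shape
        if len(self.cell_ids) != n_cells:
            raise FormatError(
                f"cell ids: expected {n_cells} rows, found {len(self.cell_ids)}"
            )
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                f"gene ids: expected {n_genes} columns, found {len(self.gene_ids)}"
            )
        if self.labels.shape[0] != n_cells:
            raise FormatError(
                f"labels: expected {n_cells} entries, found {self.labels.shape[0]}"
            )
        for name, ids in (("cell", self.cell_ids), ("gene", self.gene_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise FormatError(f"duplicate {name} id: {i!r}")
                seen.add(i)
        for cid, lab in zip(self.cell_ids, self.labels):
            if lab is None or str(lab) == "":
                raise FormatError(f"empty label for cell {cid!r}")
        if not np.all(np.isfinite(self.values)) or (self.values < 0).any():
            raise FormatError("values must be non-negative and finite")
        if self.view not in ("raw", "normalized"):
            raise FormatError(f"unknown view {self.view!r}")

    # -- basic accessors -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def types(self) -> list[str]:
        return sorted(set(self.labels))

    def class_counts(self) -> dict[str, int]:
        uniq, counts = np.unique(self.labels.astype(str), return_counts=True)
        return dict(zip(uniq.tolist(), counts.tolist()))

    # -- views and subsets -----------------------------------------------
    def normalized(self, target_sum: float = 1e6) -> "LabeledExpressionMatrix":
        """log1p counts-per-million view (identity if already normalized)."""
        if self.view == "normalized":
            return self
        totals = self.values.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        norm = np.log1p(self.values / totals * target_sum)
        return replace(self, values=norm, view="normalized")

    def subset_cells(self, index: np.ndarray) -> "LabeledExpressionMatrix":
        index = np.asarray(index)
        return replace(
            self,
            values=self.values[index],
            cell_ids=[self.cell_ids[i] for i in index],
            labels=self.labels[index],
        )

    def subset_genes(self, genes: list[str]) -> "LabeledExpressionMatrix":
        missing = [g for g in genes if g not in set(self.gene_ids)]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        pos = {g: j for j, g in enumerate(self.gene_ids)}
        cols = [pos[g] for g in genes]
        return replace(self, values=self.values[:, cols], gene_ids=list(genes))

    # -- persistence -----------------------------------------------------
    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(out / "matrix.mtx", sp.coo_matrix(self.values.T))
        (out / "genes.tsv").write_text("".join(f"{g}\n" for g in self.gene_ids))
        with open(out / "cells.tsv", "w") as fh:
            for cid, lab in zip(self.cell_ids, self.labels):
                fh.write(f"{cid}\t{lab}\n")
        return out


def load_matrix(
    matrix_path: str | Path,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
    view: str = "raw",
) -> LabeledExpressionMatrix:
    """Load an MTX + genes.tsv + cells.tsv directory or explicit triple.

    ``matrix_path`` may be the directory produced by
    :meth:`LabeledExpressionMatrix.save`, in which case the companion file
    paths are inferred.
    """
    mpath = Path(matrix_path)
    if mpath.is_dir():
        genes_path = genes_path or mpath / "genes.tsv"
        cells_path = cells_path or mpath / "cells.tsv"
        mpath = mpath / "matrix.mtx"
    if genes_path is None or cells_path is None:
        raise FormatError("genes_path and cells_path are required for a bare .mtx path")
    for p in (mpath, Path(genes_path), Path(cells_path)):
        if not p.exists():
            raise FileNotFoundError(f"missing input file: {p}")

    values = np.asarray(scipy.io.mmread(mpath).todense()).T  # stored genes x cells
    gene_ids = Path(genes_path).read_text().splitlines()
    cells = pd.read_csv(cells_path, sep="\t", header=None, dtype=str, keep_default_na=False)
    if cells.shape[1] < 2:
        raise FormatError("cells.tsv must have two tab-separated columns: cell id, label")
    cell_ids = cells.iloc[:, 0].tolist()
    labels = cells.iloc[:, 1].to_numpy(dtype=object)
    if values.shape != (len(cell_ids), len(gene_ids)):
        raise FormatError(
            f"dimension mismatch: matrix is {values.shape[0]} cells x "
            f"{values.shape[1]} genes but found {len(cell_ids)} cell ids and "
            f"{len(gene_ids)} gene ids"
        )
    return LabeledExpressionMatrix(
        values=values, cell_ids=cell_ids, gene_ids=gene_ids, labels=labels, view=view
    )


@dataclass
class DecileSummary:
    """Per (cell type, decile) mean expression of genes in that decile.

    Genes are ranked per type by their mean expression (descending, ties by
    gene id) and split into 10 contiguous near-equal bins; decile 1 holds the
    most-expressed genes.  ``table`` has columns
    ``[cell_type, decile, n_genes, mean_expression]``.
    """

    table: pd.DataFrame

    def top_decile_share(self) -> pd.Series:
        """Fraction of a type's total expression carried by its top decile."""
        t = self.table
        tot = t.assign(mass=t.n_genes * t.mean_expression).groupby("cell_type")["mass"].sum()
        top = t[t.decile == 1].set_index("cell_type")
        return (top.n_genes * top.mean_expression) / tot

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def decile_expression_summary(matrix: LabeledExpressionMatrix) -> DecileSummary:
    """Rank each type's genes by mean expression and average them per decile.

    The weighted mean of the decile means (weights = bin sizes) equals the
    type's overall per-gene mean expression exactly, which serves as a
    conservation check on the binning.
    """
    n_genes = matrix.n_genes
    if n_genes < 10:
        raise ValueError(f"need at least 10 genes for a decile summary, got {n_genes}")
    base, rem = divmod(n_genes, 10)
    sizes = [base + (1 if b < rem else 0) for b in range(10)]

    gene_arr = np.array(matrix.gene_ids)
    rows = []
    for t in matrix.types:
        means = matrix.values[matrix.labels == t].mean(axis=0)
        # descending by mean, ties by gene id (lexsort: last key is primary)
        order = np.lexsort((gene_arr, -means))
        start = 0
        for b, size in enumerate(sizes, start=1):
            chunk = means[order[start : start + size]]
            rows.append((t, b, size, float(chunk.mean())))
            start += size
    return DecileSummary(
        table=pd.DataFrame(rows, columns=["cell_type", "decile", "n_genes", "mean_expression"])
    )
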