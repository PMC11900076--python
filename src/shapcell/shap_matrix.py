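"""SHAP-value-matrix reconstruction, cell-type importance, key genes.

Local accuracy (base + sum of attributions = predicted probability) means a
gene subset's attribution columns can simply be sliced out of the full
tensor: the slice plus the excluded genes' attributions still reconstructs
every prediction exactly, which is audited here.  The resulting matrix —
rows: correctly classified test cells, columns: selected genes, entry: the
attribution of that gene to the cell's own (true = predicted) class —
is the object everything downstream consumes:

* cell-type importance = per-cell mean of the summed positive entries,
* key genes per type  = genes ranked by mean positive entry over the
  type's rows,
* a classifier retrained on the matrix itself quantifies how much of the
  label information the selected attributions retain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from sklearn.model_selection import train_test_split

from .classifier import SearchSpec, TrainedModel, evaluate_arrays, tune_and_train_arrays
from .shap_engine import AttributionTensor

__all__ = [
    "ShapMatrix",
    "ImportanceRanking",
    "reconstruct_shap_matrix",
    "cell_type_importance",
    "key_genes_per_type",
    "retrain_on_shap_matrix",
]


@dataclass
class ShapMatrix:
    """Selected-gene attribution matrix of correctly classified test cells."""

    values: pd.DataFrame  # rows: cells, columns: selected genes
    labels: np.ndarray  # per-row true (= predicted) cell type
    max_additivity_gap: float  # audit: |row sum + base + excluded phi - proba|

    @property
    def n_cells(self) -> int:
        return len(self.values)

    def rows_of(self, cell_type: str) -> pd.DataFrame:
        return self.values[self.labels == cell_type]

    def types(self) -> list[str]:
        return sorted(set(self.labels))

    def to_csv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "cell_type", self.labels)
        out.to_csv(path)


@dataclass
class ImportanceRanking:
    """Cell types ordered by per-cell mean positive attribution mass."""

    scores: pd.Series  # type -> score, descending; ties broken by type name
    excluded: dict[str, str]  # type -> reason it was excluded

    def top(self) -> str:
        return str(self.scores.index[0])


def reconstruct_shap_matrix(
    tensor: AttributionTensor,
    predictions: np.ndarray,
    labels: np.ndarray,
    gene_set,
    tol: float = 1e-6,
) -> ShapMatrix:
    """Slice the selected genes' attributions for correctly classified cells.

    Audits additivity row by row: selected-gene sum + base + excluded-gene
    sum must reproduce the predicted probability of the cell's class within
    ``tol``.
    """
    gene_set = [g for g in tensor.gene_ids if g in set(gene_set)]
    if not gene_set:
        raise ValueError("gene_set is empty or disjoint from the tensor's genes")
    predictions = np.asarray(predictions).astype(str)
    labels = np.asarray(labels).astype(str)
    correct = np.flatnonzero(predictions == labels)
    col_idx = [tensor.gene_ids.index(g) for g in gene_set]
    excluded_idx = [j for j in range(len(tensor.gene_ids)) if j not in set(col_idx)]

    rows, row_labels, row_ids = [], [], []
    max_gap = 0.0
    for i in correct:
        ci = tensor.class_index(labels[i])
        row = tensor.phi[i, col_idx, ci]
        resid = tensor.phi[i, excluded_idx, ci].sum() if excluded_idx else 0.0
        gap = abs(row.sum() + resid + tensor.base[ci] - tensor.proba[i, ci])
        max_gap = max(max_gap, gap)
        rows.append(row)
        row_labels.append(labels[i])
        row_ids.append(tensor.cell_ids[i])
    if max_gap > tol:
        raise AssertionError(
            f"additivity audit failed: max gap {max_gap:.3e} exceeds {tol:.0e}"
        )
    values = pd.DataFrame(np.vstack(rows) if rows else np.empty((0, len(gene_set))),
                          index=row_ids, columns=gene_set)
    return ShapMatrix(
        values=values,
        labels=np.array(row_labels, dtype=object),
        max_additivity_gap=max_gap,
    )


def cell_type_importance(sm: ShapMatrix, min_cells: int = 5) -> ImportanceRanking:
    """Rank types by the per-cell mean of their summed positive attributions.

    score(c) = (1/n_c) * sum over c's rows of sum_g max(entry, 0).
    The per-cell mean makes the score invariant to a type's abundance, so a
    rare type with a strong transcriptional signature can outrank a numerous
    one.  Types with fewer than ``min_cells`` correctly classified cells are
    excluded as low-quality (too few rows to trust the mean).
    """
    if sm.n_cells == 0:
        raise ValueError("SHAP matrix has no rows")
    pos = np.clip(sm.values.to_numpy(), 0.0, None).sum(axis=1)
    scores, excluded = {}, {}
    for t in sm.types():
        mask = sm.labels == t
        n_t = int(mask.sum())
        if n_t < min_cells:
            excluded[t] = f"only {n_t} correctly classified cells (min_cells={min_cells})"
            continue
        scores[t] = float(pos[mask].mean())
    if not scores:
        raise ValueError("every type was excluded by the min_cells filter")
    if all(v == 0.0 for v in scores.values()):
        warnings.warn("all positive-attribution scores are 0; ranking is by name only", stacklevel=2)
    ordered = pd.Series(scores).sort_index()
    ordered = ordered.sort_values(ascending=False, kind="stable")
    return ImportanceRanking(scores=ordered, excluded=excluded)


def key_genes_per_type(sm: ShapMatrix, k: int = 20) -> dict[str, pd.DataFrame]:
    """Per type: top-k genes by mean positive entry over the type's rows.

    Returns type -> DataFrame (gene, score) sorted descending, ties by gene
    id.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    genes = np.array(sm.values.columns)
    out: dict[str, pd.DataFrame] = {}
    for t in sm.types():
        block = np.clip(sm.rows_of(t).to_numpy(), 0.0, None)
        score = block.mean(axis=0)
        order = np.lexsort((genes, -score))[: min(k, genes.size)]
        out[t] = pd.DataFrame({"gene": genes[order], "score": score[order]}).reset_index(drop=True)
    return out


def retrain_on_shap_matrix(
    sm: ShapMatrix,
    split_seed: int = 42,
    spec: SearchSpec | None = None,
    ratio: float = 0.7,
) -> tuple[TrainedModel, float]:
    """Train a classifier on the attribution matrix itself; return test accuracy.

    Rows are samples, selected genes' attributions are features, and the row
    labels are the targets.  Types with fewer than 2 * cv_folds rows cannot
    support the stratified split plus cross-validation and are dropped with a
    warning.
    """
    spec = spec or SearchSpec()
    min_rows = 2 * spec.cv_folds
    keep_types = [t for t in sm.types() if (sm.labels == t).sum() >= min_rows]
    dropped = sorted(set(sm.types()) - set(keep_types))
    if dropped:
        warnings.warn(
            f"types with fewer than {min_rows} rows dropped from retraining: {dropped}",
            stacklevel=2,
        )
    if len(keep_types) < 2:
        raise ValueError("need at least 2 types with enough rows to retrain")
    mask = np.isin(sm.labels, keep_types)
    X = sm.values.to_numpy()[mask].astype(np.float64)
    y = sm.labels[mask].astype(str)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=ratio, random_state=split_seed, stratify=y
    )
    model = tune_and_train_arrays(X_tr, y_tr, spec)
    report = evaluate_arrays(model, X_te, y_te)
    return model, report.accuracy
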