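"""Per-type top-N attribution gene lists, their set partition, and retraining.

From each type's block of correctly classified cells, genes are scored by
their mean attribution to that type and the top N are kept.  Across the K
lists, genes fall into three named sets:

* co-expressed      — present in every list,
* specific          — present in exactly one list,
* union_sel         — co-expressed plus specific (the working gene set),
* all_distinct      — the distinct union of all lists.

Genes appearing in 2..K-1 lists belong to all_distinct only.  Sub-models are
then retrained on each set over the same train/test cell split as the parent
model, so accuracy differences reflect the gene set alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifier import EvaluationReport, SearchSpec, TrainedModel, evaluate, tune_and_train
from .io import LabeledExpressionMatrix
from .shap_engine import CorrectClassAttributions

__all__ = ["PerTypeTopGenes", "GenePartition", "per_type_top_genes", "partition_gene_sets", "retrain_on_subset"]


@dataclass
class PerTypeTopGenes:
    """Cell type -> ordered top-N gene list (by mean attribution, descending)."""

    lists: dict[str, list[str]]
    n: int

    def __getitem__(self, t: str) -> list[str]:
        return self.lists[t]


@dataclass
class GenePartition:
    """Set partition of the per-type lists (see module docstring)."""

    co_expressed: set[str]
    specific: set[str]
    union_sel: set[str]
    all_distinct: set[str]
    membership_counts: pd.Series  # gene -> number of lists containing it

    def summary(self) -> dict[str, int]:
        return {
            "co_expressed": len(self.co_expressed),
            "specific": len(self.specific),
            "union_sel": len(self.union_sel),
            "all_distinct": len(self.all_distinct),
        }

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("co_expressed", "specific", "union_sel", "all_distinct"):
            genes = sorted(getattr(self, name))
            (out / f"{name}.txt").write_text("".join(g + "\n" for g in genes))
        self.membership_counts.rename("n_lists").rename_axis("gene").to_csv(
            out / "membership.csv"
        )


def per_type_top_genes(correct: CorrectClassAttributions, n: int = 500) -> PerTypeTopGenes:
    """Top-N genes per type by mean attribution over its correct cells.

    The mean (not the sum) is used so types with few cells are scored on the
    same footing as abundant ones.  Ties break by gene id; empty class blocks
    are skipped with a warning.
    """
    lists: dict[str, list[str]] = {}
    for c, block in correct.blocks.items():
        if block.empty:
            warnings.warn(f"class {c!r} has no correctly classified cells; skipped", stacklevel=2)
            continue
        scores = block.mean(axis=0)
        genes = scores.index.to_numpy()
        order = np.lexsort((genes, -scores.to_numpy()))
        lists[c] = [str(g) for g in genes[order[: min(n, genes.size)]]]
    return PerTypeTopGenes(lists=lists, n=n)


def partition_gene_sets(lists: PerTypeTopGenes | dict[str, list[str]]) -> GenePartition:
    """Partition the per-type lists into co-expressed / specific / union sets."""
    d = lists.lists if isinstance(lists, PerTypeTopGenes) else lists
    if len(d) < 2:
        raise ValueError("partition needs at least 2 per-type lists")
    counts: dict[str, int] = {}
    for genes in d.values():
        for g in set(genes):
            counts[g] = counts.get(g, 0) + 1
    k = len(d)
    co = {g for g, c in counts.items() if c == k}
    specific = {g for g, c in counts.items() if c == 1}
    return GenePartition(
        co_expressed=co,
        specific=specific,
        union_sel=co | specific,
        all_distinct=set(counts),
        membership_counts=pd.Series(counts).sort_index(),
    )


def retrain_on_subset(
    train: LabeledExpressionMatrix,
    test: LabeledExpressionMatrix,
    gene_set,
    spec: SearchSpec | None = None,
) -> tuple[TrainedModel, EvaluationReport]:
    """Re-run the classifier pipeline with columns restricted to ``gene_set``.

    The caller passes the parent model's train/test split so the comparison
    isolates the gene subset.  Gene order within the matrix is preserved so a
    subset equal to all genes reproduces the parent model exactly.
    """
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("gene_set is empty")
    keep = [g for g in train.gene_ids if g in gene_set]
    missing = gene_set - set(train.gene_ids)
    if missing:
        raise KeyError(f"genes not in matrix: {sorted(missing)[:5]}")
    model = tune_and_train(train.subset_genes(keep), spec)
    report = evaluate(model, test.subset_genes(keep))
    return model, report
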