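"""Interventional Shapley attribution for random-forest cell-type classifiers.

For a forest f and a background set Z, the attribution of gene j to the
predicted probability of class c for a cell x is the exact Shapley value of
j in the coalition game

    v(S) = E_{z ~ Z}[ f_c(x_S, z_{S-bar}) ],

i.e. genes outside the coalition are imputed from a background cell
(interventional conditioning).  Because v is linear over trees and over
background cells, the game decomposes into one tiny game per (tree, z, leaf):
along the path to a leaf each gene either must be taken from x (x satisfies
the split, z does not), must be taken from z (the reverse), is free (both
satisfy), or kills the leaf (neither).  The Shapley value of such an
AND-game has a closed form in the counts a = |must-be-x| and b = |must-be-z|:

    phi_j = +(a-1)! b! / (a+b)! * leaf_value   for j in the x-set,
    phi_j = -a! (b-1)! / (a+b)! * leaf_value   for j in the z-set,

and 0 for free genes.  Summing over leaves, trees and background cells gives
the exact interventional Shapley value with no sampling error, which is what
lets the brute-force coalition enumeration in :func:`brute_force_shapley`
serve as an independent oracle.

Exactness buys the usual Shapley axioms for free: local accuracy
(base + sum(phi) equals the predicted probability), the dummy property
(a gene no tree splits on gets exactly 0), and symmetry.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit, prange

from .classifier import TrainedModel
from .io import LabeledExpressionMatrix

__all__ = [
    "AttributionTensor",
    "attribute",
    "brute_force_shapley",
    "filter_correct",
    "global_gene_ranking",
    "stratified_background",
]


# --------------------------------------------------------------------------
# forest flattening
# --------------------------------------------------------------------------

def _flatten_forest(model: TrainedModel):
    """Concatenate per-tree node arrays into flat arrays + per-tree roots."""
    feats, thrs, lefts, rights, values, roots = [], [], [], [], [], []
    offset = 0
    max_depth = 0
    for est in model.estimator.estimators_:
        t = est.tree_
        n = t.node_count
        roots.append(offset)
        feats.append(t.feature.astype(np.int64))
        thrs.append(t.threshold.astype(np.float64))
        left = t.children_left.astype(np.int64)
        right = t.children_right.astype(np.int64)
        lefts.append(np.where(left >= 0, left + offset, -1))
        rights.append(np.where(right >= 0, right + offset, -1))
        v = t.value[:, 0, :].astype(np.float64)
        v = v / v.sum(axis=1, keepdims=True)
        values.append(v)
        offset += n
        max_depth = max(max_depth, int(t.max_depth))
    return (
        np.concatenate(feats),
        np.concatenate(thrs),
        np.concatenate(lefts),
        np.concatenate(rights),
        np.concatenate(values),
        np.asarray(roots, dtype=np.int64),
        max_depth,
    )


@njit(cache=True)
def _pair_shap(x, z, feature, threshold, left, right, value, root, fact,
               phi, stack_node, stack_na, stack_pf, stack_pp, path_feat, path_pol):
    """Accumulate the exact Shapley values of one (cell, background, tree)."""
    C = value.shape[1]
    stack_node[0] = root
    stack_na[0] = 0
    stack_pf[0] = -1
    stack_pp[0] = 0
    sp = 1
    while sp > 0:
        sp -= 1
        node = stack_node[sp]
        na = stack_na[sp]
        pf = stack_pf[sp]
        if pf >= 0:
            path_feat[na - 1] = pf
            path_pol[na - 1] = stack_pp[sp]
        while True:
            l = left[node]
            if l < 0:  # leaf
                if na > 0:
                    a = 0
                    b = 0
                    for i in range(na):
                        if path_pol[i] > 0:
                            a += 1
                        else:
                            b += 1
                    wa = fact[a - 1] * fact[b] / fact[a + b] if a > 0 else 0.0
                    wb = fact[a] * fact[b - 1] / fact[a + b] if b > 0 else 0.0
                    for i in range(na):
                        g = path_feat[i]
                        if path_pol[i] > 0:
                            for c in range(C):
                                phi[g, c] += wa * value[node, c]
                        else:
                            for c in range(C):
                                phi[g, c] -= wb * value[node, c]
                break
            f = feature[node]
            t = threshold[node]
            r = right[node]
            cx = l if x[f] <= t else r
            cz = l if z[f] <= t else r
            if cx == cz:  # both go the same way: no constraint on f
                node = cx
                continue
            pol = 0
            for i in range(na):  # f already constrained on this path?
                if path_feat[i] == f:
                    pol = path_pol[i]
                    break
            if pol > 0:
                node = cx
                continue
            if pol < 0:
                node = cz
                continue
            # genuine divergence: branch both ways
            stack_node[sp] = cz
            stack_na[sp] = na + 1
            stack_pf[sp] = f
            stack_pp[sp] = -1
            sp += 1
            path_feat[na] = f
            path_pol[na] = 1
            na += 1
            node = cx


@njit(parallel=True, cache=True)
def _batch_shap(X, Z, feature, threshold, left, right, value, roots, fact, max_depth):
    n, d = X.shape
    C = value.shape[1]
    B = Z.shape[0]
    T = roots.shape[0]
    out = np.zeros((n, d, C))
    cap = max_depth + 8
    for i in prange(n):
        phi = np.zeros((d, C))
        stack_node = np.empty(cap, np.int64)
        stack_na = np.empty(cap, np.int64)
        stack_pf = np.empty(cap, np.int64)
        stack_pp = np.empty(cap, np.int64)
        path_feat = np.empty(cap, np.int64)
        path_pol = np.empty(cap, np.int64)
        for bi in range(B):
            for ti in range(T):
                _pair_shap(
                    X[i], Z[bi], feature, threshold, left, right, value,
                    roots[ti], fact, phi,
                    stack_node, stack_na, stack_pf, stack_pp, path_feat, path_pol,
                )
        out[i] = phi / (B * T)
    return out


# --------------------------------------------------------------------------
# public API
# --------------------------------------------------------------------------

@dataclass
class AttributionTensor:
    """Per-cell, per-gene, per-class Shapley values over a background set.

    ``phi[i, j, c] `` attributes gene j's contribution to cell i's predicted
    probability of class c relative to ``base[c]``, the mean predicted
    probability over the background cells.  ``max_additivity_gap`` is the
    largest observed |base + sum_j phi - predicted probability| and should be
    at float rounding scale.
    """

    phi: np.ndarray  # cells x genes x classes
    base: np.ndarray  # classes
    classes: list[str]
    cell_ids: list[str]
    gene_ids: list[str]
    background_ids: list[str]
    proba: np.ndarray  # cells x classes, the model's predictions
    max_additivity_gap: float

    @property
    def n_cells(self) -> int:
        return self.phi.shape[0]

    def class_index(self, c: str) -> int:
        return self.classes.index(str(c))

    def to_long(self) -> pd.DataFrame:
        """Long-format (cell, gene, class, phi) table."""
        n, d, C = self.phi.shape
        return pd.DataFrame(
            {
                "cell": np.repeat(self.cell_ids, d * C),
                "gene": np.tile(np.repeat(self.gene_ids, C), n),
                "class": np.tile(self.classes, n * d),
                "phi": self.phi.ravel(),
            }
        )


def stratified_background(
    matrix: LabeledExpressionMatrix, n: int = 128, seed: int = 0
) -> LabeledExpressionMatrix:
    """Sample up to ``n`` cells, allocated across types proportionally with at
    least one per type, as the attribution background."""
    rng = np.random.default_rng(seed)
    y = matrix.labels.astype(str)
    types = sorted(set(y))
    n = min(n, matrix.n_cells)
    counts = {t: int((y == t).sum()) for t in types}
    alloc = {t: max(1, round(n * counts[t] / matrix.n_cells)) for t in types}
    while sum(alloc.values()) > n:
        big = max(alloc, key=lambda t: (alloc[t], t))
        alloc[big] -= 1
    chosen = []
    for t in types:
        idx = np.flatnonzero(y == t)
        take = min(alloc[t], idx.size)
        if take > 0:
            chosen.append(rng.choice(idx, size=take, replace=False))
    sel = np.sort(np.concatenate(chosen))
    return matrix.subset_cells(sel)


def _as_values(obj) -> tuple[np.ndarray, list[str] | None, list[str] | None]:
    if isinstance(obj, LabeledExpressionMatrix):
        return np.ascontiguousarray(obj.values), obj.cell_ids, obj.gene_ids
    arr = np.ascontiguousarray(np.asarray(obj, dtype=np.float64))
    return arr, None, None


def attribute(
    model: TrainedModel,
    cells: LabeledExpressionMatrix | np.ndarray,
    background: LabeledExpressionMatrix | np.ndarray,
) -> AttributionTensor:
    """Exact interventional Shapley values of every gene, cell and class."""
    X, cell_ids, genes_x = _as_values(cells)
    Z, bg_ids, genes_z = _as_values(background)
    if Z.shape[0] == 0:
        raise ValueError("background set is empty")
    if X.shape[1] != Z.shape[1]:
        raise ValueError(
            f"cells and background disagree on gene space: {X.shape[1]} vs {Z.shape[1]}"
        )
    if genes_x is not None and genes_z is not None and genes_x != genes_z:
        raise ValueError("cells and background have different gene_ids")
    n_model_feats = model.estimator.n_features_in_
    if X.shape[1] != n_model_feats:
        raise ValueError(
            f"model was trained on {n_model_feats} genes, got {X.shape[1]}"
        )
    feature, threshold, left, right, value, roots, max_depth = _flatten_forest(model)
    fact = np.array([math.factorial(i) for i in range(max_depth + 3)], dtype=np.float64)
    phi = _batch_shap(X, Z, feature, threshold, left, right, value, roots, fact, max_depth)

    base = model.predict_proba(Z).mean(axis=0)
    proba = model.predict_proba(X)
    gap = float(np.abs(base[None, :] + phi.sum(axis=1) - proba).max())
    classes = [str(c) for c in model.classes_]
    return AttributionTensor(
        phi=phi,
        base=base,
        classes=classes,
        cell_ids=cell_ids or [f"cell{i}" for i in range(X.shape[0])],
        gene_ids=genes_x or [f"g{j}" for j in range(X.shape[1])],
        background_ids=bg_ids or [f"bg{i}" for i in range(Z.shape[0])],
        proba=proba,
        max_additivity_gap=gap,
    )


def brute_force_shapley(
    model: TrainedModel,
    cell: np.ndarray,
    background: LabeledExpressionMatrix | np.ndarray,
    max_genes: int = 12,
) -> np.ndarray:
    """Exact Shapley values by exhaustive coalition enumeration (oracle).

    Evaluates v(S) = mean_z f(x_S, z_{S-bar}) for all 2^d coalitions and
    applies the factorial-weighted Shapley sum, independently of the
    tree-decomposition path used by :func:`attribute`.  Refuses more than
    ``max_genes`` genes (cost 2^d model evaluations).
    Returns a genes x classes array.
    """
    Z, _, _ = _as_values(background)
    x = np.asarray(cell, dtype=np.float64).ravel()
    d = x.size
    if d > max_genes:
        raise ValueError(
            f"brute force enumerates 2^d coalitions; d={d} exceeds the bound {max_genes}"
        )
    B = Z.shape[0]
    n_masks = 1 << d
    composites = np.empty((n_masks * B, d))
    for mask in range(n_masks):
        block = Z.copy()
        for j in range(d):
            if mask >> j & 1:
                block[:, j] = x[j]
        composites[mask * B : (mask + 1) * B] = block
    v = model.predict_proba(composites).reshape(n_masks, B, -1).mean(axis=1)

    C = v.shape[1]
    phi = np.zeros((d, C))
    fact = [math.factorial(i) for i in range(d + 1)]
    for j in range(d):
        for subset in itertools.chain.from_iterable(
            itertools.combinations([i for i in range(d) if i != j], r) for r in range(d)
        ):
            s = len(subset)
            mask = sum(1 << i for i in subset)
            w = fact[s] * fact[d - s - 1] / fact[d]
            phi[j] += w * (v[mask | (1 << j)] - v[mask])
    return phi


@dataclass
class CorrectClassAttributions:
    """Per-class attribution blocks of correctly classified cells.

    ``blocks[c]`` is a cells x genes DataFrame of phi values for class c,
    restricted to cells whose prediction and label both equal c.  Classes
    with no correctly classified cell keep an empty block and are listed in
    ``empty_classes``.
    """

    blocks: dict[str, pd.DataFrame]
    empty_classes: list[str]

    @property
    def n_cells(self) -> int:
        return sum(len(b) for b in self.blocks.values())

    def to_long(self) -> pd.DataFrame:
        """All blocks concatenated into one table with a class column."""
        parts = []
        for c, block in self.blocks.items():
            part = block.copy()
            part.insert(0, "class", c)
            parts.append(part)
        return pd.concat(parts, axis=0)


def filter_correct(
    tensor: AttributionTensor,
    predictions: np.ndarray,
    labels: np.ndarray,
) -> CorrectClassAttributions:
    """Keep, per class c, the attribution rows of cells predicted and labeled c."""
    predictions = np.asarray(predictions).astype(str)
    labels = np.asarray(labels).astype(str)
    if predictions.shape[0] != tensor.n_cells or labels.shape[0] != tensor.n_cells:
        raise ValueError("predictions/labels are not aligned with the tensor's cells")
    blocks, empty = {}, []
    for ci, c in enumerate(tensor.classes):
        keep = np.flatnonzero((predictions == c) & (labels == c))
        block = pd.DataFrame(
            tensor.phi[keep, :, ci],
            index=[tensor.cell_ids[i] for i in keep],
            columns=tensor.gene_ids,
        )
        blocks[c] = block
        if keep.size == 0:
            empty.append(c)
    if empty:
        warnings.warn(f"no correctly classified cells for classes: {empty}", stacklevel=2)
    return CorrectClassAttributions(blocks=blocks, empty_classes=empty)


def global_gene_ranking(tensor: AttributionTensor, k: int = 20) -> pd.DataFrame:
    """Top-k genes by mean |phi| over cells, summed over classes.

    Returns a DataFrame (gene, importance) sorted descending, ties broken by
    gene id.  If k exceeds the gene count the full ranking is returned with
    a warning.
    """
    if tensor.n_cells == 0:
        raise ValueError("attribution tensor has no cells")
    imp = np.abs(tensor.phi).mean(axis=0).sum(axis=1)  # genes
    genes = np.array(tensor.gene_ids)
    order = np.lexsort((genes, -imp))
    if k > genes.size:
        warnings.warn(
            f"k={k} exceeds the {genes.size} available genes; returning all",
            stacklevel=2,
        )
        k = genes.size
    sel = order[:k]
    return pd.DataFrame({"gene": genes[sel], "importance": imp[sel]}).reset_index(drop=True)
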