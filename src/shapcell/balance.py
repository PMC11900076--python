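"""Class-balance ladder: one resampling scheme per cell type, plus RAW.

For K cell types the ladder holds K + 1 schemes.  Scheme "RAW" leaves the
data untouched; the scheme anchored at type T equalizes every class to T's
count — classes above the target are randomly under-sampled without
replacement, classes below are over-sampled with SMOTE-style interpolation
(a synthetic cell is x + u * (x_nn - x) with u ~ Uniform(0,1) and x_nn one
of the k nearest same-class neighbors).  One model is trained per scheme and
the ladder report compares their cross-validation (BVS) and test (ABP)
scores; the working model is the best balanced scheme by BVS, with RAW
reported alongside for reference.

Balancing is applied to the training split only, after the train/test split,
so the test set is never resampled and synthetic cells cannot leak across
the split.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .classifier import EvaluationReport, SearchSpec, TrainedModel, evaluate, tune_and_train
from .io import LabeledExpressionMatrix

__all__ = ["RAW", "Action", "BalancingScheme", "build_scheme", "apply_scheme", "run_ladder", "LadderReport"]

RAW = "RAW"


class Action(str, Enum):
    UNDERSAMPLE = "undersample"
    OVERSAMPLE = "oversample"
    KEEP = "keep"


@dataclass(frozen=True)
class BalancingScheme:
    """Resampling plan anchored at one type's count (or RAW = no-op)."""

    target_type: str
    target_count: int | None
    actions: dict[str, Action]

    @property
    def is_raw(self) -> bool:
        return self.target_type == RAW


def build_scheme(class_counts: dict[str, int], target_type: str) -> BalancingScheme:
    """Derive the under/over/keep action per class from the anchor's count."""
    if target_type == RAW:
        return BalancingScheme(
            target_type=RAW,
            target_count=None,
            actions={c: Action.KEEP for c in class_counts},
        )
    if target_type not in class_counts:
        raise KeyError(
            f"unknown target type {target_type!r}; valid types: {sorted(class_counts)}"
        )
    target = int(class_counts[target_type])
    actions = {}
    for c, n in class_counts.items():
        if n > target:
            actions[c] = Action.UNDERSAMPLE
        elif n < target:
            actions[c] = Action.OVERSAMPLE
        else:
            actions[c] = Action.KEEP
    return BalancingScheme(target_type=target_type, target_count=target, actions=actions)


def _smote(
    X: np.ndarray, n_new: int, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Interpolated synthetic samples within one class.

    k is capped at n-1 neighbors; a singleton class falls back to
    duplication (there is nothing to interpolate toward).
    """
    n = X.shape[0]
    if n == 1:
        return np.repeat(X, n_new, axis=0)
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, neigh = nn.kneighbors(X)  # column 0 is the point itself
    base = rng.integers(0, n, size=n_new)
    pick = rng.integers(1, k + 1, size=n_new)
    u = rng.random(size=(n_new, 1))
    anchors = X[base]
    partners = X[neigh[base, pick]]
    return anchors + u * (partners - anchors)


def apply_scheme(
    train: LabeledExpressionMatrix,
    scheme: BalancingScheme,
    seed: int = 42,
    smote_k: int = 5,
) -> LabeledExpressionMatrix:
    """Resample the training matrix so every class hits the scheme's target.

    Deterministic under a fixed seed.  Synthetic cells get ids of the form
    ``smote:<type>:<i>``.
    """
    if scheme.is_raw:
        return train
    y = train.labels.astype(str)
    counts = train.class_counts()
    missing = [c for c in scheme.actions if c not in counts]
    if missing:
        raise ValueError(f"classes absent from training data: {missing}")
    rng = np.random.default_rng(seed)
    target = scheme.target_count
    blocks, ids, labels = [], [], []
    for c in sorted(scheme.actions):
        idx = np.flatnonzero(y == c)
        Xc = train.values[idx]
        if counts[c] > target:
            sel = rng.choice(idx.size, size=target, replace=False)
            sel.sort()
            blocks.append(Xc[sel])
            ids.extend(train.cell_ids[idx[i]] for i in sel)
        elif counts[c] < target:
            synth = _smote(Xc, target - counts[c], smote_k, rng)
            blocks.append(np.vstack([Xc, synth]))
            ids.extend(train.cell_ids[i] for i in idx)
            ids.extend(f"smote:{c}:{i}" for i in range(synth.shape[0]))
        else:
            blocks.append(Xc)
            ids.extend(train.cell_ids[i] for i in idx)
        labels.extend([c] * target)
    return replace(
        train,
        values=np.vstack(blocks),
        cell_ids=ids,
        labels=np.array(labels, dtype=object),
    )


@dataclass
class LadderReport:
    """One row per scheme: input size, BVS, ABP; per-class metrics attached."""

    table: pd.DataFrame  # columns: scheme, total_cells, bvs, abp
    per_class: dict[str, pd.DataFrame]
    selected: str

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def run_ladder(
    train: LabeledExpressionMatrix,
    test: LabeledExpressionMatrix,
    spec: SearchSpec | None = None,
    seed: int = 42,
    smote_k: int = 5,
) -> tuple[LadderReport, BalancingScheme, dict[str, TrainedModel]]:
    """Train one model per scheme (RAW + one per type) and pick the working one.

    Selection rule: highest BVS among the balanced schemes; RAW is evaluated
    and reported but excluded from selection, since the balanced models are
    the ones whose per-class recall on rare types the ladder exists to
    improve.  Ties break toward the smaller resampled training set, then
    lexicographic scheme name.
    """
    spec = spec or SearchSpec()
    counts = train.class_counts()
    if len(counts) < 2:
        raise ValueError("ladder needs at least 2 classes")
    schemes = [build_scheme(counts, RAW)] + [
        build_scheme(counts, t) for t in sorted(counts)
    ]
    rows, per_class, models = [], {}, {}
    for scheme in schemes:
        name = scheme.target_type
        try:
            balanced = apply_scheme(train, scheme, seed=seed, smote_k=smote_k)
            model = tune_and_train(balanced, spec)
            report: EvaluationReport = evaluate(model, test)
        except Exception as err:  # noqa: BLE001 - re-raise with scheme context
            raise RuntimeError(f"scheme {name!r} failed: {err}") from err
        models[name] = model
        per_class[name] = report.per_class
        rows.append((name, balanced.n_cells, model.bvs, report.accuracy))
    table = pd.DataFrame(rows, columns=["scheme", "total_cells", "bvs", "abp"])

    balanced_rows = table[table.scheme != RAW]
    best = balanced_rows.sort_values(
        ["bvs", "total_cells", "scheme"], ascending=[False, True, True]
    ).iloc[0]
    selected = next(s for s in schemes if s.target_type == best.scheme)
    return LadderReport(table=table, per_class=per_class, selected=best.scheme), selected, models


def run_ladder_balance_first(
    matrix: LabeledExpressionMatrix,
    ratio: float = 0.7,
    split_seed: int = 42,
    spec: SearchSpec | None = None,
    seed: int = 42,
    smote_k: int = 5,
) -> tuple[LadderReport, BalancingScheme, dict[str, TrainedModel]]:
    """Alternative stage order: balance the whole matrix, then split.

    Provided for comparison with the default (split, then balance the
    training half).  Balancing before the split lets synthetic cells
    interpolated from test cells appear in training, so scores from this
    order are optimistic; the default order is the leakage-safe one.
    """
    from .classifier import split_train_test

    spec = spec or SearchSpec()
    counts = matrix.class_counts()
    if len(counts) < 2:
        raise ValueError("ladder needs at least 2 classes")
    schemes = [build_scheme(counts, RAW)] + [build_scheme(counts, t) for t in sorted(counts)]
    rows, per_class, models = [], {}, {}
    for scheme in schemes:
        name = scheme.target_type
        try:
            balanced = apply_scheme(matrix, scheme, seed=seed, smote_k=smote_k)
            train, test = split_train_test(balanced, ratio=ratio, seed=split_seed)
            model = tune_and_train(train, spec)
            report = evaluate(model, test)
        except Exception as err:  # noqa: BLE001
            raise RuntimeError(f"scheme {name!r} failed: {err}") from err
        models[name] = model
        per_class[name] = report.per_class
        rows.append((name, balanced.n_cells, model.bvs, report.accuracy))
    table = pd.DataFrame(rows, columns=["scheme", "total_cells", "bvs", "abp"])
    best = table[table.scheme != RAW].sort_values(
        ["bvs", "total_cells", "scheme"], ascending=[False, True, True]
    ).iloc[0]
    selected = next(s for s in schemes if s.target_type == best.scheme)
    return LadderReport(table=table, per_class=per_class, selected=best.scheme), selected, models
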