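"""End-to-end orchestration: simulate -> decile -> split -> ladder ->
attribute -> select -> reconstruct/rank -> atlas, from one config.

Every stage writes its artifacts under the run directory and the manifest
records the config, the seeds in play and a SHA-256 checksum of every
artifact, so an identical re-run can be verified bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import atlas as atlas_mod
from .balance import run_ladder, run_ladder_balance_first
from .classifier import SearchSpec, evaluate, split_train_test
from .io import decile_expression_summary, load_matrix
from .selection import partition_gene_sets, per_type_top_genes
from .shap_engine import attribute, filter_correct, global_gene_ranking, stratified_background
from .shap_matrix import (
    cell_type_importance,
    key_genes_per_type,
    reconstruct_shap_matrix,
    retrain_on_shap_matrix,
)
from .synthetic import generate_dataset, muscle_atlas_config, write_dataset

__all__ = ["PipelineConfig", "run_pipeline"]

STAGES = [
    "simulate",
    "decile",
    "split",
    "ladder",
    "attribute",
    "select",
    "rank",
    "atlas",
]


@dataclass
class PipelineConfig:
    """One config to drive the whole pipeline; defaults are the reference settings
    (7:3 split, seed 42, top-500 genes per type, top-20 key genes, 0.8
    correlation threshold, 5-cell low-quality floor)."""

    input_dir: str | None = None  # load instead of simulating when set
    split_ratio: float = 0.7
    seed: int = 42
    n_top: int = 500
    k_key: int = 20
    correlation_threshold: float = 0.8
    min_cells: int = 5
    background_size: int = 128
    balance_order: str = "split_first"  # or "balance_first"
    use_normalized: bool = True
    synthetic: dict = field(default_factory=dict)  # forwarded to muscle_atlas_config
    search: dict = field(default_factory=dict)  # SearchSpec overrides

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def search_spec(self) -> SearchSpec:
        overrides = dict(self.search)
        for key in ("n_trees", "max_depth", "min_split", "min_leaf"):
            if key in overrides:
                overrides[key] = tuple(overrides[key])
        overrides.setdefault("seed", self.seed)
        return SearchSpec(**overrides)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute all stages; returns the run directory containing manifest.json."""
    if config.input_dir is not None and not Path(config.input_dir).exists():
        raise FileNotFoundError(f"input_dir does not exist: {config.input_dir}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def save_df(df, name, **kw):
        path = out / name
        df.to_csv(path, **kw)
        artifacts[name] = _sha256(path)

    # 1. simulate or load -------------------------------------------------
    if config.input_dir is None:
        cfg = muscle_atlas_config(seed=config.seed, **config.synthetic)
        raw, truth = generate_dataset(cfg)
        data_dir = write_dataset(raw, truth, out / "data")
        for p in sorted(data_dir.iterdir()):
            artifacts[f"data/{p.name}"] = _sha256(p)
    else:
        raw = load_matrix(config.input_dir)
    matrix = raw.normalized() if config.use_normalized else raw

    # 2. decile summary (on counts: expression-mass shares are a statement
    # about raw expression, which the log transform would flatten) ---------
    decile = decile_expression_summary(raw)
    save_df(decile.table, "decile_summary.csv", index=False)

    # 3. split ------------------------------------------------------------
    train, test = split_train_test(matrix, ratio=config.split_ratio, seed=config.seed)

    # 4. balance ladder + model selection ---------------------------------
    spec = config.search_spec()
    if config.balance_order == "balance_first":
        report, scheme, models = run_ladder_balance_first(
            matrix, ratio=config.split_ratio, split_seed=config.seed, spec=spec, seed=config.seed
        )
    else:
        report, scheme, models = run_ladder(train, test, spec=spec, seed=config.seed)
    save_df(report.table, "ladder_report.csv", index=False)
    model = models[report.selected]
    model.to_json(out / "model.json")
    artifacts["model.json"] = _sha256(out / "model.json")

    # 5. attribute the test set -------------------------------------------
    background = stratified_background(train, n=config.background_size, seed=config.seed)
    tensor = attribute(model, test, background)
    predictions = model.predict(test.values)
    save_df(tensor.to_long(), "attributions.csv", index=False)
    save_df(
        pd.Series(tensor.base, index=tensor.classes, name="base").rename_axis("class"),
        "base_values.csv",
    )

    # 6. gene selection ---------------------------------------------------
    correct = filter_correct(tensor, predictions, test.labels)
    top_lists = per_type_top_genes(correct, n=config.n_top)
    partition = partition_gene_sets(top_lists)
    partition.write(out / "gene_sets")
    for p in sorted((out / "gene_sets").iterdir()):
        artifacts[f"gene_sets/{p.name}"] = _sha256(p)
    ranking20 = global_gene_ranking(tensor, k=min(20, len(tensor.gene_ids)))
    save_df(ranking20, "global_top_genes.csv", index=False)

    # 7. SHAP matrix, importance ranking, key genes, retrain --------------
    sm = reconstruct_shap_matrix(tensor, predictions, test.labels, partition.union_sel)
    sm.to_csv(out / "shap_matrix.csv")
    artifacts["shap_matrix.csv"] = _sha256(out / "shap_matrix.csv")
    importance = cell_type_importance(sm, min_cells=config.min_cells)
    save_df(importance.scores.rename("score").rename_axis("cell_type"), "importance_ranking.csv")
    key = key_genes_per_type(sm, k=config.k_key)
    key_table = (
        pd.concat({t: df for t, df in key.items()}, names=["cell_type", "rank"])
        .reset_index(level=0)
        .reset_index(drop=True)
    )
    save_df(key_table, "key_genes.csv", index=False)
    _, shap_retrain_acc = retrain_on_shap_matrix(sm, split_seed=config.seed, spec=spec)

    # 8. atlases + correlation screens ------------------------------------
    emb_expr = atlas_mod.umap_atlas(test, seed=config.seed)
    save_df(emb_expr, "umap_expression.csv", index=False)
    emb_shap = atlas_mod.umap_atlas(sm.values, labels=sm.labels, seed=config.seed)
    save_df(emb_shap, "umap_shap_matrix.csv", index=False)
    atlas_mod.plot_atlas(emb_expr, out / "umap_expression.png", "expression atlas")
    atlas_mod.plot_atlas(emb_shap, out / "umap_shap_matrix.png", "attribution-matrix atlas")
    corr = atlas_mod.gene_correlation(
        matrix, genes=ranking20.gene.tolist(), threshold=config.correlation_threshold
    )
    save_df(corr.matrix, "gene_correlation.csv")
    save_df(
        pd.DataFrame(corr.high_pairs, columns=["gene_a", "gene_b", "r"]),
        "gene_correlation_high_pairs.csv",
        index=False,
    )
    top_type = importance.top()
    gt = atlas_mod.gene_type_correlation(matrix, genes=key[top_type].gene.tolist())
    save_df(gt, "gene_type_correlation.csv")

    manifest = {
        "stages": STAGES,
        "config": asdict(config),
        "selected_scheme": report.selected,
        "selected_bvs": float(model.bvs),
        "selected_abp": float(model.abp) if model.abp is not None else None,
        "shap_matrix_retrain_accuracy": float(shap_retrain_acc),
        "importance_ranking": {str(t): float(s) for t, s in importance.scores.items()},
        "n_high_correlation_pairs": len(corr.high_pairs),
        "seeds": {"pipeline": config.seed, "search": spec.seed},
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
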