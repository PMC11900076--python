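"""Cell-type importance ranking and key genes from the attribution matrix.

The attribution matrix (rows: correctly classified test cells; columns:
selected genes; entries: the gene's Shapley value for the cell's own type)
is scored per type by the per-cell mean of its summed positive entries.
A rare type with a strong signature can therefore outrank an abundant one.
"""

from shapcell import (
    attribute,
    cell_type_importance,
    filter_correct,
    generate_dataset,
    key_genes_per_type,
    muscle_atlas_config,
    partition_gene_sets,
    per_type_top_genes,
    reconstruct_shap_matrix,
    retrain_on_shap_matrix,
    split_train_test,
    stratified_background,
    tune_and_train,
)
from shapcell.classifier import SearchSpec

matrix, truth = generate_dataset(muscle_atlas_config(scale=0.12, seed=7))
train, test = split_train_test(matrix.normalized(), ratio=0.7, seed=42)
spec = SearchSpec.fast()
model = tune_and_train(train, spec)

tensor = attribute(model, test, stratified_background(train, n=32, seed=0))
pred = model.predict(test.values)
correct = filter_correct(tensor, pred, test.labels)
partition = partition_gene_sets(per_type_top_genes(correct, n=100))
sm = reconstruct_shap_matrix(tensor, pred, test.labels, partition.all_distinct)

ranking = cell_type_importance(sm, min_cells=5)
print("cell-type importance (per-cell mean positive attribution):")
print(ranking.scores.round(4).to_string())
print(f"planted dominant type: {truth.dominant_type}")
for t, reason in ranking.excluded.items():
    print(f"excluded {t}: {reason}")

key = key_genes_per_type(sm, k=10)
top_type = ranking.top()
print(f"\ntop key genes of {top_type} (planted markers flagged):")
df = key[top_type]
df["planted"] = df.gene.isin(set(truth.marker_map[top_type]))
print(df.to_string(index=False))

_, acc = retrain_on_shap_matrix(sm, split_seed=42, spec=spec)
print(f"\nretrain on the attribution matrix, held-out accuracy: {acc:.3f}")
# The dominant type ranks first by signal despite not being the most
# abundant, its key genes are its planted markers, and the attribution
# matrix alone supports near-perfect reclassification.
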