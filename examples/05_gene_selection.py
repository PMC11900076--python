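"""Per-type top-gene lists, their set partition, and subset retraining.

Each type's correctly classified test cells yield a top-N gene list by mean
attribution; across lists, genes are co-expressed (in every list), specific
(in exactly one), or in between.  Retraining on a subset over the same
train/test split shows how much label information the subset keeps.
"""

from shapcell import (
    attribute,
    filter_correct,
    generate_dataset,
    muscle_atlas_config,
    partition_gene_sets,
    per_type_top_genes,
    retrain_on_subset,
    split_train_test,
    stratified_background,
    tune_and_train,
)
from shapcell.classifier import SearchSpec, evaluate

matrix, truth = generate_dataset(muscle_atlas_config(scale=0.05, n_genes=80, seed=3))
train, test = split_train_test(matrix.normalized(), ratio=0.7, seed=42)
spec = SearchSpec.fast()
model = tune_and_train(train, spec)

tensor = attribute(model, test, stratified_background(train, n=32, seed=0))
correct = filter_correct(tensor, model.predict(test.values), test.labels)
partition = partition_gene_sets(per_type_top_genes(correct, n=25))
print("partition sizes:", partition.summary())

full_acc = evaluate(model, test).accuracy
_, sub_report = retrain_on_subset(train, test, partition.union_sel, spec)
print(f"accuracy, all {matrix.n_genes} genes:      {full_acc:.3f}")
print(f"accuracy, {len(partition.union_sel)} selected genes: {sub_report.accuracy:.3f}")
# The union of co-expressed and specific genes is a small fraction of the
# transcriptome yet retrains to nearly the full model's accuracy.
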