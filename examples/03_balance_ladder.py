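"""Train one classifier per balancing scheme and pick the working model.

For K types the ladder holds K+1 schemes: RAW (no resampling) plus one
scheme per type that equalizes every class to that type's count by random
under-sampling and SMOTE-style interpolation.  Balancing touches only the
training split.
"""

from shapcell import generate_dataset, muscle_atlas_config, run_ladder, split_train_test
from shapcell.classifier import SearchSpec

matrix, _ = generate_dataset(muscle_atlas_config(scale=0.05, n_genes=80, seed=3))
train, test = split_train_test(matrix.normalized(), ratio=0.7, seed=42)

report, scheme, models = run_ladder(train, test, spec=SearchSpec.fast(), seed=42)
print(report.table.to_string(index=False))
print(f"\nselected scheme: {report.selected} (target count {scheme.target_count})")
# bvs = best cross-validation accuracy during the hyperparameter search,
# abp = test accuracy of the refit best setting.  The working model is the
# best balanced scheme by bvs; RAW is reported for reference.
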