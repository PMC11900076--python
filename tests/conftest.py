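import numpy as np
import pytest

from shapcell.classifier import SearchSpec, split_train_test, tune_and_train
from shapcell.synthetic import SyntheticConfig, generate_dataset, muscle_atlas_config


@pytest.fixture(scope="session")
def small_data():
    """3 well-separated types (50/50/10 cells), 40 genes, 5 markers each."""
    cfg = SyntheticConfig(
        n_types=3,
        type_counts=(50, 50, 10),
        n_genes=40,
        markers_per_type=5,
        marker_fold_change=8.0,
        seed=1,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def atlas_fixture():
    """Atlas-shaped fixture scaled under 1,000 cells: 6 imbalanced types
    (480/180/96/48/14/8), 200 genes, 10 markers per type at fold 8, with a
    dominant mid-abundance type carrying twice the markers at twice the fold."""
    cfg = muscle_atlas_config(scale=0.12, seed=7)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def fast_spec():
    return SearchSpec.fast()


@pytest.fixture(scope="session")
def small_model(small_data, fast_spec):
    """Train/test split + tuned forest on the 3-type fixture (normalized view)."""
    matrix, truth = small_data
    norm = matrix.normalized()
    train, test = split_train_test(norm, ratio=0.7, seed=42)
    model = tune_and_train(train, fast_spec)
    return {"train": train, "test": test, "model": model, "truth": truth}


@pytest.fixture(scope="session")
def tiny_forest():
    """5-tree forest on an 8-gene, 3-type fixture: small enough for the
    exhaustive coalition oracle."""
    cfg = SyntheticConfig(
        n_types=3, type_counts=(40, 30, 20), n_genes=8, markers_per_type=2, seed=3
    )
    matrix, _ = generate_dataset(cfg)
    norm = matrix.normalized()
    train, test = split_train_test(norm, ratio=0.7, seed=42)
    spec = SearchSpec(
        n_trees=(5, 5), max_depth=(4, 8), n_iterations=2, cv_folds=3, seed=0
    )
    model = tune_and_train(train, spec)
    return {"train": train, "test": test, "model": model}


class _StubEstimator:
    """Fixed-prediction estimator for metric-formula tests."""

    def __init__(self, predictions, classes):
        self._pred = np.asarray(predictions, dtype=object)
        self.classes_ = np.asarray(classes, dtype=object)

    def predict(self, X):
        return self._pred[: len(X)]


@pytest.fixture
def stub_model_factory():
    from shapcell.classifier import TrainedModel

    def make(predictions, classes):
        return TrainedModel(
            estimator=_StubEstimator(predictions, classes), best_params={}, bvs=1.0
        )

    return make
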