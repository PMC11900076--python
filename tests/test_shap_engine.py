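import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier

from shapcell.classifier import TrainedModel
from shapcell.shap_engine import (
    AttributionTensor,
    attribute,
    brute_force_shapley,
    filter_correct,
    global_gene_ranking,
    stratified_background,
)
from shapcell.synthetic import SyntheticConfig, generate_dataset
from shapcell.classifier import SearchSpec, split_train_test, tune_and_train


def _wrap(estimator):
    return TrainedModel(estimator=estimator, best_params={}, bvs=1.0)


def _fit_forest(X, y, **kw):
    est = RandomForestClassifier(random_state=0, **kw)
    est.fit(X, y)
    return _wrap(est)


class TestClosedForms:
    def test_constant_forest_attributes_nothing(self):
        """Root-only trees: base equals the constant prediction, phi == 0."""
        rng = np.random.default_rng(0)
        X = rng.random((30, 4))
        y = ["a"] * 20 + ["b"] * 10
        model = _fit_forest(X, y, n_estimators=3, min_samples_leaf=30, bootstrap=False)
        tensor = attribute(model, X[:5], X)
        assert (tensor.phi == 0).all()
        np.testing.assert_allclose(tensor.base, model.predict_proba(X[:1])[0], atol=1e-12)

    def test_single_split_tree_closed_form(self):
        """Depth-1 tree on gene g at t, background all below t, query above:
        phi_g = f(above) - f(below); every other gene exactly 0."""
        X = np.array([[0.0, 5.0], [1.0, 5.0], [3.0, 5.0], [4.0, 5.0]])
        y = ["lo", "lo", "hi", "hi"]
        model = _fit_forest(X, y, n_estimators=1, max_depth=1, bootstrap=False)
        background = X[:2]  # both below the split on gene 0
        query = np.array([[3.5, 5.0]])
        tensor = attribute(model, query, background)
        f_above = model.predict_proba(query)[0]
        f_below = model.predict_proba(background).mean(axis=0)
        np.testing.assert_allclose(tensor.phi[0, 0], f_above - f_below, atol=1e-12)
        assert (tensor.phi[0, 1] == 0).all()

    def test_empty_background_rejected(self, tiny_forest):
        with pytest.raises(ValueError, match="background"):
            attribute(tiny_forest["model"], tiny_forest["test"].values[:1], np.empty((0, 8)))


class TestAxioms:
    def test_local_accuracy_every_cell_and_class(self, tiny_forest):
        tensor = attribute(
            tiny_forest["model"], tiny_forest["test"], tiny_forest["train"]
        )
        recon = tensor.base[None, :] + tensor.phi.sum(axis=1)
        np.testing.assert_allclose(recon, tensor.proba, atol=1e-6)
        assert tensor.max_additivity_gap < 1e-6

    def test_unused_gene_gets_exactly_zero(self):
        """Dummy axiom: a gene no tree splits on has attribution 0.0, not
        merely small."""
        rng = np.random.default_rng(2)
        X = rng.random((40, 5))
        X[:, 3] = 0.7  # constant: never split on
        y = ["a"] * 20 + ["b"] * 20
        X[:20, 0] += 2.0
        model = _fit_forest(X, y, n_estimators=10, max_depth=4)
        used = set()
        for est in model.estimator.estimators_:
            used |= {f for f in est.tree_.feature if f >= 0}
        assert 3 not in used
        tensor = attribute(model, X[:10], X)
        assert (tensor.phi[:, 3, :] == 0.0).all()

    def test_efficiency_sum_phi_equals_f_minus_base(self, tiny_forest):
        model, test, train = (
            tiny_forest["model"],
            tiny_forest["test"],
            tiny_forest["train"],
        )
        tensor = attribute(model, test, train)
        np.testing.assert_allclose(
            tensor.phi.sum(axis=1), tensor.proba - tensor.base[None, :], atol=1e-10
        )


class TestOracle:
    def test_engine_matches_exhaustive_enumeration(self, tiny_forest):
        """Path-decomposition engine vs 2^d coalition enumeration, 1e-8."""
        model, test, train = (
            tiny_forest["model"],
            tiny_forest["test"],
            tiny_forest["train"],
        )
        bg = stratified_background(train, 64, 0)
        tensor = attribute(model, test, bg)
        for i in range(6):
            oracle = brute_force_shapley(model, test.values[i], bg)
            np.testing.assert_allclose(tensor.phi[i], oracle, atol=1e-8)

    def test_single_gene_game(self):
        """With one gene, phi = f(x) - base exactly (single-player game)."""
        X = np.array([[0.0], [1.0], [3.0], [4.0]])
        y = ["lo", "lo", "hi", "hi"]
        model = _fit_forest(X, y, n_estimators=3, bootstrap=False)
        phi = brute_force_shapley(model, X[3], X)
        expected = model.predict_proba(X[3:4])[0] - model.predict_proba(X).mean(axis=0)
        np.testing.assert_allclose(phi[0], expected, atol=1e-12)

    def test_gene_permutation_symmetry(self, tiny_forest):
        """Relabeling gene order permutes attributions and changes nothing
        else (checked through the enumeration oracle on a permuted view)."""
        model, test, train = (
            tiny_forest["model"],
            tiny_forest["test"],
            tiny_forest["train"],
        )
        bg = train.values[:16]
        perm = np.array([3, 1, 7, 0, 5, 2, 6, 4])
        inv = np.argsort(perm)

        class PermutedView:
            classes_ = model.classes_

            def predict_proba(self, X):
                return model.predict_proba(X[:, inv])

        permuted = TrainedModel(estimator=None, best_params={}, bvs=1.0)
        permuted.predict_proba = PermutedView().predict_proba  # type: ignore[assignment]
        x = test.values[0]
        direct = brute_force_shapley(model, x, bg)
        via_perm = brute_force_shapley(permuted, x[perm], bg[:, perm])
        np.testing.assert_allclose(via_perm[inv], direct, atol=1e-10)

    def test_refuses_wide_inputs(self, tiny_forest):
        with pytest.raises(ValueError, match="12"):
            brute_force_shapley(tiny_forest["model"], np.zeros(13), np.zeros((4, 13)))


class TestFilterCorrect:
    @pytest.fixture(scope="class")
    def attributed(self, tiny_forest):
        model, test, train = (
            tiny_forest["model"],
            tiny_forest["test"],
            tiny_forest["train"],
        )
        tensor = attribute(model, test, train.values[:32])
        pred = model.predict(test.values)
        return tensor, pred, test.labels.astype(str)

    def test_retained_count_equals_confusion_diagonal(self, attributed):
        from sklearn.metrics import confusion_matrix

        tensor, pred, labels = attributed
        correct = filter_correct(tensor, pred, labels)
        diag = confusion_matrix(labels, pred, labels=tensor.classes).diagonal().sum()
        assert correct.n_cells == diag

    def test_blocks_partition_by_label(self, attributed):
        tensor, pred, labels = attributed
        correct = filter_correct(tensor, pred, labels)
        for c, block in correct.blocks.items():
            ids = set(block.index)
            expected = {
                cid
                for cid, p, l in zip(tensor.cell_ids, pred, labels)
                if p == l == c
            }
            assert ids == expected

    def test_long_table_concatenates_all_blocks(self, attributed):
        tensor, pred, labels = attributed
        correct = filter_correct(tensor, pred, labels)
        long = correct.to_long()
        assert len(long) == correct.n_cells
        assert list(long.columns)[0] == "class"

    def test_class_with_no_correct_cells_is_flagged(self, attributed):
        tensor, _, labels = attributed
        wrong = np.roll(labels, 1)  # misclassify nearly everything
        with pytest.warns(UserWarning, match="no correctly classified"):
            correct = filter_correct(tensor, wrong, np.array(["zz"] * len(labels)))
        assert set(correct.blocks) == set(tensor.classes)

    def test_misaligned_inputs_rejected(self, attributed):
        tensor, pred, labels = attributed
        with pytest.raises(ValueError, match="aligned"):
            filter_correct(tensor, pred[:-1], labels[:-1])


class TestGlobalRanking:
    def test_planted_markers_dominate_top_genes(self):
        """Median over seeds: >= 80% of the top-20 global genes are planted."""
        fractions = []
        for seed in range(5):
            cfg = SyntheticConfig(
                n_types=3,
                type_counts=(60, 40, 20),
                n_genes=60,
                markers_per_type=8,
                marker_fold_change=8.0,
                seed=seed,
            )
            matrix, truth = generate_dataset(cfg)
            train, test = split_train_test(matrix.normalized(), 0.7, 42)
            model = tune_and_train(train, SearchSpec.fast(seed=seed))
            tensor = attribute(model, test, stratified_background(train, 32, seed))
            top = set(global_gene_ranking(tensor, k=20).gene)
            fractions.append(len(top & truth.all_markers()) / 20)
        assert np.median(fractions) >= 0.8

    def test_all_zero_tensor_is_ranked_by_gene_id(self):
        tensor = AttributionTensor(
            phi=np.zeros((3, 4, 2)),
            base=np.array([0.5, 0.5]),
            classes=["a", "b"],
            cell_ids=["c0", "c1", "c2"],
            gene_ids=["g3", "g1", "g0", "g2"],
            background_ids=["b0"],
            proba=np.full((3, 2), 0.5),
            max_additivity_gap=0.0,
        )
        ranking = global_gene_ranking(tensor, k=4)
        assert ranking.gene.tolist() == ["g0", "g1", "g2", "g3"]
        assert (ranking.importance == 0).all()

    def test_oversized_k_returns_full_ranking_with_warning(self, tiny_forest):
        tensor = attribute(
            tiny_forest["model"], tiny_forest["test"].values[:4], tiny_forest["train"].values[:16]
        )
        with pytest.warns(UserWarning, match="exceeds"):
            ranking = global_gene_ranking(tensor, k=99)
        assert len(ranking) == 8
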