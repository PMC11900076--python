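import numpy as np
import pandas as pd
import pytest

from shapcell.classifier import SearchSpec
from shapcell.shap_engine import attribute, stratified_background
from shapcell.shap_matrix import (
    ShapMatrix,
    cell_type_importance,
    key_genes_per_type,
    reconstruct_shap_matrix,
    retrain_on_shap_matrix,
)


@pytest.fixture(scope="module")
def attributed(small_model):
    model, train, test = (
        small_model["model"],
        small_model["train"],
        small_model["test"],
    )
    tensor = attribute(model, test, stratified_background(train, 32, 0))
    pred = model.predict(test.values)
    return tensor, pred, test.labels.astype(str), small_model["truth"]


def _sm(values, labels, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{j}" for j in range(values.shape[1])]
    return ShapMatrix(
        values=pd.DataFrame(values, index=[f"c{i}" for i in range(len(values))], columns=genes),
        labels=np.asarray(labels, dtype=object),
        max_additivity_gap=0.0,
    )


class TestReconstruction:
    def test_full_gene_set_reproduces_probabilities(self, attributed):
        tensor, pred, labels, _ = attributed
        sm = reconstruct_shap_matrix(tensor, pred, labels, tensor.gene_ids)
        correct = pred == labels
        assert sm.n_cells == int(correct.sum())
        for row_id, row_label in zip(sm.values.index, sm.labels):
            i = tensor.cell_ids.index(row_id)
            ci = tensor.class_index(row_label)
            recon = sm.values.loc[row_id].sum() + tensor.base[ci]
            assert abs(recon - tensor.proba[i, ci]) < 1e-6

    def test_subset_rows_match_full_tensor_slices(self, attributed):
        tensor, pred, labels, _ = attributed
        genes = tensor.gene_ids[::3]
        sm = reconstruct_shap_matrix(tensor, pred, labels, genes)
        assert list(sm.values.columns) == genes
        assert sm.max_additivity_gap < 1e-6

    def test_empty_gene_set_rejected(self, attributed):
        tensor, pred, labels, _ = attributed
        with pytest.raises(ValueError, match="empty"):
            reconstruct_shap_matrix(tensor, pred, labels, [])

    def test_each_types_strongest_column_is_its_marker(self, attributed):
        """Truth recovery: the largest-mean column of a type's block is one
        of that type's planted markers."""
        tensor, pred, labels, truth = attributed
        sm = reconstruct_shap_matrix(tensor, pred, labels, tensor.gene_ids)
        for t in sm.types():
            block = sm.rows_of(t)
            if len(block) < 3:
                continue
            best = block.mean(axis=0).idxmax()
            assert best in set(truth.marker_map[t])


class TestImportance:
    def test_positive_sum_scoring_hand_example(self):
        sm = _sm(
            [[1.0, -2.0], [3.0, 0.5], [0.2, 0.2], [-1.0, -1.0]],
            ["a", "a", "b", "b"],
        )
        ranking = cell_type_importance(sm, min_cells=1)
        # a: mean(1 + 3.5) = 2.25 ; b: mean(0.4 + 0) = 0.2
        assert ranking.scores["a"] == pytest.approx(2.25)
        assert ranking.scores["b"] == pytest.approx(0.2)
        assert ranking.top() == "a"

    def test_small_types_excluded_as_low_quality(self):
        sm = _sm(np.ones((6, 2)), ["a"] * 5 + ["b"])
        ranking = cell_type_importance(sm, min_cells=5)
        assert "b" in ranking.excluded
        assert list(ranking.scores.index) == ["a"]

    def test_all_nonpositive_entries_warn_and_rank_by_name(self):
        sm = _sm(-np.ones((8, 3)), ["b"] * 4 + ["a"] * 4)
        with pytest.warns(UserWarning, match="positive"):
            ranking = cell_type_importance(sm, min_cells=2)
        assert (ranking.scores == 0).all()
        assert list(ranking.scores.index) == ["a", "b"]

    def test_duplicating_a_types_rows_leaves_its_score_unchanged(self, attributed):
        """Per-cell-mean normalization: importance is invariant to abundance."""
        tensor, pred, labels, _ = attributed
        sm = reconstruct_shap_matrix(tensor, pred, labels, tensor.gene_ids)
        t = sm.types()[0]
        block = sm.rows_of(t)
        doubled = ShapMatrix(
            values=pd.concat([sm.values, block.set_axis([f"{i}+dup" for i in block.index])]),
            labels=np.concatenate([sm.labels, np.full(len(block), t, dtype=object)]),
            max_additivity_gap=sm.max_additivity_gap,
        )
        a = cell_type_importance(sm, min_cells=1).scores[t]
        b = cell_type_importance(doubled, min_cells=1).scores[t]
        assert abs(a - b) < 1e-12


class TestKeyGenes:
    def test_single_dominant_column_per_type(self):
        sm = _sm([[5.0, 0.0], [4.0, 0.1], [0.0, 3.0], [0.2, 4.0]], ["a", "a", "b", "b"])
        key = key_genes_per_type(sm, k=1)
        assert key["a"].gene.tolist() == ["g0"]
        assert key["b"].gene.tolist() == ["g1"]

    def test_identical_blocks_identical_lists(self):
        block = [[1.0, 3.0, 2.0], [0.0, 2.0, 1.0]]
        sm = _sm(block + block, ["a", "a", "b", "b"])
        key = key_genes_per_type(sm, k=3)
        assert key["a"].gene.tolist() == key["b"].gene.tolist()
        np.testing.assert_allclose(key["a"].score, key["b"].score)

    def test_negative_entries_do_not_contribute(self):
        sm = _sm([[-9.0, 1.0]], ["a"])
        key = key_genes_per_type(sm, k=2)
        assert key["a"].gene.tolist() == ["g1", "g0"]
        assert key["a"].score.tolist() == [1.0, 0.0]

    def test_scores_non_increasing(self, attributed):
        tensor, pred, labels, _ = attributed
        sm = reconstruct_shap_matrix(tensor, pred, labels, tensor.gene_ids)
        for df in key_genes_per_type(sm, k=10).values():
            assert (np.diff(df.score) <= 1e-15).all()

    def test_k_zero_rejected(self):
        with pytest.raises(ValueError, match="k"):
            key_genes_per_type(_sm([[1.0]], ["a"]), k=0)


class TestRetrain:
    def test_learnable_matrix_scores_high(self, attributed):
        tensor, pred, labels, _ = attributed
        sm = reconstruct_shap_matrix(tensor, pred, labels, tensor.gene_ids)
        _, acc = retrain_on_shap_matrix(sm, split_seed=0, spec=SearchSpec.fast())
        assert acc >= 0.9

    def test_shuffled_labels_score_near_chance(self, attributed):
        tensor, pred, labels, _ = attributed
        sm = reconstruct_shap_matrix(tensor, pred, labels, tensor.gene_ids)
        accs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            shuffled = ShapMatrix(
                values=sm.values,
                labels=rng.permutation(sm.labels),
                max_additivity_gap=0.0,
            )
            try:
                _, acc = retrain_on_shap_matrix(
                    shuffled, split_seed=seed, spec=SearchSpec.fast(seed=seed)
                )
            except ValueError:
                continue  # a permutation may starve a class below the floor
            accs.append(acc)
        assert accs and np.median(accs) < 0.85

    def test_single_type_rejected(self):
        sm = _sm(np.ones((20, 3)), ["a"] * 20)
        with pytest.raises(ValueError, match="2 types"):
            retrain_on_shap_matrix(sm, spec=SearchSpec.fast())

    def test_underpopulated_types_dropped_with_warning(self):
        rng = np.random.default_rng(0)
        vals = np.vstack([rng.normal(0, 1, (20, 3)), rng.normal(5, 1, (20, 3)), rng.normal(9, 1, (2, 3))])
        sm = _sm(vals, ["a"] * 20 + ["b"] * 20 + ["c"] * 2)
        with pytest.warns(UserWarning, match="dropped"):
            _, acc = retrain_on_shap_matrix(sm, spec=SearchSpec.fast())
        assert 0.0 <= acc <= 1.0
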