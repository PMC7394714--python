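import numpy as np
import pytest

from leafct.featgen import FeatureTable, assemble_training_table
from leafct.segmenter import (
    LeafSegmenter,
    add_estimators,
    load_model,
    predict_slices,
    predict_stack,
    save_model,
    select_training_slices,
    train,
)


class TestSelectTrainingSlices:
    def test_seeded_determinism(self):
        labeled = list(range(0, 1920, 80))  # 24 slices
        a = select_training_slices(labeled, 6, seed=5)
        b = select_training_slices(labeled, 6, seed=5)
        assert a == b and len(set(a)) == 6
        assert all(i in labeled for i in a)

    def test_exhaustive_selection(self):
        labeled = [3, 7, 9]
        assert sorted(select_training_slices(labeled, 3, 0)) == [3, 7, 9]

    @pytest.mark.parametrize("n", [0, 4])
    def test_out_of_range_rejected(self, n):
        with pytest.raises(ValueError):
            select_training_slices([1, 2, 3], n, 0)


def _toy_table(n=200, seed=0):
    rng = np.random.default_rng(seed)
    x0 = rng.normal(0, 1, (n, 2))
    x1 = rng.normal(5, 1, (n, 2))  # perfectly separable by feature 0
    X = np.vstack([x0, x1]).astype(np.float32)
    y = np.repeat([0, 3], n)
    return FeatureTable(X, ["f0", "f1"], target=y)


class TestTrain:
    def test_default_estimator_count_recorded(self):
        tab = _toy_table()
        model = train(tab, None, None, seed=0)
        assert model.metadata["n_estimators"] == 50
        assert len(model.classifier.forest_.estimators_) == 50

    def test_separable_classes_perfect_training_accuracy(self):
        tab = _toy_table()
        model = train(tab, None, None, seed=0)
        pred = model.classifier.predict(tab.values)
        assert (pred == tab.target).mean() == 1.0

    def test_warm_start_additivity(self):
        tab = _toy_table()
        model = train(tab, None, None, n_estimators=50, warm_start=True, seed=0)
        model = add_estimators(model, tab, 25)
        assert len(model.classifier.forest_.estimators_) == 75

    def test_oob_score_recorded(self):
        model = train(_toy_table(), None, None, use_oob=True, seed=0)
        assert 0.9 <= model.metadata["oob_score"] <= 1.0

    def test_single_class_rejected_without_override(self):
        tab = _toy_table()
        tab.target[:] = 0
        with pytest.raises(ValueError, match="single-class"):
            train(tab, None, None)
        model = train(tab, None, None, allow_degenerate=True)
        assert (model.classifier.predict(tab.values) == 0).all()

    def test_empty_table_rejected(self):
        tab = FeatureTable(np.empty((0, 2), np.float32), ["a", "b"], target=np.empty(0, int))
        with pytest.raises(ValueError, match="empty"):
            train(tab, None, None)


class TestLeafSegmenterEstimatorContract:
    def test_get_set_params_roundtrip(self):
        clf = LeafSegmenter(n_estimators=10, random_state=3)
        params = clf.get_params()
        assert params["n_estimators"] == 10
        clone = LeafSegmenter(**params)
        assert clone.get_params() == params

    def test_column_mismatch_rejected(self):
        tab = _toy_table()
        clf = LeafSegmenter(n_estimators=5, random_state=0).fit(tab, tab.target)
        bad = FeatureTable(tab.values, ["f1", "f0"])
        with pytest.raises(ValueError, match="feature columns differ"):
            clf.predict(bad)

    def test_predict_proba_shape(self):
        tab = _toy_table()
        clf = LeafSegmenter(n_estimators=5, random_state=0).fit(tab, tab.target)
        assert clf.predict_proba(tab.values).shape == (tab.n_rows, 2)


@pytest.fixture(scope="module")
def tiny_model(tiny_bundle_m, tiny_lt_m, tiny_labels_m, tiny_cfg_m):
    idx = list(tiny_labels_m.labeled_slice_indices[:4])
    tab = assemble_training_table(
        tiny_bundle_m.gridrec, tiny_bundle_m.phase, tiny_lt_m, tiny_labels_m, idx, tiny_cfg_m
    )
    return train(tab, tiny_labels_m.class_map, tiny_cfg_m, seed=7, slice_indices=idx)


# module-scoped aliases of the session fixtures so tiny_model can cache
@pytest.fixture(scope="module")
def tiny_bundle_m(tiny_bundle):
    return tiny_bundle


@pytest.fixture(scope="module")
def tiny_lt_m(tiny_lt):
    return tiny_lt


@pytest.fixture(scope="module")
def tiny_labels_m(tiny_labels):
    return tiny_labels


@pytest.fixture(scope="module")
def tiny_cfg_m(tiny_cfg):
    return tiny_cfg


class TestPredictStack:
    def test_training_slice_reproduced(self, tiny_model, tiny_bundle, tiny_lt):
        """A slice used verbatim in training is segmented near-identically."""
        z = tiny_model.metadata["slice_indices"][0]
        pred = predict_slices(tiny_model, tiny_bundle.gridrec, tiny_bundle.phase, tiny_lt, [z])
        truth = tiny_bundle.truth.voxels[z]
        assert (pred[0] == truth).mean() >= 0.99

    def test_never_emits_sentinel_and_deterministic(self, tiny_model, tiny_bundle, tiny_lt):
        pred1 = predict_stack(tiny_model, tiny_bundle.gridrec, tiny_bundle.phase, tiny_lt)
        pred2 = predict_stack(tiny_model, tiny_bundle.gridrec, tiny_bundle.phase, tiny_lt)
        np.testing.assert_array_equal(pred1.voxels, pred2.voxels)
        assert tiny_bundle.truth.class_map.sentinel not in np.unique(pred1.voxels)

    def test_heldout_recall_on_separable_phantom(self, tiny_model, tiny_bundle, tiny_lt):
        held_out = [
            z for z in range(tiny_bundle.truth.shape[0])
            if z not in tiny_model.metadata["slice_indices"]
        ][:4]
        pred = predict_slices(
            tiny_model, tiny_bundle.gridrec, tiny_bundle.phase, tiny_lt, held_out
        )
        truth = tiny_bundle.truth.voxels[held_out]
        cm = tiny_bundle.truth.class_map
        for name in ("background", "mesophyll_cell", "airspace"):
            code = cm.code(name)
            mask = truth == code
            recall = (pred[mask] == code).mean()
            assert recall >= 0.90, f"{name} recall {recall:.3f}"

    def test_model_persistence_roundtrip(self, tiny_model, tiny_bundle, tiny_lt, tmp_path):
        p = tmp_path / "model.joblib"
        save_model(tiny_model, p)
        assert p.with_suffix(".joblib.json").exists()
        back = load_model(p)
        z = [tiny_model.metadata["slice_indices"][0]]
        a = predict_slices(tiny_model, tiny_bundle.gridrec, tiny_bundle.phase, tiny_lt, z)
        b = predict_slices(back, tiny_bundle.gridrec, tiny_bundle.phase, tiny_lt, z)
        np.testing.assert_array_equal(a, b)
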