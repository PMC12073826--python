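import numpy as np
import pytest

from doublecrop.models import (
    DOUBLE,
    SINGLE,
    FeatureVector,
    LabeledDataset,
    TrainedModel,
    dtw_distance,
    dtw_matrix,
    oversample_minority,
    predict,
    render_series_image,
    stratified_split,
    to_feature_vector,
    train_classifier,
)
from doublecrop.preprocess import preprocess

from .test_preprocess import smooth_from_values


def dtw_oracle(a, b):
    """Exhaustive recursion over all monotone warping paths."""

    def rec(i, j):
        c = abs(a[i] - b[j])
        if i == 0 and j == 0:
            return c
        best = np.inf
        if i > 0:
            best = min(best, rec(i - 1, j))
        if j > 0:
            best = min(best, rec(i, j - 1))
        if i > 0 and j > 0:
            best = min(best, rec(i - 1, j - 1))
        return c + best

    return rec(len(a) - 1, len(b) - 1)


def make_dataset(rng, n=60, crops=("wheat", "buckwheat", "apple")):
    """Separable synthetic vectors: doubles have two bumps, singles one."""
    recs, strata = [], []
    for i in range(n):
        label = DOUBLE if rng.random() < 0.3 else SINGLE
        x = np.full(36, 0.1)
        if label == DOUBLE:
            x[8:14] = 0.8
            x[20:27] = 0.75
        else:
            x[10:24] = 0.8
        x = x + rng.normal(0, 0.03, size=36)
        recs.append(FeatureVector(values=x, field_id=f"F{i}", label=label))
        strata.append(crops[i % len(crops)])
    return LabeledDataset(records=recs, strata=strata)


class TestDtw:
    def test_identity_and_symmetry(self, rng):
        for _ in range(50):
            a = rng.uniform(0, 1, size=int(rng.integers(2, 10)))
            b = rng.uniform(0, 1, size=int(rng.integers(2, 10)))
            assert dtw_distance(a, a) == 0.0
            assert dtw_distance(a, b) == pytest.approx(dtw_distance(b, a))
            assert dtw_distance(a, b) >= 0.0

    def test_shift_absorbed(self):
        assert dtw_distance([0, 1, 0], [0, 0, 1, 0]) == 0.0

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(500):
            a = rng.uniform(0, 1, size=int(rng.integers(1, 7)))
            b = rng.uniform(0, 1, size=int(rng.integers(1, 7)))
            assert dtw_distance(a, b) == pytest.approx(dtw_oracle(a, b))

    def test_warping_never_worse_than_lockstep(self, rng):
        for _ in range(50):
            a = rng.uniform(0, 1, size=12)
            b = rng.uniform(0, 1, size=12)
            assert dtw_distance(a, b) <= np.abs(a - b).sum() + 1e-12

    def test_band_constraint(self):
        a = [0.0, 1.0, 0.0, 0.0]
        b = [0.0, 0.0, 0.0, 1.0]
        assert dtw_distance(a, b, window=3) <= dtw_distance(a, b, window=1) + 1e-12

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            dtw_distance([], [1.0])

    def test_matrix_agrees_with_scalar(self, rng):
        A = rng.uniform(0, 1, size=(4, 8))
        B = rng.uniform(0, 1, size=(3, 8))
        D = dtw_matrix(A, B)
        for i in range(4):
            for j in range(3):
                assert D[i, j] == pytest.approx(dtw_distance(A[i], B[j]))


class TestFeatureVector:
    def test_from_smooth_series(self):
        sm = smooth_from_values(np.linspace(0, 1, 36))
        fv = to_feature_vector(sm, label=SINGLE)
        np.testing.assert_array_equal(fv.values, sm.values)
        assert fv.label == SINGLE

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            FeatureVector(values=np.zeros(35), field_id="x")


class TestStratifiedSplit:
    def test_counts_per_stratum(self, rng):
        ds = make_dataset(rng, n=50, crops=("wheat",))
        train, test = stratified_split(ds, 0.2, seed=3)
        assert len(test) == 10
        assert len(train) == 40

    def test_disjoint_and_exhaustive(self, rng):
        ds = make_dataset(rng, n=60)
        train, test = stratified_split(ds, 0.2, seed=3)
        ids_train = {r.field_id for r in train.records}
        ids_test = {r.field_id for r in test.records}
        assert ids_train & ids_test == set()
        assert ids_train | ids_test == {r.field_id for r in ds.records}

    def test_deterministic_per_seed(self, rng):
        ds = make_dataset(rng, n=60)
        a = stratified_split(ds, 0.2, seed=9)
        b = stratified_split(ds, 0.2, seed=9)
        assert [r.field_id for r in a[1].records] == [r.field_id for r in b[1].records]

    def test_singleton_stratum_goes_to_train(self, rng):
        ds = make_dataset(rng, n=31, crops=("wheat",))
        ds.strata[-1] = "rare_crop"
        train, test = stratified_split(ds, 0.2, seed=1)
        assert "rare_crop" in train.strata
        assert "rare_crop" not in test.strata


class TestOversampleMinority:
    def _imbalanced(self, rng, n_major=100, n_minor=20):
        recs, strata = [], []
        for i in range(n_major + n_minor):
            label = SINGLE if i < n_major else DOUBLE
            recs.append(
                FeatureVector(
                    values=rng.uniform(0, 1, 36), field_id=f"F{i}", label=label
                )
            )
            strata.append("c")
        return LabeledDataset(records=recs, strata=strata)

    def test_minority_grown_to_half_of_majority(self, rng):
        ds = self._imbalanced(rng)
        out = oversample_minority(ds, 0.5, seed=2)
        y = out.y
        assert int(np.sum(y == DOUBLE)) == 50
        assert int(np.sum(y == SINGLE)) == 100

    def test_duplicates_come_from_original_minority(self, rng):
        ds = self._imbalanced(rng)
        out = oversample_minority(ds, 0.5, seed=2)
        minority_ids = {r.field_id for r in ds.records if r.label == DOUBLE}
        assert {r.field_id for r in out.records if r.label == DOUBLE} <= minority_ids
        # all originals retained
        assert {r.field_id for r in out.records} == {r.field_id for r in ds.records}

    def test_already_balanced_unchanged(self, rng):
        ds = self._imbalanced(rng, n_major=40, n_minor=30)
        out = oversample_minority(ds, 0.5, seed=2)
        assert len(out) == len(ds)

    def test_deterministic_per_seed(self, rng):
        ds = self._imbalanced(rng)
        a = oversample_minority(ds, 0.5, seed=7)
        b = oversample_minority(ds, 0.5, seed=7)
        assert [r.field_id for r in a.records] == [r.field_id for r in b.records]

    def test_single_class_rejected(self, rng):
        ds = self._imbalanced(rng, n_major=10, n_minor=0)
        with pytest.raises(ValueError):
            oversample_minority(ds, 0.5, seed=0)


class TestTraining:
    @pytest.mark.parametrize("kind", ["svm", "rf", "knn_dtw"])
    def test_separable_data_recovered(self, kind, rng):
        train = make_dataset(rng, n=150)
        test = make_dataset(rng, n=60)
        model = train_classifier(kind, train, seed=4)
        pred = predict(model, test.X)
        assert np.mean(pred == test.y) >= 0.95

    def test_grid_of_size_one_returned(self, rng):
        ds = make_dataset(rng, n=60)
        model = train_classifier("rf", ds, grid=[{"n_estimators": 50}], seed=0)
        assert model.config["params"] == {"n_estimators": 50}

    def test_same_seed_same_hyperparameters(self, rng):
        ds = make_dataset(rng, n=80)
        a = train_classifier("svm", ds, seed=6)
        b = train_classifier("svm", ds, seed=6)
        assert a.config["params"] == b.config["params"]
        assert a.cv_table == b.cv_table

    def test_one_nn_predicts_training_record_label(self, rng):
        ds = make_dataset(rng, n=40)
        model = train_classifier("knn_dtw", ds, grid=[{"n_neighbors": 1}], seed=0)
        pred = predict(model, ds.X)
        assert np.array_equal(pred, ds.y)

    def test_permutation_equivariance(self, rng):
        ds = make_dataset(rng, n=60)
        model = train_classifier("svm", ds, seed=1)
        X = ds.X
        perm = rng.permutation(len(X))
        assert np.array_equal(predict(model, X)[perm], predict(model, X[perm]))

    def test_serialization_round_trip(self, tmp_path, rng):
        ds = make_dataset(rng, n=60)
        for kind in ["svm", "knn_dtw"]:
            model = train_classifier(kind, ds, seed=1)
            path = tmp_path / f"{kind}.joblib"
            model.save(path)
            back = TrainedModel.load(path)
            assert np.array_equal(predict(model, ds.X), predict(back, ds.X))


class TestRenderSeriesImage:
    def test_deterministic(self):
        sm = smooth_from_values(np.abs(np.sin(np.linspace(0, 3, 36))) * 0.8)
        a = render_series_image(sm)
        b = render_series_image(sm)
        assert np.array_equal(a, b)

    def test_constant_series_single_row(self):
        sm = smooth_from_values(np.full(36, 0.5))
        img = render_series_image(sm, width=72, height=50)
        rows = np.unique(np.nonzero(img)[0])
        assert len(rows) == 1

    def test_higher_peak_higher_on_canvas(self):
        low = render_series_image(smooth_from_values(np.full(36, 0.2)), 72, 100)
        high = render_series_image(smooth_from_values(np.full(36, 0.9)), 72, 100)
        assert np.nonzero(high)[0].max() < np.nonzero(low)[0].min()

    def test_bad_dimensions_rejected(self):
        with pytest.raises(ValueError):
            render_series_image(smooth_from_values(np.zeros(36)), 0, 10)


class TestRatioVsModelsErrorDirection:
    def test_ratio_overpredicts_doubles_versus_every_model(self, confuser_smoothed):
        from doublecrop.ratio_method import classify_ratio

        smoothed, truths = confuser_smoothed
        ds = LabeledDataset(
            records=[
                to_feature_vector(s, label=t.label)
                for s, t in zip(smoothed, truths)
            ],
            strata=[t.crop for t in truths],
        )
        train, test = stratified_split(ds, 0.2, seed=13)
        by_id = {s.meta.field_id: s for s in smoothed}
        ratio_fd = sum(
            1
            for r in test.records
            if r.label == SINGLE and classify_ratio(by_id[r.field_id]).label == DOUBLE
        )
        assert ratio_fd > 0
        for kind in ["svm", "rf", "knn_dtw"]:
            model = train_classifier(kind, train, seed=13)
            pred = predict(model, test.X)
            model_fd = int(np.sum((test.y == SINGLE) & (pred == DOUBLE)))
            assert ratio_fd > model_fd, kind
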