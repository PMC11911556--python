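import numpy as np
import pytest

import m5censemble as m
from m5censemble import ensemble_models as em

VALID = "A" * 20 + "C" + "A" * 20


def balanced_dataset(n_per_class, seed=7):
    return m.generate(n_per_class, n_per_class, m.default_logo(0.4, seed=seed))


def separable_features(n_per_class=40, seed=0):
    """Linearly separable toy features: class fully determined by column 0."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n_per_class, 5))
    y = np.array([1] * n_per_class + [0] * n_per_class)
    X[:, 0] = y * 10.0 + rng.normal(scale=0.1, size=y.size)
    return X, y


def test_independent_split_stratified_arithmetic():
    ds = balanced_dataset(50)
    train, test = m.independent_split(ds, m.SplitSpec(seed=1))
    assert len(train) == 80 and len(test) == 20
    assert np.bincount(train.labels).tolist() == [40, 40]
    assert np.bincount(test.labels).tolist() == [10, 10]
    train_ids = {w.id for w in train}
    test_ids = {w.id for w in test}
    assert not train_ids & test_ids
    assert train_ids | test_ids == {w.id for w in ds}


def test_independent_split_seed_determinism():
    ds = balanced_dataset(50)
    t1, _ = m.independent_split(ds, m.SplitSpec(seed=3))
    t2, _ = m.independent_split(ds, m.SplitSpec(seed=3))
    t3, _ = m.independent_split(ds, m.SplitSpec(seed=4))
    assert [w.id for w in t1] == [w.id for w in t2]
    assert [w.id for w in t1] != [w.id for w in t3]


def test_independent_split_rejects_single_class():
    ds = m.LabeledDataset(
        [m.SequenceWindow(f"w{i}", VALID, 1) for i in range(10)]
    )
    with pytest.raises(ValueError):
        m.independent_split(ds, m.SplitSpec(seed=0))


def test_kfold_partition_and_stratification():
    ds = balanced_dataset(50)
    folds = m.kfold_split(ds, k=10, seed=2)
    assert len(folds) == 10
    assert all(len(f) == 10 for f in folds)
    assert all(np.bincount(f.labels).tolist() == [5, 5] for f in folds)
    ids = [w.id for f in folds for w in f]
    assert sorted(ids) == sorted(w.id for w in ds)


def test_kfold_rejects_k_larger_than_dataset():
    ds = balanced_dataset(3)
    with pytest.raises(ValueError):
        m.kfold_split(ds, k=7, seed=0)


def test_model_spec_rejects_unknown_family():
    with pytest.raises(ValueError, match="family"):
        m.ModelSpec(family="SVM")


def test_train_rejects_single_class():
    X, y = separable_features()
    with pytest.raises(ValueError):
        m.train(m.ModelSpec(family="RF", seed=0), X, np.ones_like(y))


def test_rf_training_accuracy_on_separable_features():
    X, y = separable_features()
    model = m.train(m.ModelSpec(family="RF", seed=0), X, y)
    assert np.array_equal(model.predict(X), y)


@pytest.mark.parametrize("family", em.FAMILIES)
def test_every_family_runs_and_is_reproducible(family, small_features):
    """Smoke suite: all eight families end-to-end, repeat run identical."""
    X, y, names = small_features
    spec = m.ModelSpec(family=family, seed=5)
    split = m.SplitSpec(seed=5)
    _, first = m.train_and_evaluate_split(spec, X, y, split, names)
    _, second = m.train_and_evaluate_split(spec, X, y, split, names)
    assert first.to_dict() == second.to_dict()
    assert 0.0 <= first.acc <= 1.0
    assert -1.0 <= first.mcc <= 1.0
    assert first.counts.total == 12  # 20% of 60 windows


def test_predict_refuses_mismatched_feature_names(small_features):
    X, y, names = small_features
    model, _ = m.train_and_evaluate_split(
        m.ModelSpec(family="DT", seed=1), X, y, m.SplitSpec(seed=1), names
    )
    wrong = tuple(reversed(names))
    with pytest.raises(ValueError, match="feature names"):
        model.predict_scores(X, names=wrong)


def test_model_archive_roundtrip(tmp_path, small_features):
    X, y, names = small_features
    model, _ = m.train_and_evaluate_split(
        m.ModelSpec(family="RF", seed=9), X, y, m.SplitSpec(seed=9), names
    )
    path = tmp_path / "model.bin"
    model.save(path)
    back = m.TrainedModel.load(path)
    assert back.spec == model.spec
    assert back.feature_names == model.feature_names
    assert np.allclose(back.predict_scores(X), model.predict_scores(X))


def test_cross_validate_perfect_separation_and_fold_count():
    X, y = separable_features(n_per_class=50, seed=3)
    result = m.cross_validate(
        m.ModelSpec(family="DT", seed=0), X, y, k=10, seed=0
    )
    assert len(result["folds"]) == 10
    assert all(r.acc == 1.0 for r in result["folds"])
    assert result["summary"]["mean_acc"] == 1.0


def test_cross_validate_fits_scaler_on_training_rows_only(monkeypatch):
    """Leakage instrumentation: every scaler fit sees exactly the fold's
    training rows, never the full dataset."""
    X, y = separable_features(n_per_class=25, seed=4)
    seen: list[int] = []
    original = em.fit_scaler

    def spy(train, names=None):
        seen.append(train.shape[0])
        return original(train, names)

    monkeypatch.setattr(em, "fit_scaler", spy)
    m.cross_validate(m.ModelSpec(family="DT", seed=0), X, y, k=5, seed=0)
    assert seen == [40] * 5  # 50 samples, 5 folds -> 40 training rows each


def test_independent_split_protocol_scales_with_train_stats(monkeypatch):
    X, y = separable_features(n_per_class=25, seed=5)
    seen: list[int] = []
    original = em.fit_scaler

    def spy(train, names=None):
        seen.append(train.shape[0])
        return original(train, names)

    monkeypatch.setattr(em, "fit_scaler", spy)
    m.train_and_evaluate_split(
        m.ModelSpec(family="DT", seed=0), X, y, m.SplitSpec(seed=0)
    )
    assert seen == [40]  # 80% of 50
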