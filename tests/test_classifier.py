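"""Bayesian-regularized trainer, prediction, evaluation and model selection."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ricemorph as rm
from ricemorph import classifier as clf
from ricemorph.classifier import BRConfig, SchemaError
from ricemorph.specs import FEATURE_NAMES
from ricemorph.synthetic import separable_class_specs

FAST = BRConfig(max_epochs=60, seed=0)


def _small_table(n_classes=5, n=30, seed=0):
    return rm.sample_feature_table(separable_class_specs(n_classes), n, seed=seed)


# ------------------------------------------------------------------ split

@pytest.mark.parametrize(
    "n,fraction,expected",
    [(3839, 0.7, (2687, 1152)), (9839, 0.7, (6887, 2952)), (10, 0.7, (7, 3))],
)
def test_split_sizes_match_floor_rule(n, fraction, expected):
    table = pd.DataFrame({"class_id": np.arange(n) % 15})
    train, test = clf.split_dataset(table, fraction, seed=0)
    assert (len(train), len(test)) == expected


def test_split_is_a_partition_and_deterministic():
    table = _small_table()
    a1, b1 = clf.split_dataset(table, 0.7, seed=5)
    a2, b2 = clf.split_dataset(table, 0.7, seed=5)
    pd.testing.assert_frame_equal(a1, a2)
    assert len(a1) + len(b1) == len(table)


def test_split_rejects_bad_inputs():
    with pytest.raises(ValueError):
        clf.split_dataset(pd.DataFrame(), 0.7)
    with pytest.raises(ValueError):
        clf.split_dataset(_small_table(), 1.5)


def test_stratified_split_keeps_class_proportions():
    table = _small_table(n_classes=5, n=40)
    train, _ = clf.split_dataset(table, 0.7, seed=0, stratify=True)
    counts = train.groupby("class_id").size()
    assert (counts == 28).all()  # floor(0.7 * 40) per class


# ---------------------------------------------------------------- training

def test_br_training_reaches_high_accuracy_on_separable_classes(
    separable_model, separable_table
):
    train, test = clf.split_dataset(separable_table, 0.7, seed=3)
    assert clf.evaluate(separable_model, train).accuracy >= 99.0
    assert clf.evaluate(separable_model, test).accuracy >= 95.0


def test_br_objective_monotone_and_gamma_bounded(separable_model):
    hist = separable_model.objective_history
    assert len(hist) > 0
    assert all(f_after <= f_before for f_before, f_after in hist)
    assert 0.0 <= separable_model.gamma <= separable_model.n_weights


def test_br_deterministic_for_fixed_seed():
    table = _small_table()
    train, _ = clf.split_dataset(table, 0.7, seed=1)
    m1 = clf.train_br(train, n_hidden=3, config=FAST)
    m2 = clf.train_br(train, n_hidden=3, config=FAST)
    assert np.array_equal(m1.W1, m2.W1) and np.array_equal(m1.W2, m2.W2)
    assert m1.alpha == m2.alpha and m1.n_epochs == m2.n_epochs


def test_br_rejects_invalid_training_tables():
    table = _small_table()
    single = table[table["class_id"] == 1]
    with pytest.raises(ValueError, match="two classes"):
        clf.train_br(single, n_hidden=3, config=FAST)
    bad = table.copy()
    bad.loc[0, "FD"] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        clf.train_br(bad, n_hidden=3, config=FAST)
    with pytest.raises(ValueError):
        clf.train_br(table, n_hidden=0, config=FAST)


def test_br_warns_when_overparameterized():
    table = _small_table(n_classes=3, n=10)  # 30 rows
    with pytest.warns(UserWarning, match="over-parameterization"):
        clf.train_br(table, n_hidden=10, config=FAST)


def test_gdm_baseline_learns_above_chance():
    table = _small_table(n_classes=5, n=40)
    train, test = clf.split_dataset(table, 0.7, seed=0)
    model = clf.train_gdm(train, n_hidden=5, max_epochs=400, seed=0)
    assert clf.evaluate(model, test).accuracy > 2 * 100.0 / 5


# -------------------------------------------------------------- prediction

def test_predict_breaks_ties_toward_lowest_class_id(separable_model):
    model = separable_model
    degenerate = clf.NetworkModel(
        W1=np.zeros_like(model.W1),
        b1=np.zeros_like(model.b1),
        W2=np.zeros_like(model.W2),
        b2=np.zeros_like(model.b2),
        input_center=model.input_center,
        input_scale=model.input_scale,
        class_ids=model.class_ids,
        alpha=0.0, beta=1.0, gamma=0.0, n_hidden=model.n_hidden,
    )
    rows = _small_table(n_classes=2, n=3)
    scores = clf.predict(degenerate, rows)
    assert (scores["predicted_class"] == min(model.class_ids)).all()


def test_predict_schema_is_strict(separable_model):
    rows = _small_table(n_classes=2, n=3)
    with_extra = rows.copy()
    with_extra["stray_column"] = 1.0
    with pytest.raises(SchemaError, match="stray_column"):
        clf.predict(separable_model, with_extra)
    with pytest.raises(SchemaError, match="missing"):
        clf.predict(separable_model, rows.drop(columns=["FD"]))


def test_predict_scores_lie_in_unit_interval(separable_model, separable_table):
    scores = clf.predict(separable_model, separable_table.head(50))
    cols = [f"score_{c}" for c in separable_model.class_ids]
    assert ((scores[cols] >= 0) & (scores[cols] <= 1)).all().all()


# -------------------------------------------------------------- evaluation

def test_evaluate_perfect_scores_give_exact_accuracy_and_mse(separable_table):
    from conftest import OneHotStub

    labels = separable_table["class_id"].to_numpy()
    stub = OneHotStub(sorted(set(labels)), labels)
    report = clf.evaluate(stub, separable_table, "testing")
    assert report.accuracy == 100.0
    assert report.mse == 0.0
    assert report.error == 0.0
    for points in report.roc.values():
        assert clf.roc_auc(points) == pytest.approx(1.0)


def test_evaluate_confusion_matrix_structure(separable_model, separable_table):
    report = clf.evaluate(separable_model, separable_table)
    assert report.confusion.sum() == len(separable_table)
    counts = separable_table.groupby("class_id").size()
    assert np.array_equal(
        report.confusion.sum(axis=1), counts.loc[report.class_ids].to_numpy()
    )
    assert report.accuracy + report.error == 100.0


def test_evaluate_chance_level_on_shuffled_labels():
    table = rm.sample_feature_table(separable_class_specs(15), 40, seed=8)
    rng = np.random.default_rng(0)
    table["class_id"] = rng.permutation(table["class_id"].to_numpy())
    train, test = clf.split_dataset(table, 0.7, seed=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        model = clf.train_br(train, n_hidden=3, config=FAST)
    assert clf.evaluate(model, test).accuracy == pytest.approx(100 / 15, abs=5.0)


def test_roc_curves_are_monotone_staircases(separable_model, separable_table):
    report = clf.evaluate(separable_model, separable_table)
    for points in report.roc.values():
        assert np.allclose(points[0], [0, 0]) and np.allclose(points[-1], [1, 1])
        assert np.all(np.diff(points, axis=0) >= 0)


def test_combined_accuracy_is_count_weighted_mean():
    assert clf.combine_stage_accuracies([(6887, 91.6), (2952, 88.5)]) == pytest.approx(
        90.7, abs=0.05
    )
    assert clf.combine_stage_accuracies([(10, 100.0), (10, 0.0)]) == 50.0


# ---------------------------------------------------------- model selection

def test_fit_flags_implement_no_overfit_rule():
    assert clf.fit_flags(0.02, 0.01, 90, 88) == ["underfit-suspect"]
    assert clf.fit_flags(0.01, 0.02, 99, 80) == ["overfit-suspect"]
    assert clf.fit_flags(0.01, 0.02, 90, 88) == []


def test_neuron_trimming_reports_each_configuration():
    table = _small_table(n_classes=4, n=30)
    report = clf.neuron_trimming(
        table, neuron_counts=[4, 2], seeds=[0], config=FAST
    )
    assert sorted(report.table["n_hidden"].unique()) == [2, 4]
    assert {"train_mse", "test_mse", "overall_accuracy", "flags"} <= set(
        report.table.columns
    )
    assert report.recommended_n_hidden in (2, 4)
    with pytest.raises(ValueError):
        clf.neuron_trimming(table, neuron_counts=[])


def test_retrain_on_union_of_datasets():
    old = _small_table(n_classes=4, n=30, seed=0)
    new = _small_table(n_classes=4, n=15, seed=1)
    model, reports = clf.retrain(old, new, n_hidden=4, config=FAST, seed=0)
    assert reports["training"].n + reports["testing"].n == len(old) + len(new)
    # empty new table falls back to the old table alone, deterministically
    m2, _ = clf.retrain(old, old.iloc[0:0], n_hidden=4, config=FAST, seed=0)
    m3, _ = clf.retrain(old, None, n_hidden=4, config=FAST, seed=0)
    assert np.array_equal(m2.W1, m3.W1)
    with pytest.raises(SchemaError):
        clf.retrain(old, new.drop(columns=["FD"]), n_hidden=4, config=FAST)


def test_retrain_warm_start_keeps_class_map():
    old = _small_table(n_classes=4, n=30, seed=0)
    base = clf.train_br(
        clf.split_dataset(old, 0.7, seed=0)[0], n_hidden=4, config=FAST
    )
    new = _small_table(n_classes=4, n=15, seed=1)
    model, _ = clf.retrain(old, new, config=FAST, warm_start=base)
    assert model.class_ids == base.class_ids
    assert model.n_hidden == base.n_hidden


# ------------------------------------------------------------- persistence

def test_model_json_roundtrip(tmp_path, separable_model, separable_table):
    path = tmp_path / "model.json"
    separable_model.save(path)
    loaded = clf.NetworkModel.load(path)
    rows = separable_table.head(20)
    pd.testing.assert_frame_equal(
        clf.predict(separable_model, rows), clf.predict(loaded, rows)
    )
    assert loaded.gamma == separable_model.gamma


@settings(deadline=None, max_examples=20)
@given(n=st.integers(2, 500), frac=st.floats(0.1, 0.9))
def test_split_size_floor_property(n, frac):
    table = pd.DataFrame({"class_id": np.arange(n)})
    train, test = clf.split_dataset(table, frac, seed=0)
    assert len(train) == int(np.floor(frac * n))
    assert len(train) + len(test) == n
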