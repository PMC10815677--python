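"""Cross-validation, tuning, importances, RFE and LASSO selection."""

import numpy as np
import pandas as pd
import pytest

from methylpanel.selection_engines import (
    BoostGrid,
    ForestGrid,
    cv_evaluate,
    default_grid,
    importance_bt,
    importance_rf,
    lasso_select,
    make_learner,
    rfe,
    selection_from_trace,
    tune,
    _l1_logistic,
)


def planted_cohort(make_ds, rng, n=120, p=8, n_planted=2, effect=0.35):
    """First ``n_planted`` features shifted in cases, the rest pure noise."""
    n_cases = n // 2
    values = rng.uniform(0.1, 0.5, size=(n, p))
    values[:n_cases, :n_planted] += effect
    values = np.clip(values, 0, 1)
    groups = ["case"] * n_cases + ["control"] * (n - n_cases)
    return make_ds(values, groups)


def test_default_grids_cover_published_winning_settings():
    fg = default_grid("rf")
    bg = default_grid("bt")
    assert {2, 3} <= set(fg.mtry)
    assert {6, 10} <= set(bg.rounds)
    assert {2, 4} <= set(bg.depth)


# -- cross-validated evaluation --------------------------------------------

def test_cv_separable_accuracy_near_one(make_ds, rng):
    ds = planted_cohort(make_ds, rng, effect=0.5)
    for method, params in [
        ("rf", {"mtry": 2, "n_trees": 25}),
        ("bt", {"rounds": 10, "depth": 2}),
    ]:
        m = cv_evaluate(method, ds.values, ds.y, params, k=5, seed=1)
        assert m.accuracy >= 0.95


def test_cv_deterministic_given_seed(make_ds, rng):
    ds = planted_cohort(make_ds, rng)
    a = cv_evaluate("rf", ds.values, ds.y, {"mtry": 2, "n_trees": 25}, k=5, seed=3)
    b = cv_evaluate("rf", ds.values, ds.y, {"mtry": 2, "n_trees": 25}, k=5, seed=3)
    assert a == b


def test_cv_permutation_null_near_chance(make_ds):
    accs = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0, 1, size=(100, 5))
        groups = list(rng.permutation(["case"] * 60 + ["control"] * 40))
        ds = make_ds(values, groups)
        m = cv_evaluate("bt", ds.values, ds.y, {"rounds": 10, "depth": 2}, k=5, seed=seed)
        accs.append(m.accuracy)
    assert abs(np.mean(accs) - 0.5) < 0.08


def test_cv_requires_k_members_per_class(make_ds, rng):
    ds = planted_cohort(make_ds, rng, n=12)
    with pytest.raises(ValueError, match="at least k"):
        cv_evaluate("rf", ds.values, ds.y, {"mtry": 1, "n_trees": 10}, k=10, seed=0)


# -- hyperparameter tuning --------------------------------------------------

def test_tune_single_point_grid(make_ds, rng):
    ds = planted_cohort(make_ds, rng)
    grid = ForestGrid(mtry=(3,), n_trees=20)
    params, _ = tune("rf", ds.values, ds.y, grid, "accuracy", k=5, seed=0)
    assert params == {"mtry": 3, "n_trees": 20}


def test_tune_prefers_dominating_point(make_ds, rng):
    """Two features predictive only jointly (XOR-like): depth-2 boosted
    trees dominate stumps, and the grid search must find that."""
    n = 200
    a = rng.random(n) < 0.5
    b = rng.random(n) < 0.5
    label = a ^ b
    values = np.column_stack(
        [
            np.where(a, 0.7, 0.3) + rng.normal(0, 0.02, n),
            np.where(b, 0.7, 0.3) + rng.normal(0, 0.02, n),
        ]
    ).clip(0, 1)
    ds = make_ds(values, ["case" if l else "control" for l in label])
    grid = BoostGrid(rounds=(30,), depth=(1, 2))
    params, metrics = tune("bt", ds.values, ds.y, grid, "accuracy", k=5, seed=2)
    assert params["depth"] == 2
    assert metrics.accuracy > 0.9


# -- importances ------------------------------------------------------------

def test_rf_importance_ranks_planted_feature_first(make_ds, rng):
    ds = planted_cohort(make_ds, rng, p=6, n_planted=1, effect=0.45)
    model = make_learner("rf", {"mtry": 2, "n_trees": 50}, seed=0)
    model.fit(ds.values.to_numpy(), ds.y)
    imp = importance_rf(model, ds.values, ds.y, seed=0)
    assert imp.idxmax() == ds.cpg_names[0]
    assert imp.drop(ds.cpg_names[0]).abs().max() < 0.05  # noise ~ zero
    imp2 = importance_rf(model, ds.values, ds.y, seed=0)
    pd.testing.assert_series_equal(imp, imp2)


def test_bt_importance_is_probability_vector(make_ds, rng):
    ds = planted_cohort(make_ds, rng, p=6, n_planted=2)
    model = make_learner("bt", {"rounds": 10, "depth": 2}, seed=0)
    model.fit(ds.values.to_numpy(), ds.y)
    imp = importance_bt(model, ds.cpg_names)
    assert imp.sum() == pytest.approx(1.0)
    assert (imp >= 0).all()


def test_bt_importance_single_carrier_feature(make_ds, rng):
    """One perfectly separating feature plus noise: all gain on it."""
    n = 100
    sep = np.concatenate([np.full(50, 0.8), np.full(50, 0.2)])
    noise = rng.uniform(0.4, 0.6, n)
    ds = make_ds(np.column_stack([sep, noise]), ["case"] * 50 + ["control"] * 50)
    model = make_learner("bt", {"rounds": 3, "depth": 1}, seed=0)
    model.fit(ds.values.to_numpy(), ds.y)
    imp = importance_bt(model, ds.cpg_names)
    assert imp.iloc[0] == pytest.approx(1.0)
    assert imp.iloc[1] == 0.0


# -- recursive feature elimination -----------------------------------------

def test_rfe_trace_structure(make_ds, rng):
    ds = planted_cohort(make_ds, rng, n=100, p=6, effect=0.4)
    res = rfe(ds, "rf", "accuracy", grid=ForestGrid(mtry=(2,), n_trees=15), k=4, seed=1, n_repeats=2)
    sizes = [len(r.features) for r in res.trace]
    assert sizes[0] == 6
    assert all(b < a for a, b in zip(sizes, sizes[1:]))
    total_eliminated = sum(len(r.eliminated) for r in res.trace)
    assert total_eliminated == 6
    assert set(res.trace[-1].features) == set(res.trace[-1].eliminated) or len(res.trace[-1].features) == len(res.trace[-1].eliminated)
    assert res.selected  # something got selected
    assert res.metric_value == max(r.accuracy for r in res.trace)


def test_rfe_single_feature(make_ds, rng):
    ds = planted_cohort(make_ds, rng, n=60, p=2, n_planted=1)
    res = rfe(ds, "rf", "accuracy", grid=ForestGrid(mtry=(1,), n_trees=10),
              features=[ds.cpg_names[0]], k=3, seed=0, n_repeats=2)
    assert len(res.trace) == 1
    assert res.selected == frozenset({ds.cpg_names[0]})


def test_rfe_bt_drops_unused_features_in_one_step(make_ds, rng):
    ds = planted_cohort(make_ds, rng, n=120, p=10, n_planted=2, effect=0.45)
    res = rfe(ds, "bt", "accuracy", grid=BoostGrid(rounds=(5,), depth=(2,)), k=4, seed=1)
    # a shallow model on 10 features leaves several unused -> bulk elimination
    assert any(len(r.eliminated) > 1 for r in res.trace)
    for r in res.trace:
        if len(r.eliminated) > 1:
            assert all(r.importances[f] == 0 for f in r.eliminated)


def test_rfe_trace_independent_of_criterion_with_degenerate_grid(make_ds, rng):
    ds = planted_cohort(make_ds, rng, n=80, p=4)
    grid = ForestGrid(mtry=(2,), n_trees=10)
    acc = rfe(ds, "rf", "accuracy", grid=grid, k=4, seed=7, n_repeats=2)
    spec = rfe(ds, "rf", "specificity", grid=grid, k=4, seed=7, n_repeats=2)
    assert [r.features for r in acc.trace] == [r.features for r in spec.trace]
    derived = selection_from_trace("rf", "specificity", acc.trace)
    assert derived.selected == spec.selected
    assert derived.metric_value == spec.metric_value


def test_rfe_recovers_planted_features(make_ds):
    """Two complementary planted markers (each imperfect alone) survive
    elimination; a strong redundant pair would legitimately collapse to one."""
    hits = 0
    for seed in range(5):
        rng = np.random.default_rng(100 + seed)
        ds = planted_cohort(make_ds, rng, n=150, p=8, n_planted=2, effect=0.18)
        res = rfe(ds, "rf", "accuracy", grid=ForestGrid(mtry=(2,), n_trees=25),
                  k=4, seed=seed, n_repeats=2)
        hits += set(ds.cpg_names[:2]) <= res.selected
    assert hits >= 4


# -- LASSO ------------------------------------------------------------------

def test_lasso_selects_overwhelming_feature(make_ds):
    for seed in range(3):
        rng = np.random.default_rng(seed)
        ds = planted_cohort(make_ds, rng, n=150, p=10, n_planted=1, effect=0.45)
        res = lasso_select(ds, k=5, seed=seed)
        assert ds.cpg_names[0] in res.selected
        assert len(res.selected) <= 5
        assert res.method == "lasso" and res.criterion == "not_applicable"
        assert res.trace == ()


def test_lasso_lambda_max_zeroes_everything(make_ds, rng):
    ds = planted_cohort(make_ds, rng, n=80, p=5, effect=0.3)
    X = ds.values.to_numpy()
    Xs = (X - X.mean(0)) / X.std(0)
    y = ds.y
    lam_max = float(np.max(np.abs(Xs.T @ (y - y.mean()))) / len(y))
    model = _l1_logistic(Xs, y, 2 * lam_max)
    assert np.allclose(model.coef_, 0.0)


def test_lasso_deterministic(make_ds, rng):
    ds = planted_cohort(make_ds, rng, n=100, p=6)
    a = lasso_select(ds, k=5, seed=4)
    b = lasso_select(ds, k=5, seed=4)
    assert a.selected == b.selected and a.details["lambda"] == b.details["lambda"]
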