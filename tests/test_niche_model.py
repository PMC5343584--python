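import numpy as np
import pandas as pd
import pytest

from coastrange import (
    HyperparameterGrid,
    ensemble_predict,
    enumerate_predictor_sets,
    fit_brt,
    mpa_score,
    predictor_contributions,
    select_ensemble,
    temporal_transferability,
)
from coastrange.errors import UndefinedContributionError
from coastrange.niche_model import SubsetResult, TransferabilityResult
from conftest import make_stack

# ---------------------------------------------------------------- subsets


def test_enumerate_three_uncorrelated_gives_seven(stack_factory):
    rng = np.random.default_rng(0)
    stack = stack_factory(
        {n: rng.normal(size=(30, 4)) for n in ("a", "b", "c")}, range(2000, 2004)
    )
    assert len(enumerate_predictor_sets(stack, rho_max=0.8)) == 7


def test_enumerate_excludes_correlated_pair(stack_factory):
    rng = np.random.default_rng(1)
    a = rng.normal(size=(30, 4))
    b = a + rng.normal(scale=0.01, size=a.shape)  # |rho(a,b)| ~ 1
    c = rng.normal(size=(30, 4))
    stack = stack_factory({"a": a, "b": b, "c": c}, range(2000, 2004))
    subsets = {frozenset(s) for s in enumerate_predictor_sets(stack, rho_max=0.8)}
    assert subsets == {
        frozenset({"a"}), frozenset({"b"}), frozenset({"c"}),
        frozenset({"a", "c"}), frozenset({"b", "c"}),
    }


def test_enumerate_single_predictor(stack_factory):
    stack = stack_factory(
        {"a": np.random.default_rng(2).normal(size=(10, 2))}, range(2000, 2002)
    )
    assert enumerate_predictor_sets(stack) == [("a",)]


def test_enumerate_max_size_caps_subsets(stack_factory):
    rng = np.random.default_rng(3)
    stack = stack_factory(
        {n: rng.normal(size=(40, 3)) for n in "abcd"}, range(2000, 2003)
    )
    subsets = enumerate_predictor_sets(stack, rho_max=0.8, max_size=2)
    assert max(len(s) for s in subsets) == 2


# ---------------------------------------------------------------- fit_brt


def separable_train(n=120, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 10, size=n)
    z = rng.uniform(0, 10, size=n)
    return pd.DataFrame({"x": x, "z": z, "presence": (x < 5).astype(int)})


SMALL_GRID = HyperparameterGrid(n_trees=(100,), learning_rates=(0.01,),
                                max_complexity=1)


def test_monotone_constraint_conformance():
    rng = np.random.default_rng(4)
    train = pd.DataFrame(
        {
            "sst": rng.uniform(0, 10, 200),
            "cui": rng.uniform(0, 10, 200),
            "presence": rng.integers(0, 2, 200),
        }
    )
    model = fit_brt(train, ("sst", "cui"), {"sst": -1, "cui": 1},
                    HyperparameterGrid(n_trees=(150,), learning_rates=(0.01,),
                                       max_complexity=2), seed=0)
    probe = pd.DataFrame({"sst": np.linspace(0, 10, 50), "cui": 5.0})
    p = model.predict_proba(probe)
    assert (np.diff(p) <= 1e-12).all()  # non-increasing in SST
    probe2 = pd.DataFrame({"sst": 5.0, "cui": np.linspace(0, 10, 50)})
    p2 = model.predict_proba(probe2)
    assert (np.diff(p2) >= -1e-12).all()  # non-decreasing in CUI


def test_separable_data_perfect_holdout():
    train = separable_train(seed=5)
    test = separable_train(seed=6)
    model = fit_brt(
        train, ("x",), {"x": -1},
        HyperparameterGrid(n_trees=(500,), learning_rates=(0.01,),
                           allow_custom=True),
        seed=0,
    )
    p = model.predict_proba(test)
    y = test["presence"].to_numpy()
    sens = ((p >= 0.5) & (y == 1)).sum() / (y == 1).sum()
    spec = ((p < 0.5) & (y == 0)).sum() / (y == 0).sum()
    assert sens == 1.0 and spec == 1.0
    # near-zero deviance on the training rows
    pt = np.clip(model.predict_proba(train), 1e-9, 1 - 1e-9)
    yt = train["presence"].to_numpy()
    dev = -2 * np.mean(yt * np.log(pt) + (1 - yt) * np.log(1 - pt))
    assert dev < 0.2


def test_cv_selects_among_grid_points():
    train = separable_train(n=80, seed=7)
    grid = HyperparameterGrid(n_trees=(100, 150), learning_rates=(0.01,),
                              max_complexity=1)
    model = fit_brt(train, ("x",), {"x": -1}, grid, seed=0, cv_folds=4)
    assert model.spec.n_trees in (100, 150)
    assert np.isfinite(model.spec.cv_deviance)


def test_nonstandard_learning_rate_rejected():
    with pytest.raises(ValueError):
        HyperparameterGrid(learning_rates=(0.05,))
    # explicit override allowed
    HyperparameterGrid(learning_rates=(0.05,), allow_custom=True)


def test_nonstandard_tree_count_rejected():
    with pytest.raises(ValueError):
        HyperparameterGrid(n_trees=(123,))


def test_one_class_training_rejected():
    train = pd.DataFrame({"x": [1.0, 2.0, 3.0], "presence": [1, 1, 1]})
    with pytest.raises(ValueError):
        fit_brt(train, ("x",), {"x": -1}, SMALL_GRID)


def test_missing_sign_rejected():
    train = separable_train(n=40)
    with pytest.raises(ValueError):
        fit_brt(train, ("x",), {}, SMALL_GRID)


# ---------------------------------------------------------------- MPA


def test_mpa_perfect_separation():
    probs = np.array([1.0, 1.0, 0.0, 0.0, 0.0, 0.0])
    thr, mpa = mpa_score(probs, np.array([0, 1]))
    assert thr == 1.0
    assert mpa == pytest.approx(2 / 6)


def test_mpa_worked_example():
    probs = np.array([0.9, 0.8, 0.7, 0.2, 0.1, 0.05])
    thr, mpa = mpa_score(probs, np.array([0, 1, 2, 3]), sens_min=0.9)
    assert thr == pytest.approx(0.2)
    assert mpa == pytest.approx(4 / 6)


def test_mpa_uniform_probabilities():
    probs = np.full(10, 0.4)
    thr, mpa = mpa_score(probs, np.array([2, 5]))
    assert mpa == 1.0


def test_mpa_monotone_in_sens_min():
    rng = np.random.default_rng(8)
    probs = rng.uniform(size=50)
    pres = rng.choice(50, size=12, replace=False)
    mpas = [mpa_score(probs, pres, sens_min=s)[1] for s in (0.5, 0.7, 0.9, 1.0)]
    assert all(a <= b for a, b in zip(mpas, mpas[1:]))


def test_mpa_requires_presences():
    with pytest.raises(ValueError):
        mpa_score(np.array([0.1, 0.2]), np.array([], dtype=int))


# ---------------------------------------------------------------- selection


def _result(mpas: dict[str, float]) -> TransferabilityResult:
    return TransferabilityResult(
        subsets=[
            SubsetResult(tuple(k.split("+")), {(2010, 2012): v, (2012, 2010): v})
            for k, v in mpas.items()
        ]
    )


def test_select_single_candidate():
    res = _result({"a": 0.5})
    assert [s.predictors for s in select_ensemble(res)] == [("a",)]


def test_select_lowest_decile():
    res = _result({"a": 0.2, "b": 0.21, "c": 0.8})
    chosen = {s.predictors[0] for s in select_ensemble(res)}
    assert chosen == {"a", "b"}


def test_select_keeps_ties_at_minimum():
    res = _result({"a": 0.3, "b": 0.3, "c": 0.3})
    assert len(select_ensemble(res)) == 3


def test_best_is_lowest_mean_mpa():
    res = _result({"a": 0.5, "b": 0.3})
    assert res.best().predictors == ("b",)


# ---------------------------------------------------------------- ensemble


def test_ensemble_identical_members_equals_member(stack_factory):
    rng = np.random.default_rng(9)
    stack = stack_factory({"x": rng.uniform(0, 10, size=(25, 3)),
                           "z": rng.uniform(0, 10, size=(25, 3))},
                          range(2000, 2003))
    frame = stack.frame.copy()
    frame["presence"] = (frame["x"] < 5).astype(int)
    m = fit_brt(frame, ("x",), {"x": -1}, SMALL_GRID, seed=0)
    single = ensemble_predict([m], stack)
    double = ensemble_predict([m, m], stack)
    np.testing.assert_allclose(single.values, double.values)


def test_ensemble_mean_and_order_invariance(stack_factory):
    rng = np.random.default_rng(10)
    stack = stack_factory({"x": rng.uniform(0, 10, size=(30, 2)),
                           "z": rng.uniform(0, 10, size=(30, 2))},
                          range(2000, 2002))
    frame = stack.frame.copy()
    frame["presence"] = (frame["x"] < 5).astype(int)
    m1 = fit_brt(frame, ("x",), {"x": -1}, SMALL_GRID, seed=0)
    frame2 = frame.copy()
    frame2["presence"] = (frame2["z"] < 5).astype(int)
    m2 = fit_brt(frame2, ("z",), {"z": -1}, SMALL_GRID, seed=0)
    ab = ensemble_predict([m1, m2], stack)
    ba = ensemble_predict([m2, m1], stack)
    np.testing.assert_allclose(ab.values, ba.values)
    p1 = ensemble_predict([m1], stack).values
    p2 = ensemble_predict([m2], stack).values
    np.testing.assert_allclose(ab.values, (p1 + p2) / 2)
    assert (ab.values <= np.maximum(p1, p2) + 1e-12).all()
    assert (ab.values >= np.minimum(p1, p2) - 1e-12).all()


def test_ensemble_missing_predictor_rejected(stack_factory):
    rng = np.random.default_rng(11)
    stack = stack_factory({"x": rng.uniform(size=(10, 2))}, range(2000, 2002))
    frame = stack.frame.copy()
    frame["z"] = rng.uniform(size=len(frame))
    frame["presence"] = (frame["z"] < 0.5).astype(int)
    m = fit_brt(frame, ("z",), {"z": -1}, SMALL_GRID, seed=0)
    with pytest.raises(ValueError):
        ensemble_predict([m], stack)


# ---------------------------------------------------------------- contributions


def test_contributions_transform_arithmetic():
    # a added to {c} -> MPA 0.4; b added to {c} -> MPA 0.7
    res = _result({"a": 0.9, "b": 0.9, "c": 0.9, "a+c": 0.4, "b+c": 0.7})
    contrib = predictor_contributions(res, method="transform")
    assert sum(contrib.values()) == pytest.approx(100.0, abs=1e-9)
    # transformed scores 0.6 vs 0.3: a contributes twice as much as b
    assert contrib["a"] / contrib["b"] == pytest.approx(2.0, rel=1e-9)


def test_contributions_equal_mpa_equal_share():
    res = _result({"a": 0.5, "b": 0.5, "a+b": 0.4})
    contrib = predictor_contributions(res, method="transform")
    assert contrib["a"] == pytest.approx(50.0)
    assert contrib["b"] == pytest.approx(50.0)


def test_contributions_reduction_method():
    res = _result({"a": 0.9, "b": 0.9, "c": 0.9, "a+c": 0.4, "b+c": 0.7})
    contrib = predictor_contributions(res, method="reduction")
    # drops: a 0.5, b 0.2, c mean of (0.9-0.4, 0.9-0.7) = 0.35
    total = 0.5 + 0.2 + 0.35
    assert contrib["a"] == pytest.approx(100 * 0.5 / total)
    assert contrib["b"] == pytest.approx(100 * 0.2 / total)


def test_contributions_sum_to_100():
    rng = np.random.default_rng(12)
    mpas = {}
    for names in ("a", "b", "c", "a+b", "a+c", "b+c", "a+b+c"):
        mpas[names] = float(rng.uniform(0.1, 0.9))
    for method in ("transform", "reduction"):
        contrib = predictor_contributions(_result(mpas), method=method)
        assert sum(contrib.values()) == pytest.approx(100.0, abs=1e-9)


def test_contributions_never_addable_rejected():
    res = _result({"a": 0.5, "b": 0.6})  # no multi-predictor models
    with pytest.raises(UndefinedContributionError):
        predictor_contributions(res)


# ---------------------------------------------------------------- transferability


def make_labeled_stack(seed=0, n_cells=60):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 10, size=(n_cells, 2))
    z = rng.uniform(0, 10, size=(n_cells, 2))
    stack = make_stack({"x": x, "z": z}, [2010, 2012])
    pres = {
        y: set(
            int(c)
            for c in rng.choice(
                np.flatnonzero(x[:, i] < 4), size=10, replace=False
            )
        )
        for i, y in enumerate([2010, 2012])
    }
    return stack, pres


def test_identical_year_datasets_symmetric_mpa():
    rng = np.random.default_rng(13)
    x = rng.uniform(0, 10, size=(60, 1))
    stack = make_stack({"x": np.repeat(x, 2, axis=1),
                        "z": np.repeat(rng.uniform(0, 10, (60, 1)), 2, axis=1)},
                       [2010, 2012])
    pres_cells = set(int(c) for c in np.flatnonzero(x[:, 0] < 3)[:8])
    pres = {2010: pres_cells, 2012: pres_cells}
    res = temporal_transferability(stack, pres, [("x",)], grid=SMALL_GRID, seed=0)
    vals = list(res.subsets[0].mpa_by_direction.values())
    assert vals[0] == pytest.approx(vals[1])


def test_transferability_ranks_informative_predictor():
    stack, pres = make_labeled_stack(seed=14)
    res = temporal_transferability(stack, pres, [("x",), ("z",)],
                                   grid=SMALL_GRID, seed=0)
    by_name = {s.predictors: s.mean_mpa for s in res.subsets}
    assert by_name[("x",)] < by_name[("z",)]


def test_transferability_requires_presences():
    stack, pres = make_labeled_stack(seed=15)
    pres[2012] = set()
    with pytest.raises(ValueError):
        temporal_transferability(stack, pres, [("x",)], grid=SMALL_GRID)


def test_transferability_requires_two_years(stack_factory):
    stack, pres = make_labeled_stack(seed=16)
    with pytest.raises(ValueError):
        temporal_transferability(stack, {2010: pres[2010]}, [("x",)],
                                 grid=SMALL_GRID)
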