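"""Imputation, rounding, scaling and split-plan machinery."""

import numpy as np
import pandas as pd
import pytest

from ppsc.exceptions import ParameterError, SchemaError
from ppsc.preprocess import (
    ChainedImputer,
    make_split_plan,
    minmax_fit,
    minmax_transform,
    round_integer_features,
)


def _gaussian_with_mask(rng, n=300, p=6, rate=0.2, rho=0.8):
    cov = rho * np.ones((p, p)) + (1 - rho) * np.eye(p)
    X = rng.multivariate_normal(np.zeros(p), cov, size=n)
    mask = rng.random((n, p)) < rate
    mask[:, 0] = False  # keep one complete feature
    Xm = X.copy()
    Xm[mask] = np.nan
    cols = [f"x{j}" for j in range(p)]
    return pd.DataFrame(X, columns=cols), pd.DataFrame(Xm, columns=cols), mask


def test_complete_table_passes_through_with_zero_iterations(rng):
    df = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
    imp = ChainedImputer(seed=0)
    out = imp.fit_transform(df)
    assert np.allclose(out.to_numpy(), df.to_numpy())
    assert imp.state.n_iterations == 0
    assert imp.state.imputation_order == []
    # and transform of complete data is also the identity
    assert np.allclose(imp.transform(df).to_numpy(), df.to_numpy())


def test_collinear_cell_imputed_by_the_linear_prediction(rng):
    a = rng.normal(0, 5, 400)
    df = pd.DataFrame({"a": a, "b": 2 * a, "c": rng.normal(size=400)})
    truth = df.at[5, "b"]
    df.at[5, "b"] = np.nan
    imp = ChainedImputer(seed=0)
    out = imp.fit_transform(df)
    assert out.at[5, "b"] == pytest.approx(truth, abs=0.1)
    # train-fitted regressions apply to new rows without refitting
    new = pd.DataFrame({"a": [3.0], "b": [np.nan], "c": [0.0]})
    assert imp.transform(new).at[0, "b"] == pytest.approx(6.0, abs=0.2)


def test_mice_beats_median_fill_on_correlated_gaussians(rng):
    X, Xm, mask = _gaussian_with_mask(rng)
    completed = ChainedImputer(seed=0).fit_transform(Xm)
    rmse_mice = np.sqrt(np.mean((completed.to_numpy()[mask] - X.to_numpy()[mask]) ** 2))
    medians = Xm.median()
    filled = Xm.fillna(medians)
    rmse_median = np.sqrt(np.mean((filled.to_numpy()[mask] - X.to_numpy()[mask]) ** 2))
    assert rmse_mice < rmse_median


def test_imputation_order_is_fewest_missing_first(rng):
    X, Xm, _ = _gaussian_with_mask(rng)
    Xm["x1"] = np.where(rng.random(len(Xm)) < 0.45, np.nan, X["x1"])
    imp = ChainedImputer(seed=0)
    imp.fit_transform(Xm)
    counts = [Xm[c].isna().sum() for c in imp.state.imputation_order]
    assert counts == sorted(counts)


def test_no_leakage_from_held_out_rows(rng):
    X, Xm, _ = _gaussian_with_mask(rng)
    train, test = Xm.iloc[:200], Xm.iloc[200:]
    imp = ChainedImputer(seed=0)
    imp.fit_transform(train)
    baseline = imp.transform(train.copy())
    _ = imp.transform(test * 100.0)  # perturbed held-out rows
    again = imp.transform(train.copy())
    assert np.allclose(baseline.to_numpy(), again.to_numpy())


def test_all_missing_feature_is_rejected():
    df = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
    with pytest.raises(ParameterError):
        ChainedImputer().fit_transform(df)


def test_schema_mismatch_rejected(rng):
    df = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
    imp = ChainedImputer()
    imp.fit_transform(df)
    with pytest.raises(SchemaError):
        imp.transform(df.rename(columns={"c": "z"}))


@pytest.mark.parametrize("x,want", [(0.4, 0.0), (0.5, 1.0), (1.0, 1.0), (-0.5, -1.0), (2.49, 2.0)])
def test_integer_rounding_half_away_from_zero(x, want):
    df = pd.DataFrame({"v": [x]})
    assert round_integer_features(df, ["v"]).at[0, "v"] == want


def test_binary_features_clipped_to_unit_range():
    df = pd.DataFrame({"b": [-0.4, 0.2, 1.7]})
    out = round_integer_features(df, ["b"], ["b"])
    assert out["b"].tolist() == [0.0, 0.0, 1.0]


def test_minmax_contracts(rng):
    train = pd.DataFrame({"a": [0.0, 5.0, 10.0], "c": [7.0, 7.0, 7.0]})
    state = minmax_fit(train)
    out = minmax_transform(state, train)
    assert out["a"].tolist() == [0.0, 0.5, 1.0]
    assert (out["c"] == 0.0).all()  # constant features map to zero
    test = pd.DataFrame({"a": [20.0], "c": [7.0]})
    assert minmax_transform(state, test).at[0, "a"] == 2.0  # no clipping
    # idempotence at the degenerate fixed point: constant-zero data maps to
    # zero, so a second transform changes nothing
    const = pd.DataFrame({"a": [0.0, 0.0], "c": [0.0, 0.0]})
    st2 = minmax_fit(const)
    once = minmax_transform(st2, const)
    twice = minmax_transform(st2, once)
    assert np.allclose(once.to_numpy(), twice.to_numpy())


def test_split_plan_arithmetic_on_the_cohort_margins():
    y = np.array([1] * 220 + [0] * 361)
    plan = make_split_plan(y, seed=0)
    assert len(plan.test_idx) in (116, 117)
    assert y[plan.test_idx].sum() == 44
    assert len(plan.validation_cycles) == 50
    # each repetition partitions the training indices exactly once
    for rep in range(plan.n_repeats):
        held_out = np.concatenate(
            [va for r, _, _, va in plan.validation_cycles if r == rep])
        assert sorted(held_out) == sorted(plan.train_idx)
    # stratification: fold class ratio within one patient of the global ratio
    ratio = y[plan.train_idx].mean()
    for _, _, tr, va in plan.validation_cycles:
        assert abs(y[va].sum() - ratio * len(va)) <= 1.0


def test_split_plan_rejects_tiny_classes():
    with pytest.raises(ParameterError):
        make_split_plan(np.array([1, 0, 0, 0, 0, 0, 0, 0]))
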