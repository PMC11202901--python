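"""Model zoo, soft voting, metric formulas, tuning and pruning."""

import numpy as np
import pytest
from sklearn.tree import DecisionTreeClassifier

from ppsc.exceptions import ParameterError
from ppsc.modeling import (
    ConfusionMatrix,
    FAMILIES,
    MODEL_GRIDS,
    OPTIMAL_PARAMS,
    auroc,
    auroc_ci,
    build_model,
    confusion_metrics,
    predict_labels,
    soft_vote_proba,
    tune_and_fit,
)


def concordance_oracle(scores, labels):
    """Exhaustive pairwise concordance with ties counted 1/2."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return total / (len(pos) * len(neg))


def test_auroc_equals_concordance_oracle_on_small_instances(rng):
    for _ in range(200):
        n = int(rng.integers(4, 13))
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            continue
        scores = rng.integers(0, 5, n).astype(float)  # coarse grid forces ties
        assert auroc(scores, labels) == pytest.approx(
            concordance_oracle(scores, labels), abs=1e-12)


def test_auroc_degenerate_cases():
    assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
    with pytest.raises(ParameterError):
        auroc([0.5, 0.6], [1, 1])
    rng = np.random.default_rng(0)
    scores = rng.random(4000)
    labels = rng.random(4000) < 0.5
    assert auroc(scores, labels) == pytest.approx(0.5, abs=0.03)


def test_auroc_ci_brackets_the_point_estimate(rng):
    scores = np.concatenate([rng.normal(1, 1, 60), rng.normal(0, 1, 60)])
    labels = np.array([1] * 60 + [0] * 60)
    point = auroc(scores, labels)
    lo, hi = auroc_ci(scores, labels, n_boot=300, seed=0)
    assert lo <= point <= hi


def test_confusion_metrics_match_direct_formulas(rng):
    for _ in range(50):
        tp, fp, fn, tn = rng.integers(1, 60, 4)
        m = confusion_metrics(ConfusionMatrix(tp, fp, fn, tn))
        assert m["recall"] == pytest.approx(tp / (tp + fn))
        assert m["precision"] == pytest.approx(tp / (tp + fp))
        assert m["balanced_accuracy"] == pytest.approx(
            (tp / (tp + fn) + tn / (tn + fp)) / 2)
        assert m["f1"] == pytest.approx(2 * tp / (2 * tp + fp + fn))


def test_confusion_metrics_perfect_and_undefined():
    perfect = confusion_metrics(ConfusionMatrix(10, 0, 0, 10))
    assert all(v == 1.0 for v in perfect.values())
    m = confusion_metrics(ConfusionMatrix(0, 0, 0, 10))  # no positives at all
    assert m["recall"] is None and m["balanced_accuracy"] is None


class _Const:
    def __init__(self, p):
        self.p = p

    def predict_proba(self, X):
        return np.column_stack([np.full(len(X), 1 - self.p), np.full(len(X), self.p)])


def test_soft_vote_is_the_unweighted_mean_and_tie_positive(rng):
    X = np.zeros((4, 2))
    models = {f"m{i}": _Const(p) for i, p in enumerate([0.7, 0.7, 0.7])}
    assert np.allclose(soft_vote_proba(models, X), 0.7)
    split = {f"m{i}": _Const(float(i < 4)) for i in range(8)}
    proba = soft_vote_proba(split, X)
    assert np.allclose(proba, 0.5)
    assert predict_labels(proba).tolist() == [1, 1, 1, 1]  # >= 0.5 is positive
    ps = rng.random(8)
    models = {f"m{i}": _Const(p) for i, p in enumerate(ps)}
    got = soft_vote_proba(models, X)
    assert got[0] == pytest.approx(ps.mean(), abs=1e-12)
    assert ps.min() <= got[0] <= ps.max()
    shuffled = {k: models[k] for k in sorted(models, reverse=True)}
    assert np.allclose(soft_vote_proba(shuffled, X), got)


def test_soft_vote_requires_probability_output():
    class NoProba:
        pass

    with pytest.raises(ParameterError):
        soft_vote_proba({"m": NoProba()}, np.zeros((2, 2)))
    with pytest.raises(ParameterError):
        soft_vote_proba({}, np.zeros((2, 2)))


def test_grids_cover_all_families_and_optima_lie_inside():
    assert set(MODEL_GRIDS) == set(FAMILIES) == set(OPTIMAL_PARAMS)
    for fam, grid in MODEL_GRIDS.items():
        for key, value in OPTIMAL_PARAMS[fam].items():
            assert value in grid[key]


def test_single_point_grid_returns_that_point(rng):
    X = rng.normal(size=(60, 3))
    y = (X[:, 0] + rng.normal(0, 0.5, 60) > 0).astype(int)
    model, best = tune_and_fit("logistic", X, y, seed=0, grid={"C": [0.7]})
    assert best == {"C": 0.7}


def test_linear_svm_separates_separable_data(rng):
    X = np.vstack([rng.normal(3, 0.3, size=(40, 2)), rng.normal(-3, 0.3, size=(40, 2))])
    y = np.array([1] * 40 + [0] * 40)
    model, _ = tune_and_fit("svm_linear", X, y, seed=0,
                            grid={"C": [0.6], "kernel": ["linear"], "degree": [2]})
    assert auroc(model.predict_proba(X)[:, 1], y) == 1.0


def test_every_family_fits_and_emits_probabilities(rng):
    X = rng.normal(size=(80, 4))
    y = (X[:, 0] > 0).astype(int)
    for fam in FAMILIES:
        m = build_model(fam, seed=0, params=OPTIMAL_PARAMS[fam])
        m.fit(X, y)
        p = m.predict_proba(X)[:, 1]
        assert p.shape == (80,)
        assert np.all((p >= 0) & (p <= 1))


def test_cost_complexity_pruning_is_monotone_in_alpha(rng):
    X = rng.normal(size=(300, 5))
    y = (X[:, 0] + 0.5 * X[:, 1] + rng.normal(0, 0.8, 300) > 0).astype(int)
    leaves = []
    for alpha in [0.0, 0.005, 0.01, 0.015, 0.02, 0.025, 0.05, 0.1]:
        t = DecisionTreeClassifier(ccp_alpha=alpha, random_state=0).fit(X, y)
        leaves.append(t.get_n_leaves())
    assert all(b <= a for a, b in zip(leaves, leaves[1:]))
    assert leaves[-1] < leaves[0]
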