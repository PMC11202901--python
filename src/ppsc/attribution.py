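"""Shapley-value attribution for probability-emitting classifiers.

Model-agnostic permutation-sampling estimator: for each explained row, the
marginal contribution of every feature is averaged over random feature
orderings, each paired with one background row drawn from the training
partition. Walking a permutation from the background row to the explained
row telescopes exactly, so local accuracy holds by construction: per row,
the attributions sum to the model prediction minus the mean prediction of
the sampled background rows. The attribution scale is the positive-class
probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ParameterError


@dataclass
class AttributionSummary:
    """Per-row, per-feature attribution matrix plus the global ranking."""

    values: np.ndarray            # (n_rows, n_features), probability scale
    base_values: np.ndarray       # (n_rows,) mean background prediction
    predictions: np.ndarray       # (n_rows,) model output on explained rows
    feature_names: list[str]
    feature_values: np.ndarray    # (n_rows, n_features) raw inputs, for plots

    @property
    def mean_abs(self) -> pd.Series:
        return pd.Series(np.abs(self.values).mean(axis=0), index=self.feature_names)

    @property
    def ranking(self) -> list[str]:
        return self.mean_abs.sort_values(ascending=False, kind="stable").index.tolist()


def sampling_shap(
    predict_fn,
    X_explain,
    background,
    n_permutations: int = 32,
    seed: int = 0,
    feature_names=None,
) -> AttributionSummary:
    """Permutation-sampling Shapley attributions.

    ``predict_fn`` maps an (n, p) array to n scalar outputs (positive-class
    probabilities). ``background`` supplies the reference distribution;
    every permutation is paired with one sampled background row, and each
    permutation contributes p+1 model evaluations (the telescoping walk).
    """
    Xe = np.asarray(X_explain, dtype=float)
    bg = np.asarray(background, dtype=float)
    if bg.ndim != 2 or bg.shape[0] == 0:
        raise ParameterError("background must be a non-empty 2-D sample")
    if Xe.ndim == 1:
        Xe = Xe[None, :]
    n, p = Xe.shape
    if feature_names is None:
        if isinstance(X_explain, pd.DataFrame):
            feature_names = list(X_explain.columns)
        else:
            feature_names = [f"f{j}" for j in range(p)]

    rng = np.random.default_rng(seed)
    values = np.zeros((n, p))
    base = np.zeros(n)
    preds = predict_fn(Xe)

    for i in range(n):
        perms = np.array([rng.permutation(p) for _ in range(n_permutations)])
        bg_rows = bg[rng.integers(0, bg.shape[0], size=n_permutations)]
        # batched telescoping walk: block m holds p+1 rows morphing bg -> x
        batch = np.repeat(bg_rows, p + 1, axis=0).reshape(n_permutations, p + 1, p)
        for m in range(n_permutations):
            for step, j in enumerate(perms[m]):
                batch[m, step + 1:, j] = Xe[i, j]
        out = predict_fn(batch.reshape(-1, p)).reshape(n_permutations, p + 1)
        contrib = np.diff(out, axis=1)  # (M, p): step k adds feature perms[m, k]
        phi = np.zeros(p)
        for m in range(n_permutations):
            phi[perms[m]] += contrib[m]
        values[i] = phi / n_permutations
        base[i] = out[:, 0].mean()

    return AttributionSummary(
        values=values,
        base_values=base,
        predictions=np.asarray(preds, dtype=float),
        feature_names=list(feature_names),
        feature_values=Xe,
    )


def shapley_attributions(
    model_or_fn,
    X_test,
    background,
    n_permutations: int = 32,
    seed: int = 0,
) -> AttributionSummary:
    """Attribution summary for a fitted classifier on test rows.

    Accepts either a prediction callable or an estimator exposing
    ``predict_proba`` (the positive-class column is used).
    """
    if callable(model_or_fn) and not hasattr(model_or_fn, "predict_proba"):
        fn = model_or_fn
    else:
        fn = lambda A: model_or_fn.predict_proba(np.asarray(A, dtype=float))[:, 1]
    names = list(X_test.columns) if isinstance(X_test, pd.DataFrame) else None
    return sampling_shap(fn, X_test, background, n_permutations=n_permutations,
                         seed=seed, feature_names=names)


def rank_and_export(summary: AttributionSummary, k: int = 20) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k mean-|attribution| table plus beeswarm-style plot data.

    The direction summary is the sign of the correlation between a
    feature's value and its attribution (positive: larger values push the
    predicted recovery probability up).
    """
    if k < 1 or k > len(summary.feature_names):
        raise ParameterError("k must be between 1 and the feature count")
    order = summary.ranking[:k]
    mean_abs = summary.mean_abs
    rows = []
    plot_rows = []
    for rank, name in enumerate(order, start=1):
        j = summary.feature_names.index(name)
        vals = summary.values[:, j]
        feats = summary.feature_values[:, j]
        if np.std(feats) > 0 and np.std(vals) > 0:
            direction = float(np.sign(np.corrcoef(feats, vals)[0, 1]))
        else:
            direction = 0.0
        rows.append({"rank": rank, "feature": name, "mean_abs_shap": float(mean_abs[name]),
                     "direction": direction})
        for v, fv in zip(vals, feats):
            plot_rows.append({"feature": name, "rank": rank, "shap_value": float(v),
                              "feature_value": float(fv)})
    return pd.DataFrame(rows), pd.DataFrame(plot_rows)


def save_summary_plot(plot_data: pd.DataFrame, path) -> None:
    """Beeswarm-style summary plot (matplotlib, written to ``path``)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    features = plot_data.sort_values("rank")["feature"].unique()
    fig, ax = plt.subplots(figsize=(8, 0.35 * len(features) + 2))
    rng = np.random.default_rng(0)
    for y, name in enumerate(reversed(features)):
        sub = plot_data[plot_data["feature"] == name]
        fv = sub["feature_value"].to_numpy()
        span = fv.max() - fv.min()
        color = (fv - fv.min()) / span if span > 0 else np.full(len(fv), 0.5)
        ax.scatter(sub["shap_value"], y + rng.normal(0, 0.08, len(sub)),
                   c=color, cmap="coolwarm", s=12, alpha=0.8)
    ax.set_yticks(range(len(features)))
    ax.set_yticklabels(list(reversed(features)))
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("attribution (probability scale)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
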