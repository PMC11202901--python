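"""Train-only preprocessing: chained-equations imputation, integer
rounding, min-max scaling, and the split/fold machinery.

Everything here is fit on a training partition and applied frozen to
held-out data; no statistic ever leaks from validation or test rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer
from sklearn.linear_model import Ridge
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.preprocessing import MinMaxScaler

from .exceptions import ParameterError, SchemaError


@dataclass
class ImputerState:
    """Fitted chained-equations imputer plus its bookkeeping."""

    columns: list[str]
    imputation_order: list[str]
    initial_medians: pd.Series
    n_iterations: int
    converged: bool
    _imputer: IterativeImputer = field(repr=False, default=None)


class ChainedImputer:
    """Round-robin chained-equations imputation with ridge regressions.

    Missing cells start at their feature medians; features are then visited
    from fewest to most missing, each regressed on all the others and its
    missing cells overwritten, cycling until the largest change in an
    imputed cell falls below ``tol`` (on each feature's scale) or
    ``max_iter`` (default 20) cycles elapse. ``transform`` applies the
    train-fitted regressions to new data without refitting.
    """

    def __init__(self, max_iter: int = 20, tol: float = 1e-3, seed: int = 0):
        if max_iter > 20:
            raise ParameterError("imputation iteration cap is 20")
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed
        self.state: ImputerState | None = None

    def fit_transform(self, table: pd.DataFrame) -> pd.DataFrame:
        if table.isna().all(axis=0).any():
            bad = table.columns[table.isna().all(axis=0)].tolist()
            raise ParameterError(f"all-missing feature(s) {bad}; drop them before imputation")
        imp = IterativeImputer(
            estimator=Ridge(alpha=1.0),
            max_iter=self.max_iter,
            tol=self.tol,
            initial_strategy="median",
            imputation_order="ascending",  # fewest missing first
            sample_posterior=False,
            random_state=self.seed,
            keep_empty_features=False,
        )
        import warnings
        from sklearn.exceptions import ConvergenceWarning

        with warnings.catch_warnings():
            # non-convergence inside the iteration cap is a reported state
            # (ImputerState.converged), not a warning condition
            warnings.simplefilter("ignore", ConvergenceWarning)
            completed = imp.fit_transform(table.to_numpy(dtype=float))
        miss = table.isna().sum()
        order = miss[miss > 0].sort_values(kind="stable").index.tolist()
        n_iter = int(imp.n_iter_) if order else 0  # complete tables need no cycles
        self.state = ImputerState(
            columns=list(table.columns),
            imputation_order=order,
            initial_medians=table.median(),
            n_iterations=n_iter,
            converged=bool(n_iter < self.max_iter),
            _imputer=imp,
        )
        return pd.DataFrame(completed, index=table.index, columns=table.columns)

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        if self.state is None:
            raise ParameterError("imputer is not fitted")
        if list(table.columns) != self.state.columns:
            raise SchemaError("column layout differs from the fitting table")
        completed = self.state._imputer.transform(table.to_numpy(dtype=float))
        return pd.DataFrame(completed, index=table.index, columns=table.columns)


def round_integer_features(
    table: pd.DataFrame, integer_features, binary_features=()
) -> pd.DataFrame:
    """Round listed features half-away-from-zero; clip binaries to {0, 1}."""
    df = table.copy()
    for col in integer_features:
        if col not in df.columns:
            continue
        x = df[col].to_numpy(dtype=float)
        df[col] = np.sign(x) * np.floor(np.abs(x) + 0.5)
    for col in binary_features:
        if col in df.columns:
            df[col] = df[col].clip(0, 1)
    return df


@dataclass
class ScalerState:
    columns: list[str]
    data_min: np.ndarray
    data_max: np.ndarray
    _scaler: MinMaxScaler = field(repr=False, default=None)


def minmax_fit(table: pd.DataFrame) -> ScalerState:
    """Fit per-feature min/max on the training partition.

    Constant features map to 0; out-of-range values on later data are
    allowed to fall outside [0, 1] (no clipping).
    """
    sc = MinMaxScaler(clip=False)
    sc.fit(table.to_numpy(dtype=float))
    return ScalerState(
        columns=list(table.columns),
        data_min=sc.data_min_.copy(),
        data_max=sc.data_max_.copy(),
        _scaler=sc,
    )


def minmax_transform(state: ScalerState, table: pd.DataFrame) -> pd.DataFrame:
    if list(table.columns) != state.columns:
        raise SchemaError("column layout differs from the fitting table")
    out = state._scaler.transform(table.to_numpy(dtype=float))
    return pd.DataFrame(out, index=table.index, columns=table.columns)


@dataclass
class SplitPlan:
    """80/20 stratified split plus the repeated-CV fold structure.

    ``validation_cycles`` lists (repeat, fold, subtrain_idx, val_idx)
    positions INTO the training index array; the tuning scheme is 3-fold
    stratified on whatever set it is later given.
    """

    train_idx: np.ndarray
    test_idx: np.ndarray
    validation_cycles: list[tuple[int, int, np.ndarray, np.ndarray]]
    n_repeats: int
    n_folds: int
    tuning_folds: int
    seed: int


def make_split_plan(
    labels,
    seed: int = 0,
    test_size: float = 0.2,
    n_repeats: int = 10,
    n_folds: int = 5,
    tuning_folds: int = 3,
) -> SplitPlan:
    """Stratified 80/20 split and ``n_repeats`` independently shuffled
    stratified ``n_folds``-fold partitions of the training set."""
    y = np.asarray(labels).astype(int)
    if min(np.bincount(y, minlength=2)) < n_folds:
        raise ParameterError("a class has fewer members than folds")
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_size, stratify=y, random_state=seed
    )
    cycles = []
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + 1 + rep)
        for fold, (tr, va) in enumerate(skf.split(train_idx, y[train_idx])):
            cycles.append((rep, fold, train_idx[tr], train_idx[va]))
    return SplitPlan(
        train_idx=train_idx,
        test_idx=test_idx,
        validation_cycles=cycles,
        n_repeats=n_repeats,
        n_folds=n_folds,
        tuning_folds=tuning_folds,
        seed=seed,
    )


def preprocess_fit(
    X_train: pd.DataFrame,
    integer_features=(),
    binary_features=(),
    seed: int = 0,
) -> tuple[pd.DataFrame, ChainedImputer, ScalerState]:
    """Impute -> round integers -> fit scaler, all on training rows only."""
    imputer = ChainedImputer(seed=seed)
    completed = imputer.fit_transform(X_train)
    completed = round_integer_features(completed, integer_features, binary_features)
    scaler = minmax_fit(completed)
    return minmax_transform(scaler, completed), imputer, scaler


def preprocess_apply(
    X_new: pd.DataFrame,
    imputer: ChainedImputer,
    scaler: ScalerState,
    integer_features=(),
    binary_features=(),
) -> pd.DataFrame:
    """Apply train-fitted imputer and scaler to held-out rows."""
    completed = imputer.transform(X_new)
    completed = round_integer_features(completed, integer_features, binary_features)
    return minmax_transform(scaler, completed)
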