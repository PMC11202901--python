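"""Cohort-level statistics: exclusion cascade, assessment shift, group tests.

Three pieces of the analysis live here. The sequential *exclusion cascade*
removes unusable records (duplicates, missing audiometry, bilateral cases,
no qualifying impaired run) in a fixed order, counting removals per rule.
The *assessment shift* compares recovered/non-recovered margins between the
traditional and personalized Siegel variants, with a Pearson chi-square on
the resulting 2x2 table (no continuity correction, matching the primary
analysis; a paired McNemar test is available as an extra). The *group
comparison* reproduces the recovered-vs-non-recovered descriptive table:
Shapiro-Wilk gates t-test vs Mann-Whitney for continuous variables,
chi-square (Fisher's exact for sparse 2x2) for categorical ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .audiometry import DetectionConfig, detect_impaired_range
from .exceptions import ParameterError, SchemaError
from .siegel import _threshold_columns

EXCLUSION_RULES = (
    "duplicate_record",
    "missing_month1_pta",
    "missing_initial_pta",
    "bilateral",
    "no_qualifying_run",
)


@dataclass
class ExclusionReport:
    initial_n: int
    excluded: dict[str, int]
    final_n: int

    def __post_init__(self) -> None:
        assert self.final_n == self.initial_n - sum(self.excluded.values())


def apply_exclusion_cascade(
    cohort: pd.DataFrame,
    config: DetectionConfig = DetectionConfig(),
    order: tuple[str, ...] = EXCLUSION_RULES,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the five exclusion rules sequentially.

    Each patient is removed at the FIRST rule it violates, in the stated
    ``order`` (default: duplicate record; missing one-month affected-ear
    audiometry; missing initial audiometry in either ear; bilateral
    disease; no qualifying impaired run). Duplicates keep their first
    occurrence. Per-step counts depend on the order; final membership does
    not.
    """
    if set(order) != set(EXCLUSION_RULES):
        raise ParameterError(f"order must be a permutation of {EXCLUSION_RULES}")
    df = cohort.copy()
    initial_n = len(df)

    ignore = [c for c in ("patient_id", "planted_violation", "recovered", "latent_prognosis") if c in df.columns]
    data_cols = [c for c in df.columns if c not in ignore]

    aff_t1 = _threshold_columns("aff", "month1")
    aff_t0 = _threshold_columns("aff", "initial")
    una_t0 = _threshold_columns("una", "initial")

    def _violates(df: pd.DataFrame, rule: str) -> pd.Series:
        if len(df) == 0:
            return pd.Series(False, index=df.index, dtype=bool)
        if rule == "duplicate_record":
            return df.duplicated(subset=data_cols, keep="first")
        if rule == "missing_month1_pta":
            return df[aff_t1].isna().any(axis=1)
        if rule == "missing_initial_pta":
            return df[aff_t0 + una_t0].isna().any(axis=1)
        if rule == "bilateral":
            if "bilateral" not in df.columns:
                return pd.Series(False, index=df.index, dtype=bool)
            return df["bilateral"].fillna(0).astype(float) > 0
        if rule == "no_qualifying_run":
            return df[aff_t0].apply(
                lambda r: detect_impaired_range(r.to_numpy(dtype=float), config) is None,
                axis=1,
            )
        raise ParameterError(f"unknown rule {rule!r}")

    counts: dict[str, int] = {}
    for rule in order:
        bad = _violates(df, rule)
        counts[rule] = int(bad.sum())
        df = df.loc[~bad]

    report = ExclusionReport(initial_n=initial_n, excluded=counts, final_n=len(df))
    return df.reset_index(drop=True), report


@dataclass
class ShiftTable:
    """Recovered/non-recovered margins of both variants plus transitions."""

    n: int
    recovered_traditional: int
    recovered_ppsc: int
    n_up: int    # non-recovered (traditional) -> recovered (ppsc)
    n_down: int  # recovered (traditional) -> non-recovered (ppsc)

    @property
    def n_changed(self) -> int:
        return self.n_up + self.n_down

    def contingency(self) -> np.ndarray:
        """2x2 table, rows = variant, cols = (recovered, non-recovered)."""
        return np.array(
            [
                [self.recovered_traditional, self.n - self.recovered_traditional],
                [self.recovered_ppsc, self.n - self.recovered_ppsc],
            ]
        )

    def paired_table(self) -> np.ndarray:
        """2x2 paired agreement table (traditional x ppsc status)."""
        both = self.recovered_traditional - self.n_down
        neither = self.n - self.recovered_traditional - self.n_up
        return np.array([[both, self.n_down], [self.n_up, neither]])


def assessment_shift(traditional: pd.DataFrame, ppsc: pd.DataFrame) -> ShiftTable:
    """Pair the two score tables by patient and count status transitions."""
    t = traditional.set_index("patient_id")["recovered"].astype(bool)
    p = ppsc.set_index("patient_id")["recovered"].astype(bool)
    if set(t.index) != set(p.index) or len(t) != len(p):
        raise SchemaError("traditional and ppsc score tables must cover the same patients")
    p = p.reindex(t.index)
    table = ShiftTable(
        n=len(t),
        recovered_traditional=int(t.sum()),
        recovered_ppsc=int(p.sum()),
        n_up=int((~t & p).sum()),
        n_down=int((t & ~p).sum()),
    )
    # marginal identity by construction; keep as a hard check
    assert table.recovered_ppsc == table.recovered_traditional - table.n_down + table.n_up
    return table


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 count table, df=1, NO continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise SchemaError("expected a 2x2 table")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ParameterError("counts must be non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ParameterError("zero marginal in contingency table")
    stat, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), float(p)


def mcnemar_test(paired_table) -> tuple[float, float]:
    """Paired McNemar test on the traditional x ppsc agreement table.

    Not part of the primary analysis (which treats the two assessments as
    independent samples); provided as the statistically paired alternative.
    """
    from statsmodels.stats.contingency_tables import mcnemar

    res = mcnemar(np.asarray(paired_table), exact=True)
    return float(res.statistic), float(res.pvalue)


@dataclass
class GroupComparison:
    variable: str
    kind: str  # "continuous" | "categorical"
    test: str
    p_value: float | None
    summary_group0: str
    summary_group1: str
    n_missing_group0: int
    n_missing_group1: int
    note: str = ""


def _summ_continuous(x: pd.Series, normal: bool) -> str:
    x = x.dropna()
    if normal:
        return f"{x.mean():.2f} ({x.std():.2f})"
    q1, med, q3 = x.quantile([0.25, 0.5, 0.75])
    return f"{med:.2f} ({q1:.2f}, {q3:.2f})"


def compare_groups(
    cohort: pd.DataFrame,
    continuous: list[str],
    categorical: list[str],
    group_col: str = "recovered",
    alpha_normal: float = 0.05,
) -> pd.DataFrame:
    """Recovered-vs-non-recovered comparison for every listed variable.

    Continuous variables: Shapiro-Wilk in each group; if both look normal
    (p > 0.05) use Welch's t-test and mean (SD) summaries, else
    Mann-Whitney U and median (Q1, Q3). Categorical: chi-square on the
    level x group table; Fisher's exact when a 2x2 table has an expected
    cell below 5. Constant variables are summarized with the test skipped.
    """
    g = cohort[group_col].astype(bool)
    g0, g1 = cohort.loc[~g], cohort.loc[g]
    out: list[GroupComparison] = []

    for var in continuous:
        x0, x1 = g0[var].dropna(), g1[var].dropna()
        miss0, miss1 = g0[var].isna().sum(), g1[var].isna().sum()
        if pd.concat([x0, x1]).nunique() <= 1:
            out.append(GroupComparison(var, "continuous", "skipped", None,
                                       _summ_continuous(g0[var], False), _summ_continuous(g1[var], False),
                                       miss0, miss1, note="constant variable"))
            continue
        normal = True
        for x in (x0, x1):
            if len(x) < 3 or x.nunique() < 3:
                normal = False
                break
            if stats.shapiro(x).pvalue <= alpha_normal:
                normal = False
                break
        if normal:
            stat, p = stats.ttest_ind(x0, x1, equal_var=False)
            test = "t-test"
        else:
            stat, p = stats.mannwhitneyu(x0, x1, alternative="two-sided")
            test = "mann-whitney"
        out.append(GroupComparison(var, "continuous", test, float(p),
                                   _summ_continuous(g0[var], normal), _summ_continuous(g1[var], normal),
                                   miss0, miss1))

    for var in categorical:
        miss0, miss1 = g0[var].isna().sum(), g1[var].isna().sum()
        tab = pd.crosstab(cohort[var], g)
        n0, n1 = len(g0[var].dropna()), len(g1[var].dropna())

        def _summ(sub: pd.Series, n: int) -> str:
            counts = sub.dropna().value_counts().sort_index()
            return "; ".join(f"{lvl}: {c} ({100 * c / max(n, 1):.2f}%)" for lvl, c in counts.items())

        if tab.shape[0] < 2 or tab.shape[1] < 2:
            out.append(GroupComparison(var, "categorical", "skipped", None,
                                       _summ(g0[var], n0), _summ(g1[var], n1), miss0, miss1,
                                       note="constant variable"))
            continue
        expected = stats.contingency.expected_freq(tab.to_numpy())
        if tab.shape == (2, 2) and (expected < 5).any():
            _, p = stats.fisher_exact(tab.to_numpy())
            test = "fisher"
        else:
            _, p, _, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
            test = "chi-square"
        out.append(GroupComparison(var, "categorical", test, float(p),
                                   _summ(g0[var], n0), _summ(g1[var], n1), miss0, miss1))

    return pd.DataFrame([vars(c) for c in out])
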