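"""Exclusion cascade, assessment shift and the group-comparison table."""

import numpy as np
import pandas as pd
import pytest

from ppsc.cohort_stats import (
    EXCLUSION_RULES,
    apply_exclusion_cascade,
    assessment_shift,
    chi_square_2x2,
    compare_groups,
    mcnemar_test,
)
from ppsc.exceptions import ParameterError, SchemaError
from ppsc.simulate import GeneratorConfig, generate_cohort


def _score_frames(traditional, ppsc):
    ids = [f"P{i}" for i in range(len(traditional))]
    t = pd.DataFrame({"patient_id": ids, "recovered": traditional})
    p = pd.DataFrame({"patient_id": ids, "recovered": ppsc})
    return t, p


def test_shift_counts_match_pairwise_oracle(rng):
    for _ in range(20):
        n = int(rng.integers(5, 80))
        a = rng.random(n) < 0.5
        b = rng.random(n) < 0.5
        table = assessment_shift(*_score_frames(a, b))
        assert table.recovered_traditional == int(a.sum())
        assert table.recovered_ppsc == int(b.sum())
        assert table.n_up == sum(1 for x, y in zip(a, b) if not x and y)
        assert table.n_down == sum(1 for x, y in zip(a, b) if x and not y)
        # marginal identity
        assert table.recovered_ppsc == table.recovered_traditional - table.n_down + table.n_up
        assert table.paired_table().sum() == n


def test_identical_scores_give_zero_transitions(rng):
    a = rng.random(40) < 0.4
    table = assessment_shift(*_score_frames(a, a))
    assert table.n_changed == 0
    assert (table.contingency()[0] == table.contingency()[1]).all()


def test_shift_requires_matching_patients():
    t, p = _score_frames([True, False], [True, False])
    p["patient_id"] = ["Q0", "Q1"]
    with pytest.raises(SchemaError):
        assessment_shift(t, p)


def test_chi_square_matches_direct_formula(rng):
    for _ in range(30):
        t = rng.integers(1, 60, size=(2, 2))
        stat, p = chi_square_2x2(t)
        total = t.sum()
        expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / total
        assert stat == pytest.approx(((t - expected) ** 2 / expected).sum(), abs=1e-9)
        assert 0 <= p <= 1


def test_chi_square_trivial_and_error_cases():
    stat, p = chi_square_2x2([[10, 20], [10, 20]])
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)
    with pytest.raises(SchemaError):
        chi_square_2x2([[1, 2, 3], [4, 5, 6]])
    with pytest.raises(ParameterError):
        chi_square_2x2([[0, 0], [3, 4]])


def test_mcnemar_differs_from_unpaired_chi_square():
    # same margins as the unpaired test but a paired view of the 7-up/34-down
    # transition structure: McNemar sees a strongly asymmetric discordance
    paired = [[213, 34], [7, 327]]
    _, p_mcnemar = mcnemar_test(paired)
    _, p_chi2 = chi_square_2x2([[247, 334], [220, 361]])
    assert p_mcnemar < 0.001 < p_chi2


@pytest.fixture(scope="module")
def planted_cohort():
    cfg = GeneratorConfig(n_patients=120, seed=21, violations=(2, 7, 5, 4, 3))
    return generate_cohort(cfg)


def test_cascade_counts_match_plants(planted_cohort):
    kept, report = apply_exclusion_cascade(planted_cohort)
    assert report.initial_n == 120 + 21
    assert report.excluded == {
        "duplicate_record": 2,
        "missing_month1_pta": 7,
        "missing_initial_pta": 5,
        "bilateral": 4,
        "no_qualifying_run": 3,
    }
    assert report.final_n == 120
    assert (kept["planted_violation"] == "").all()


def test_cascade_final_membership_is_order_invariant(planted_cohort):
    kept_default, _ = apply_exclusion_cascade(planted_cohort)
    reordered = tuple(reversed(EXCLUSION_RULES))
    kept_reordered, rep = apply_exclusion_cascade(planted_cohort, order=reordered)
    assert set(kept_default["patient_id"]) == set(kept_reordered["patient_id"])
    assert sum(rep.excluded.values()) == 21


def test_cascade_on_clean_cohort_removes_nobody(small_cohort):
    kept, report = apply_exclusion_cascade(small_cohort)
    assert report.final_n == report.initial_n == len(small_cohort)
    assert all(v == 0 for v in report.excluded.values())


def test_cascade_empty_cohort(small_cohort):
    kept, report = apply_exclusion_cascade(small_cohort.iloc[:0])
    assert report.initial_n == report.final_n == 0


def test_compare_groups_detects_planted_shift_and_skips_constants(rng):
    n = 400
    g = rng.random(n) < 0.5
    df = pd.DataFrame({
        "recovered": g,
        "shifted": rng.normal(0, 1, n) + 3.0 * g,   # large location shift
        "constant": np.ones(n),
        "flag": (rng.random(n) < (0.2 + 0.4 * g)),  # rate contrast
        "balanced_flag": rng.random(n) < 0.5,
    })
    out = compare_groups(df, ["shifted", "constant"], ["flag", "balanced_flag"]).set_index("variable")
    assert out.loc["shifted", "p_value"] < 0.001
    assert out.loc["constant", "test"] == "skipped"
    assert out.loc["flag", "p_value"] < 0.001
    assert out.loc["balanced_flag", "p_value"] > 0.01


def test_compare_groups_direction_on_calibrated_cohort():
    cohort = generate_cohort(GeneratorConfig(n_patients=2000, seed=31))
    g = cohort["recovered"].astype(bool)
    # non-recovery stratum older, more dizziness/hypertension, less tinnitus,
    # worse affected-ear PTA -- the published contrast directions
    assert cohort.loc[~g, "age"].median() > cohort.loc[g, "age"].median()
    assert cohort.loc[~g, "dizziness"].mean() > cohort.loc[g, "dizziness"].mean()
    assert cohort.loc[~g, "hypertension"].mean() > cohort.loc[g, "hypertension"].mean()
    assert cohort.loc[~g, "tinnitus"].mean() < cohort.loc[g, "tinnitus"].mean()
    assert cohort.loc[~g, "pta_avg_ae"].median() > cohort.loc[g, "pta_avg_ae"].median()
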