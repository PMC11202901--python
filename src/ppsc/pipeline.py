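"""End-to-end orchestration: simulate -> exclude -> score -> shift ->
preprocess -> model -> attribute, with every artifact stamped for
reproducibility."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .attribution import rank_and_export, shapley_attributions, save_summary_plot
from .cohort_stats import (
    apply_exclusion_cascade,
    assessment_shift,
    chi_square_2x2,
    compare_groups,
)
from .modeling import FAMILIES, run_test_evaluation, run_validation, soft_vote_proba
from .preprocess import make_split_plan
from .siegel import score_cohort
from .simulate import (
    CATEGORICAL_FEATURES,
    CONTINUOUS_FEATURES,
    FEATURE_COLUMNS,
    GeneratorConfig,
    INTEGER_FEATURES,
    generate_cohort,
    read_cohort_csv,
    write_cohort_csv,
)

log = logging.getLogger("ppsc")

BINARY_FEATURES = tuple(
    c for c in CATEGORICAL_FEATURES
    if c not in ("itdi_delay_category", "onset_month", "run_length", "severity_ae", "severity_uae")
)


@dataclass
class PipelineConfig:
    out_dir: str = "ppsc_run"
    seed: int = 0
    n_patients: int = 581
    cohort_csv: str | None = None      # use an existing cohort instead of simulating
    variant: str = "both"              # "ppsc" | "traditional" | "both"
    tune: bool = False                 # grid-search vs printed-optimal parameters
    n_repeats: int = 10
    n_folds: int = 5
    families: tuple = FAMILIES
    shap_rows: int = 40
    shap_permutations: int = 24
    shap_background: int = 100
    n_boot: int = 2000
    make_plots: bool = False
    generator_overrides: dict = field(default_factory=dict)


def _config_hash(cfg: PipelineConfig) -> str:
    """Hash of the scientific configuration (artifact paths excluded)."""
    payload = {k: v for k, v in asdict(cfg).items() if k not in ("out_dir", "make_plots")}
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full analysis and write artifacts into ``cfg.out_dir``.

    Artifacts: cohort.csv (when simulated), exclusion.json, scores.csv,
    shift.json (variant='both' only), table3.csv, report.json,
    shap_summary.csv, manifest.json. Returns the report as a dict.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"seed": cfg.seed, "config_hash": _config_hash(cfg), "version": __version__}

    if cfg.cohort_csv:
        raw = read_cohort_csv(cfg.cohort_csv)
        log.info("loaded cohort from %s (%d rows)", cfg.cohort_csv, len(raw))
    else:
        gen = GeneratorConfig(n_patients=cfg.n_patients, seed=cfg.seed,
                              **cfg.generator_overrides)
        raw = generate_cohort(gen)
        write_cohort_csv(raw, out / "cohort.csv")
        log.info("simulated cohort of %d rows", len(raw))

    cohort, excl = apply_exclusion_cascade(raw)
    (out / "exclusion.json").write_text(json.dumps(
        {"initial_n": excl.initial_n, "excluded": excl.excluded,
         "final_n": excl.final_n, **stamp}, indent=2))
    log.info("exclusion cascade: %d -> %d", excl.initial_n, excl.final_n)

    variants = ["traditional", "ppsc"] if cfg.variant == "both" else [cfg.variant]
    scores = pd.concat([score_cohort(cohort, v) for v in variants], ignore_index=True)
    scores.to_csv(out / "scores.csv", index=False)

    shift_payload = None
    if cfg.variant == "both":
        trad = scores[scores["variant"] == "traditional"]
        ppsc_scores = scores[scores["variant"] == "ppsc"]
        shift = assessment_shift(trad, ppsc_scores)
        stat, p = chi_square_2x2(shift.contingency())
        shift_payload = {
            "n": shift.n,
            "recovered_traditional": shift.recovered_traditional,
            "recovered_ppsc": shift.recovered_ppsc,
            "n_up": shift.n_up, "n_down": shift.n_down, "n_changed": shift.n_changed,
            "contingency": shift.contingency().tolist(),
            "chi2": stat, "p_value": p, **stamp,
        }
        (out / "shift.json").write_text(json.dumps(shift_payload, indent=2))
        log.info("assessment shift: %d changed, chi2=%.3f p=%.3f", shift.n_changed, stat, p)
    else:
        log.info("shift stage skipped: variant=%s needs both score sets", cfg.variant)

    labelled = cohort.copy()
    ppsc_rec = score_cohort(cohort, "ppsc").set_index("patient_id")["recovered"]
    labelled["recovered"] = ppsc_rec.reindex(labelled["patient_id"]).to_numpy()
    table3 = compare_groups(labelled, list(CONTINUOUS_FEATURES), list(CATEGORICAL_FEATURES))
    table3.to_csv(out / "table3.csv", index=False)

    X = labelled[list(FEATURE_COLUMNS)].astype(float)
    y = labelled["recovered"].astype(int).to_numpy()
    plan = make_split_plan(y, seed=cfg.seed, n_repeats=cfg.n_repeats, n_folds=cfg.n_folds)
    params = "tune" if cfg.tune else "optimal"

    val = run_validation(X, y, plan, families=cfg.families, params=params,
                         integer_features=INTEGER_FEATURES, binary_features=BINARY_FEATURES,
                         seed=cfg.seed)
    test, models, (Xtr, ytr, Xte, yte) = run_test_evaluation(
        X, y, plan, families=cfg.families, params=val.params,
        integer_features=INTEGER_FEATURES, binary_features=BINARY_FEATURES,
        seed=cfg.seed, n_boot=cfg.n_boot, return_models=True)
    log.info("best test model: %s (AUROC %.3f)", test.best_model,
             test.table.loc[test.best_model, "auroc"])

    rng = np.random.default_rng(cfg.seed)
    bg_idx = rng.choice(len(Xtr), size=min(cfg.shap_background, len(Xtr)), replace=False)
    n_rows = min(cfg.shap_rows, len(Xte))
    if test.best_model == "soft_vote":
        predict = lambda A: soft_vote_proba(models, A)
    else:
        best = models[test.best_model]
        predict = lambda A: best.predict_proba(np.asarray(A, dtype=float))[:, 1]
    summary = shapley_attributions(predict, Xte.iloc[:n_rows], Xtr.iloc[bg_idx].to_numpy(),
                                   n_permutations=cfg.shap_permutations, seed=cfg.seed)
    ranked, plot_data = rank_and_export(summary, k=min(20, len(FEATURE_COLUMNS)))
    ranked.to_csv(out / "shap_summary.csv", index=False)
    if cfg.make_plots:
        save_summary_plot(plot_data, out / "shap_summary.png")

    report = {
        **stamp,
        "n_cohort": len(cohort),
        "exclusion": {"initial_n": excl.initial_n, "excluded": excl.excluded,
                      "final_n": excl.final_n},
        "shift": shift_payload,
        "validation": {"table": val.table.round(6).to_dict(),
                       "auroc_ci": {k: list(v) for k, v in val.auroc_ci.items()},
                       "n_cycles": val.n_cycles, "best_model": val.best_model},
        "test": {"table": test.table.round(6).to_dict(),
                 "auroc_ci": {k: list(v) for k, v in test.auroc_ci.items()},
                 "best_model": test.best_model},
        "model_params": val.params,
        "top_features": ranked["feature"].tolist(),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    (out / "manifest.json").write_text(json.dumps(
        {**stamp, "config": asdict(cfg)}, indent=2, default=str))
    return report
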