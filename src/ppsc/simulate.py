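"""Seeded synthetic ISSHL cohort generator.

The study's clinical dataset is not public, so every stage of the package
runs against cohorts drawn from this generator. A cohort row carries four
audiograms (affected/unaffected ear at the initial visit and one month
post-treatment), the 50 clinical features used by the prognosis models, a
laterality flag, and labels that are always *emergent*: the recovery status
is recomputed from the audiograms by the Siegel scorer, never planted.

The generative story: each patient has a latent prognosis score in [0, 1].
A prognosis stratum (recovery-leaning with probability
``recovery_target_rate``) selects the stratum-conditional distributions --
audiogram shape mix, initial severity, and the published recovered vs
non-recovered contrasts of the clinical covariates (rates and
median/quartile targets). Post-treatment thresholds shrink the initial loss
toward a per-frequency pre-morbid floor by a recovered fraction drawn from
a prognosis-dependent normal; the gain parameters are calibrated so the
emergent personalized-criteria recovery rate sits at the configured target
(default 0.379). Missingness is injected MCAR at per-feature rates matching
the published missing-value percentages; audiometric summary features and
the outcome are never masked.

Labeled protocol violations (duplicates, missing audiometry, bilateral
cases, audiograms with no qualifying run) can be planted in configurable
counts to exercise the exclusion cascade.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import audiometry
from .audiometry import (
    DetectionConfig,
    FREQUENCIES_KHZ,
    N_FREQS,
    classify_audiogram_shape,
    derive_audiometric_features,
    detect_impaired_range,
)
from .exceptions import ParameterError
from .siegel import assess_patient, _threshold_columns

_Z_QUARTILE = 0.6744897501960817  # standard normal 75th percentile


def _lognorm_params(q1: float, med: float, q3: float) -> tuple[float, float]:
    """Log-normal (mu, sigma) matched to the median and quartiles."""
    mu = math.log(med)
    sigma = (math.log(q3) - math.log(q1)) / (2 * _Z_QUARTILE)
    return mu, sigma


def _norm_params(q1: float, med: float, q3: float) -> tuple[float, float]:
    return med, (q3 - q1) / (2 * _Z_QUARTILE)


# Audiogram shape templates: per-frequency offsets (dB) around the severity
# target, built so the shape classifier round-trips under 5-dB quantization.
_SHAPE_TEMPLATES: dict[str, np.ndarray] = {
    "flat": np.zeros(N_FREQS),
    "ascending": np.array([16.0, 14.0, 12.0, 0.0, -4.0, -11.0, -13.0, -14.0]),
    "descending": np.array([-16.0, -14.0, -12.0, 0.0, 4.0, 11.0, 13.0, 14.0]),
    "u_shaped": np.array([-9.0, -11.0, -7.0, 15.0, 17.0, -3.0, -1.0, -1.0]),
    "deaf": np.zeros(N_FREQS),
}

# Stratum-conditional audiogram shape mix (non-recovery, recovery), from the
# published cohort contrasts.
_SHAPE_PROBS = {
    0: {"ascending": 0.0969, "u_shaped": 0.0471, "descending": 0.3296, "flat": 0.2244, "deaf": 0.3019},
    1: {"ascending": 0.2136, "u_shaped": 0.1272, "descending": 0.2409, "flat": 0.3773, "deaf": 0.0409},
}

# Continuous covariates with stratum-specific (q1, median, q3) targets and a
# distribution family. Entries without stratum contrast use one target.
_CONTINUOUS_PARAMS: dict[str, dict] = {
    "age": {"family": "normal", 0: (47.0, 55.0, 64.0), 1: (38.25, 48.0, 57.0), "clip": (18, 95), "round": 0},
    "triacylglycerol": {"family": "lognormal", 0: (66.5, 99.0, 148.0), 1: (56.0, 82.0, 132.0), "clip": (20, 600), "round": 1},
    "bun": {"family": "lognormal", 0: (12.4, 15.2, 19.58), 1: (11.5, 13.6, 16.0), "clip": (4, 60), "round": 2},
    "creatinine": {"family": "lognormal", 0: (0.71, 0.88, 1.04), 1: (0.70, 0.83, 0.98), "clip": (0.3, 4.0), "round": 2},
    "duration_onset_itdi": {"family": "lognormal", 0: (3.0, 6.0, 16.0), 1: (2.0, 5.0, 8.5), "clip": (0, 90), "round": 0},
    "duration_onset_treatment": {"family": "lognormal", 0: (2.5, 5.0, 12.0), 1: (2.0, 4.0, 8.0), "clip": (0, 90), "round": 0},
    "height": {"family": "normal", 0: (156.0, 162.0, 168.0), 1: (156.0, 162.0, 168.0), "clip": (130, 200), "round": 1},
    "weight": {"family": "normal", 0: (57.0, 65.0, 74.0), 1: (57.0, 65.0, 74.0), "clip": (35, 140), "round": 1},
    "sbp": {"family": "normal", 0: (115.0, 126.0, 138.0), 1: (112.0, 123.0, 134.0), "clip": (80, 210), "round": 0},
    "dbp": {"family": "normal", 0: (70.0, 78.0, 86.0), 1: (69.0, 77.0, 85.0), "clip": (40, 130), "round": 0},
    "total_cholesterol": {"family": "normal", 0: (168.0, 192.0, 218.0), 1: (165.0, 190.0, 215.0), "clip": (80, 400), "round": 0},
    "ldl": {"family": "normal", 0: (93.0, 115.0, 139.0), 1: (91.0, 113.0, 137.0), "clip": (30, 300), "round": 0},
    "hemoglobin": {"family": "normal", 0: (13.2, 14.2, 15.2), 1: (13.3, 14.3, 15.3), "clip": (7, 20), "round": 1},
    "wbc_count": {"family": "lognormal", 0: (5.6, 7.0, 8.8), 1: (5.4, 6.7, 8.3), "clip": (2, 25), "round": 2},
    "neutrophil_pct": {"family": "normal", 0: (51.0, 59.0, 67.0), 1: (49.0, 57.0, 65.0), "clip": (15, 95), "round": 1},
    "lymphocyte_pct": {"family": "normal", 0: (24.0, 31.0, 38.0), 1: (26.0, 33.0, 40.0), "clip": (3, 70), "round": 1},
    "platelet_count": {"family": "normal", 0: (205.0, 245.0, 290.0), 1: (210.0, 250.0, 295.0), "clip": (50, 700), "round": 0},
    "prothrombin_time": {"family": "normal", 0: (10.9, 11.5, 12.1), 1: (10.9, 11.5, 12.1), "clip": (8, 20), "round": 1},
    "aptt": {"family": "normal", 0: (27.5, 30.0, 32.5), 1: (27.5, 30.0, 32.5), "clip": (18, 60), "round": 1},
}

# Binary covariate rates (non-recovery, recovery); published contrasts where
# available, field-plausible shared rates elsewhere.
_BINARY_RATES: dict[str, tuple[float, float]] = {
    "gender_female": (0.4875, 0.55),
    "hypertension": (0.3629, 0.2091),
    "diabetes": (0.3130, 0.2136),
    "stroke": (0.05, 0.04),
    "dizziness": (0.4211, 0.1773),
    "tinnitus": (0.6371, 0.7455),
    "hyperlipidemia": (0.15, 0.13),
    "ckd": (0.04, 0.02),
    "mi_angina": (0.0582, 0.014),
    "hospitalization": (0.85, 0.85),
    "affected_side_left": (0.5, 0.5),
}

# MCAR per-feature missingness rates; published totals where available.
DEFAULT_MISSING_RATES: dict[str, float] = {
    "triacylglycerol": 0.4010,
    "bun": 0.1205,
    "creatinine": 0.0981,
    "duration_onset_itdi": 0.3993,
    "itdi_delay_category": 0.3993,
    "hypertension": 0.009,
    "diabetes": 0.007,
    "mi_angina": 0.009,
    "dizziness": 0.005,
    "tinnitus": 0.003,
    "total_cholesterol": 0.35,
    "ldl": 0.36,
    "hemoglobin": 0.10,
    "wbc_count": 0.12,
    "neutrophil_pct": 0.12,
    "lymphocyte_pct": 0.12,
    "nl_ratio": 0.12,
    "platelet_count": 0.12,
    "prothrombin_time": 0.25,
    "aptt": 0.25,
    "height": 0.05,
    "weight": 0.05,
    "bmi": 0.06,
    "smoking_packs_year": 0.08,
    "sbp": 0.04,
    "dbp": 0.04,
    "stroke": 0.008,
    "hyperlipidemia": 0.01,
    "ckd": 0.008,
    "smoking": 0.02,
    "smoking_post_cessation": 0.02,
    "duration_onset_treatment": 0.05,
}

#: The 50 model features, in a fixed order.
CONTINUOUS_FEATURES: tuple[str, ...] = (
    "age", "height", "weight", "bmi", "smoking_packs_year", "sbp", "dbp",
    "total_cholesterol", "ldl", "triacylglycerol", "hemoglobin", "bun",
    "creatinine", "wbc_count", "neutrophil_pct", "lymphocyte_pct", "nl_ratio",
    "platelet_count", "prothrombin_time", "aptt",
    "duration_onset_treatment", "duration_onset_itdi",
    "pta_avg_ae", "pta_avg_uae",
)
CATEGORICAL_FEATURES: tuple[str, ...] = (
    "gender_female", "smoking", "smoking_post_cessation",
    "hypertension", "diabetes", "stroke", "dizziness", "tinnitus",
    "hyperlipidemia", "ckd", "mi_angina",
    "hospitalization", "affected_side_left",
    "itdi_delay_category", "onset_month", "run_length",
    "tx_systemic_steroid", "tx_itdi", "tx_combined",
    "severity_ae", "severity_uae",
    "shape_ascending", "shape_u_shaped", "shape_descending", "shape_flat", "shape_deaf",
)
FEATURE_COLUMNS: tuple[str, ...] = CONTINUOUS_FEATURES + CATEGORICAL_FEATURES
assert len(FEATURE_COLUMNS) == 50

#: Features stored as integers (rounded before min-max scaling downstream).
INTEGER_FEATURES: tuple[str, ...] = (
    "age", "sbp", "dbp", "total_cholesterol", "ldl", "platelet_count",
    "duration_onset_treatment", "duration_onset_itdi",
) + CATEGORICAL_FEATURES

THRESHOLD_COLUMNS: tuple[str, ...] = tuple(
    c
    for ear in ("aff", "una")
    for tp in ("initial", "month1")
    for c in _threshold_columns(ear, tp)
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic cohort.

    ``violations`` are per-rule planted counts for the exclusion cascade, in
    cascade order (duplicate, missing month-1 audiometry, missing initial
    audiometry, bilateral, no qualifying run); they are added ON TOP of
    ``n_patients`` clean rows. The gain parameters map the latent prognosis
    score to the recovered fraction of the initial loss; their defaults are
    calibrated so the emergent personalized recovery rate matches
    ``recovery_target_rate``.
    """

    n_patients: int = 581
    seed: int = 0
    recovery_target_rate: float = 0.379
    violations: tuple[int, int, int, int, int] = (0, 0, 0, 0, 0)
    gain_intercept: float = -0.05
    gain_slope: float = 1.1
    gain_sd: float = 0.12
    latent_sd: float = 0.10
    threshold_noise_sd: float = 2.0
    missing_rates: dict = field(default_factory=lambda: dict(DEFAULT_MISSING_RATES))
    detection: DetectionConfig = DetectionConfig()
    stratum_contrast: bool = True  # False draws every covariate from the pooled mix

    def __post_init__(self) -> None:
        if not 0 <= self.recovery_target_rate <= 1:
            raise ParameterError("recovery_target_rate must be in [0, 1]")
        if any(v < 0 for v in self.violations):
            raise ParameterError("violation counts must be non-negative")
        for k, r in self.missing_rates.items():
            if not 0 <= r <= 1:
                raise ParameterError(f"missingness rate for {k!r} outside [0, 1]")


def _round5(x: np.ndarray) -> np.ndarray:
    return np.round(np.asarray(x, dtype=float) / 5.0) * 5.0


def sample_initial_audiogram(
    shape: str,
    severity_target_db: float,
    rng: np.random.Generator,
    config: DetectionConfig = DetectionConfig(),
    noise_sd: float = 3.0,
    max_tries: int = 200,
) -> np.ndarray:
    """Draw an initial affected-ear audiogram of a requested shape.

    Thresholds follow the shape template around the severity target, in 5-dB
    steps, and are redrawn until (a) a qualifying impaired run exists and
    (b) the shape classifier returns the requested shape. Raises
    :class:`ParameterError` for infeasible shape/severity combinations
    (e.g. a deaf profile at 35 dB).
    """
    if shape not in _SHAPE_TEMPLATES:
        raise ParameterError(f"unknown shape {shape!r}")
    if not 30 <= severity_target_db <= 115:
        raise ParameterError("severity_target_db must lie in [30, 115]")
    if shape == "deaf" and severity_target_db < 90:
        raise ParameterError("a deaf profile needs a severity target of at least 90 dB")
    if shape != "deaf" and severity_target_db > 85:
        raise ParameterError("non-deaf profiles need a severity target of at most 85 dB")
    template = _SHAPE_TEMPLATES[shape]
    for _ in range(max_tries):
        t = severity_target_db + template + rng.normal(0.0, noise_sd, N_FREQS)
        t = _round5(t)
        if shape == "deaf":
            t = np.maximum(t, 90.0)
        t = np.clip(t, -10.0, 120.0)
        if detect_impaired_range(t, config) is None:
            continue
        if classify_audiogram_shape(t) == shape:
            return t
    raise ParameterError(f"could not realize shape {shape!r} at {severity_target_db} dB")


def sample_posttreatment_audiogram(
    initial: np.ndarray,
    floor: np.ndarray,
    latent_prognosis: float,
    rng: np.random.Generator,
    gain_intercept: float = -0.05,
    gain_slope: float = 1.1,
    gain_sd: float = 0.12,
    noise_sd: float = 2.0,
) -> np.ndarray:
    """One-month audiogram: shrink the loss above ``floor`` by a recovered
    fraction drawn from a prognosis-dependent normal, clipped to [0, 1].

    Thresholds stay within [-10, initial + 5] (5 dB of measurement noise)
    and are quantized to 5-dB steps.
    """
    g = float(np.clip(rng.normal(gain_intercept + gain_slope * latent_prognosis, gain_sd), 0.0, 1.0))
    floor = np.minimum(np.asarray(floor, dtype=float), initial)
    t1 = floor + (initial - floor) * (1.0 - g) + rng.normal(0.0, noise_sd, N_FREQS)
    t1 = _round5(np.clip(t1, -10.0, initial + 5.0))
    return np.clip(t1, -10.0, 120.0)


def _draw_continuous(name: str, stratum: int, rng: np.random.Generator) -> float:
    p = _CONTINUOUS_PARAMS[name]
    q1, med, q3 = p[stratum]
    if p["family"] == "lognormal":
        mu, sigma = _lognorm_params(q1, med, q3)
        x = float(np.exp(rng.normal(mu, sigma)))
    else:
        mu, sigma = _norm_params(q1, med, q3)
        x = float(rng.normal(mu, sigma))
    lo, hi = p["clip"]
    return round(min(max(x, lo), hi), p["round"])


def sample_clinical_features(stratum: int, latent_prognosis: float, rng: np.random.Generator,
                             pta_avg_ae: float | None = None) -> dict[str, float]:
    """Draw the non-audiometric clinical covariates for one patient.

    ``stratum`` selects the recovery-conditional distributions (1 =
    recovery-leaning). Derived quantities (BMI, neutrophil-lymphocyte
    ratio, the treatment-delay category) are computed, not drawn. Treatment
    assignment is severity-conditioned when ``pta_avg_ae`` is given:
    steroid-only therapy is more frequent at milder losses, mirroring the
    clinical pattern that severe cases receive added intratympanic
    injections.
    """
    f: dict[str, float] = {}
    for name in _CONTINUOUS_PARAMS:
        f[name] = _draw_continuous(name, stratum, rng)
    f["bmi"] = round(f["weight"] / (f["height"] / 100.0) ** 2, 1)
    f["nl_ratio"] = round(f["neutrophil_pct"] / max(f["lymphocyte_pct"], 1.0), 2)

    # smoking: never / current / post-cessation
    smoke = rng.choice(3, p=[0.63, 0.22, 0.15])
    f["smoking"] = float(smoke == 1)
    f["smoking_post_cessation"] = float(smoke == 2)
    f["smoking_packs_year"] = (
        round(float(np.exp(rng.normal(math.log(15.0), 0.6))), 1) if smoke else 0.0
    )

    for name, rates in _BINARY_RATES.items():
        f[name] = float(rng.random() < rates[stratum])

    if pta_avg_ae is not None and pta_avg_ae < 60:
        tx_probs = [0.38, 0.06, 0.56]
    else:
        tx_probs = [0.20, 0.12, 0.68]
    tx = rng.choice(3, p=tx_probs)  # steroid-only / itdi-only / combined
    f["tx_systemic_steroid"] = float(tx == 0)
    f["tx_itdi"] = float(tx == 1)
    f["tx_combined"] = float(tx == 2)

    d = f["duration_onset_itdi"]
    f["itdi_delay_category"] = 1.0 if d <= 3 else 2.0 if d <= 7 else 3.0 if d <= 12 else 4.0
    f["onset_month"] = float(rng.integers(1, 13))
    return f


def inject_missingness(
    cohort: pd.DataFrame, rates: dict[str, float], rng: np.random.Generator
) -> pd.DataFrame:
    """MCAR masking per feature at the configured rates.

    Audiometric summary features and the outcome are never masked (rates for
    them are rejected).
    """
    protected = {"pta_avg_ae", "pta_avg_uae", "severity_ae", "severity_uae",
                 "run_length", "recovered"} | {f"shape_{s}" for s in audiometry.SHAPES}
    df = cohort.copy()
    for col, rate in rates.items():
        if not 0 <= rate <= 1:
            raise ParameterError(f"rate for {col!r} outside [0, 1]")
        if col in protected:
            raise ParameterError(f"{col!r} must never be masked")
        if col not in df.columns or rate == 0:
            continue
        mask = rng.random(len(df)) < rate
        df.loc[mask, col] = np.nan
    return df


def _severity_quartiles(stratum: int) -> tuple[float, float, float]:
    return (56.77, 75.63, 98.44) if stratum == 0 else (48.33, 61.25, 77.34)


def _uae_quartiles(stratum: int) -> tuple[float, float, float]:
    return (15.0, 23.13, 36.25) if stratum == 0 else (10.83, 16.88, 23.59)


def _sample_patient(config: GeneratorConfig, rng: np.random.Generator) -> dict:
    """One clean (cascade-passing) synthetic patient as a flat record."""
    stratum = int(rng.random() < config.recovery_target_rate)
    draw_stratum = stratum if config.stratum_contrast else int(rng.random() < config.recovery_target_rate)
    latent = float(np.clip(rng.normal(0.25 + 0.5 * stratum, config.latent_sd), 0.0, 1.0))

    shapes = list(_SHAPE_PROBS[draw_stratum])
    probs = np.array([_SHAPE_PROBS[draw_stratum][s] for s in shapes])
    shape = str(rng.choice(shapes, p=probs / probs.sum()))

    mu, sigma = _lognorm_params(*_severity_quartiles(draw_stratum))
    target = float(np.exp(rng.normal(mu, sigma)))
    if shape == "deaf":
        target = min(max(target, 95.0), 112.0)
    else:
        target = min(max(target, 36.0), 85.0)
    aff_t0 = sample_initial_audiogram(shape, target, rng, config.detection)

    mu_u, sigma_u = _lognorm_params(*_uae_quartiles(draw_stratum))
    una_target = min(max(float(np.exp(rng.normal(mu_u, sigma_u))), -5.0), 60.0)
    una_t0 = np.clip(_round5(una_target + rng.normal(0.0, 4.0, N_FREQS)), -10.0, 120.0)
    una_t1 = np.clip(_round5(una_t0 + rng.normal(0.0, config.threshold_noise_sd, N_FREQS)), -10.0, 120.0)

    floor = np.minimum(una_t0, 20.0)
    aff_t1 = sample_posttreatment_audiogram(
        aff_t0, floor, latent, rng,
        config.gain_intercept, config.gain_slope, config.gain_sd, config.threshold_noise_sd,
    )

    audio_feats = derive_audiometric_features(aff_t0, una_t0, config.detection)
    clin = sample_clinical_features(draw_stratum, latent, rng, pta_avg_ae=audio_feats["pta_avg_ae"])

    rec: dict = {"bilateral": 0.0, "latent_prognosis": latent, "planted_violation": ""}
    for cols, vals in (
        (_threshold_columns("aff", "initial"), aff_t0),
        (_threshold_columns("aff", "month1"), aff_t1),
        (_threshold_columns("una", "initial"), una_t0),
        (_threshold_columns("una", "month1"), una_t1),
    ):
        rec.update(zip(cols, vals))
    rec.update(clin)
    rec.update(audio_feats)
    return rec


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Assemble a full cohort table, plants included.

    Returns ``n_patients + sum(violations)`` rows in shuffled order with
    sequential patient ids. The ``recovered`` column is computed by the
    personalized Siegel scorer from the stored audiograms (NaN for rows
    that cannot be scored); ``planted_violation`` names the cascade rule a
    planted row violates (empty for clean rows).
    """
    rng = np.random.default_rng(config.seed)
    clean = [_sample_patient(config, rng) for _ in range(config.n_patients)]

    aff_t0_cols = _threshold_columns("aff", "initial")
    aff_t1_cols = _threshold_columns("aff", "month1")
    una_t0_cols = _threshold_columns("una", "initial")

    plants: list[dict] = []
    n_dup, n_miss_t1, n_miss_t0, n_bilat, n_norun = config.violations
    if n_dup > config.n_patients:
        raise ParameterError("cannot plant more duplicates than clean patients")
    for i in range(n_dup):
        rec = dict(clean[i % config.n_patients])
        rec["planted_violation"] = "duplicate_record"
        rec["_dup_src"] = i % config.n_patients
        plants.append(rec)
    for _ in range(n_miss_t1):
        rec = _sample_patient(config, rng)
        drop = rng.choice(N_FREQS, size=int(rng.integers(1, N_FREQS + 1)), replace=False)
        for j in drop:
            rec[aff_t1_cols[j]] = np.nan
        rec["planted_violation"] = "missing_month1_pta"
        plants.append(rec)
    for _ in range(n_miss_t0):
        rec = _sample_patient(config, rng)
        cols = aff_t0_cols if rng.random() < 0.5 else una_t0_cols
        drop = rng.choice(N_FREQS, size=int(rng.integers(1, 4)), replace=False)
        for j in drop:
            rec[cols[j]] = np.nan
        rec["planted_violation"] = "missing_initial_pta"
        plants.append(rec)
    for _ in range(n_bilat):
        rec = _sample_patient(config, rng)
        rec["bilateral"] = 1.0
        rec["planted_violation"] = "bilateral"
        plants.append(rec)
    for _ in range(n_norun):
        rec = _sample_patient(config, rng)
        sub = np.clip(_round5(rng.uniform(0.0, 27.0, N_FREQS)), -10.0, 25.0)
        rec.update(zip(aff_t0_cols, sub))
        # keep the stored audiometric summaries consistent with... none exist:
        # the row is removed by the cascade before feature use.
        rec["planted_violation"] = "no_qualifying_run"
        plants.append(rec)

    rows = clean + plants
    df = pd.DataFrame(rows)
    df = inject_missingness(df, config.missing_rates, rng)

    # duplicate plants must stay cell-identical to their source row, so the
    # MCAR mask of the source is copied over after injection
    if "_dup_src" in df.columns:
        sync_cols = [c for c in df.columns if c not in ("planted_violation", "_dup_src")]
        dup_rows = df.index[df["planted_violation"] == "duplicate_record"]
        for i in dup_rows:
            df.loc[i, sync_cols] = df.loc[int(df.at[i, "_dup_src"]), sync_cols]
        df = df.drop(columns="_dup_src")

    recovered = []
    for _, r in df.iterrows():
        t0 = r[aff_t0_cols].to_numpy(dtype=float)
        t1 = r[aff_t1_cols].to_numpy(dtype=float)
        try:
            recovered.append(float(assess_patient(t0, t1, "ppsc", config.detection).recovered))
        except Exception:
            recovered.append(np.nan)
    df["recovered"] = recovered

    order = rng.permutation(len(df))
    df = df.iloc[order].reset_index(drop=True)
    df.insert(0, "patient_id", [f"P{i:05d}" for i in range(1, len(df) + 1)])

    ordered = (
        ["patient_id"]
        + list(THRESHOLD_COLUMNS)
        + ["bilateral"]
        + list(FEATURE_COLUMNS)
        + ["recovered", "latent_prognosis", "planted_violation"]
    )
    return df[ordered]


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "planted_violation" in df.columns:
        df["planted_violation"] = df["planted_violation"].fillna("")
    return df
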