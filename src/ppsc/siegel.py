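"""Siegel recovery grading, traditional and patient-personalized.

Siegel's criteria grade recovery from sudden sensorineural hearing loss
using the one-month mean threshold and the hearing gain (initial mean minus
one-month mean) over a frequency band:

- complete: one-month mean <= 25 dB (regardless of gain)
- partial:  gain > 15 dB and one-month mean in (25, 45]
- slight:   gain > 15 dB and one-month mean in (45, 75]
- none:     otherwise

``complete`` and ``partial`` count as recovered. The *traditional* variant
averages the fixed 0.5/1/2/3 kHz band; the *patient-personalized* variant
(PPSC) averages the patient's own impaired frequency run detected on the
initial affected-ear audiogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import audiometry
from .audiometry import DetectionConfig, TRADITIONAL_BAND, detect_impaired_range, mean_pta
from .exceptions import MissingDataError, NoQualifyingRunError, ParameterError

VARIANTS = ("traditional", "ppsc")
CLASSES = ("complete", "partial", "slight", "none")
RECOVERED_CLASSES = frozenset({"complete", "partial"})


@dataclass(frozen=True)
class SiegelThresholds:
    """dB boundaries of the grading rules."""

    complete_max_db: float = 25.0
    gain_min_db: float = 15.0
    partial_max_db: float = 45.0
    slight_max_db: float = 75.0

    def __post_init__(self) -> None:
        if not (0 < self.complete_max_db < self.partial_max_db < self.slight_max_db):
            raise ParameterError("require 0 < complete_max < partial_max < slight_max")
        if self.gain_min_db <= 0:
            raise ParameterError("gain_min_db must be positive")


@dataclass(frozen=True)
class SiegelResult:
    variant: str
    initial_mean_db: float
    month1_mean_db: float
    gain_db: float
    klass: str
    recovered: bool


def siegel_classify(
    initial_mean_db: float,
    month1_mean_db: float,
    thresholds: SiegelThresholds = SiegelThresholds(),
    variant: str = "ppsc",
) -> SiegelResult:
    """Grade one band-mean pair. Classes are exhaustive and exclusive.

    A gain of exactly 15 dB does not grant recovery (the two recovery rules
    require a gain strictly above 15 dB).
    """
    if not (np.isfinite(initial_mean_db) and np.isfinite(month1_mean_db)):
        raise ParameterError("both means must be finite")
    gain = initial_mean_db - month1_mean_db
    if month1_mean_db <= thresholds.complete_max_db:
        klass = "complete"
    elif gain > thresholds.gain_min_db and month1_mean_db <= thresholds.partial_max_db:
        klass = "partial"
    elif gain > thresholds.gain_min_db and month1_mean_db <= thresholds.slight_max_db:
        klass = "slight"
    else:
        klass = "none"
    return SiegelResult(
        variant=variant,
        initial_mean_db=float(initial_mean_db),
        month1_mean_db=float(month1_mean_db),
        gain_db=float(gain),
        klass=klass,
        recovered=klass in RECOVERED_CLASSES,
    )


def assess_patient(
    affected_initial,
    affected_month1,
    variant: str = "ppsc",
    config: DetectionConfig = DetectionConfig(),
    thresholds: SiegelThresholds = SiegelThresholds(),
) -> SiegelResult:
    """Score one patient's affected-ear audiogram pair under a variant.

    For ``ppsc`` the averaging band is the impaired run detected on the
    initial audiogram (raises :class:`NoQualifyingRunError` when absent);
    for ``traditional`` it is the fixed 0.5-3 kHz band. Missing thresholds
    inside the band raise :class:`MissingDataError`.
    """
    if variant == "ppsc":
        run = detect_impaired_range(affected_initial, config)
        if run is None:
            raise NoQualifyingRunError("patient has no qualifying impaired run")
        band = run.indices
    elif variant == "traditional":
        band = TRADITIONAL_BAND
    else:
        raise ParameterError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    initial_mean = mean_pta(affected_initial, band)
    month1_mean = mean_pta(affected_month1, band)
    return siegel_classify(initial_mean, month1_mean, thresholds, variant=variant)


def _threshold_columns(ear: str, timepoint: str) -> list[str]:
    t = {"initial": "t0", "month1": "t1"}[timepoint]
    return [f"ac_{ear}_{f:g}_{t}" for f in audiometry.FREQUENCIES_KHZ]


def score_cohort(
    cohort: pd.DataFrame,
    variant: str = "ppsc",
    config: DetectionConfig = DetectionConfig(),
    thresholds: SiegelThresholds = SiegelThresholds(),
) -> pd.DataFrame:
    """Score every patient of a cohort table under one variant.

    Expects the threshold column layout ``ac_aff_<freq>_<t0|t1>`` and a
    ``patient_id`` column. Returns one row per patient with the variant,
    band means, gain, class and recovered flag.
    """
    rows = []
    for _, r in cohort.iterrows():
        t0 = r[_threshold_columns("aff", "initial")].to_numpy(dtype=float)
        t1 = r[_threshold_columns("aff", "month1")].to_numpy(dtype=float)
        res = assess_patient(t0, t1, variant=variant, config=config, thresholds=thresholds)
        rows.append(
            {
                "patient_id": r["patient_id"],
                "variant": res.variant,
                "initial_mean_db": res.initial_mean_db,
                "month1_mean_db": res.month1_mean_db,
                "gain_db": res.gain_db,
                "klass": res.klass,
                "recovered": res.recovered,
            }
        )
    return pd.DataFrame(rows)
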