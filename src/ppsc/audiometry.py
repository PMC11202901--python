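"""Pure-tone audiogram model and range-restricted scoring.

An audiogram here is a vector of 8 air-conduction thresholds in dB HL on the
standard test grid 0.125-8 kHz. The module finds the patient-specific
*impaired frequency run* -- the contiguous block of at least three
frequencies whose thresholds reach the sudden-hearing-loss cutoff (30 dB HL)
-- and derives the audiometric features used downstream: range-restricted
PTA averages for both ears, 5-level severity categories, the run length, and
a coarse audiogram shape type.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .exceptions import MissingDataError, NoQualifyingRunError, ParameterError, SchemaError

#: The eight standard audiometric test frequencies, in kHz, low to high.
FREQUENCIES_KHZ: tuple[float, ...] = (0.125, 0.25, 0.5, 1.0, 2.0, 3.0, 4.0, 8.0)
N_FREQS = len(FREQUENCIES_KHZ)

#: Grid indices of the fixed 0.5/1/2/3 kHz band used by the traditional
#: Siegel assessment.
TRADITIONAL_BAND: tuple[int, ...] = (2, 3, 4, 5)

# Band partition used by the audiogram shape heuristic.
_LOW = slice(0, 3)   # 0.125-0.5 kHz
_MID = slice(3, 5)   # 1-2 kHz
_HIGH = slice(5, 8)  # 3-8 kHz

SHAPES = ("ascending", "u_shaped", "descending", "flat", "deaf")

SEVERITY_LABELS = {1: "mild", 2: "moderate", 3: "severe", 4: "profound", 5: "deaf"}


@dataclass(frozen=True)
class DetectionConfig:
    """Impaired-run detection rule: ``min_run_length`` contiguous frequencies
    at or above ``cutoff_db``."""

    cutoff_db: float = 30.0
    min_run_length: int = 3

    def __post_init__(self) -> None:
        if not self.cutoff_db > 0:
            raise ParameterError("cutoff_db must be positive")
        if self.min_run_length < 1:
            raise ParameterError("min_run_length must be >= 1")


@dataclass(frozen=True)
class ImpairedRange:
    """Contiguous qualifying run: ``length`` frequencies starting at grid
    index ``start``."""

    start: int
    length: int

    @property
    def indices(self) -> tuple[int, ...]:
        return tuple(range(self.start, self.start + self.length))

    @property
    def frequencies_khz(self) -> tuple[float, ...]:
        return tuple(FREQUENCIES_KHZ[i] for i in self.indices)


def _as_threshold_vector(thresholds: Sequence[float]) -> np.ndarray:
    t = np.asarray(thresholds, dtype=float)
    if t.shape != (N_FREQS,):
        raise SchemaError(
            f"expected {N_FREQS} thresholds aligned to the frequency grid, got shape {t.shape}"
        )
    return t


def detect_impaired_range(
    thresholds: Sequence[float], config: DetectionConfig = DetectionConfig()
) -> Optional[ImpairedRange]:
    """Find the impaired frequency run of an initial affected-ear audiogram.

    A position qualifies when its threshold is present and >= the cutoff.
    Among all maximal contiguous qualifying runs of length >=
    ``min_run_length``, the longest wins; ties go to the run starting at the
    lowest frequency. Qualifying positions outside the selected run (e.g. an
    isolated 8 kHz loss) are excluded. Returns ``None`` when no run
    qualifies. Missing thresholds never qualify.
    """
    t = _as_threshold_vector(thresholds)
    qualifies = np.isfinite(t) & (t >= config.cutoff_db)

    best: Optional[ImpairedRange] = None
    i = 0
    while i < N_FREQS:
        if not qualifies[i]:
            i += 1
            continue
        j = i
        while j < N_FREQS and qualifies[j]:
            j += 1
        length = j - i
        if length >= config.min_run_length and (best is None or length > best.length):
            best = ImpairedRange(start=i, length=length)
        i = j
    return best


def mean_pta(thresholds: Sequence[float], indices: Iterable[int] | ImpairedRange) -> float:
    """Arithmetic mean threshold (dB HL) over a frequency index set.

    Raises :class:`MissingDataError` if any covered threshold is absent.
    """
    t = _as_threshold_vector(thresholds)
    if isinstance(indices, ImpairedRange):
        indices = indices.indices
    idx = list(indices)
    covered = t[idx]
    if not np.all(np.isfinite(covered)):
        missing = [FREQUENCIES_KHZ[i] for i, v in zip(idx, covered) if not np.isfinite(v)]
        raise MissingDataError(f"missing thresholds at {missing} kHz inside the averaging range")
    return float(np.mean(covered))


def severity_category(mean_db: float) -> int:
    """5-level hearing severity from a mean threshold.

    Half-open 20-dB bands: <40 mild (1), [40,60) moderate (2), [60,80)
    severe (3), [80,100) profound (4), >=100 deaf (5).
    """
    if not np.isfinite(mean_db):
        raise ParameterError(f"mean_db must be finite, got {mean_db!r}")
    if mean_db < 40:
        return 1
    if mean_db < 60:
        return 2
    if mean_db < 80:
        return 3
    if mean_db < 100:
        return 4
    return 5


def classify_audiogram_shape(thresholds: Sequence[float]) -> str:
    """Assign one of five coarse audiogram shapes.

    Deterministic band-mean heuristic (low = 0.125-0.5, mid = 1-2,
    high = 3-8 kHz, margin 10 dB), checked in order:

    - deaf: overall mean >= 90 dB
    - flat: band means within a 10 dB spread
    - ascending: low-band mean exceeds high-band mean by > 10 dB
    - descending: high-band mean exceeds low-band mean by > 10 dB
    - u_shaped: mid-band mean exceeds both edge bands by > 10 dB
    - fallback: flat
    """
    t = _as_threshold_vector(thresholds)
    if not np.all(np.isfinite(t)):
        raise MissingDataError("shape classification requires a complete audiogram")
    low = float(t[_LOW].mean())
    mid = float(t[_MID].mean())
    high = float(t[_HIGH].mean())
    if t.mean() >= 90:
        return "deaf"
    if max(low, mid, high) - min(low, mid, high) <= 10:
        return "flat"
    if low > high + 10:
        return "ascending"
    if high > low + 10:
        return "descending"
    if mid > low + 10 and mid > high + 10:
        return "u_shaped"
    return "flat"


def derive_audiometric_features(
    affected_initial: Sequence[float],
    unaffected_initial: Sequence[float],
    config: DetectionConfig = DetectionConfig(),
) -> dict[str, float]:
    """Audiometric feature block for one patient.

    Both ears are averaged over the SAME run, the one detected on the
    initial affected-ear audiogram. Returns pta averages, severity
    categories, the run length and five one-hot shape flags. Raises
    :class:`NoQualifyingRunError` when no run qualifies (the patient is an
    exclusion case, see the cohort cascade).
    """
    run = detect_impaired_range(affected_initial, config)
    if run is None:
        raise NoQualifyingRunError("no contiguous impaired run in the initial affected-ear audiogram")
    pta_aff = mean_pta(affected_initial, run)
    pta_una = mean_pta(unaffected_initial, run)
    shape = classify_audiogram_shape(affected_initial)
    feats: dict[str, float] = {
        "pta_avg_ae": pta_aff,
        "pta_avg_uae": pta_una,
        "severity_ae": float(severity_category(pta_aff)),
        "severity_uae": float(severity_category(pta_una)),
        "run_length": float(run.length),
    }
    for s in SHAPES:
        feats[f"shape_{s}"] = float(shape == s)
    return feats
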