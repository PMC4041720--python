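"""Alarm generation and statistical evaluation.

Pattern-count series are normalized against a reference interictal
period (subtract its mean, divide by its maximum), thresholded either
statically (a fixed multiple ``c`` of the reference standard deviation) or
dynamically (deviation from a trailing moving average of ``m`` windows),
combined across pattern lengths by fractional voting, and de-bounced with
a refractory period.  Alarms are scored either as detections (overlap with
an annotated seizure) or as predictions within the intervention-time /
seizure-occurrence-period (IT/SOP) framework, and prediction sensitivity
is compared with the analytic sensitivity of a chance-level (binomial)
random predictor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from epigram.ngram_engine import PatternCountSeries
from epigram.signal_io import SeizureAnnotation

__all__ = [
    "ReferenceStats",
    "ThresholdModel",
    "PredictionScheme",
    "EvaluationResult",
    "RandomPredictorModel",
    "reference_stats",
    "normalize_series",
    "static_markers",
    "dynamic_markers",
    "combine_votes",
    "evaluate_detection",
    "evaluate_prediction",
    "random_predictor_critical",
]


@dataclass(frozen=True)
class ReferenceStats:
    """Per-length statistics of the raw reference (interictal) counts:
    mean, maximum, and standard deviation of the normalized values."""

    mean: np.ndarray
    max: np.ndarray
    std: np.ndarray


def reference_stats(reference_counts: np.ndarray) -> ReferenceStats:
    """Compute normalization statistics from raw reference counts.

    ``reference_counts`` is (n_lengths, n_windows).  The maximum of the
    raw counts is the normalization scale; the standard deviation is taken
    on the normalized values, so thresholds are in normalized units.
    """
    ref = np.asarray(reference_counts, dtype=np.float64)
    if ref.ndim != 2 or ref.shape[1] == 0:
        raise ValueError("reference must be a non-empty (lengths, windows) array")
    mx = ref.max(axis=1)
    if np.any(mx <= 0):
        raise ValueError("all-zero reference period cannot normalize counts")
    mu = ref.mean(axis=1)
    norm = (ref - mu[:, None]) / mx[:, None]
    return ReferenceStats(mean=mu, max=mx, std=norm.std(axis=1))


def normalize_series(
    counts: np.ndarray, ref: ReferenceStats
) -> np.ndarray:
    """Normalize raw counts: (x - mean_ref) / max_ref, per pattern length."""
    x = np.asarray(counts, dtype=np.float64)
    return (x - ref.mean[:, None]) / ref.max[:, None]


@dataclass(frozen=True)
class ThresholdModel:
    """Alarm threshold on normalized pattern counts.

    kind
        "static": fire where the normalized count deviates from zero by at
        least ``c`` reference standard deviations.  "dynamic": fire where
        it deviates from the trailing moving average of the previous ``m``
        windows by the same margin.
    direction
        "two_sided" (default: large-pattern counts fall while small-pattern
        counts rise at onset), "above" or "below".
    """

    kind: str = "dynamic"
    c: float = 3.0
    ma_window: int = 10
    direction: str = "two_sided"
    # deviations below this floor (normalized units) never fire; guards a
    # degenerate zero-variance reference
    sigma_floor: float = 1e-4

    def __post_init__(self) -> None:
        if self.kind not in ("static", "dynamic"):
            raise ValueError("kind must be 'static' or 'dynamic'")
        if self.c <= 0:
            raise ValueError("multiplier c must be positive")
        if self.ma_window < 1:
            raise ValueError("ma_window must be >= 1")
        if self.direction not in ("above", "below", "two_sided"):
            raise ValueError("bad direction")


def _apply_direction(dev: np.ndarray, thr: np.ndarray, direction: str) -> np.ndarray:
    if direction == "above":
        return dev >= thr
    if direction == "below":
        return -dev >= thr
    return np.abs(dev) >= thr


def static_markers(
    normalized: np.ndarray, model: ThresholdModel, ref: ReferenceStats
) -> np.ndarray:
    """Boolean markers per (length, window) for a static threshold."""
    if model.kind != "static":
        raise ValueError("static_markers requires a static model")
    sigma = np.maximum(ref.std, model.sigma_floor)
    thr = model.c * sigma[:, None]
    return _apply_direction(np.asarray(normalized, dtype=float), thr, model.direction)


def dynamic_markers(
    normalized: np.ndarray, model: ThresholdModel, ref: ReferenceStats
) -> np.ndarray:
    """Boolean markers for the moving-average (dynamic) threshold.

    The moving average at window t uses windows t-m .. t-1; the first m
    windows are warm-up and never fire.
    """
    if model.kind != "dynamic":
        raise ValueError("dynamic_markers requires a dynamic model")
    x = np.asarray(normalized, dtype=np.float64)
    m = model.ma_window
    L, T = x.shape
    out = np.zeros((L, T), dtype=bool)
    if T <= m:
        return out
    csum = np.cumsum(x, axis=1)
    # MA_t = (csum[t-1] - csum[t-m-1]) / m for t >= m
    ma = (csum[:, m - 1 : T - 1] - np.concatenate(
        [np.zeros((L, 1)), csum[:, : T - m - 1]], axis=1
    )) / m
    dev = x[:, m:] - ma
    sigma = np.maximum(ref.std, model.sigma_floor)
    out[:, m:] = _apply_direction(dev, model.c * sigma[:, None], model.direction)
    return out


@dataclass(frozen=True)
class PredictionScheme:
    """IT/SOP prediction bookkeeping.

    An alarm raised at time t forecasts a seizure onset inside
    ``[t + IT, t + IT + SOP)``: the intervention time IT is the lead
    period before the seizure-occurrence period SOP opens.
    """

    it_min: float = 20.0
    sop_min: float = 10.0
    refractory_min: float | None = None

    def __post_init__(self) -> None:
        if self.it_min <= 0 or self.sop_min <= 0:
            raise ValueError("IT and SOP must be positive")

    @property
    def horizon_min(self) -> float:
        return self.it_min + self.sop_min

    @property
    def effective_refractory_min(self) -> float:
        """Default refractory spans the whole alarm horizon IT+SOP, so one
        forecast is pending at a time."""
        if self.refractory_min is not None:
            return self.refractory_min
        return self.horizon_min


def combine_votes(
    markers: np.ndarray,
    p: float,
    *,
    window_s: float,
    start_time_s: float = 0.0,
    refractory_s: float = 0.0,
    channel_markers: Sequence[np.ndarray] | None = None,
) -> np.ndarray:
    """Combine per-length markers into alarm times by fractional voting.

    An alarm is raised at window t when at least a fraction ``p`` of the
    selected pattern lengths carry a marker there; with
    ``channel_markers`` the per-channel votes are OR-ed first.  Alarms
    within ``refractory_s`` of the previous surviving alarm are
    suppressed.  Returns alarm times (window start, seconds).
    """
    if not 0 < p <= 1:
        raise ValueError("vote fraction p must lie in (0, 1]")
    stacks = [np.asarray(markers, dtype=bool)]
    if channel_markers is not None:
        stacks += [np.asarray(m, dtype=bool) for m in channel_markers]
    fired = None
    for mk in stacks:
        if mk.ndim != 2 or mk.shape[0] == 0:
            raise ValueError("markers must be a non-empty (lengths, windows) array")
        votes = mk.mean(axis=0) >= p - 1e-12
        fired = votes if fired is None else (fired | votes)
    times = start_time_s + np.flatnonzero(fired) * window_s
    if refractory_s > 0 and times.size:
        kept = [times[0]]
        for t in times[1:]:
            if t - kept[-1] >= refractory_s:
                kept.append(t)
        times = np.asarray(kept)
    return times


@dataclass
class EvaluationResult:
    """Sensitivity / false-rate bookkeeping for one evaluation."""

    n_seizures: int
    n_hit: int
    per_seizure: list[bool]
    false_alarms: int
    interictal_hours: float
    mode: str = "prediction"

    @property
    def sensitivity(self) -> float | None:
        if self.n_seizures == 0:
            return None
        return self.n_hit / self.n_seizures

    @property
    def false_rate_per_hour(self) -> float:
        return self.false_alarms / self.interictal_hours

    def as_dict(self) -> dict:
        return {
            "mode": self.mode,
            "n_seizures": self.n_seizures,
            "n_hit": self.n_hit,
            "per_seizure": list(map(bool, self.per_seizure)),
            "sensitivity": self.sensitivity,
            "false_alarms": self.false_alarms,
            "interictal_hours": self.interictal_hours,
            "false_rate_per_hour": self.false_rate_per_hour,
        }


def evaluate_detection(
    alarm_times_s: Sequence[float],
    annotations: Sequence[SeizureAnnotation],
    interictal_hours: float,
    *,
    window_s: float = 60.0,
    post_ictal_s: float = 0.0,
) -> EvaluationResult:
    """Score alarms as detections.

    A seizure is detected when at least one alarm window (half-open,
    ``window_s`` long) overlaps it; alarms overlapping no seizure are
    false detections; FDR = false detections / interictal hours.  Alarms
    raised within ``post_ictal_s`` after a seizure offset are dropped,
    matching the exclusion of post-ictal time from the denominator.
    """
    if interictal_hours <= 0:
        raise ValueError("interictal_hours must be positive")
    alarms = np.sort(np.asarray(alarm_times_s, dtype=float))
    if post_ictal_s > 0 and alarms.size:
        keep = np.ones(alarms.size, dtype=bool)
        for ann in annotations:
            keep &= ~(
                (alarms >= ann.offset_s)
                & (alarms < ann.offset_s + post_ictal_s)
            )
        alarms = alarms[keep]
    hits = []
    used = np.zeros(alarms.size, dtype=bool)
    for ann in annotations:
        hit = False
        for i, t in enumerate(alarms):
            if ann.overlaps(t, t + window_s):
                hit = True
                used[i] = True
        hits.append(hit)
    false_alarms = int(np.count_nonzero(~used))
    return EvaluationResult(
        n_seizures=len(list(annotations)),
        n_hit=sum(hits),
        per_seizure=hits,
        false_alarms=false_alarms,
        interictal_hours=interictal_hours,
        mode="detection",
    )


def evaluate_prediction(
    alarm_times_s: Sequence[float],
    annotations: Sequence[SeizureAnnotation],
    scheme: PredictionScheme,
    interictal_hours: float,
    *,
    ignore_ictal_alarms: bool = True,
    post_ictal_s: float = 0.0,
) -> EvaluationResult:
    """Score alarms as predictions under the IT/SOP framework.

    An alarm at t truly predicts a seizure when that seizure's onset falls
    in ``[t + IT, t + IT + SOP)``; a seizure counts as predicted when at
    least one alarm predicts it.  Alarms predicting no seizure are false
    predictions.  Alarms raised while a seizure is already running are
    dropped by default (prediction is moot once the event has begun), as
    are alarms within ``post_ictal_s`` after an offset — post-ictal time
    is likewise excluded from the interictal hours of the denominator.
    """
    if interictal_hours <= 0:
        raise ValueError("interictal_hours must be positive")
    it_s = scheme.it_min * 60.0
    sop_s = scheme.sop_min * 60.0
    alarms = np.sort(np.asarray(alarm_times_s, dtype=float))
    anns = list(annotations)
    if ignore_ictal_alarms and alarms.size:
        keep = np.ones(alarms.size, dtype=bool)
        for ann in anns:
            keep &= ~(
                (alarms >= ann.onset_s)
                & (alarms < ann.offset_s + post_ictal_s)
            )
        alarms = alarms[keep]
    hits = []
    predicts_any = np.zeros(alarms.size, dtype=bool)
    for ann in anns:
        in_window = (alarms + it_s <= ann.onset_s) & (
            ann.onset_s < alarms + it_s + sop_s
        )
        predicts_any |= in_window
        hits.append(bool(in_window.any()))
    false_alarms = int(np.count_nonzero(~predicts_any))
    return EvaluationResult(
        n_seizures=len(anns),
        n_hit=sum(hits),
        per_seizure=hits,
        false_alarms=false_alarms,
        interictal_hours=interictal_hours,
        mode="prediction",
    )


# ---------------------------------------------------------------------------
# random predictor


@dataclass(frozen=True)
class RandomPredictorModel:
    """Chance-level predictor raising Poisson alarms at rate ``fpr_max``.

    The probability that such a predictor forecasts a given seizure is
    ``P = 1 - exp(-fpr_max * SOP)``; the chance of predicting at least k
    of K independent seizures follows a binomial tail, corrected for ``d``
    independent features/electrodes by ``1 - (1 - tail)^d``.
    """

    fpr_max: float = 0.15  # alarms per hour
    sop_hours: float = 10.0 / 60.0
    n_seizures: int = 1
    d: int = 1
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.d < 1 or self.n_seizures < 1:
            raise ValueError("d and n_seizures must be >= 1")
        if self.fpr_max < 0 or self.sop_hours <= 0:
            raise ValueError("fpr_max must be >= 0 and SOP positive")

    @property
    def chance_hit_probability(self) -> float:
        return 1.0 - math.exp(-self.fpr_max * self.sop_hours)


def random_predictor_critical(model: RandomPredictorModel) -> dict:
    """Critical sensitivities of the matched random predictor.

    Returns ``sigma_upper`` — the smallest achieved sensitivity k/K whose
    corrected chance probability is below ``alpha`` (performance above it
    is significantly better than chance) — ``sigma_lower`` (the analogous
    bound on the lower tail) and the per-k corrected tail probabilities.
    """
    K = model.n_seizures
    P = model.chance_hit_probability
    ks = np.arange(K + 1)
    upper_tail = stats.binom.sf(ks - 1, K, P)  # P[X >= k]
    lower_tail = stats.binom.cdf(ks, K, P)  # P[X <= k]
    corr_upper = 1.0 - (1.0 - upper_tail) ** model.d
    corr_lower = 1.0 - (1.0 - lower_tail) ** model.d
    sig_up = np.flatnonzero(corr_upper < model.alpha)
    sigma_upper = float(sig_up[0]) / K if sig_up.size else 1.0
    sig_lo = np.flatnonzero(corr_lower < model.alpha)
    sigma_lower = float(sig_lo[-1]) / K if sig_lo.size else 0.0
    return {
        "sigma_upper": sigma_upper,
        "sigma_lower": sigma_lower,
        "chance_hit_probability": P,
        "upper_tail": corr_upper,
        "lower_tail": corr_lower,
    }
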