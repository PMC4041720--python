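"""Per-patient training of the alarm-generation parameters.

Each available seizure serves in turn as the training seizure: the
threshold kind and multiplier, the subset of pattern lengths, the vote
fraction, the channel (each focal channel alone plus the OR of all), and —
for prediction — the intervention time are grid-searched on that seizure
together with one seeded, randomly chosen interictal hour.  Candidates are
ranked lexicographically: first hit the training seizure, then raise the
fewest false events on the training hour, then use the smallest threshold
multiplier.  The winning configuration is then applied to all remaining
seizures and interictal data, and the per-training-seizure results are
summarized as a first-case (seizure #1) and a best-case choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np

from epigram.decision import (
    PredictionScheme,
    ReferenceStats,
    ThresholdModel,
    combine_votes,
    dynamic_markers,
    evaluate_detection,
    evaluate_prediction,
    normalize_series,
    reference_stats,
    static_markers,
)
from epigram.ngram_engine import PatternCountSeries
from epigram.signal_io import SeizureAnnotation

__all__ = ["SearchSpace", "TrainingRun", "TrainingResult", "train_patient",
           "summarize_cases"]


class TrainingError(ValueError):
    """Raised when a patient cannot be trained (no seizures or no data)."""


@dataclass(frozen=True)
class SearchSpace:
    """Grid of candidate alarm parameters."""

    # candidate threshold multipliers sit above the ~3 reference-SD noise
    # floor of normalized interictal counts; training then takes the
    # smallest that hits the training seizure without false events
    multipliers: tuple[float, ...] = (4.0, 6.0, 8.0, 12.0)
    kinds: tuple[str, ...] = ("dynamic", "static")
    length_subsets: tuple[tuple[int, ...], ...] = (
        (16, 14, 12, 10, 8, 6),
        (16, 14, 12),
    )
    vote_fractions: tuple[float, ...] = (0.5,)
    its_min: tuple[float, ...] = (10.0, 20.0, 30.0)
    ma_window: int = 10

    def __post_init__(self) -> None:
        for name in ("multipliers", "kinds", "length_subsets",
                     "vote_fractions", "its_min"):
            if not getattr(self, name):
                raise TrainingError(f"search space field {name} is empty")


@dataclass
class TrainingRun:
    """Outcome of one training iteration (one training seizure)."""

    train_index: int
    chosen: dict
    training_hit: bool
    training_false_events: int
    heldout: dict | None  # EvaluationResult.as_dict() or None
    per_it: dict[float, dict] = field(default_factory=dict)


@dataclass
class TrainingResult:
    mode: str
    sop_min: float | None
    reference_hour_s: tuple[float, float]
    runs: list[TrainingRun]
    no_heldout: bool
    seed: int

    def run_for(self, train_index: int) -> TrainingRun:
        return next(r for r in self.runs if r.train_index == train_index)


# ---------------------------------------------------------------------------
# interictal bookkeeping


def interictal_intervals(
    duration_s: float,
    annotations: Sequence[SeizureAnnotation],
    *,
    pre_pad_s: float,
    post_pad_s: float,
) -> list[tuple[float, float]]:
    """Timeline minus each seizure padded by the preictal horizon before
    onset and a recovery margin after offset."""
    cuts = []
    for ann in annotations:
        cuts.append((max(ann.onset_s - pre_pad_s, 0.0),
                     min(ann.offset_s + post_pad_s, duration_s)))
    cuts.sort()
    out = []
    cursor = 0.0
    for a, b in cuts:
        if a > cursor:
            out.append((cursor, a))
        cursor = max(cursor, b)
    if cursor < duration_s:
        out.append((cursor, duration_s))
    return out


def _pick_reference_window(
    intervals: list[tuple[float, float]],
    window_s: float,
    rng: np.random.Generator,
    target_s: float = 3600.0,
    min_windows: int = 10,
) -> tuple[float, float]:
    """A seeded, randomly placed reference hour inside interictal data.

    Falls back to the longest interictal stretch when no full hour exists;
    at least ``min_windows`` analysis windows are required.
    """
    fitting = [(a, b) for a, b in intervals if b - a >= target_s]
    if fitting:
        a, b = fitting[int(rng.integers(len(fitting)))]
        start = float(rng.uniform(a, b - target_s))
        start = np.floor(start / window_s) * window_s
        return start, start + target_s
    if not intervals:
        raise TrainingError("no interictal data to train on")
    a, b = max(intervals, key=lambda iv: iv[1] - iv[0])
    a = np.ceil(a / window_s) * window_s
    b = np.floor(b / window_s) * window_s
    if b - a < min_windows * window_s:
        raise TrainingError("interictal data too short for a reference period")
    return float(a), float(b)


def _hours_in(intervals: list[tuple[float, float]]) -> float:
    return sum(b - a for a, b in intervals) / 3600.0


# ---------------------------------------------------------------------------
# training


class _MarkerCache:
    """Normalized series and per-(channel, kind, c) marker matrices."""

    def __init__(
        self,
        series_by_channel: dict[str, PatternCountSeries],
        ref_slice: slice,
        ma_window: int,
    ):
        self.series = series_by_channel
        self.ma_window = ma_window
        self.norm: dict[str, np.ndarray] = {}
        self.ref: dict[str, ReferenceStats] = {}
        for ch, s in series_by_channel.items():
            ref = reference_stats(s.counts[:, ref_slice])
            self.ref[ch] = ref
            self.norm[ch] = normalize_series(s.counts, ref)
        self._markers: dict[tuple, np.ndarray] = {}

    def markers(self, channel: str, kind: str, c: float) -> np.ndarray:
        key = (channel, kind, c)
        if key not in self._markers:
            model = ThresholdModel(kind=kind, c=c, ma_window=self.ma_window)
            fn = static_markers if kind == "static" else dynamic_markers
            self._markers[key] = fn(self.norm[channel], model, self.ref[channel])
        return self._markers[key]


def _subset_rows(lengths: tuple[int, ...], subset: tuple[int, ...]) -> list[int]:
    return [lengths.index(n) for n in subset]


def train_patient(
    series_by_channel: dict[str, PatternCountSeries],
    annotations: Sequence[SeizureAnnotation],
    *,
    mode: str = "prediction",
    sop_min: float = 10.0,
    space: SearchSpace | None = None,
    seed: int = 0,
    duration_s: float | None = None,
) -> TrainingResult:
    """Leave-one-seizure-in training over a patient's count series.

    ``series_by_channel`` maps channel label to the raw pattern-count
    series of that channel (common window grid).  Every seizure is used
    once as the training seizure; the result carries the chosen
    parameters, training objective and held-out metrics per iteration.
    """
    if mode not in ("prediction", "detection"):
        raise ValueError("mode must be 'prediction' or 'detection'")
    space = space or SearchSpace()
    anns = sorted(annotations, key=lambda a: a.onset_s)
    if not anns:
        raise TrainingError("training requires at least one seizure")
    first = next(iter(series_by_channel.values()))
    window_s = first.window_s
    lengths = first.lengths
    T = first.n_windows
    if duration_s is None:
        duration_s = T * window_s
    rng = np.random.default_rng(seed)

    max_it = max(space.its_min) if mode == "prediction" else 0.0
    pre_pad = (max_it + sop_min) * 60.0 if mode == "prediction" else window_s
    # post-ictal pad covers the moving-average span, during which the
    # dynamic threshold is still contaminated by the seizure itself
    post_pad = window_s + space.ma_window * window_s
    inter = interictal_intervals(
        duration_s, anns, pre_pad_s=pre_pad, post_pad_s=post_pad
    )
    if not inter:
        raise TrainingError("no interictal data available")
    h0, h1 = _pick_reference_window(inter, window_s, rng)
    ref_slice = slice(int(h0 // window_s), int(h1 // window_s))

    cache = _MarkerCache(series_by_channel, ref_slice, space.ma_window)
    channel_names = list(series_by_channel)
    channel_options: list[tuple[str, ...]] = [(c,) for c in channel_names]
    if len(channel_names) > 1:
        channel_options.append(tuple(channel_names))

    its = tuple(space.its_min) if mode == "prediction" else (None,)

    # keep only candidate subsets whose lengths were actually counted;
    # fall back to everything the series provides
    subsets = tuple(
        s for s in space.length_subsets if set(s) <= set(lengths)
    ) or (tuple(lengths),)

    # interictal hours available for held-out false-rate scoring: total
    # interictal minus the training hour
    test_inter = []
    for a, b in inter:
        # subtract [h0, h1)
        if b <= h0 or a >= h1:
            test_inter.append((a, b))
        else:
            if a < h0:
                test_inter.append((a, h0))
            if b > h1:
                test_inter.append((h1, b))
    test_hours = max(_hours_in(test_inter), 1e-9)

    runs: list[TrainingRun] = []
    for si, train_seizure in enumerate(anns):
        best: dict[float, tuple] = {}  # per-IT: (objective, chosen, alarms)
        for kind, c, subset, p, chans, it in product(
            space.kinds,
            space.multipliers,
            subsets,
            space.vote_fractions,
            channel_options,
            its,
        ):
            rows = _subset_rows(lengths, subset)
            stacks = [cache.markers(ch, kind, c)[rows] for ch in chans]
            if mode == "prediction":
                scheme = PredictionScheme(it_min=it, sop_min=sop_min)
                refractory = scheme.effective_refractory_min * 60.0
            else:
                scheme = None
                refractory = window_s
            alarms = combine_votes(
                stacks[0],
                p,
                window_s=window_s,
                start_time_s=first.start_time_s,
                refractory_s=refractory,
                channel_markers=stacks[1:] or None,
            )
            hit = _hits_seizure(alarms, train_seizure, mode, scheme, window_s)
            n_false = int(np.count_nonzero((alarms >= h0) & (alarms < h1)))
            objective = (0 if hit else 1, n_false, c)
            chosen = {
                "kind": kind,
                "c": c,
                "lengths": subset,
                "vote_fraction": p,
                "channels": chans,
                "it_min": it,
                "sop_min": sop_min if mode == "prediction" else None,
            }
            key = it if it is not None else 0.0
            if key not in best or objective < best[key][0]:
                best[key] = (objective, chosen, alarms)

        per_it: dict[float, dict] = {}
        overall = None
        for key, (objective, chosen, alarms) in best.items():
            heldout = _heldout_metrics(
                alarms, anns, si, mode, chosen, window_s,
                (h0, h1), test_hours, post_pad,
            )
            entry = {
                "chosen": chosen,
                "objective": {
                    "training_hit": objective[0] == 0,
                    "false_events": objective[1],
                    "c": objective[2],
                },
                "heldout": heldout,
            }
            per_it[key] = entry
            if overall is None or objective < overall[0]:
                overall = (objective, entry)
        _, winner = overall
        runs.append(
            TrainingRun(
                train_index=si,
                chosen=winner["chosen"],
                training_hit=winner["objective"]["training_hit"],
                training_false_events=winner["objective"]["false_events"],
                heldout=winner["heldout"],
                per_it=per_it,
            )
        )

    return TrainingResult(
        mode=mode,
        sop_min=sop_min if mode == "prediction" else None,
        reference_hour_s=(h0, h1),
        runs=runs,
        no_heldout=len(anns) < 2,
        seed=seed,
    )


def _hits_seizure(
    alarms: np.ndarray,
    seizure: SeizureAnnotation,
    mode: str,
    scheme: PredictionScheme | None,
    window_s: float,
) -> bool:
    if mode == "detection":
        return any(seizure.overlaps(t, t + window_s) for t in alarms)
    it_s = scheme.it_min * 60.0
    sop_s = scheme.sop_min * 60.0
    return bool(
        np.any(
            (alarms + it_s <= seizure.onset_s)
            & (seizure.onset_s < alarms + it_s + sop_s)
        )
    )


def _heldout_metrics(
    alarms: np.ndarray,
    anns: list[SeizureAnnotation],
    train_index: int,
    mode: str,
    chosen: dict,
    window_s: float,
    train_hour: tuple[float, float],
    test_hours: float,
    post_pad_s: float,
) -> dict | None:
    """Apply a trained configuration to the held-out seizures.

    The training hour and all alarms attributable to the training seizure
    (its preictal horizon for prediction, its ictal span for detection)
    are excluded so the training seizure never enters its own test
    aggregate.
    """
    heldout_anns = [a for a in anns if a is not anns[train_index]]
    h0, h1 = train_hour
    keep = ~((alarms >= h0) & (alarms < h1))
    train_seizure = anns[train_index]
    if mode == "prediction":
        scheme = PredictionScheme(
            it_min=chosen["it_min"], sop_min=chosen["sop_min"]
        )
        horizon_s = scheme.horizon_min * 60.0
        keep &= ~(
            (alarms >= train_seizure.onset_s - horizon_s)
            & (alarms < train_seizure.offset_s + post_pad_s)
        )
    else:
        keep &= ~(
            (alarms >= train_seizure.onset_s - window_s)
            & (alarms < train_seizure.offset_s + post_pad_s)
        )
    test_alarms = alarms[keep]
    if not heldout_anns:
        return None
    if mode == "prediction":
        result = evaluate_prediction(
            test_alarms, heldout_anns, scheme, test_hours,
            post_ictal_s=post_pad_s,
        )
    else:
        result = evaluate_detection(
            test_alarms, heldout_anns, test_hours, window_s=window_s,
            post_ictal_s=post_pad_s,
        )
    return result.as_dict()


# ---------------------------------------------------------------------------
# summaries


def _case_metrics(run: TrainingRun) -> dict:
    out = {
        "train_index": run.train_index,
        "chosen": run.chosen,
        "heldout": run.heldout,
    }
    if run.per_it:
        scored = [
            (e["heldout"]["false_rate_per_hour"],
             -(e["heldout"]["sensitivity"] or 0.0), it, e)
            for it, e in sorted(run.per_it.items())
            if e["heldout"] is not None
        ]
        if scored:
            out["opt_min_fpr"] = min(scored)[3]["heldout"]
            by_sens = [
                (-(e["heldout"]["sensitivity"] or 0.0),
                 e["heldout"]["false_rate_per_hour"], it, e)
                for it, e in sorted(run.per_it.items())
                if e["heldout"] is not None
            ]
            out["opt_max_sens"] = min(by_sens)[3]["heldout"]
    return out


def summarize_cases(result: TrainingResult) -> dict:
    """First-case and best-case summaries of a training result.

    ``first_case`` reports the run trained on seizure #1; ``best_case``
    the run with the highest held-out sensitivity (ties: lowest false
    rate, then earliest training seizure).
    """
    if not result.runs:
        raise TrainingError("empty training result")
    first = _case_metrics(result.runs[0])

    def rank(run: TrainingRun):
        if run.heldout is None:
            return (1, 0.0, 0.0, run.train_index)
        sens = run.heldout["sensitivity"]
        sens = -1.0 if sens is None else sens
        return (0, -sens, run.heldout["false_rate_per_hour"], run.train_index)

    best_run = min(result.runs, key=rank)
    return {"first_case": first, "best_case": _case_metrics(best_run)}
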