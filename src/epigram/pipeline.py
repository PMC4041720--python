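"""End-to-end convenience pipeline.

Chains the stages — signal conditioning, symbolization, windowing,
multiresolution pattern counting, training and evaluation — for a whole
recording, in the configuration used throughout the package's own
studies: 60 s windows, 8-bit symbols, overlapping multi-length patterns
(16, 14, 12, 10, 8, 6) counted per window.

The study configuration counts every unique cluster (``k_sig=0``) with
exact matching (a similarity threshold of 1): pseudo-periodic ictal
activity then collapses the number of unique patterns at every length by
orders of magnitude relative to irregular background, which is the margin
the thresholds exploit.  Sub-unit similarity thresholds are fully
supported by the engine but cost quadratic time in the number of clusters
per window, which is prohibitive at 15 360 symbols per window; they are
exercised on shorter windows.
"""

from __future__ import annotations

from dataclasses import dataclass

from epigram.ngram_engine import NgramConfig, PatternCountSeries, count_series
from epigram.preprocess import FilterConfig, preprocess_recording
from epigram.signal_io import MultichannelRecording, SeizureAnnotation
from epigram.symbolize import QuantizerConfig, segment_windows, symbolize_channel
from epigram.training import SearchSpace, TrainingResult, train_patient

__all__ = ["StudyConfig", "analyze_recording", "run_patient_study"]


@dataclass(frozen=True)
class StudyConfig:
    """Fixed analysis parameters of a detection/prediction study."""

    window_s: float = 60.0
    filter: FilterConfig = FilterConfig()
    quantizer: QuantizerConfig = QuantizerConfig(source_bits=16, target_bits=8)
    ngram: NgramConfig = NgramConfig(
        method=4,
        pattern_lengths=(16, 14, 12, 10, 8, 6),
        k_sig=0,
        similarity_metric="hamming",
        similarity_threshold=1.0,
    )
    preprocess: bool = True


def analyze_recording(
    recording: MultichannelRecording,
    config: StudyConfig | None = None,
) -> dict[str, PatternCountSeries]:
    """Condition, symbolize and pattern-count every channel.

    Returns the per-channel series of significant unique-pattern counts on
    a common window grid.
    """
    config = config or StudyConfig()
    rec = preprocess_recording(recording, config.filter) if config.preprocess \
        else recording
    out: dict[str, PatternCountSeries] = {}
    for label, x in zip(rec.channel_labels, rec.samples):
        seq = symbolize_channel(x, config.quantizer, channel=label)
        windows = segment_windows(seq, config.window_s, rec.sampling_rate)
        out[label] = count_series(
            windows,
            config.ngram,
            window_s=config.window_s,
            channel=label,
            start_time_s=rec.start_time,
        )
    return out


def run_patient_study(
    recording: MultichannelRecording,
    annotations: tuple[SeizureAnnotation, ...],
    *,
    mode: str = "prediction",
    sop_min: float = 10.0,
    space: SearchSpace | None = None,
    config: StudyConfig | None = None,
    seed: int = 0,
) -> TrainingResult:
    """Full study on one patient recording: analyze, then train/evaluate."""
    series = analyze_recording(recording, config)
    return train_patient(
        series,
        annotations,
        mode=mode,
        sop_min=sop_min,
        space=space,
        seed=seed,
        duration_s=recording.duration_s,
    )
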