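"""Synthetic intracranial EEG with planted seizures.

The generator emulates the statistical structure that the pattern-counting
method exploits, without attempting clinically faithful EEG morphology:

* interictal background: spectrally shaped Gaussian noise with a 1/f^alpha
  spectrum (alpha ~ 1), i.e. broadband, "high-dimensional" activity;
* ictal segments: high-amplitude pseudo-periodic bursts — a rhythm
  frequency plus decaying harmonics under a smooth on/off envelope — which
  collapse the number of unique large symbol patterns per window;
* optionally, a preictal ramp of the same rhythm growing linearly up to a
  fraction of the ictal amplitude ahead of onset, so prediction (not just
  detection) can be exercised;
* artifacts: additive mains interference and electrode/amplifier
  saturation plateaus clipped at the bit-depth rails.

Every sample derives from one explicit seed; identical configurations
produce bit-identical recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from epigram.signal_io import MultichannelRecording, SeizureAnnotation

__all__ = [
    "SynthConfig",
    "generate_recording",
    "inject_artifacts",
    "patient_config",
]


class PlacementError(ValueError):
    """Raised when the requested seizures cannot be placed disjointly."""


@dataclass(frozen=True)
class SynthConfig:
    """Synthetic-recording parameters (amplitudes in raw code units).

    The defaults model a 16-bit, 256 Hz, 3-focal-channel acquisition whose
    gain is set for ictal headroom: interictal background RMS of 400 codes
    (~1.2% of the +-32768 range, as for a ~100 uV background on a +-3 mV
    input span) leaves room for ictal discharges an order of magnitude
    larger.  Seizures average 1.8 minutes (0.5-2 min range) with a 3 Hz
    spike-wave-like rhythm whose peak amplitude is ``seizure_gain`` times
    the background RMS; artifacts comprise a 50 Hz mains component and
    optional saturation episodes.
    """

    duration_s: float
    sampling_rate: float = 256.0
    n_channels: int = 3
    bit_depth: int = 16
    seed: int = 0
    # background
    background_exponent: float = 1.0
    background_rms: float = 400.0
    # seizures
    n_seizures: int = 0
    seizure_mean_duration_s: float = 108.0
    seizure_duration_range_s: tuple[float, float] = (30.0, 120.0)
    seizure_onsets_s: tuple[float, ...] | None = None
    rhythm_freq: float = 3.0
    n_harmonics: int = 3
    seizure_gain: float = 8.0
    seizure_edge_s: float = 5.0
    # fraction of the background suppressed at full ictal drive: seizures
    # recruit the local network into synchronous firing, so the irregular
    # background largely disappears into the rhythm
    ictal_sync: float = 0.9
    # preictal regime (off by default: no preictal signature)
    preictal_ramp_s: float = 0.0
    preictal_gain_fraction: float = 0.5
    # artifacts
    mains_freq: float = 50.0
    mains_amplitude: float = 0.0
    saturation_count: int = 0
    saturation_duration_s: float = 2.0
    # placement
    min_gap_s: float = 900.0
    edge_margin_s: float = 120.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.sampling_rate <= 0:
            raise ValueError("duration and sampling rate must be positive")
        if self.rhythm_freq >= self.sampling_rate / 2:
            raise ValueError("rhythm_freq must lie below Nyquist")
        lo, hi = self.seizure_duration_range_s
        if not 0 < lo <= hi:
            raise ValueError("invalid seizure duration range")

    @property
    def rails(self) -> tuple[int, int]:
        half = 1 << (self.bit_depth - 1)
        return -half, half - 1


def _shaped_noise(
    rng: np.random.Generator, n: int, alpha: float, rms: float
) -> np.ndarray:
    """Gaussian noise with a 1/f^alpha amplitude spectrum and target RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-alpha / 2.0)
    shape[0] = 0.0  # no DC offset
    x = np.fft.irfft(spec * shape, n=n)
    x *= rms / max(np.sqrt(np.mean(x**2)), 1e-300)
    return x


def _place_seizures(
    config: SynthConfig, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Draw disjoint (onset, duration) pairs honouring margins and gaps."""
    lo, hi = config.seizure_duration_range_s
    durations = np.clip(
        rng.normal(config.seizure_mean_duration_s, 20.0, config.n_seizures),
        lo,
        hi,
    )
    lead = config.edge_margin_s + config.preictal_ramp_s
    if config.seizure_onsets_s is not None:
        onsets = np.asarray(config.seizure_onsets_s, dtype=float)
        if len(onsets) != config.n_seizures:
            raise PlacementError(
                f"{len(onsets)} onsets given for {config.n_seizures} seizures"
            )
    else:
        # evenly partition the timeline, jitter each onset within its slot
        usable = config.duration_s - lead - config.edge_margin_s
        need = durations.sum() + config.min_gap_s * max(config.n_seizures - 1, 0)
        if usable <= 0 or need > usable:
            raise PlacementError(
                f"cannot place {config.n_seizures} seizures disjointly in "
                f"{config.duration_s} s"
            )
        slot = usable / max(config.n_seizures, 1)
        onsets = np.array(
            [
                lead + k * slot + rng.uniform(0, max(slot - durations[k] - 1, 0))
                for k in range(config.n_seizures)
            ]
        )
    events = sorted(zip(onsets, durations))
    prev_end = None
    for onset, dur in events:
        if onset < lead - 1e-9 or onset + dur > config.duration_s - 1e-9:
            raise PlacementError("seizure outside the recording margins")
        if prev_end is not None and onset - prev_end < config.preictal_ramp_s:
            raise PlacementError("seizures too close to be disjoint events")
        prev_end = onset + dur
    return [(float(o), float(d)) for o, d in events]


def _rhythm_wave(
    config: SynthConfig, t: np.ndarray, phases: np.ndarray
) -> np.ndarray:
    """Pseudo-periodic ictal waveform, peak-normalized to ~1."""
    wave = np.zeros_like(t)
    for h in range(1, config.n_harmonics + 1):
        wave += np.sin(2 * np.pi * h * config.rhythm_freq * t + phases[h - 1]) / h
    return wave / np.max(np.abs(wave), initial=1.0)


def generate_recording(
    config: SynthConfig,
) -> tuple[MultichannelRecording, tuple[SeizureAnnotation, ...]]:
    """Generate an annotated integer recording from a configuration.

    Background, seizures and (if configured) artifacts are superposed per
    channel, clipped to the bit-depth rails and rounded to integer codes.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs
    events = _place_seizures(config, rng) if config.n_seizures else []

    channels = np.empty((config.n_channels, n), dtype=np.float64)
    for ch in range(config.n_channels):
        x = _shaped_noise(rng, n, config.background_exponent, config.background_rms)
        amp_peak = config.seizure_gain * config.background_rms
        for onset, dur in events:
            phases = rng.uniform(0, 2 * np.pi, config.n_harmonics)
            i0, i1 = int(onset * fs), int((onset + dur) * fs)
            seg_t = t[i0:i1]
            envelope = np.ones(i1 - i0)
            edge = int(min(config.seizure_edge_s, dur / 2) * fs)
            if edge > 0:
                ramp = 0.5 * (1 - np.cos(np.pi * np.arange(edge) / edge))
                envelope[:edge] = ramp
                envelope[-edge:] = ramp[::-1]
            x[i0:i1] *= 1.0 - config.ictal_sync * envelope
            x[i0:i1] += amp_peak * envelope * _rhythm_wave(config, seg_t, phases)
            if config.preictal_ramp_s > 0:
                p0 = int((onset - config.preictal_ramp_s) * fs)
                pre_t = t[p0:i0]
                grow = np.linspace(0.0, 1.0, i0 - p0, endpoint=False)
                pre_amp = config.preictal_gain_fraction * amp_peak
                x[p0:i0] += pre_amp * grow * _rhythm_wave(config, pre_t, phases)
        channels[ch] = x

    lo, hi = config.rails
    recording = MultichannelRecording(
        samples=np.clip(np.rint(channels), lo, hi).astype(np.int32),
        sampling_rate=fs,
        channel_labels=tuple(f"focal{i}" for i in range(config.n_channels)),
        bit_depth=config.bit_depth,
    )
    if config.mains_amplitude > 0 or config.saturation_count > 0:
        recording = inject_artifacts(recording, config)
    annotations = tuple(
        SeizureAnnotation(onset, onset + dur, f"seizure{k}")
        for k, (onset, dur) in enumerate(events)
    )
    return recording, annotations


def inject_artifacts(
    recording: MultichannelRecording, config: SynthConfig
) -> MultichannelRecording:
    """Add mains interference and saturation episodes to a recording.

    The 50 Hz (by default) sinusoid is added to every channel; each
    saturation episode drives all channels onto a bit-depth rail for
    ``saturation_duration_s``.  Output stays within the integer code range.
    """
    rng = np.random.default_rng(config.seed + 0x5A7)
    fs = recording.sampling_rate
    n = recording.n_samples
    t = np.arange(n) / fs
    x = recording.samples.astype(np.float64)
    if config.mains_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        x += config.mains_amplitude * np.sin(
            2 * np.pi * config.mains_freq * t + phase
        )
    lo, hi = recording.code_range
    if config.saturation_count > 0:
        dur = int(config.saturation_duration_s * fs)
        if dur >= n:
            raise ValueError("saturation episode longer than recording")
        starts = np.sort(rng.choice(n - dur, config.saturation_count, replace=False))
        # keep plateaus apart so they stay countable as distinct episodes
        for k in range(1, len(starts)):
            if starts[k] - starts[k - 1] < 2 * dur:
                starts[k] = min(starts[k - 1] + 2 * dur, n - dur - 1)
        for k, s in enumerate(starts):
            rail = hi if k % 2 == 0 else lo
            x[:, s : s + dur] = 2.0 * rail
    clipped = np.clip(np.rint(x), lo, hi).astype(np.int32)
    return replace(recording, samples=clipped)


def patient_config(seed: int, *, preictal: bool = True) -> SynthConfig:
    """Canonical synthetic patient used in the package's own studies.

    ~4.2 hours at 256 Hz on 3 focal channels with 3 planted seizures, over
    2 hours of clean seizure-free background and mains interference (the
    notch stage removes it); saturation artifacts are left out here and
    exercised separately.  With ``preictal=True`` each seizure is preceded
    by a 20-minute linear rhythm ramp (the regime prediction studies
    exercise); with ``preictal=False`` seizures start abruptly out of
    background (the detection regime).
    """
    return SynthConfig(
        duration_s=15000.0,
        n_seizures=3,
        seizure_onsets_s=(2520.0, 6720.0, 10920.0),
        preictal_ramp_s=1200.0 if preictal else 0.0,
        preictal_gain_fraction=0.5,
        mains_amplitude=200.0,
        seed=seed,
    )
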