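"""Signal conditioning: mains-notch filtering and smoothing-based
artifact suppression.

Two linear filters are applied before symbolization:

* a zero-phase Butterworth band-stop ("notch") around the mains frequency
  (50 Hz in Europe), and
* a smooth-and-subtract stage: a least-squares polynomial (Savitzky-Golay
  style) smooth over a 101-point window (50 samples each side) is computed
  and *subtracted* from the signal.  Slow, large-amplitude structure such as
  electrode/amplifier saturation plateaus and baseline drift lives in the
  smooth component and is thereby removed, while fast oscillatory activity
  passes through essentially untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from epigram.signal_io import MultichannelRecording

__all__ = [
    "FilterConfig",
    "notch_filter",
    "artifact_smooth_subtract",
    "preprocess_recording",
]


@dataclass(frozen=True)
class FilterConfig:
    """Parameters of the conditioning chain.

    mains_freq
        Centre of the band-stop, Hz.
    notch_order
        Butterworth band-stop order (even, >= 2).
    notch_half_bandwidth
        Half width of the stop band, Hz.
    smooth_half_width
        Samples each side of the centre point of the smoothing window;
        50 gives the 101-point window.
    smooth_poly_order
        Degree of the least-squares polynomial ("quadratic" smoothing by
        default).
    """

    mains_freq: float = 50.0
    notch_order: int = 4
    notch_half_bandwidth: float = 1.0
    smooth_half_width: int = 50
    smooth_poly_order: int = 2

    def __post_init__(self) -> None:
        if self.notch_order < 2 or self.notch_order % 2:
            raise ValueError("notch_order must be an even integer >= 2")
        if self.smooth_half_width < 1:
            raise ValueError("smooth_half_width must be >= 1")
        if self.smooth_poly_order >= 2 * self.smooth_half_width + 1:
            raise ValueError("smooth_poly_order must be < window length")

    @property
    def smooth_window(self) -> int:
        return 2 * self.smooth_half_width + 1


def notch_filter(
    recording: MultichannelRecording, config: FilterConfig | None = None
) -> MultichannelRecording:
    """Zero-phase Butterworth band-stop around the mains frequency.

    The filter is applied forward and backward (``sosfiltfilt``) so alarm
    timing downstream is not smeared by phase delay.  Output samples are
    floating point; length and channel order are preserved.
    """
    config = config or FilterConfig()
    nyquist = recording.sampling_rate / 2.0
    hi = config.mains_freq + config.notch_half_bandwidth
    if hi >= nyquist:
        raise ValueError(
            f"stop band edge {hi} Hz must lie below Nyquist {nyquist} Hz"
        )
    lo = config.mains_freq - config.notch_half_bandwidth
    # butter() doubles the order for band filters; halve to honour the
    # requested overall order.
    sos = sps.butter(
        config.notch_order // 2,
        [lo / nyquist, hi / nyquist],
        btype="bandstop",
        output="sos",
    )
    filtered = sps.sosfiltfilt(sos, recording.samples.astype(np.float64), axis=1)
    return replace(recording, samples=filtered)


def artifact_smooth_subtract(
    x: np.ndarray, config: FilterConfig | None = None
) -> np.ndarray:
    """Subtract the sliding least-squares polynomial smooth from a signal.

    At every sample a polynomial of degree ``smooth_poly_order`` is fitted
    over the surrounding ``2*smooth_half_width + 1`` points and its central
    value taken as the smoothed signal, which is then removed.  Any
    polynomial trend of degree <= the fit order is annihilated exactly in
    the window interior; edges use mirror padding.
    """
    config = config or FilterConfig()
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("expects a single-channel sample vector")
    if x.size <= 2 * config.smooth_half_width:
        raise ValueError(
            f"signal length {x.size} must exceed 2*half_width "
            f"({2 * config.smooth_half_width})"
        )
    smoothed = sps.savgol_filter(
        x, config.smooth_window, config.smooth_poly_order, mode="mirror"
    )
    return x - smoothed


def preprocess_recording(
    recording: MultichannelRecording, config: FilterConfig | None = None
) -> MultichannelRecording:
    """Full conditioning chain: notch first, then smooth-and-subtract."""
    config = config or FilterConfig()
    notched = notch_filter(recording, config)
    cleaned = np.vstack(
        [artifact_smooth_subtract(ch, config) for ch in notched.samples]
    )
    return replace(notched, samples=cleaned)
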