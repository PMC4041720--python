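"""Amplitude re-quantization and hexadecimal symbolization.

A B-bit acquisition maps the reference span [Vref-, Vref+] onto the
integer codes 0 .. 2^B - 1.  Re-quantization to a coarser b-bit alphabet
simply truncates the B - b least significant bits; signed acquisition codes
are first offset-shifted into the unsigned range.  Each b-bit code is then
written as a fixed-width uppercase hexadecimal symbol, and the symbol
stream is cut into fixed, non-overlapping analysis windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "QuantizerConfig",
    "SymbolSequence",
    "requantize",
    "quantize_real",
    "encode_symbols",
    "decode_symbols",
    "segment_windows",
    "symbolize_channel",
]


@dataclass(frozen=True)
class QuantizerConfig:
    """Re-quantization parameters.

    source_bits
        Bit depth B of the acquisition codes.
    target_bits
        Bit depth b of the symbol alphabet (alphabet size 2^b);
        8 bits is the working default, which empirically yields the most
        variation in meaningful patterns on intracranial EEG.
    vref
        (Vref-, Vref+) span, only needed for real-valued (e.g. filtered)
        input.  Defaults to the signed code range of ``source_bits`` so that
        filtered signals in raw code units re-digitize consistently.
    levels
        Optional non-binary level count; when set, real-valued input is
        quantized onto this many uniform levels instead of 2^target_bits.
    """

    source_bits: int = 16
    target_bits: int = 8
    vref: tuple[float, float] | None = None
    levels: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.target_bits <= self.source_bits:
            raise ValueError(
                f"need 1 <= target_bits ({self.target_bits}) <= "
                f"source_bits ({self.source_bits})"
            )
        if self.levels is not None and self.levels < 2:
            raise ValueError("levels must be >= 2")

    @property
    def n_levels(self) -> int:
        return self.levels if self.levels is not None else 1 << self.target_bits

    @property
    def span(self) -> tuple[float, float]:
        if self.vref is not None:
            return self.vref
        half = float(1 << (self.source_bits - 1))
        return -half, half


def requantize(
    codes: Sequence[int] | np.ndarray,
    config: QuantizerConfig,
    *,
    signed: bool | None = None,
) -> np.ndarray:
    """Truncate B-bit amplitude codes to an unsigned b-bit alphabet by
    dropping the B - b least significant bits.

    Signed codes are first offset-shifted by 2^(B-1) into 0 .. 2^B - 1 so
    truncation acts on non-negative values.  With ``signed=None`` the
    convention is inferred: any negative code implies signed input,
    otherwise the codes are taken as already unsigned.  The mapping is
    monotone and, for b = B, the identity (up to the offset shift).
    """
    codes = np.asarray(codes)
    if not np.issubdtype(codes.dtype, np.integer):
        raise TypeError("requantize expects integer codes; see quantize_real")
    B, b = config.source_bits, config.target_bits
    half = 1 << (B - 1)
    if signed is None:
        signed = bool(codes.size and codes.min() < 0)
    lo, hi = (-half, half - 1) if signed else (0, (1 << B) - 1)
    if codes.size and (codes.min() < lo or codes.max() > hi):
        raise ValueError(
            f"codes exceed {'signed' if signed else 'unsigned'} {B}-bit range"
        )
    shifted = codes.astype(np.int64) + (half if signed else 0)
    return (shifted >> (B - b)).astype(np.int64)


def quantize_real(x: np.ndarray, config: QuantizerConfig) -> np.ndarray:
    """Digitize real-valued samples onto the target alphabet.

    Uniform quantization of the [Vref-, Vref+] span onto ``n_levels``
    codes with floor rounding, clamped to the code range.  Used to
    re-digitize filtered (non-integer) signals before symbolization.
    """
    x = np.asarray(x, dtype=np.float64)
    lo, hi = config.span
    n = config.n_levels
    q = np.floor((x - lo) / (hi - lo) * n)
    return np.clip(q, 0, n - 1).astype(np.int64)


@dataclass
class SymbolSequence:
    """A window of b-bit symbol codes.

    ``codes`` are the integer symbol values; the hexadecimal string view is
    available through :attr:`symbols` / :meth:`to_hex`.
    """

    codes: np.ndarray
    alphabet_bits: int = 8
    start_sample: int = 0
    channel: str = ""

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.ndim != 1:
            raise ValueError("codes must be one-dimensional")
        hi = (1 << self.alphabet_bits) - 1
        if self.codes.size and (self.codes.min() < 0 or self.codes.max() > hi):
            raise ValueError(
                f"symbol codes outside [0, {hi}] for a "
                f"{self.alphabet_bits}-bit alphabet"
            )

    def __len__(self) -> int:
        return self.codes.size

    @property
    def hex_width(self) -> int:
        return -(-self.alphabet_bits // 4)

    @property
    def symbols(self) -> list[str]:
        return self.to_hex()

    def to_hex(self) -> list[str]:
        w = self.hex_width
        return [format(int(c), f"0{w}X") for c in self.codes]


def encode_symbols(
    codes: Sequence[int] | np.ndarray,
    b: int = 8,
    *,
    start_sample: int = 0,
    channel: str = "",
) -> SymbolSequence:
    """Wrap unsigned codes in [0, 2^b - 1] as a hexadecimal symbol sequence."""
    return SymbolSequence(
        codes=np.asarray(codes),
        alphabet_bits=b,
        start_sample=start_sample,
        channel=channel,
    )


def decode_symbols(symbols: Sequence[str], b: int = 8) -> np.ndarray:
    """Inverse of the hexadecimal encoding."""
    codes = np.array([int(s, 16) for s in symbols], dtype=np.int64)
    hi = (1 << b) - 1
    if codes.size and (codes.min() < 0 or codes.max() > hi):
        raise ValueError(f"symbol decodes outside [0, {hi}]")
    return codes


def segment_windows(
    seq: SymbolSequence, window_s: float, sampling_rate: float
) -> list[SymbolSequence]:
    """Cut a symbol stream into consecutive non-overlapping windows.

    Each window holds exactly ``window_s * sampling_rate`` symbols (which
    must be a whole number >= 1); a trailing partial window is discarded.
    """
    w = window_s * sampling_rate
    n = int(round(w))
    if n < 1 or abs(w - n) > 1e-9:
        raise ValueError(
            f"window of {window_s} s at {sampling_rate} Hz is not a whole "
            f"number of samples"
        )
    out = []
    for k in range(len(seq) // n):
        out.append(
            SymbolSequence(
                codes=seq.codes[k * n : (k + 1) * n],
                alphabet_bits=seq.alphabet_bits,
                start_sample=seq.start_sample + k * n,
                channel=seq.channel,
            )
        )
    return out


def symbolize_channel(
    x: np.ndarray,
    config: QuantizerConfig | None = None,
    *,
    channel: str = "",
) -> SymbolSequence:
    """Symbolize one channel: integer codes are truncated, real samples
    re-digitized through the reference span first."""
    config = config or QuantizerConfig()
    x = np.asarray(x)
    if np.issubdtype(x.dtype, np.integer):
        codes = requantize(x, config, signed=True)
        bits = config.target_bits
    else:
        codes = quantize_real(x, config)
        # a non-binary level count needs enough bits to hold every code
        bits = max(config.target_bits, int(config.n_levels - 1).bit_length())
    return SymbolSequence(codes=codes, alphabet_bits=bits, channel=channel)
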