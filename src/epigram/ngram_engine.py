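"""Multiresolution N-gram pattern extraction and counting.

Within each fixed analysis window, contiguous runs of symbols (N-grams) are
extracted and clustered; the per-window number of unique (and of
*significant*, i.e. repeating) pattern clusters is the feature tracked for
seizure detection and prediction.  Four extraction methods are provided:

1. non-overlapping, single pattern length (the window is tiled);
2. overlapping, single pattern length (one-symbol steps);
3. non-overlapping, multiple lengths (method 1 run per length);
4. overlapping, multiple lengths with *dominance*: at each position the
   longest configured pattern is looked up first, and if it is already
   known the shorter patterns at that position are skipped — the largest
   repeating pattern dominates anything it overlaps.  If no length matches,
   the substrings at every configured length enter the tables as new
   clusters.

Clustering uses a similarity index instead of exact matching, so that small
symbol-level variations of one underlying waveform are counted together:
either the inverse Hamming distance (fraction of agreeing positions) or a
Needleman-Wunsch global-alignment score (match +2, mismatch 0, gap -1,
normalized by the summed pattern lengths).  A candidate joins the first
cluster, in insertion order, whose representative is at least
``similarity_threshold`` similar; a threshold of 1 recovers exact matching.

Pseudo-periodic (seizure-like) activity collapses the number of unique
large patterns in a window, while irregular background keeps it high — that
contrast is the detection/prediction signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from epigram import _kernels
from epigram.symbolize import SymbolSequence

__all__ = [
    "NgramConfig",
    "PatternCluster",
    "PatternTable",
    "PatternCountSeries",
    "inverse_hamming",
    "nw_similarity",
    "match_cluster",
    "extract_window_patterns",
    "count_series",
]

_METRICS = ("exact", "hamming", "nw")


@dataclass(frozen=True)
class NgramConfig:
    """Configuration of the pattern extraction stage.

    method
        1 = non-overlap single, 2 = overlap single, 3 = non-overlap multi,
        4 = overlap multi with dominance (the best performer).
    pattern_lengths
        Distinct positive lengths, kept in descending order; methods 1 and
        2 require exactly one.
    k_sig
        A cluster is *significant* when its count exceeds ``k_sig``
        occurrences; ``k_sig=0`` counts every unique cluster.
    similarity_metric
        "hamming" (default), "nw" or "exact".
    similarity_threshold
        Minimum similarity for joining an existing cluster, in (0, 1].
    """

    method: int = 4
    pattern_lengths: tuple[int, ...] = (16, 14, 12, 10, 8, 6)
    k_sig: int = 1
    similarity_metric: str = "hamming"
    similarity_threshold: float = 0.8

    def __post_init__(self) -> None:
        if self.method not in (1, 2, 3, 4):
            raise ValueError("method must be 1, 2, 3 or 4")
        lengths = tuple(int(n) for n in self.pattern_lengths)
        if not lengths or any(n < 1 for n in lengths):
            raise ValueError("pattern_lengths must be positive integers")
        if len(set(lengths)) != len(lengths):
            raise ValueError("pattern_lengths must be distinct")
        object.__setattr__(
            self, "pattern_lengths", tuple(sorted(lengths, reverse=True))
        )
        if self.method in (1, 2) and len(lengths) != 1:
            raise ValueError(f"method {self.method} takes exactly one length")
        if self.similarity_metric not in _METRICS:
            raise ValueError(f"similarity_metric must be one of {_METRICS}")
        if not 0.0 < self.similarity_threshold <= 1.0:
            raise ValueError("similarity_threshold must lie in (0, 1]")
        if self.k_sig < 0:
            raise ValueError("k_sig must be >= 0")

    @property
    def exact(self) -> bool:
        """True when clustering degenerates to exact matching."""
        return self.similarity_metric == "exact" or (
            self.similarity_metric == "hamming"
            and self.similarity_threshold >= 1.0
        )


# ---------------------------------------------------------------------------
# similarity metrics


def inverse_hamming(p: Sequence[int], q: Sequence[int]) -> float:
    """Fraction of positions at which two equal-length patterns agree."""
    p = np.asarray(p)
    q = np.asarray(q)
    if p.size != q.size or p.size == 0:
        raise ValueError("inverse_hamming needs equal, non-zero lengths")
    return float(np.count_nonzero(p == q)) / p.size


_NW_MATCH = 2
_NW_MISMATCH = 0
_NW_GAP = -1


def nw_similarity(p: Sequence[int], q: Sequence[int]) -> float:
    """Needleman-Wunsch similarity of two (possibly unequal) patterns.

    Symbols absent from the other pattern are removed first; the filtered
    patterns are globally aligned with match +2, mismatch 0, gap -1; the
    optimal score is divided by the sum of the *original* lengths and
    negative values clamp to zero.  Identical patterns score exactly 1.
    """
    p = tuple(int(v) for v in p)
    q = tuple(int(v) for v in q)
    if not p or not q:
        raise ValueError("nw_similarity needs non-empty patterns")
    sp, sq = set(p), set(q)
    fp = [v for v in p if v in sq]
    fq = [v for v in q if v in sp]
    score = _nw_score(fp, fq)
    sim = score / (len(p) + len(q))
    return max(0.0, sim)


def _nw_score(a: Sequence[int], b: Sequence[int]) -> float:
    """Optimal global-alignment score (dynamic programming)."""
    if not a or not b:
        return _NW_GAP * (len(a) + len(b))
    a_arr = np.asarray(a)
    b_arr = np.asarray(b)
    prev = _NW_GAP * np.arange(len(b) + 1, dtype=np.float64)
    for i in range(1, len(a) + 1):
        cur = np.empty_like(prev)
        cur[0] = _NW_GAP * i
        sub = np.where(b_arr == a_arr[i - 1], _NW_MATCH, _NW_MISMATCH)
        for j in range(1, len(b) + 1):
            cur[j] = max(
                prev[j - 1] + sub[j - 1],
                prev[j] + _NW_GAP,
                cur[j - 1] + _NW_GAP,
            )
        prev = cur
    return float(prev[-1])


def _similarity(metric: str, p: Sequence[int], q: Sequence[int]) -> float:
    if metric == "hamming":
        return inverse_hamming(p, q)
    if metric == "nw":
        return nw_similarity(p, q)
    # exact
    p = np.asarray(p)
    q = np.asarray(q)
    return 1.0 if p.size == q.size and bool(np.all(p == q)) else 0.0


# ---------------------------------------------------------------------------
# pattern tables


@dataclass
class PatternCluster:
    """A cluster of mutually similar patterns: first-seen representative
    plus the number of member occurrences."""

    representative: tuple[int, ...]
    count: int = 1


@dataclass
class PatternTable:
    """All clusters found at one pattern length within one window."""

    length: int
    clusters: list[PatternCluster] = field(default_factory=list)
    alphabet_bits: int = 8

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def total_count(self) -> int:
        return sum(c.count for c in self.clusters)

    def significant(self, k_sig: int) -> list[PatternCluster]:
        """Clusters that occurred more than ``k_sig`` times."""
        return [c for c in self.clusters if c.count > k_sig]

    def representative_hex(self, cluster: PatternCluster) -> str:
        w = -(-self.alphabet_bits // 4)
        return "".join(format(v, f"0{w}X") for v in cluster.representative)


def match_cluster(
    table: PatternTable,
    candidate: Sequence[int],
    config: NgramConfig,
) -> PatternCluster | None:
    """First cluster (insertion order) whose representative is at least
    ``similarity_threshold`` similar to the candidate, or None.

    With the Hamming metric the candidate must have the table's length;
    the alignment metric accepts any length.
    """
    cand = tuple(int(v) for v in candidate)
    metric = config.similarity_metric
    if metric in ("hamming", "exact") and len(cand) != table.length:
        raise ValueError(
            f"candidate length {len(cand)} != table length {table.length}"
        )
    tau = config.similarity_threshold
    for cluster in table.clusters:
        if _similarity(metric, cand, cluster.representative) >= tau:
            return cluster
    return None


# ---------------------------------------------------------------------------
# window scans
#
# Internal scans keep clusters as parallel lists (representatives, counts)
# so that the hot exact path can use a bytes -> index dictionary and the
# Hamming path a vectorized comparison against the stacked representatives.


class _Table:
    __slots__ = ("n", "reps", "counts", "index", "mat")

    def __init__(self, n: int, exact: bool):
        self.n = n
        self.reps: list[bytes | tuple] = []
        self.counts: list[int] = []
        self.index: dict | None = {} if exact else None
        self.mat: np.ndarray | None = None  # lazily grown (cap, n) array


def _table_match_exact(tbl: _Table, key: bytes) -> int:
    idx = tbl.index.get(key, -1)
    return idx


def _table_add_exact(tbl: _Table, key: bytes) -> None:
    tbl.index[key] = len(tbl.reps)
    tbl.reps.append(key)
    tbl.counts.append(1)


def _table_match_sim(
    tbl: _Table, cand: np.ndarray, metric: str, tau: float
) -> int:
    k = len(tbl.reps)
    if k == 0:
        return -1
    if metric == "hamming":
        sims = np.count_nonzero(tbl.mat[:k] == cand, axis=1) / tbl.n
        hits = np.flatnonzero(sims >= tau)
        return int(hits[0]) if hits.size else -1
    for i in range(k):
        if _similarity(metric, cand, tbl.reps[i]) >= tau:
            return i
    return -1


def _table_add_sim(tbl: _Table, cand: np.ndarray) -> None:
    k = len(tbl.reps)
    if tbl.mat is None or k == len(tbl.mat):
        cap = max(64, 2 * k)
        new = np.empty((cap, tbl.n), dtype=np.int64)
        if tbl.mat is not None:
            new[:k] = tbl.mat[:k]
        tbl.mat = new
    tbl.mat[k] = cand
    tbl.reps.append(tuple(int(v) for v in cand))
    tbl.counts.append(1)


def _scan_exact(
    codes: np.ndarray, lengths: Sequence[int], stride: int
) -> dict[int, _Table]:
    """Dominance scan with exact matching via a bytes-keyed dictionary."""
    if codes.size and codes.max() > 255:
        buf = codes.astype(">u2").tobytes()
        width = 2
    else:
        buf = codes.astype(np.uint8).tobytes()
        width = 1
    W = codes.size
    tables = {n: _Table(n, exact=True) for n in lengths}
    for t in range(0, W, stride):
        o = t * width
        matched = False
        for n in lengths:
            if t + n > W:
                continue
            tbl = tables[n]
            key = buf[o : o + n * width]
            idx = tbl.index.get(key, -1)
            if idx >= 0:
                tbl.counts[idx] += 1
                matched = True
                break
        if not matched:
            for n in lengths:
                if t + n <= W:
                    tbl = tables[n]
                    key = buf[o : o + n * width]
                    tbl.index[key] = len(tbl.reps)
                    tbl.reps.append(key)
                    tbl.counts.append(1)
    return tables


def _scan_sim(
    codes: np.ndarray,
    lengths: Sequence[int],
    stride: int,
    metric: str,
    tau: float,
) -> dict[int, _Table]:
    """Dominance scan with similarity clustering."""
    W = codes.size
    tables = {n: _Table(n, exact=False) for n in lengths}
    for t in range(0, W, stride):
        matched = False
        for n in lengths:
            if t + n > W:
                continue
            tbl = tables[n]
            cand = codes[t : t + n]
            idx = _table_match_sim(tbl, cand, metric, tau)
            if idx >= 0:
                tbl.counts[idx] += 1
                matched = True
                break
        if not matched:
            for n in lengths:
                if t + n <= W:
                    _table_add_sim(tables[n], codes[t : t + n])
    return tables


def _scan(
    codes: np.ndarray, config: NgramConfig
) -> dict[int, _Table]:
    """Run the configured method; returns internal tables per length."""
    lengths = config.pattern_lengths
    if config.method == 1:
        n = lengths[0]
        return _run_one(codes, (n,), stride=n, config=config)
    if config.method == 2:
        return _run_one(codes, lengths, stride=1, config=config)
    if config.method == 3:
        out: dict[int, _Table] = {}
        for n in lengths:
            out.update(_run_one(codes, (n,), stride=n, config=config))
        return out
    return _run_one(codes, lengths, stride=1, config=config)


def _run_one(
    codes: np.ndarray,
    lengths: Sequence[int],
    stride: int,
    config: NgramConfig,
) -> dict[int, _Table]:
    if config.exact:
        return _scan_exact(codes, lengths, stride)
    return _scan_sim(
        codes, lengths, stride, config.similarity_metric,
        config.similarity_threshold,
    )


def _decode_rep(rep, width: int) -> tuple[int, ...]:
    if isinstance(rep, bytes):
        dtype = ">u2" if width == 2 else np.uint8
        return tuple(int(v) for v in np.frombuffer(rep, dtype=dtype))
    return rep


def _window_cluster_counts(
    codes: np.ndarray, config: NgramConfig
) -> list[tuple[int, np.ndarray]]:
    """Per-length cluster occurrence counts for one window.

    Dispatches to the packed numba kernel when exact matching applies and
    the alphabet/pattern lengths fit; otherwise runs the reference scan.
    """
    lengths = config.pattern_lengths
    if config.exact and _kernels.supports_fast(codes, lengths):
        if config.method == 1:
            n = lengths[0]
            fast = _kernels.scan_exact_fast(codes, (n,), stride=n)
        elif config.method == 3:
            fast = {}
            for n in lengths:
                fast.update(_kernels.scan_exact_fast(codes, (n,), stride=n))
        else:  # methods 2 and 4 share the stride-1 scan
            fast = _kernels.scan_exact_fast(codes, lengths, stride=1)
        return [(n, fast[n][2]) for n in lengths]
    tables = _scan(codes, config)
    return [(n, np.asarray(tables[n].counts)) for n in lengths]


# ---------------------------------------------------------------------------
# public extraction API


def extract_window_patterns(
    window: SymbolSequence, config: NgramConfig
) -> dict[int, PatternTable]:
    """Extract pattern tables for one window, one per configured length.

    A length longer than the window yields an empty table.
    """
    codes = window.codes
    tables = _scan(codes, config)
    width = 2 if (codes.size and codes.max() > 255) else 1
    out: dict[int, PatternTable] = {}
    for n in config.pattern_lengths:
        tbl = tables[n]
        out[n] = PatternTable(
            length=n,
            clusters=[
                PatternCluster(_decode_rep(rep, width), count)
                for rep, count in zip(tbl.reps, tbl.counts)
            ],
            alphabet_bits=window.alphabet_bits,
        )
    return out


@dataclass
class PatternCountSeries:
    """Per-window counts of significant unique pattern clusters.

    ``counts[i, t]`` is the number of clusters with more than ``k_sig``
    occurrences in window ``t`` at pattern length ``lengths[i]``.
    """

    lengths: tuple[int, ...]
    counts: np.ndarray  # (n_lengths, n_windows) int
    window_s: float
    channel: str = ""
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != len(self.lengths):
            raise ValueError("counts must be (n_lengths, n_windows)")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_windows(self) -> int:
        return self.counts.shape[1]

    def window_start_times(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.n_windows) * self.window_s

    def window_index_at(self, time_s: float) -> int:
        return int((time_s - self.start_time_s) // self.window_s)


def count_series(
    windows: Sequence[SymbolSequence],
    config: NgramConfig,
    *,
    window_s: float | None = None,
    channel: str = "",
    start_time_s: float = 0.0,
) -> PatternCountSeries:
    """Count significant unique patterns per window and pattern length.

    Tables are reset at every window boundary: patterns never persist
    across windows.
    """
    lengths = config.pattern_lengths
    counts = np.zeros((len(lengths), len(windows)), dtype=np.int64)
    for t, win in enumerate(windows):
        for i, (n, cs) in enumerate(_window_cluster_counts(win.codes, config)):
            counts[i, t] = int(np.count_nonzero(np.asarray(cs) > config.k_sig))
    if window_s is None:
        window_s = float(len(windows[0])) if windows else 0.0
    return PatternCountSeries(
        lengths=lengths,
        counts=counts,
        window_s=window_s,
        channel=channel,
        start_time_s=start_time_s,
    )


def tables_to_rows(
    tables_by_window: Iterable[dict[int, PatternTable]],
) -> list[dict]:
    """Flatten per-window pattern tables into pattern-count TSV rows."""
    rows = []
    for w, tables in enumerate(tables_by_window):
        for n, table in sorted(tables.items(), reverse=True):
            for cluster in table.clusters:
                rows.append(
                    {
                        "window_index": w,
                        "pattern_length": n,
                        "representative_pattern_hex": table.representative_hex(
                            cluster
                        ),
                        "count": cluster.count,
                    }
                )
    return rows
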