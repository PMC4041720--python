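import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epigram.ngram_engine import (
    NgramConfig,
    PatternCluster,
    PatternTable,
    count_series,
    extract_window_patterns,
    inverse_hamming,
    match_cluster,
    nw_similarity,
    tables_to_rows,
)
from epigram.symbolize import SymbolSequence

from reference_ngram import (
    brute_sliding_counts,
    brute_tiling_counts,
    oracle_nw_similarity,
    reference_multilength_scan,
)

# the worked bigram example sequence C, A, 5, 8, A, 5
FIG_SEQ = (0xC, 0xA, 0x5, 0x8, 0xA, 0x5)


def _win(codes, bits=8):
    return SymbolSequence(np.asarray(codes, dtype=np.int64), alphabet_bits=bits)


def _table_as_pairs(table: PatternTable):
    return [(c.representative, c.count) for c in table.clusters]


class TestInverseHamming:
    def test_identical_tuples_score_one(self):
        p = tuple(range(12))
        assert inverse_hamming(p, p) == 1.0

    def test_disjoint_tuples_score_zero(self):
        assert inverse_hamming((1, 2, 3), (4, 5, 6)) == 0.0

    def test_three_quarters_agreement(self):
        assert inverse_hamming((10, 11, 10, 11), (10, 11, 11, 11)) == 0.75

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            inverse_hamming((1, 2), (1, 2, 3))

    @given(st.lists(st.integers(0, 15), min_size=1, max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_symmetric_and_bounded(self, p):
        q = list(reversed(p))
        s = inverse_hamming(p, q)
        assert 0.0 <= s <= 1.0
        assert s == inverse_hamming(q, p)


class TestNwSimilarity:
    def test_identical_tuples_score_exactly_one(self):
        p = (1, 2, 3, 4, 5)
        assert nw_similarity(p, p) == 1.0

    def test_no_shared_symbols_scores_zero(self):
        assert nw_similarity((1, 2, 3), (4, 5, 6)) == 0.0

    def test_deletion_case(self):
        # (A,B,C) vs (A,C): B filtered out, perfect alignment of (A,C)
        # scores 4, normalized by 3 + 2 original symbols
        assert nw_similarity((10, 11, 12), (10, 12)) == pytest.approx(0.8)

    def test_empty_pattern_rejected(self):
        with pytest.raises(ValueError):
            nw_similarity((), (1,))

    def test_matches_enumeration_oracle_on_random_pairs(self, rng):
        for _ in range(60):
            p = tuple(rng.integers(0, 4, rng.integers(1, 6)))
            q = tuple(rng.integers(0, 4, rng.integers(1, 6)))
            assert nw_similarity(p, q) == pytest.approx(
                oracle_nw_similarity(p, q)
            ), (p, q)

    def test_agrees_with_hamming_when_gapless_alignment_optimal(self):
        p = (1, 2, 3, 1, 2, 3)
        q = (1, 2, 1, 1, 2, 3)
        # same symbols, equal lengths, no filtering: per-position agreement
        assert nw_similarity(p, q) >= inverse_hamming(p, q) - 1e-12


class TestMatchCluster:
    def test_empty_table_returns_none(self):
        table = PatternTable(length=4)
        cfg = NgramConfig(method=2, pattern_lengths=(4,))
        assert match_cluster(table, (1, 2, 3, 4), cfg) is None

    def test_exact_threshold_matches_identical_only(self):
        table = PatternTable(length=3, clusters=[PatternCluster((1, 2, 3))])
        cfg = NgramConfig(
            method=2, pattern_lengths=(3,), similarity_threshold=1.0
        )
        assert match_cluster(table, (1, 2, 3), cfg) is table.clusters[0]
        assert match_cluster(table, (1, 2, 4), cfg) is None

    def test_tie_break_prefers_earlier_cluster(self):
        table = PatternTable(
            length=4,
            clusters=[PatternCluster((1, 2, 3, 4)), PatternCluster((1, 2, 3, 5))],
        )
        cfg = NgramConfig(
            method=2, pattern_lengths=(4,), similarity_threshold=0.75
        )
        # candidate is within threshold of both representatives
        assert match_cluster(table, (1, 2, 3, 6), cfg) is table.clusters[0]

    def test_wrong_length_rejected_for_hamming(self):
        table = PatternTable(length=4)
        cfg = NgramConfig(method=2, pattern_lengths=(4,))
        with pytest.raises(ValueError):
            match_cluster(table, (1, 2, 3), cfg)


class TestWorkedExample:
    def test_sliding_bigram_of_fig_sequence(self):
        cfg = NgramConfig(
            method=2, pattern_lengths=(2,), similarity_metric="exact"
        )
        tables = extract_window_patterns(_win(FIG_SEQ, bits=4), cfg)
        pairs = dict(_table_as_pairs(tables[2]))
        assert len(pairs) == 4
        assert pairs[(0xA, 0x5)] == 2
        assert sum(pairs.values()) == len(FIG_SEQ) - 2 + 1

    def test_tiled_bigram_of_fig_sequence(self):
        cfg = NgramConfig(
            method=1, pattern_lengths=(2,), similarity_metric="exact"
        )
        tables = extract_window_patterns(_win(FIG_SEQ, bits=4), cfg)
        pairs = _table_as_pairs(tables[2])
        assert len(pairs) == 3
        assert all(count == 1 for _, count in pairs)


class TestOracleEquivalence:
    @pytest.mark.parametrize("n", [2, 5, 8])
    def test_tiling_matches_brute_force(self, rng, n):
        for _ in range(20):
            seq = rng.integers(0, 8, rng.integers(n, 120))
            cfg = NgramConfig(
                method=1, pattern_lengths=(n,), similarity_metric="exact"
            )
            tables = extract_window_patterns(_win(seq), cfg)
            assert dict(_table_as_pairs(tables[n])) == brute_tiling_counts(seq, n)

    @pytest.mark.parametrize("n", [2, 5, 8])
    def test_sliding_matches_brute_force(self, rng, n):
        for _ in range(20):
            seq = rng.integers(0, 8, rng.integers(n, 120))
            cfg = NgramConfig(
                method=2, pattern_lengths=(n,), similarity_metric="exact"
            )
            tables = extract_window_patterns(_win(seq), cfg)
            assert dict(_table_as_pairs(tables[n])) == brute_sliding_counts(seq, n)

    def test_multilength_tiling_is_per_length_tiling(self, rng):
        lengths = (7, 4, 2)
        for _ in range(20):
            seq = rng.integers(0, 6, 100)
            cfg = NgramConfig(
                method=3, pattern_lengths=lengths, similarity_metric="exact"
            )
            tables = extract_window_patterns(_win(seq), cfg)
            for n in lengths:
                assert dict(_table_as_pairs(tables[n])) == brute_tiling_counts(seq, n)

    @pytest.mark.parametrize("tau", [1.0, 0.75])
    def test_dominance_scan_matches_reference(self, rng, tau):
        lengths = (6, 4, 3)
        for _ in range(15):
            seq = rng.integers(0, 4, 60)
            cfg = NgramConfig(
                method=4,
                pattern_lengths=lengths,
                similarity_metric="hamming",
                similarity_threshold=tau,
            )
            tables = extract_window_patterns(_win(seq), cfg)
            ref = reference_multilength_scan(seq, lengths, tau=tau)
            for n in lengths:
                assert _table_as_pairs(tables[n]) == ref[n], (list(seq), n)

    def test_single_length_dominance_reduces_to_sliding(self, rng):
        for tau in (1.0, 0.8):
            seq = rng.integers(0, 4, 200)
            cfg4 = NgramConfig(method=4, pattern_lengths=(5,),
                               similarity_threshold=tau)
            cfg2 = NgramConfig(method=2, pattern_lengths=(5,),
                               similarity_threshold=tau)
            t4 = extract_window_patterns(_win(seq), cfg4)
            t2 = extract_window_patterns(_win(seq), cfg2)
            assert _table_as_pairs(t4[5]) == _table_as_pairs(t2[5])


class TestConservation:
    @given(
        st.integers(0, 2**32 - 1),
        st.integers(2, 12),
        st.integers(50, 400),
    )
    @settings(max_examples=60, deadline=None)
    def test_totals_conserved(self, seed, n, W):
        """Tiling scans count floor(W/n) patterns, sliding W - n + 1 —
        regardless of the clustering threshold."""
        seq = np.random.default_rng(seed).integers(0, 16, W)
        for tau in (1.0, 0.8):
            t1 = extract_window_patterns(
                _win(seq),
                NgramConfig(method=1, pattern_lengths=(n,),
                            similarity_threshold=tau),
            )
            assert t1[n].total_count == W // n
            t2 = extract_window_patterns(
                _win(seq),
                NgramConfig(method=2, pattern_lengths=(n,),
                            similarity_threshold=tau),
            )
            assert t2[n].total_count == W - n + 1

    def test_similarity_clustering_never_adds_clusters(self, rng):
        seq = rng.integers(0, 4, 300)
        exact = extract_window_patterns(
            _win(seq), NgramConfig(method=2, pattern_lengths=(6,),
                                   similarity_metric="exact")
        )
        merged = extract_window_patterns(
            _win(seq), NgramConfig(method=2, pattern_lengths=(6,),
                                   similarity_threshold=0.5)
        )
        assert len(merged[6]) <= len(exact[6])


class TestCountSeries:
    def _cfg(self, **kw):
        base = dict(method=2, pattern_lengths=(6,), similarity_metric="exact")
        base.update(kw)
        return NgramConfig(**base)

    def test_empty_window_set_gives_empty_series(self):
        s = count_series([], self._cfg())
        assert s.n_windows == 0

    def test_degenerate_repeated_symbol_gives_single_significant_cluster(self):
        win = _win(np.full(100, 7))
        s = count_series([win], self._cfg(k_sig=1))
        assert s.counts[0, 0] == 1

    def test_periodic_window_bounded_by_period(self, rng):
        base = rng.integers(0, 256, 4)
        win = _win(np.tile(base, 50))
        s = count_series([win], self._cfg(pattern_lengths=(8,), k_sig=0))
        assert s.counts[0, 0] <= 4

    def test_periodic_fewer_large_clusters_than_random(self, rng):
        periodic = _win(np.tile(rng.integers(0, 256, 85), 40))
        random_w = _win(rng.integers(0, 256, 85 * 40))
        cfg = NgramConfig(method=4, pattern_lengths=(16, 12),
                          similarity_threshold=1.0, k_sig=0)
        sp = count_series([periodic], cfg)
        sr = count_series([random_w], cfg)
        assert sp.counts[0, 0] < 0.1 * sr.counts[0, 0]

    def test_length_longer_than_window_counts_zero(self):
        win = _win(np.arange(10) % 4)
        s = count_series([win], self._cfg(pattern_lengths=(16,), k_sig=0))
        assert s.counts[0, 0] == 0

    def test_windows_are_independent(self, rng):
        """Tables reset at window boundaries: counts per window equal the
        counts of each window analyzed alone."""
        w1 = _win(rng.integers(0, 8, 120))
        w2 = _win(rng.integers(0, 8, 120))
        cfg = self._cfg(k_sig=0)
        joint = count_series([w1, w2], cfg)
        alone = [count_series([w], cfg).counts[0, 0] for w in (w1, w2)]
        assert list(joint.counts[0]) == alone

    def test_fast_and_reference_paths_agree(self, rng):
        """The packed exact-matching kernel and the generic scan produce
        identical counts on every method."""
        seq = rng.integers(0, 256, 500)
        for method, lengths in [(1, (6,)), (2, (6,)), (3, (8, 6, 4)),
                                (4, (16, 12, 8, 6))]:
            fast_cfg = NgramConfig(method=method, pattern_lengths=lengths,
                                   similarity_metric="hamming",
                                   similarity_threshold=1.0, k_sig=0)
            exact_cfg = NgramConfig(method=method, pattern_lengths=lengths,
                                    similarity_metric="exact", k_sig=0)
            fast = count_series([_win(seq)], fast_cfg)
            tables = extract_window_patterns(_win(seq), exact_cfg)
            for i, n in enumerate(fast.lengths):
                assert fast.counts[i, 0] == len(tables[n])


def test_tables_to_rows_flattens_hex(rng):
    cfg = NgramConfig(method=2, pattern_lengths=(3,), similarity_metric="exact")
    tables = extract_window_patterns(_win([1, 2, 3, 1, 2, 3, 1]), cfg)
    rows = tables_to_rows([tables])
    assert rows[0]["representative_pattern_hex"] == "010203"
    assert {r["pattern_length"] for r in rows} == {3}
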