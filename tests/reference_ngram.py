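"""Independent straight-line reference implementations used as oracles.

Everything here is deliberately naive — plain lists, explicit loops, no
shared code with the optimized engine — so the tests compare two
independently written realizations of the same procedure.
"""

from collections import Counter


def brute_tiling_counts(seq, n):
    """Non-overlapping (tiled) n-gram counts."""
    seq = [int(v) for v in seq]
    blocks = [
        tuple(seq[i: i + n])
        for i in range(0, len(seq) - n + 1, n)
    ]
    return Counter(blocks)


def brute_sliding_counts(seq, n):
    """Overlapping (one-step sliding) n-gram counts."""
    seq = [int(v) for v in seq]
    return Counter(tuple(seq[i: i + n]) for i in range(len(seq) - n + 1))


def hamming_sim(p, q):
    assert len(p) == len(q)
    return sum(1 for a, b in zip(p, q) if a == b) / len(p)


def reference_multilength_scan(seq, lengths, tau=1.0):
    """Straight-line realization of the dominance procedure.

    Walk the sequence one symbol at a time; at each position try the
    pattern lengths from longest to shortest against the existing tables
    (first sufficiently similar cluster, insertion order).  On the first
    length that matches, bump that cluster and skip the shorter lengths at
    this position; if nothing matches anywhere, insert the substring at
    every length as a fresh cluster.
    """
    seq = [int(v) for v in seq]
    lengths = sorted(set(int(n) for n in lengths), reverse=True)
    tables = {n: [] for n in lengths}  # list of [representative, count]

    exact = tau >= 1.0

    def find(n, cand):
        for cluster in tables[n]:
            if cluster[0] == cand if exact else hamming_sim(cluster[0], cand) >= tau:
                return cluster
        return None

    for pos in range(len(seq)):
        matched = False
        for n in lengths:
            if pos + n > len(seq):
                continue
            cand = tuple(seq[pos: pos + n])
            cluster = find(n, cand)
            if cluster is not None:
                cluster[1] += 1
                matched = True
                break
        if not matched:
            for n in lengths:
                if pos + n <= len(seq):
                    tables[n].append([tuple(seq[pos: pos + n]), 1])
    return {n: [(rep, count) for rep, count in tables[n]] for n in lengths}


def enum_alignment_score(a, b, match=2, mismatch=0, gap=-1):
    """Optimal global alignment score by exhaustive recursion (no DP)."""
    if not a and not b:
        return 0
    best = None
    if a and b:
        sub = match if a[0] == b[0] else mismatch
        best = sub + enum_alignment_score(a[1:], b[1:], match, mismatch, gap)
    if a:
        cand = gap + enum_alignment_score(a[1:], b, match, mismatch, gap)
        best = cand if best is None else max(best, cand)
    if b:
        cand = gap + enum_alignment_score(a, b[1:], match, mismatch, gap)
        best = cand if best is None else max(best, cand)
    return best


def oracle_nw_similarity(p, q):
    """Alignment similarity via the exhaustive-enumeration score."""
    p = tuple(int(v) for v in p)
    q = tuple(int(v) for v in q)
    fp = tuple(v for v in p if v in set(q))
    fq = tuple(v for v in q if v in set(p))
    score = enum_alignment_score(fp, fq)
    return max(0.0, score / (len(p) + len(q)))
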