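"""Shared brute-force oracles for the test suite.

Every oracle here is deliberately naive (per-base boolean arrays, all-pairs
scans, exhaustive enumeration) and independent of the library's sweep/
searchsorted implementations.
"""

from itertools import combinations

import numpy as np

from silencerscan.intervals import GenomicInterval, IntervalSet


def random_interval_set(rng, n, chrom_len=10_000, chroms=("chr1",), label="x"):
    ivs = []
    for i in range(n):
        c = chroms[int(rng.integers(0, len(chroms)))]
        s = int(rng.integers(0, chrom_len - 2))
        e = int(rng.integers(s + 1, min(chrom_len, s + 1 + int(rng.integers(1, 400)))))
        ivs.append(GenomicInterval(c, s, e, name=f"{label}{i}"))
    return IntervalSet(ivs, label=label)


def coverage_array(ivset, chrom, length):
    """Per-base boolean membership oracle."""
    cov = np.zeros(length, dtype=bool)
    for iv in ivset:
        if iv.chrom == chrom:
            cov[iv.start : iv.end] = True
    return cov


def brute_overlap_bp(a_iv, b_iv):
    if a_iv.chrom != b_iv.chrom:
        return 0
    return max(0, min(a_iv.end, b_iv.end) - max(a_iv.start, b_iv.start))


def brute_subtract(a, b, min_bp=1):
    """All-pairs whole-record subtraction oracle."""
    keep = []
    for x in a:
        if all(brute_overlap_bp(x, y) < min_bp for y in b):
            keep.append(x)
    return IntervalSet(keep, label=a.label)


def brute_overlap_counts(a, b):
    out = []
    for x in a:
        hits = [brute_overlap_bp(x, y) for y in b]
        hits = [h for h in hits if h > 0]
        out.append((len(hits), sum(hits)))
    return out


def brute_gapped_kmer_counts(seq, l, k):
    """Exhaustive window x position-subset enumeration (no RC collapsing).

    Returns a dict mapping gapped-word strings (wildcards '.') to counts.
    """
    counts = {}
    for i in range(len(seq) - l + 1):
        win = seq[i : i + l]
        for combo in combinations(range(l), k):
            if any(win[p] == "N" for p in combo):
                continue
            word = ["."] * l
            for p in combo:
                word[p] = win[p]
            key = "".join(word)
            counts[key] = counts.get(key, 0) + 1
    return counts


def pairwise_auroc(scores, labels):
    """O(n^2) Mann-Whitney pair-count AUROC with half credit for ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (pos.size * neg.size)


def brute_bh(p):
    """Step-up BH by explicit definition (O(m^2), no vectorized tricks)."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: (p[i], i))
    q = [0.0] * m
    for rank_pos, i in enumerate(order, start=1):
        q[i] = min(
            min(m * p[order[s - 1]] / s for s in range(rank_pos, m + 1)), 1.0
        )
    return q


def brute_threshold_scan(scores, labels):
    """Exhaustive max-accuracy cutpoint scan, rule: positive if score >= t."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    n = scores.size
    cands = sorted(set(scores.tolist())) + [float("inf")]
    best_t, best_acc = None, -1.0
    for t in cands:
        acc = float(((scores >= t) == labels).sum()) / n
        if acc > best_acc:
            best_t, best_acc = t, acc
    # lowest qualifying threshold among ties
    for t in cands:
        acc = float(((scores >= t) == labels).sum()) / n
        if acc == best_acc:
            return t, best_acc
    return best_t, best_acc
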