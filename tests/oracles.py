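"""Independent brute-force oracles used by the test suite.

Deliberately naive: per-base bit vectors for interval arithmetic, full
enumeration for permutation and hypergeometric tails.  They share no code
with the implementation they check.
"""

from itertools import combinations
from math import comb

import numpy as np


def bitvector_union(intervals):
    """Per-base union: returns (merged intervals, total bp)."""
    by_chrom = {}
    for chrom, s, e in intervals:
        by_chrom.setdefault(chrom, []).append((s, e))
    merged, total = [], 0
    for chrom in sorted(by_chrom):
        hi = max(e for _, e in by_chrom[chrom])
        bits = np.zeros(hi + 1, dtype=bool)
        for s, e in by_chrom[chrom]:
            bits[s:e] = True
        total += int(bits.sum())
        # extract runs
        padded = np.concatenate([[False], bits, [False]])
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        merged.extend((chrom, int(s), int(e)) for s, e in zip(starts, ends))
    return merged, total


def bitvector_intersection_bp(a, b):
    bp = 0
    chroms = {c for c, _, _ in a} | {c for c, _, _ in b}
    for chrom in chroms:
        ia = [(s, e) for c, s, e in a if c == chrom]
        ib = [(s, e) for c, s, e in b if c == chrom]
        if not ia or not ib:
            continue
        hi = max(e for _, e in ia + ib)
        xa = np.zeros(hi, dtype=bool)
        xb = np.zeros(hi, dtype=bool)
        for s, e in ia:
            xa[s:e] = True
        for s, e in ib:
            xb[s:e] = True
        bp += int((xa & xb).sum())
    return bp


def project_base_by_base(start, end, block):
    """Project an interval through one alignment block, one base at a time."""
    out = []
    for x in range(start, end):
        if block.hap_start <= x < block.hap_end:
            if block.strand == "+":
                out.append(block.ref_start + (x - block.hap_start))
            else:
                out.append(block.ref_end - 1 - (x - block.hap_start))
    if not out:
        return None
    return (block.ref_chrom, min(out), max(out) + 1)


def exhaustive_permutation_p(a, b, statistic, alternative="auto"):
    """Exact label-permutation P over all group-A assignments."""
    pooled = list(a) + list(b)
    n_a = len(a)
    observed = statistic(np.array(a, float), np.array(b, float))
    stats = []
    for idx in combinations(range(len(pooled)), n_a):
        ga = np.array([pooled[i] for i in idx], float)
        gb = np.array([pooled[i] for i in range(len(pooled)) if i not in idx], float)
        stats.append(statistic(ga, gb))
    stats = np.array(stats)
    tol = 1e-12
    if alternative == "auto":
        if observed >= 0:
            extreme = np.sum(stats >= observed - tol)
        else:
            extreme = np.sum(stats <= observed + tol)
    elif alternative == "greater":
        extreme = np.sum(stats >= observed - tol)
    elif alternative == "less":
        extreme = np.sum(stats <= observed + tol)
    else:
        extreme = np.sum(np.abs(stats) >= abs(observed) - tol)
    return extreme / len(stats)


def exhaustive_mannwhitney_p(a, b):
    """Exact two-sided Mann–Whitney P by full enumeration, ties by average
    ranks, two-sidedness by distance of U from its null centre."""
    from scipy.stats import rankdata

    pooled = np.concatenate([np.asarray(a, float), np.asarray(b, float)])
    m, n = len(a), len(b)
    ranks = rankdata(pooled)
    centre = m * n / 2
    u_obs = ranks[:m].sum() - m * (m + 1) / 2
    extreme = total = 0
    for idx in combinations(range(m + n), m):
        u = ranks[list(idx)].sum() - m * (m + 1) / 2
        total += 1
        if abs(u - centre) >= abs(u_obs - centre) - 1e-9:
            extreme += 1
    return u_obs, extreme / total


def hypergeometric_fisher_p(table):
    """Two-sided Fisher exact P by summing hypergeometric probabilities not
    larger than the observed table's."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = pmf(a)
    return sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs * (1 + 1e-9))


def binomial_tail(k, n):
    """Pr(X >= k) for X ~ Binomial(n, 1/2), by direct summation."""
    return sum(comb(n, j) for j in range(k, n + 1)) / 2 ** n
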