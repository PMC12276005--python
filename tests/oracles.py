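"""Independent brute-force oracles for the interval and statistics stack.

Everything here is deliberately naive — per-base-pair membership sets,
O(n*m) double loops, exact hypergeometric enumeration — and shares no code
with the package implementations it checks.
"""

from __future__ import annotations

import math
from itertools import combinations


def overlaps(a, b) -> bool:
    """>= 1 bp overlap between (chrom, start, end) triples."""
    return a[0] == b[0] and a[1] < b[2] and b[1] < a[2]


def bf_precision_recall(query, reference):
    prec = sum(any(overlaps(q, r) for r in reference) for q in query) / len(query)
    rec = sum(any(overlaps(r, q) for q in query) for r in reference) / len(reference)
    return prec, rec


def bp_set(records):
    return {(c, p) for c, s, e in records for p in range(s, e)}


def bf_jaccard(a, b):
    sa, sb = bp_set(a), bp_set(b)
    union = sa | sb
    if not union:
        return float("nan")
    return len(sa & sb) / len(union)


def bf_consensus(sets_of_records, min_count, chrom_len, chroms=("chr1",)):
    """Per-bp membership counting; returns merged (chrom, start, end) list."""
    out = []
    for chrom in chroms:
        covered = []
        for pos in range(chrom_len):
            n = sum(
                any(c == chrom and s <= pos < e for c, s, e in records)
                for records in sets_of_records
            )
            covered.append(n >= min_count)
        start = None
        for pos, flag in enumerate(covered):
            if flag and start is None:
                start = pos
            elif not flag and start is not None:
                out.append((chrom, start, pos))
                start = None
        if start is not None:
            out.append((chrom, start, chrom_len))
    return out


def bf_count_matrix(lib_frames, regions):
    """Double loop: reads (copy-weighted) overlapping each region per library."""
    out = []
    for r in regions:
        row = []
        for frame in lib_frames:
            total = 0
            for frag in frame.itertuples(index=False):
                if overlaps((frag.chrom, frag.start, frag.end), r):
                    total += frag.copy_count
            row.append(total)
        out.append(row)
    return out


def bf_signal_blocks(values, bin_size, chrom="chr1"):
    """Per-bin scan for runs of positive bins -> (chrom, start, end, auc, maxh)."""
    blocks = []
    run = []
    for i, v in enumerate(list(values) + [0.0]):
        if v > 0:
            run.append((i, v))
        elif run:
            auc = sum(val for _, val in run) * bin_size
            blocks.append(
                (chrom, run[0][0] * bin_size, (run[-1][0] + 1) * bin_size,
                 auc, max(val for _, val in run))
            )
            run = []
    return blocks


def bf_fisher_two_sided(table, tol=1e-7):
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_comb(n_, k_):
        return math.lgamma(n_ + 1) - math.lgamma(k_ + 1) - math.lgamma(n_ - k_ + 1)

    def pmf(k):
        return math.exp(
            log_comb(r1, k) + log_comb(r2, c1 - k) - log_comb(n, c1)
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = pmf(a)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + tol))


def bh_adjust(pvals):
    """Textbook Benjamini-Hochberg step-up adjustment."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    adj = [0.0] * n
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        val = pvals[i] * n / rank_from_top
        running_min = min(running_min, val)
        adj[i] = min(running_min, 1.0)
    return adj


def bf_self_overlap_pairs(records):
    """Number of overlapping pairs within one record list."""
    return sum(overlaps(a, b) for a, b in combinations(records, 2))


def bf_overlap_pairs(a_records, b_records):
    return sum(overlaps(a, b) for a in a_records for b in b_records)
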