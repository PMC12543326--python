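"""Independent brute-force oracles used by the test suite.

Everything here works per-base or all-pairs on plain (chrom, start, end)
tuples so the oracles share no code path with the sweep-line/searchsorted
implementations they check. Only suitable for small coordinates.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def _tuples(intervals):
    return [(iv.chrom, iv.start, iv.end) for iv in intervals]


def coverage_merge_oracle(intervals, max_gap):
    """Merge via boolean per-base coverage: mark covered bases, bridge gaps
    <= max_gap, extract runs. Returns sorted (chrom, start, end) tuples."""
    by_chrom = {}
    for chrom, start, end in _tuples(intervals):
        cov = by_chrom.setdefault(chrom, set())
        cov.update(range(start, end))
    out = []
    for chrom in sorted(by_chrom):
        bases = sorted(by_chrom[chrom])
        run_start = prev = bases[0]
        for b in bases[1:]:
            if b - prev - 1 > max_gap:  # uncovered stretch longer than max_gap
                out.append((chrom, run_start, prev + 1))
                run_start = b
            prev = b
        out.append((chrom, run_start, prev + 1))
    return out


def gap_oracle(a, b):
    """Gap between two tuples/intervals; None across chromosomes."""
    ca, sa, ea = a.chrom, a.start, a.end
    cb, sb, eb = b.chrom, b.start, b.end
    if ca != cb:
        return None
    if sa < sb:
        return max(sb - ea, 0)
    return max(sa - eb, 0)


def subset_oracle(query, subject, max_gap, invert):
    """All-pairs subset-by-overlap; returns the kept query intervals."""
    kept = []
    for q in query:
        hit = any(
            (g := gap_oracle(q, s)) is not None and g <= max_gap for s in subject
        )
        if hit != invert:
            kept.append(q)
    return kept


def consensus_oracle(replicates, k):
    """Per-base replicate-support counting, thresholded at k."""
    support = {}
    for rep in replicates:
        seen = set()
        for chrom, start, end in _tuples(rep):
            for b in range(start, end):
                seen.add((chrom, b))
        for key in seen:
            support[key] = support.get(key, 0) + 1
    passing = sorted(key for key, n in support.items() if n >= k)
    out = []
    for chrom, b in passing:
        if out and out[-1][0] == chrom and out[-1][2] == b:
            out[-1][2] = b + 1
        else:
            out.append([chrom, b, b + 1])
    return [tuple(x) for x in out]


def midpoint_count_oracle(windows, fragments):
    """Quadratic midpoint-in-window counting; one column of the count matrix."""
    counts = []
    for w in windows:
        n = 0
        for f in fragments:
            mid = (f.start + f.end) // 2
            if f.chrom == w.chrom and w.start <= mid < w.end:
                n += 1
        counts.append(n)
    return counts


def bh_oracle(pvalues):
    """BH step-up by direct enumeration of the definition."""
    m = len(pvalues)
    indexed = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    for rank_pos, i in enumerate(indexed):
        best = min(
            pvalues[indexed[j]] * m / (j + 1) for j in range(rank_pos, m)
        )
        q[i] = min(best, 1.0)
    return q


def conditional_binomial_pvalue(s_a, total, n_a, n_b):
    """Exact two-sided conditional binomial p-value with Fraction arithmetic:
    sum of P(X = x), X ~ Binomial(total, n_a/(n_a+n_b)), over every x whose
    probability is at most that of the observed split."""
    p = Fraction(n_a, n_a + n_b)
    probs = [
        comb(total, x) * p**x * (1 - p) ** (total - x) for x in range(total + 1)
    ]
    obs = probs[s_a]
    return float(min(sum(pr for pr in probs if pr <= obs), Fraction(1)))


def pearson_chi2_oracle(a, b, c, d):
    """Closed-form Pearson statistic N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d))."""
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
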