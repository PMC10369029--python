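"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from scratch, in the plainest
possible style, so the implementations under test are checked against a
second, independent reading of the rules.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import product


def haversine_m(lat1, lon1, lat2, lon2, radius=6371008.8):
    """Great-circle distance on a mean-radius sphere, metres."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * radius * math.asin(math.sqrt(a))


def bout_runs(mask, dt=1.0, min_s=15.0, gap_s=5.0, forbid=None):
    """Reference run/gap/min-length bout rules on a boolean per-sample mask.

    Scan for maximal True runs, merge runs separated by at most ``gap_s``
    seconds of False, then keep merged runs covering at least ``min_s``
    seconds (a run of k samples covers k*dt seconds). A gap containing any
    sample flagged in ``forbid`` (the opposite behaviour class) is never
    merged across. Returns a list of (start, end) inclusive sample indices.
    """
    runs = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            runs.append([i, j])
            i = j + 1
        else:
            i += 1
    merged = []
    for run in runs:
        if merged and (run[0] - merged[-1][1] - 1) * dt <= gap_s + 1e-9:
            gap_has_forbidden = forbid is not None and any(
                forbid[k] for k in range(merged[-1][1] + 1, run[0])
            )
            if not gap_has_forbidden:
                merged[-1][1] = run[1]
                continue
        merged.append(run)
    return [
        (s, e) for s, e in merged if (e - s + 1) * dt >= min_s - 1e-9
    ]


def fisher_exact_fraction(table):
    """Exact two-sided Fisher p for an r x c table with rational arithmetic.

    Enumerates candidate tables by brute force over all cell values bounded
    by the row sums, keeps those with the observed margins, and sums the
    multivariate hypergeometric probabilities of every table whose
    probability does not exceed the observed one. Exact; only usable for
    small totals.
    """
    rows = [sum(r) for r in table]
    cols = [sum(c) for c in zip(*table)]
    n = sum(rows)
    if any(r == 0 for r in rows) or any(c == 0 for c in cols):
        return Fraction(1)

    const = Fraction(1)
    for r in rows:
        const *= math.factorial(r)
    for c in cols:
        const *= math.factorial(c)
    const = Fraction(const, math.factorial(n))

    def prob(tab):
        denom = 1
        for row in tab:
            for v in row:
                denom *= math.factorial(v)
        return const / denom

    p_obs = prob(table)
    r, c = len(rows), len(cols)
    total = Fraction(0)
    cell_ranges = []
    for i in range(r):
        for j in range(c):
            cell_ranges.append(range(min(rows[i], cols[j]) + 1))
    for flat in product(*cell_ranges):
        tab = [list(flat[i * c:(i + 1) * c]) for i in range(r)]
        if [sum(row) for row in tab] != rows:
            continue
        if [sum(col) for col in zip(*tab)] != cols:
            continue
        p = prob(tab)
        if p <= p_obs:
            total += p
    return total


def kruskal_h_no_ties(groups):
    """Kruskal-Wallis H without tie correction (mid-ranks, textbook formula)."""
    pooled = sorted((v, gi) for gi, g in enumerate(groups) for v in g)
    n = len(pooled)
    # mid-ranks
    ranks = {}
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[j + 1][0] == pooled[i][0]:
            j += 1
        mid = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks.setdefault(id(pooled[k]), None)
        for k in range(i, j + 1):
            pooled[k] = (pooled[k][0], pooled[k][1], mid)
        i = j + 1
    rank_sums = [0.0] * len(groups)
    counts = [0] * len(groups)
    for _, gi, rk in pooled:
        rank_sums[gi] += rk
        counts[gi] += 1
    h = 12.0 / (n * (n + 1)) * sum(
        rs**2 / c for rs, c in zip(rank_sums, counts)
    ) - 3 * (n + 1)
    return h
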