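"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles in plain
Python (no reuse of package internals): a dynamic-programming aligner
following the documented conventions, exhaustive permutation null
distributions for the rank tests, and a hand-rolled BH step-up.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import rankdata


def oracle_semiglobal(a: str, b: str, match=1.0, mismatch=-1.0, gap=-2.0):
    """Plain-Python semi-global alignment: free terminal gaps, fixed
    tie-breaks (canonical sequence order; end cell scanned along the last
    row then the last column keeping the first strict maximum; traceback
    preference diagonal > gap-in-b > gap-in-a).  Returns
    (score, matches, columns-excluding-overhangs)."""
    a = a.upper().replace("U", "T")
    b = b.upper().replace("U", "T")
    if b < a:
        a, b = b, a
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            ok = a[i - 1] == b[j - 1] and a[i - 1] in "ACGT"
            s = match if ok else mismatch
            H[i][j] = max(H[i - 1][j - 1] + s, H[i - 1][j] + gap, H[i][j - 1] + gap)
    best = -float("inf")
    cell = (n, m)
    for j in range(m + 1):
        if H[n][j] > best:
            best, cell = H[n][j], (n, j)
    for i in range(n):
        if H[i][m] > best:
            best, cell = H[i][m], (i, m)
    i, j = cell
    matches = columns = 0
    while i > 0 and j > 0:
        ok = a[i - 1] == b[j - 1] and a[i - 1] in "ACGT"
        s = match if ok else mismatch
        if abs(H[i][j] - (H[i - 1][j - 1] + s)) < 1e-9:
            matches += ok
            i, j = i - 1, j - 1
        elif abs(H[i][j] - (H[i - 1][j] + gap)) < 1e-9:
            i -= 1
        else:
            j -= 1
        columns += 1
    return best, matches, columns


def oracle_mannwhitney_p(a, b) -> float:
    """Two-sided exact Mann-Whitney p by full enumeration of group
    assignments (2*min(P(U<=u), P(U>=u)), capped at 1)."""
    pooled = list(a) + list(b)
    n1 = len(a)

    def U(idx):
        sel = set(idx)
        ga = [pooled[i] for i in sel]
        gb = [pooled[i] for i in range(len(pooled)) if i not in sel]
        return sum(
            1.0 if x > y else 0.5 if x == y else 0.0 for x in ga for y in gb
        )

    obs = U(range(n1))
    us = [U(c) for c in itertools.combinations(range(len(pooled)), n1)]
    lo = sum(u <= obs + 1e-9 for u in us) / len(us)
    hi = sum(u >= obs - 1e-9 for u in us) / len(us)
    return min(1.0, 2 * min(lo, hi))


def oracle_wilcoxon_p(a, b) -> float:
    """Two-sided exact Wilcoxon signed-rank p by enumerating all sign
    assignments of the non-zero differences."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    r = rankdata(np.abs(d))
    obs = r[d > 0].sum()
    ws = [
        sum(ri for ri, s in zip(r, signs) if s)
        for signs in itertools.product([0, 1], repeat=len(d))
    ]
    lo = sum(w <= obs + 1e-9 for w in ws) / len(ws)
    hi = sum(w >= obs - 1e-9 for w in ws) / len(ws)
    return min(1.0, 2 * min(lo, hi))


def oracle_bh(pvals) -> list[float]:
    """Hand-rolled BH step-up: q_(i) = min_{j>=i} p_(j) * m / j."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        q[i] = running
    return q


def oracle_ef(c13h, c13l, c12h, c12l, taxon, pseudocount=0.5, universe=None):
    """One-line EF from raw counts: pseudocounted proportions, then
    heavy/light ratio difference."""
    universe = universe or sorted(set(c13h) | set(c13l) | set(c12h) | set(c12l))

    def relab(counts):
        tot = sum(counts.get(t, 0) + pseudocount for t in universe)
        return (counts.get(taxon, 0) + pseudocount) / tot

    return relab(c13h) / relab(c13l) - relab(c12h) / relab(c12l)
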