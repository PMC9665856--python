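"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity directly from its definition, with no
code shared with the implementation it checks.
"""

from __future__ import annotations

import math
from typing import List, Sequence, Tuple


def paraclu_bruteforce(
    sites: Sequence[Tuple[int, int]], floor: float = 0.0
) -> List[Tuple[int, int, float, float]]:
    """O(n^2) re-derivation of the density-clustering recursion.

    Returns sorted (start, end, min_density, max_density) tuples for every
    cluster in the hierarchy. Break = minimum over proper-prefix densities
    sum(c_1..c_k)/(p_{k+1}-p_1) and proper-suffix densities
    sum(c_k..c_n)/(p_n-p_{k-1}); ties resolve prefix-before-suffix, smaller
    k first.
    """
    out: List[Tuple[int, int, float, float]] = []

    def recurse(sub: List[Tuple[int, int]], fl: float) -> None:
        n = len(sub)
        if n == 1:
            out.append((sub[0][0], sub[0][0] + 1, fl, math.inf))
            return
        best = None  # (density, kind, k)
        for k in range(n - 1):  # prefix sub[0..k]
            d = sum(c for _, c in sub[: k + 1]) / (sub[k + 1][0] - sub[0][0])
            if best is None or d < best[0]:
                best = (d, 0, k)
        for k in range(1, n):  # suffix sub[k..n-1]
            d = sum(c for _, c in sub[k:]) / (sub[-1][0] - sub[k - 1][0])
            if d < best[0]:
                best = (d, 1, k)
        d, kind, k = best
        out.append((sub[0][0], sub[-1][0] + 1, fl, d))
        split = k + 1 if kind == 0 else k
        recurse(sub[:split], d)
        recurse(sub[split:], d)

    recurse(list(sites), floor)
    return sorted(out)


def auc_bruteforce(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Pairwise concordance probability with ties counted 0.5."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def levenshtein_dp(a: str, b: str) -> int:
    """Textbook dynamic-programming edit distance; N matches nothing."""
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            match = a[i - 1] == b[j - 1] and a[i - 1] != "N" and b[j - 1] != "N"
            cur[j] = min(
                prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (0 if match else 1)
            )
        prev = cur
    return prev[n]


def elbow_bruteforce(totals: Sequence[float]) -> float:
    """Direct evaluation of the scaled-slope rule on the sorted totals."""
    ts = sorted(totals)
    n = len(ts)
    lo, hi = ts[0], ts[-1]
    if hi == lo:
        return float(hi)
    cutoff = float(ts[-1])
    for i in range(n - 1):
        x0, x1 = i / (n - 1), (i + 1) / (n - 1)
        y0 = (ts[i] - lo) / (hi - lo)
        y1 = (ts[i + 1] - lo) / (hi - lo)
        if (y1 - y0) / (x1 - x0) > 1.0:
            cutoff = float(ts[i])
            break
    return cutoff
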