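"""Independent reference implementations used only to check the package.

Deliberately naive: plain Python loops and closed forms, no shared code
with the implementation under test.
"""

import math


def brute_force_best_arc(x, min_bins):
    """Exhaustive max-|t| arc search over all (i, j) windows.

    Same admissibility rule as the implementation (every resulting piece
    of the split must have at least min_bins bins), evaluated by direct
    two-group statistics.
    """
    n = len(x)
    best = (0.0, 0, n)
    eps = 1e-9
    for i in range(0, n):
        for j in range(i + 1, n + 1):
            m = j - i
            if m < min_bins or n - m < min_bins:
                continue
            if i not in (0,) and i < min_bins:
                continue
            if j != n and n - j < min_bins:
                continue
            arc = x[i:j]
            rest = list(x[:i]) + list(x[j:])
            mean1 = sum(arc) / m
            mean2 = sum(rest) / (n - m)
            ss = sum((v - mean1) ** 2 for v in arc) + sum((v - mean2) ** 2 for v in rest)
            pooled = max(ss / max(n - 2, 1), eps)
            t = abs(mean1 - mean2) / math.sqrt(pooled * (1.0 / m + 1.0 / (n - m)))
            if t > best[0] * (1 + 1e-12) + 1e-15:
                best = (t, i, j)
    return best


def mcnemar_enumeration(b, c):
    """Two-sided exact McNemar p by direct binomial-tail enumeration."""
    m = b + c
    if m == 0:
        return 1.0
    k = min(b, c)
    tail = sum(math.comb(m, i) for i in range(k + 1)) / 2.0**m
    return min(1.0, 2.0 * tail)
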