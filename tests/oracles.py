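"""Independent brute-force oracles used to freeze expected values.

Deliberately naive (explicit Python loops, literal recurrences) and shared
by several test modules; kept independent of the package's vectorized
implementation paths.
"""

from __future__ import annotations

from itertools import combinations


def walk_es(stats, hit_positions, exponent=1.0):
    """Literal weighted KS walk; returns (es, full walk)."""
    n = len(stats)
    hits = set(hit_positions)
    k = len(hits)
    if exponent == 0:
        weights = {i: 1.0 for i in hits}
    else:
        weights = {i: abs(stats[i]) ** exponent for i in hits}
    wsum = sum(weights.values())
    if wsum == 0:
        weights = {i: 1.0 for i in hits}
        wsum = float(k)
    walk, s = [], 0.0
    for i in range(n):
        s += weights[i] / wsum if i in hits else -1.0 / (n - k)
        walk.append(s)
    hi = max(walk)
    lo = min(min(walk), 0.0)
    # ties between |max| and |min| resolve positive, with a rounding tolerance
    es = hi if hi >= -lo - 1e-12 else lo
    es = max(-1.0, min(1.0, es))
    return es, walk


def enumerate_null(stats, set_size, exponent=1.0):
    """ES of every subset of the given size, by literal walk evaluation."""
    n = len(stats)
    return [
        walk_es(stats, sub, exponent)[0] for sub in combinations(range(n), set_size)
    ]


def pvalue_same_sign(es, null):
    """+1-corrected permutation p against same-sign null values."""
    if es == 0:
        return 1.0
    same = [x for x in null if (x > 0) == (es > 0) and x != 0]
    if not same:
        return 1.0 / (1.0 + len(null))
    # a null score equal to |es| up to rounding counts as at least as extreme
    worse = sum(1 for x in same if abs(x) >= abs(es) - 1e-12)
    return (1.0 + worse) / (1.0 + len(same))


def bh_adjust(pvals):
    """Benjamini-Hochberg by the textbook step-up recurrence."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        prev = min(prev, pvals[idx] * m / rank)
        q[idx] = prev
    return q


def pearson(xs, ys):
    """Pearson r by the direct covariance / sigma formula."""
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    cov = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    vx = sum((x - mx) ** 2 for x in xs)
    vy = sum((y - my) ** 2 for y in ys)
    return cov / (vx * vy) ** 0.5
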