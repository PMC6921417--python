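"""Independent brute-force oracles used to validate the implementation.

Everything here is computed from first principles (binomial pmf sums,
bisection, exhaustive enumeration) without calling the code under test
or scipy's interval/power shortcuts.
"""

from __future__ import annotations

import math


def binom_tail(k: int, n: int, p: float) -> float:
    """P(X >= k | n, p) by direct pmf summation."""
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    if p == 0.0:
        return 0.0
    if p == 1.0:
        return 1.0
    total = 0.0
    for i in range(k, n + 1):
        total += math.comb(n, i) * p**i * (1.0 - p) ** (n - i)
    return min(total, 1.0)


def lower_bound_bisect(successes: int, n: int, confidence_level: float, tol: float = 1e-13) -> float:
    """One-sided exact lower bound: solve P(X >= successes | n, L) = 1 - level.

    The tail is increasing in p, so plain bisection on [0, 1] converges.
    """
    if successes == 0:
        return 0.0
    alpha = 1.0 - confidence_level
    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if binom_tail(successes, n, mid) < alpha:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def exact_power_enum(n: int, mac: float, true_p: float, alpha: float) -> float:
    """Power of the exact one-sided test of H0: p <= mac, by enumeration.

    Finds the smallest critical count k* with P(X >= k* | n, mac) <= alpha,
    then sums the pmf at true_p from k* upward.
    """
    k_star = None
    for k in range(0, n + 2):
        if binom_tail(k, n, mac) <= alpha:
            k_star = k
            break
    if k_star is None or k_star > n:
        return 0.0
    return binom_tail(k_star, n, true_p)


def scan_tables_bruteforce(scores, status, threshold, direction="higher_positive"):
    """2x2 cells at one threshold by direct counting."""
    tp = fp = fn = tn = 0
    for s, d in zip(scores, status):
        if direction == "higher_positive":
            pos = s >= threshold
        else:
            pos = s <= threshold
        if d == 1:
            tp += pos
            fn += not pos
        else:
            fp += pos
            tn += not pos
    return tp, fp, fn, tn
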