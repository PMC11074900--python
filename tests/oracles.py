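"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results with the most literal possible code
(scans, tallies, closed forms) and share nothing with the package internals.
"""

from __future__ import annotations

import numpy as np

BRE = (23400, 30600)
LUN = (39600, 46800)
DIN = (63000, 70200)


def brute_force_segments(times, window=7200):
    """Scan-and-reanchor segmentation: list of lists of indices."""
    groups = []
    anchor = None
    current = []
    for i, t in enumerate(times):
        if anchor is None or t > anchor + window:
            if current:
                groups.append(current)
            current = [i]
            anchor = t
        else:
            current.append(i)
    if current:
        groups.append(current)
    return groups


def brute_force_slot(t):
    """Nearest-slot classification with ties to the earlier slot."""
    gaps = []
    for lo, hi in (BRE, LUN, DIN):
        if lo <= t <= hi:
            gaps.append(0)
        else:
            gaps.append(min(abs(t - lo), abs(t - hi)))
    k = gaps.index(min(gaps))
    return ("breakfast", "lunch", "dinner")[k], gaps[k] > 0


def direct_mad(values):
    """median(|x - median(x)|) by enumeration."""
    v = sorted(float(x) for x in values)
    med = _median(v)
    dev = sorted(abs(x - med) for x in v)
    return _median(dev)


def _median(sorted_vals):
    n = len(sorted_vals)
    mid = n // 2
    if n % 2:
        return sorted_vals[mid]
    return 0.5 * (sorted_vals[mid - 1] + sorted_vals[mid])


def bh_adjust(p):
    """Textbook Benjamini-Hochberg step-up with monotonicity enforcement."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running_min = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        val = p[i] * m / rank_from_end
        running_min = min(running_min, val)
        adj[i] = min(running_min, 1.0)
    return adj


def cross_product_or(n11, n10, n01, n00):
    """2x2 odds ratio: (case-exposed * control-unexposed) / (control-exposed * case-unexposed)."""
    return (n11 * n00) / (n10 * n01)
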