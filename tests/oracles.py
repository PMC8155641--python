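"""Independent brute-force oracles used by the test suite.

These deliberately use different algorithms from the package: all-pairs
distance scans instead of sorted searches, and an endpoint sweep-line
instead of clip-and-merge for tiled time.
"""

from __future__ import annotations

import numpy as np


def proportion_within_brute(a, b, dt):
    """Fraction of a-spikes with some b-spike at distance <= dt (all pairs)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size == 0:
        return float("nan")
    hits = 0
    for x in a:
        if any(abs(x - y) <= dt for y in b):
            hits += 1
    return hits / a.size


def tiled_fraction_brute(times, dt, duration):
    """Union length of +/-dt windows clipped to [0, duration], via sweep-line."""
    times = np.asarray(times, float)
    if times.size == 0:
        return 0.0
    endpoints = []
    for t in times:
        endpoints.append((max(t - dt, 0.0), +1))
        endpoints.append((min(t + dt, duration), -1))
    endpoints.sort()
    covered = 0.0
    depth = 0
    prev = None
    for x, step in endpoints:
        if depth > 0:
            covered += x - prev
        depth += step
        prev = x
    return covered / duration


def sttc_brute(a, b, dt, duration):
    """STTC from the brute-force constituents."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        return float("nan")
    p_a = proportion_within_brute(a, b, dt)
    p_b = proportion_within_brute(b, a, dt)
    t_a = tiled_fraction_brute(a, dt, duration)
    t_b = tiled_fraction_brute(b, dt, duration)

    def term(p, t):
        denom = 1.0 - p * t
        return 0.0 if denom == 0 else (p - t) / denom

    return 0.5 * (term(p_a, t_b) + term(p_b, t_a))


def min_window_std_brute(values, window):
    """Minimum std over every contiguous window, by direct enumeration."""
    values = np.asarray(values, float)
    return min(values[i:i + window].std() for i in range(len(values) - window + 1))
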