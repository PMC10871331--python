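"""Independent brute-force oracles used to validate pipeline operations.

These are deliberately naive loop implementations, coded separately from the
package, so agreement with the vectorized implementations is meaningful.
"""

from __future__ import annotations

import math


def brute_force_derivative(v, dt):
    """Forward-difference first derivative, sample by sample."""
    return [(v[i + 1] - v[i]) / dt for i in range(len(v) - 1)]


def brute_force_second_derivative(v, dt):
    """Central second difference at interior samples."""
    return [(v[i + 1] - 2 * v[i] + v[i - 1]) / dt**2 for i in range(1, len(v) - 1)]


def brute_force_detect(v, dt, up=30.0, down=-15.0, pair_ms=10.0, min_peak=0.0):
    """Enumerate every derivative-sample crossing pair by direct scanning.

    Returns a list of (upcross_time, downcross_time, peak_voltage) tuples
    using the crossing rule d[i-1] < theta <= d[i] (up) / d[i-1] > theta >=
    d[i] (down), event at sample i, resuming after an accepted down-cross.
    """
    d = brute_force_derivative(v, dt)
    pair_n = int(math.floor(pair_ms / dt))
    events = []
    i = 1
    n = len(d)
    while i < n:
        if d[i - 1] < up <= d[i]:
            j = i + 1
            found = None
            while j < n:
                if d[j - 1] > down >= d[j]:
                    found = j
                    break
                j += 1
            if found is not None and found - i <= pair_n:
                peak = max(v[i : found + 1])
                if peak > min_peak:
                    events.append((i * dt, found * dt, peak))
                    i = found + 1
                    continue
        i += 1
    return events


def brute_force_window_extrema(v, dt, start_ms, len_ms):
    """Min/max over a half-open time window by direct looping."""
    lo = int(round(start_ms / dt))
    hi = lo + int(round(len_ms / dt))
    seg = [v[i] for i in range(lo, min(hi, len(v)))]
    return min(seg), max(seg)


def hand_ranked_kruskal(groups):
    """Kruskal-Wallis H by explicit rank bookkeeping (no tie correction
    needed when all values are distinct)."""
    pooled = sorted((x, gi) for gi, g in enumerate(groups) for x in g)
    n = len(pooled)
    rank_sums = [0.0] * len(groups)
    for rank0, (_, gi) in enumerate(pooled):
        rank_sums[gi] += rank0 + 1
    h = 12.0 / (n * (n + 1)) * sum(
        rs**2 / len(g) for rs, g in zip(rank_sums, groups)
    ) - 3 * (n + 1)
    return h


def enumerate_mwu_pvalue(a, b):
    """Exact two-sided Mann-Whitney p by enumerating all group assignments."""
    import itertools

    pooled = list(a) + list(b)
    n_a = len(a)

    def u_of(idx_a):
        ga = [pooled[i] for i in idx_a]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx_a]
        u = sum(1 for x in ga for y in gb if x > y) + 0.5 * sum(
            1 for x in ga for y in gb if x == y
        )
        return u

    u_obs = u_of(tuple(range(n_a)))
    n_ab = n_a * len(b)
    # two-sided: distance of U from its mean
    dev_obs = abs(u_obs - n_ab / 2.0)
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        total += 1
        if abs(u_of(idx) - n_ab / 2.0) >= dev_obs - 1e-12:
            count += 1
    return u_obs, count / total
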