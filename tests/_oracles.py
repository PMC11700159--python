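"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive results from first principles (plain Python
loops, textbook formulas) so they share no code path with the package.
"""

from __future__ import annotations

import numpy as np


def brute_force_spikes(v, sr, up=30.0, down=-15.0, window_ms=10.0, min_peak=0.0):
    """Exhaustive scan for slope-pair spike events.

    Enumerates every up-crossing of the up-slope criterion in order, pairs
    each with the first subsequent down-crossing, and accepts the pair when
    the down-crossing lies within the window and the voltage maximum
    between the crossings exceeds ``min_peak``.  A consumed crossing cannot
    seed another event.  Returns a list of (upcross_index, peak_index).
    """
    v = list(map(float, v))
    dt_ms = 1000.0 / sr
    slopes = [(v[i + 1] - v[i]) / dt_ms for i in range(len(v) - 1)]

    def is_up(i):
        return slopes[i] >= up and (i == 0 or slopes[i - 1] < up)

    def is_down(i):
        return slopes[i] <= down and (i == 0 or slopes[i - 1] > down)

    w = int(round(window_ms * sr / 1000.0))
    events = []
    pos = 0
    while pos < len(slopes):
        if not is_up(pos):
            pos += 1
            continue
        j = pos + 1
        while j < len(slopes) and not is_down(j):
            j += 1
        if j >= len(slopes) or j - pos > w:
            pos += 1  # up-cross consumed without an event
            continue
        seg = v[pos : j + 2]
        pk = max(seg)
        if pk > min_peak:
            events.append((pos, pos + seg.index(pk)))
        pos = j + 1  # both crossings consumed
    return events


def gg_epsilon_formula(y, groups=None):
    """Greenhouse-Geisser epsilon by the classical elementwise formula.

    ``y`` is subjects x levels.  When ``groups`` is given the covariance is
    pooled within groups (each group mean-centered).
    """
    y = np.asarray(y, dtype=float)
    n, k = y.shape
    if groups is None:
        groups = np.zeros(n, dtype=int)
    groups = np.asarray(groups)
    centered = y.copy()
    for g in np.unique(groups):
        centered[groups == g] -= centered[groups == g].mean(axis=0)
    s = centered.T @ centered / max(n - np.unique(groups).size, 1)

    s_bar = s.mean()
    s_diag = np.trace(s) / k
    row_means = s.mean(axis=1)
    num = (k * (s_diag - s_bar)) ** 2
    den = (k - 1) * (
        (s**2).sum() - 2 * k * (row_means**2).sum() + k**2 * s_bar**2
    )
    if den <= 0:
        return 1.0 / (k - 1)
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def kruskal_h_by_hand(groups):
    """Kruskal-Wallis H from explicit rank sums (no ties expected)."""
    pooled = sorted((val, gi) for gi, g in enumerate(groups) for val in g)
    n = len(pooled)
    rank_sums = {}
    for rank, (_, gi) in enumerate(pooled, start=1):
        rank_sums[gi] = rank_sums.get(gi, 0) + rank
    h = 12.0 / (n * (n + 1)) * sum(
        rank_sums[gi] ** 2 / len(groups[gi]) for gi in rank_sums
    ) - 3 * (n + 1)
    return h


def mann_whitney_exact_p(a, b):
    """Two-sided exact Mann-Whitney p by full enumeration of arrangements."""
    from itertools import combinations

    pooled = list(a) + list(b)
    n_a = len(a)

    def u_stat(idx_a):
        aa = [pooled[i] for i in idx_a]
        bb = [pooled[i] for i in range(len(pooled)) if i not in idx_a]
        u = sum(1 for x in aa for y in bb if x > y) + 0.5 * sum(
            1 for x in aa for y in bb if x == y
        )
        return u

    observed = u_stat(tuple(range(n_a)))
    n_ab = len(a) * len(b)
    # two-sided: distance of U from its null mean
    obs_dev = abs(observed - n_ab / 2.0)
    count = total = 0
    for idx in combinations(range(len(pooled)), n_a):
        total += 1
        if abs(u_stat(idx) - n_ab / 2.0) >= obs_dev - 1e-12:
            count += 1
    return count / total
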