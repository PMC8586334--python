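import itertools

import numpy as np
import pytest

from unwindkit.trace import UnwindingTrace, MIN_FRAGMENT_SAMPLES
from unwindkit.trace import _prefix_sums, _segment_rss_from_sums


@pytest.fixture
def polymer():
    from unwindkit.tether import PolymerParams

    return PolymerParams()


def make_piecewise_trace(rng, n=None, max_breaks=3, noise_sd=1.0,
                         min_seg=5, frame_dt=0.1):
    """Random piecewise-linear trace with known breakpoints (continuous
    at the breaks, which the fitter does not assume)."""
    if n is None:
        n = int(rng.integers(20, 151))
    k = int(rng.integers(0, max_breaks + 1))
    while True:
        breaks = np.sort(rng.choice(np.arange(min_seg, n - min_seg + 1),
                                    size=k, replace=False))
        bounds = np.concatenate([[0], breaks, [n]])
        if np.all(np.diff(bounds) >= min_seg):
            break
    t = np.arange(n) * frame_dt
    slopes = np.empty(k + 1)
    slopes[0] = rng.uniform(-10, 10)
    for i in range(1, k + 1):
        while True:
            s = rng.uniform(-10, 10)
            if abs(s - slopes[i - 1]) >= 4.0:
                slopes[i] = s
                break
    y = np.empty(n)
    level = 0.0
    for (b0, b1), s in zip(zip(bounds[:-1], bounds[1:]), slopes):
        seg_t = t[b0:b1] - t[b0]
        y[b0:b1] = level + s * seg_t
        level = y[b1 - 1] + s * frame_dt
    if noise_sd > 0:
        y = y + rng.normal(0, noise_sd, n)
    return UnwindingTrace(time_s=t, unwound_bp=y), breaks


def brute_force_min_cost(trace, penalty, max_breaks=3,
                         min_seg=MIN_FRAGMENT_SAMPLES):
    """Exhaustive enumeration over all breakpoint sets of size 0..max_breaks.

    Independent of the DP recursion; shares only the per-segment RSS
    primitive.  Returns the minimum of sum(RSS) + penalty * n_breaks.
    """
    n = len(trace)
    sums = _prefix_sums(trace.time_s, trace.unwound_bp)

    def rss(s, e):
        return float(_segment_rss_from_sums(sums, np.array([s]), e)[0])

    best = rss(0, n)
    positions = range(min_seg, n - min_seg + 1)
    for k in range(1, max_breaks + 1):
        for combo in itertools.combinations(positions, k):
            bounds = (0,) + combo + (n,)
            if any(b1 - b0 < min_seg for b0, b1 in zip(bounds[:-1], bounds[1:])):
                continue
            cost = sum(rss(b0, b1) for b0, b1 in zip(bounds[:-1], bounds[1:]))
            cost += penalty * k
            if cost < best:
                best = cost
    return best


def brute_force_min_cost_fast(trace, penalty, max_breaks=3,
                              min_seg=MIN_FRAGMENT_SAMPLES):
    """Vectorized variant of :func:`brute_force_min_cost` (same search
    space, same answer) for the 200-trace acceptance sweep."""
    n = len(trace)
    sums = _prefix_sums(trace.time_s, trace.unwound_bp)
    starts = np.arange(n + 1)
    rss_mat = np.full((n + 1, n + 1), np.inf)
    for e in range(min_seg, n + 1):
        s = np.arange(0, e - min_seg + 1)
        rss_mat[s, e] = _segment_rss_from_sums(sums, s, e)

    best = rss_mat[0, n]
    positions = np.arange(min_seg, n - min_seg + 1)
    for k in range(1, max_breaks + 1):
        combos = np.array(list(itertools.combinations(positions, k)))
        if combos.size == 0:
            continue
        bounds = np.column_stack([
            np.zeros(len(combos), dtype=int), combos,
            np.full(len(combos), n),
        ])
        ok = np.all(np.diff(bounds, axis=1) >= min_seg, axis=1)
        bounds = bounds[ok]
        if not len(bounds):
            continue
        cost = np.zeros(len(bounds))
        for j in range(k + 1):
            cost += rss_mat[bounds[:, j], bounds[:, j + 1]]
        best = min(best, float(cost.min()) + penalty * k)
    return best
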