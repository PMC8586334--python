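"""Segmentation and statistics of unwinding traces.

Implements exact penalized least-squares change-point segmentation into
constant-velocity fragments, velocity/processivity summaries, survival
curves, and equipartition force calibration from transverse bead
fluctuations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import median_filter

from .errors import EmptyResultError, InputError, OverfitWarning

__all__ = [
    "BeadTrajectory",
    "UnwindingTrace",
    "VelocityFragment",
    "UnwindingEvent",
    "TraceSummary",
    "AnalysisConfig",
    "default_penalty",
    "segment_constant_velocity",
    "fragment_velocity_fit",
    "summarize_velocity",
    "detect_events",
    "survival_probability",
    "calibrate_force_variance",
    "analyze_condition",
    "MIN_FRAGMENT_SAMPLES",
]

#: Minimum number of samples in a constant-velocity fragment.
MIN_FRAGMENT_SAMPLES = 3


@dataclass
class BeadTrajectory:
    """Raw bead time series at fixed frame rate with applied force."""

    time_s: np.ndarray
    extension_nm: np.ndarray
    force_pN: float = np.nan
    frame_rate_hz: float = 30.0
    transverse_nm: Optional[np.ndarray] = None
    label: str = ""

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.extension_nm = np.asarray(self.extension_nm, dtype=float)
        if self.transverse_nm is not None:
            self.transverse_nm = np.asarray(self.transverse_nm, dtype=float)
            if self.transverse_nm.shape != self.time_s.shape:
                raise InputError("transverse_nm length differs from time_s")
        if self.time_s.shape != self.extension_nm.shape:
            raise InputError("time_s and extension_nm lengths differ")
        if self.time_s.size >= 2:
            dt = np.diff(self.time_s)
            if np.any(dt <= 0):
                raise InputError("time_s must be strictly increasing")
            if np.ptp(dt) > 1e-6 * dt.mean():
                raise InputError("time_s spacing is not uniform (1e-6 relative)")
        if not np.all(np.isfinite(self.extension_nm)):
            raise InputError("extension_nm contains non-finite values")

    def __len__(self) -> int:
        return self.time_s.size


@dataclass
class UnwindingTrace:
    """Time versus base pairs unwound, after tether-model conversion."""

    time_s: np.ndarray
    unwound_bp: np.ndarray
    force_pN: float = np.nan

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.unwound_bp = np.asarray(self.unwound_bp, dtype=float)
        if self.time_s.shape != self.unwound_bp.shape:
            raise InputError("time_s and unwound_bp lengths differ")
        if not np.all(np.isfinite(self.unwound_bp)):
            raise InputError("unwound_bp contains non-finite values")

    def __len__(self) -> int:
        return self.time_s.size


@dataclass(frozen=True)
class VelocityFragment:
    """One constant-velocity fragment (0-based, half-open index range)."""

    i_start: int
    i_end: int
    velocity_bp_per_s: float
    intercept_bp: float
    rss: float


@dataclass(frozen=True)
class UnwindingEvent:
    """One continuous unwinding run and its processivity."""

    t_start_s: float
    t_end_s: float
    processivity_bp: float


@dataclass
class TraceSummary:
    """Pooled statistics of a measurement condition."""

    mean_velocity_bp_per_s: Optional[float]
    sem_velocity: Optional[float]
    n_fragments: int
    mean_processivity_bp: Optional[float]
    sem_processivity: Optional[float]
    n_events: int
    survival_x_bp: np.ndarray
    survival_p: np.ndarray


@dataclass
class AnalysisConfig:
    """Parameters of :func:`analyze_condition`.

    ``penalty=None`` selects ``penalty_scale`` times the per-trace
    default penalty; the BIC-like default alone over-segments traces
    whose stepping is stochastic rather than smoothly linear, so a
    larger scale is used for condition-level analysis.  The headline
    velocity uses ``velocity_pause_threshold`` (0 keeps every fragment);
    rezipping fragments are excluded when ``exclude_negative_velocity``
    is set, since they report tether re-annealing rather than enzyme
    stepping.  With ``restrict_velocity_to_events`` only fragments whose
    midpoints fall inside a detected unwinding event contribute to the
    velocity mean, which keeps idle-tether and rezip-corner fragments
    out of it, and ``weight_velocity_by_duration`` weights each fragment
    by its length (set it False for the plain per-fragment mean).
    Events ending within ``censored_event_margin_s`` of the last sample
    are dropped from processivity statistics as right-censored.
    """

    penalty: Optional[float] = None
    penalty_scale: float = 10.0
    velocity_pause_threshold_bp_per_s: float = 5.0
    exclude_negative_velocity: bool = True
    restrict_velocity_to_events: bool = True
    weight_velocity_by_duration: bool = True
    min_processivity_bp: float = 100.0
    smoothing_window: int = 15
    event_hysteresis_bp: Optional[float] = None
    censored_event_margin_s: float = 2.0


# ---------------------------------------------------------------------------
# fragment least squares


def _prefix_sums(t: np.ndarray, y: np.ndarray):
    """Prefix sums enabling O(1) per-segment OLS residuals."""
    z = np.zeros(1)
    return (
        np.concatenate([z, np.cumsum(t)]),
        np.concatenate([z, np.cumsum(y)]),
        np.concatenate([z, np.cumsum(t * t)]),
        np.concatenate([z, np.cumsum(y * y)]),
        np.concatenate([z, np.cumsum(t * y)]),
    )


def _segment_rss_from_sums(sums, s, e):
    """Vectorized OLS residual sum of squares on [s, e) (s may be an array)."""
    st, sy, stt, syy, sty = sums
    m = e - s
    sx = st[e] - st[s]
    sy_ = sy[e] - sy[s]
    sxx = stt[e] - stt[s]
    syy_ = syy[e] - syy[s]
    sxy = sty[e] - sty[s]
    varx = sxx - sx * sx / m
    covxy = sxy - sx * sy_ / m
    vary = syy_ - sy_ * sy_ / m
    with np.errstate(divide="ignore", invalid="ignore"):
        rss = vary - np.where(varx > 0, covxy * covxy / np.where(varx > 0, varx, 1.0), 0.0)
    return np.maximum(rss, 0.0)


def fragment_velocity_fit(trace: UnwindingTrace, i_start: int, i_end: int):
    """OLS line fit over the half-open sample range [i_start, i_end).

    Returns ``(velocity_bp_per_s, intercept_bp, rss)``.
    """
    if i_end - i_start < 2:
        raise InputError(f"fragment [{i_start}, {i_end}) has fewer than 2 samples")
    t = trace.time_s[i_start:i_end]
    y = trace.unwound_bp[i_start:i_end]
    tc = t - t.mean()
    varx = float(np.dot(tc, tc))
    if varx == 0.0:
        raise InputError("degenerate fragment: all time values identical")
    slope = float(np.dot(tc, y) / varx)
    intercept = float(y.mean() - slope * t.mean())
    resid = y - (slope * t + intercept)
    return slope, intercept, float(np.dot(resid, resid))


def default_penalty(trace: UnwindingTrace) -> float:
    """BIC-like segmentation penalty ``sigma^2 * log(n)``.

    The noise scale ``sigma`` is the median absolute deviation of first
    differences, scaled to a Gaussian sd (the differencing doubles the
    variance, hence the sqrt(2)).
    """
    n = len(trace)
    if n < 2:
        raise InputError("need at least 2 samples to estimate a penalty")
    d = np.diff(trace.unwound_bp)
    mad = np.median(np.abs(d - np.median(d)))
    sigma = mad / 0.6744897501960817 / np.sqrt(2.0)
    if sigma == 0.0:
        sigma = 1e-12
    return float(sigma**2 * np.log(n))


def segment_constant_velocity(trace: UnwindingTrace,
                              penalty: Optional[float] = None):
    """Optimal segmentation into independent linear fragments.

    Minimizes ``sum of fragment RSS + penalty * (number of breakpoints)``
    exactly by O(n^2) dynamic programming with a minimum fragment length
    of 3 samples.  Fragments are fitted independently (no continuity at
    breakpoints) and returned ordered by start index.
    """
    n = len(trace)
    if n < 4:
        raise InputError(f"need at least 4 samples to segment, got {n}")
    if penalty is None:
        penalty = default_penalty(trace)
    if penalty < 0:
        raise InputError(f"penalty must be non-negative, got {penalty}")
    if penalty == 0:
        warnings.warn(
            "penalty=0 overfits to minimum-length fragments", OverfitWarning,
            stacklevel=2,
        )
    t = trace.time_s
    y = trace.unwound_bp
    sums = _prefix_sums(t, y)

    # cost[e] = optimal cost of segmenting [0, e); parent[e] = argmin start
    cost = np.full(n + 1, np.inf)
    parent = np.zeros(n + 1, dtype=np.int64)
    cost[0] = 0.0
    m = MIN_FRAGMENT_SAMPLES
    for e in range(m, n + 1):
        starts = np.arange(0, e - m + 1)
        valid = np.isfinite(cost[starts])
        starts = starts[valid]
        if starts.size == 0:
            continue
        cand = cost[starts] + _segment_rss_from_sums(sums, starts, e)
        cand += np.where(starts > 0, penalty, 0.0)
        k = int(np.argmin(cand))
        cost[e] = cand[k]
        parent[e] = starts[k]

    # backtrack
    bounds = [n]
    e = n
    while e > 0:
        e = int(parent[e])
        bounds.append(e)
    bounds.reverse()

    fragments = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        slope, intercept, rss = fragment_velocity_fit(trace, s, e)
        fragments.append(VelocityFragment(s, e, slope, intercept, rss))
    return fragments


def summarize_velocity(fragments: Sequence[VelocityFragment],
                       pause_threshold_bp_per_s: float = 0.0,
                       exclude_negative: bool = False,
                       weight_by_duration: bool = False):
    """Mean and SEM of fragment velocities.

    Fragments with ``|velocity| < pause_threshold`` are excluded as
    pauses (threshold 0 keeps all).  With ``exclude_negative``, fragments
    of negative velocity (re-zipping) are dropped as well.  With
    ``weight_by_duration`` each fragment is weighted by its sample count
    and the SEM uses the effective sample size; otherwise the plain
    per-fragment mean and SEM = sd/sqrt(n) are returned.  SEM is None
    when a single fragment remains.
    """
    if not fragments:
        raise InputError("no fragments to summarize")
    v = np.array([f.velocity_bp_per_s for f in fragments])
    w = np.array([float(f.i_end - f.i_start) for f in fragments])
    keep = np.abs(v) >= pause_threshold_bp_per_s
    if exclude_negative:
        keep &= v > 0
    v, w = v[keep], w[keep]
    if v.size == 0:
        raise EmptyResultError("no fragments survive the pause filter")
    if weight_by_duration:
        mean = float(np.average(v, weights=w))
        if v.size > 1:
            n_eff = w.sum() ** 2 / np.dot(w, w)
            var = float(np.average((v - mean) ** 2, weights=w))
            sem = float(np.sqrt(var / n_eff))
        else:
            sem = None
    else:
        mean = float(v.mean())
        sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else None
    return mean, sem, int(v.size)


# ---------------------------------------------------------------------------
# event detection


def _alternating_extrema(y: np.ndarray):
    """Indices of alternating local minima/maxima of ``y``, endpoints
    included; plateaus collapse to their first sample."""
    keep = np.concatenate([[True], np.diff(y) != 0])
    idx = np.nonzero(keep)[0]
    yv = y[idx]
    if yv.size == 1:
        return np.array([], dtype=np.int64), np.array([], dtype=bool)
    d = np.sign(np.diff(yv))
    turning = [0]
    for i in range(1, d.size):
        if d[i] != d[i - 1]:
            turning.append(i)
    turning.append(yv.size - 1)
    ext = idx[np.array(turning, dtype=np.int64)]
    is_min = np.zeros(len(turning), dtype=bool)
    is_min[0] = d[0] > 0
    for j in range(1, len(turning)):
        is_min[j] = not is_min[j - 1]
    return ext, is_min


def _prune_extrema(idx: np.ndarray, is_min: np.ndarray, y: np.ndarray,
                   hysteresis: float):
    """Remove adjacent extremum pairs whose amplitude is below the
    hysteresis, merging the neighbouring runs; alternation is preserved."""
    pts = list(zip(idx.tolist(), is_min.tolist()))
    changed = True
    while changed and len(pts) >= 3:
        changed = False
        amps = [abs(y[pts[i + 1][0]] - y[pts[i][0]]) for i in range(len(pts) - 1)]
        # interior pairs only; removing an endpoint pair would drop real runs
        order = sorted(range(1, len(pts) - 2), key=lambda i: amps[i])
        for i in order:
            if amps[i] < hysteresis:
                del pts[i + 1]
                del pts[i]
                changed = True
                break
    if not pts:
        return np.array([], dtype=np.int64), np.array([], dtype=bool)
    out_idx = np.array([p[0] for p in pts], dtype=np.int64)
    out_min = np.array([p[1] for p in pts], dtype=bool)
    return out_idx, out_min


def detect_events(trace: UnwindingTrace, min_processivity_bp: float = 100.0,
                  smoothing_window: int = 15,
                  hysteresis_bp: Optional[float] = None):
    """Detect unwinding events on the median-smoothed trace.

    An event is a maximal run from a local minimum to the next local
    maximum whose rise is at least ``min_processivity_bp``; its
    processivity is that rise.  Noise wiggles smaller than
    ``hysteresis_bp`` (default: ``min_processivity_bp``) are merged
    before pairing extrema, so a single long run broken by small dips
    counts once.  Events are non-overlapping and time-ordered.
    """
    if len(trace) == 0:
        raise InputError("empty trace")
    if min_processivity_bp <= 0:
        raise InputError(
            f"min_processivity_bp must be positive, got {min_processivity_bp}"
        )
    if hysteresis_bp is None:
        hysteresis_bp = min_processivity_bp
    window = int(smoothing_window)
    if window > 1:
        window = min(window, len(trace))
        if window % 2 == 0:
            window -= 1
        y = median_filter(trace.unwound_bp, size=window, mode="nearest") \
            if window >= 3 else trace.unwound_bp.copy()
    else:
        y = trace.unwound_bp.copy()

    idx, is_min = _alternating_extrema(y)
    if idx.size < 2:
        return []
    idx, is_min = _prune_extrema(idx, is_min, y, hysteresis_bp)

    events = []
    for j in range(idx.size - 1):
        if is_min[j] and not is_min[j + 1]:
            rise = y[idx[j + 1]] - y[idx[j]]
            if rise >= min_processivity_bp:
                events.append(
                    UnwindingEvent(
                        t_start_s=float(trace.time_s[idx[j]]),
                        t_end_s=float(trace.time_s[idx[j + 1]]),
                        processivity_bp=float(rise),
                    )
                )
    return events


# ---------------------------------------------------------------------------
# survival curve and force calibration


def survival_probability(values):
    """Empirical survival function S(x) = P(value > x).

    Returns ``(x, S)`` where ``x`` holds the sorted unique values and
    ``S[i]`` the right-continuous survival just at ``x[i]``; S is 1
    below the smallest value and 0 at the largest.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise InputError("survival_probability needs at least one value")
    x = np.unique(values)
    n = values.size
    s = np.array([(values > xi).sum() / n for xi in x])
    return x, s


def calibrate_force_variance(transverse_nm, tether_length_nm: float,
                             kBT_pN_nm: float = 4.114) -> float:
    """Equipartition force estimate ``F = kBT * L / var(x)``.

    Uses the unbiased sample variance of the transverse bead coordinate.
    No motion-blur or aliasing correction is applied.
    """
    x = np.asarray(transverse_nm, dtype=float)
    if x.size < 100:
        raise InputError(f"need at least 100 samples, got {x.size}")
    if tether_length_nm <= 0:
        raise InputError(f"tether length must be positive, got {tether_length_nm}")
    var = float(x.var(ddof=1))
    if var == 0.0:
        raise InputError("zero variance: cannot calibrate force")
    return kBT_pN_nm * tether_length_nm / var


# ---------------------------------------------------------------------------
# condition-level pooling


def analyze_condition(traces: Sequence[UnwindingTrace],
                      config: Optional[AnalysisConfig] = None) -> TraceSummary:
    """Pool fragments and events across traces of one condition."""
    if not traces:
        raise InputError("analyze_condition needs at least one trace")
    if config is None:
        config = AnalysisConfig()

    fragments = []
    events = []
    for trace in traces:
        penalty = config.penalty
        if penalty is None:
            penalty = config.penalty_scale * default_penalty(trace)
        trace_fragments = segment_constant_velocity(trace, penalty)
        trace_events = detect_events(
            trace,
            min_processivity_bp=config.min_processivity_bp,
            smoothing_window=config.smoothing_window,
            hysteresis_bp=config.event_hysteresis_bp,
        )
        # drop right-censored events: the engagement ran into the end of
        # the recording, so its rise under-reports the processivity
        t_last = float(trace.time_s[-1])
        trace_events = [
            e for e in trace_events
            if e.t_end_s <= t_last - config.censored_event_margin_s
        ]
        if config.restrict_velocity_to_events and trace_events:
            t = trace.time_s
            kept = []
            for f in trace_fragments:
                mid = 0.5 * (t[f.i_start] + t[f.i_end - 1])
                if any(e.t_start_s <= mid <= e.t_end_s for e in trace_events):
                    kept.append(f)
            trace_fragments = kept
        elif config.restrict_velocity_to_events:
            trace_fragments = []
        fragments.extend(trace_fragments)
        events.extend(trace_events)

    try:
        mean_v, sem_v, n_v = summarize_velocity(
            fragments,
            pause_threshold_bp_per_s=config.velocity_pause_threshold_bp_per_s,
            exclude_negative=config.exclude_negative_velocity,
            weight_by_duration=config.weight_velocity_by_duration,
        )
    except EmptyResultError:
        mean_v, sem_v, n_v = None, None, 0

    if events:
        proc = np.array([e.processivity_bp for e in events])
        mean_p = float(proc.mean())
        sem_p = float(proc.std(ddof=1) / np.sqrt(proc.size)) if proc.size > 1 else None
        sx, sp = survival_probability(proc)
    else:
        mean_p, sem_p = None, None
        sx, sp = np.array([]), np.array([])

    return TraceSummary(
        mean_velocity_bp_per_s=mean_v,
        sem_velocity=sem_v,
        n_fragments=n_v,
        mean_processivity_bp=mean_p,
        sem_processivity=sem_p,
        n_events=len(events),
        survival_x_bp=sx,
        survival_p=sp,
    )
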