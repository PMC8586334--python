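"""Seeded simulators for every input the analysis pipeline consumes.

The unwinding simulator runs a continuous-time Markov model of a single
enzyme (1-bp steps, Poisson pauses, geometric per-step detachment with
re-initiation) on the nicked-flap tether, maps base pairs unwound to
bead extension through the tether model, and samples with camera-style
within-frame averaging plus Gaussian noise and linear drift.  Companion
generators cover transverse fluctuations, mass-photometry landings,
binding titrations and NADH time courses.  All simulators are pure
functions of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import InputError
from .massphot import MassCalibration, MassEventSet
from .quantify import BindingCurve
from .tether import (
    PolymerParams,
    TetherGeometry,
    bp_step_signal_nm,
    ds_relative_extension,
    ss_relative_extension,
)
from .trace import BeadTrajectory

__all__ = [
    "SimConfig",
    "GroundTruth",
    "tether_baseline_nm",
    "simulate_unwinding_trajectory",
    "simulate_condition",
    "simulate_transverse_fluctuations",
    "simulate_mass_events",
    "simulate_binding_assay",
    "simulate_atpase_timecourse",
]


@dataclass
class SimConfig:
    """Unwinding-simulation parameters.

    ``mean_processivity_bp=inf`` disables detachment;
    ``pause_entry_per_s=0`` disables pausing; ``reinitiation_per_s=0``
    means a detached enzyme never restarts.  After detachment the tether
    re-anneals toward zero at ``rezip_bp_per_s``.
    """

    seed: int
    n_traces: int = 25
    frame_rate_hz: float = 30.0
    duration_s: float = 180.0
    force_pN: float = 30.0
    velocity_bp_per_s: float = 44.0
    mean_processivity_bp: float = 2300.0
    pause_entry_per_s: float = 0.02
    pause_exit_per_s: float = 0.5
    reinitiation_per_s: float = 0.05
    rezip_bp_per_s: float = 400.0
    noise_sd_nm: float = 5.0
    drift_nm_per_s: float = 0.0
    polymer: PolymerParams = field(default_factory=PolymerParams)
    geometry: TetherGeometry = field(default_factory=TetherGeometry)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise InputError("seed is mandatory")
        for name in (
            "n_traces", "frame_rate_hz", "duration_s", "force_pN",
            "velocity_bp_per_s", "pause_entry_per_s", "pause_exit_per_s",
            "reinitiation_per_s", "rezip_bp_per_s", "noise_sd_nm",
        ):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be non-negative")
        if self.mean_processivity_bp <= 0:
            raise InputError("mean_processivity_bp must be positive (inf to disable)")
        if self.velocity_bp_per_s <= 0:
            raise InputError("velocity_bp_per_s must be positive")
        if self.rezip_bp_per_s <= 0:
            raise InputError("rezip_bp_per_s must be positive")


@dataclass
class GroundTruth:
    """Per-trace truth emitted alongside the observable trajectory."""

    time_s: np.ndarray
    true_unwound_bp: np.ndarray
    event_processivities_bp: List[float]
    event_intervals_s: List[Tuple[float, float]]
    pause_intervals_s: List[Tuple[float, float]]
    force_pN: float
    baseline_nm: float
    bp_step_signal_nm: float
    clamped: bool


def tether_baseline_nm(force_pN: float, polymer: PolymerParams,
                       geometry: TetherGeometry) -> float:
    """Extension of the fully annealed tether (zero bp unwound)."""
    ds = geometry.ds_bp_total * polymer.ds_rise_nm_per_bp * ds_relative_extension(
        force_pN, polymer
    )
    ss = geometry.flap_nt * polymer.ss_contour_nm_per_nt * ss_relative_extension(
        force_pN, polymer
    )
    return geometry.handle_contribution_nm + ds + ss


def _simulate_truth_knots(cfg: SimConfig, rng: np.random.Generator):
    """Piecewise-linear knots of the true unwound-bp signal.

    Returns (knot_times, knot_values, events, pauses, clamped).
    """
    duration = cfg.duration_s
    v = cfg.velocity_bp_per_s
    p_detach = (
        0.0 if math.isinf(cfg.mean_processivity_bp)
        else 1.0 / cfg.mean_processivity_bp
    )
    cap = cfg.geometry.ds_bp_total

    kt: List[float] = [0.0]
    kv: List[float] = [0.0]
    events: List[float] = []
    intervals: List[Tuple[float, float]] = []
    pauses: List[Tuple[float, float]] = []
    clamped = False
    t = 0.0

    while t < duration:
        t_engage = t
        # ---- one engagement: stepping with pauses until detachment/cap
        if p_detach > 0:
            n_steps = int(rng.geometric(p_detach))
        else:
            n_steps = cap
        hit_cap = n_steps >= cap
        n_steps = min(n_steps, cap)
        step_waits = rng.exponential(1.0 / v, size=n_steps)
        active = float(step_waits.sum())

        # Poisson pauses over the active (stepping) time, inserted into it
        if cfg.pause_entry_per_s > 0 and cfg.pause_exit_per_s > 0 and active > 0:
            n_pause = rng.poisson(cfg.pause_entry_per_s * active)
            pause_at = np.sort(rng.uniform(0.0, active, size=n_pause))
            pause_len = rng.exponential(1.0 / cfg.pause_exit_per_s, size=n_pause)
        else:
            pause_at = np.empty(0)
            pause_len = np.empty(0)

        step_active = np.cumsum(step_waits)
        # wall-clock offset accumulated from pauses before each step
        shift = np.zeros(n_steps)
        if pause_at.size:
            shift = np.cumsum(pause_len)[
                np.searchsorted(pause_at, step_active, side="left") - 1
            ]
            shift[np.searchsorted(pause_at, step_active, side="left") == 0] = 0.0
        step_wall = t + step_active + shift

        n0 = kv[-1]
        done = np.searchsorted(step_wall, duration)
        for j in range(done):
            kt.append(float(step_wall[j]))
            kv.append(n0 + j + 1)
        for a, ln in zip(pause_at, pause_len):
            start = t + a + float(np.sum(pause_len[pause_at < a]))
            if start >= duration:
                break
            pauses.append((start, min(start + ln, duration)))
        if done < n_steps:
            # ran out of recording time mid-engagement
            t = duration
            break
        t = float(step_wall[-1]) if n_steps else t
        if hit_cap:
            clamped = True
        events.append(float(n_steps))
        intervals.append((t_engage, t))

        # ---- rezip ramp back to zero
        n_now = kv[-1]
        rezip_end = t + n_now / cfg.rezip_bp_per_s
        if rezip_end >= duration:
            frac = (duration - t) / (rezip_end - t) if rezip_end > t else 1.0
            kt.append(duration)
            kv.append(n_now * (1 - frac))
            t = duration
            break
        kt.append(rezip_end)
        kv.append(0.0)
        t = rezip_end

        # ---- idle until re-initiation
        if cfg.reinitiation_per_s <= 0:
            break
        t += float(rng.exponential(1.0 / cfg.reinitiation_per_s))
        if t >= duration:
            break
        kt.append(t)
        kv.append(0.0)

    if kt[-1] < duration:
        kt.append(duration)
        kv.append(kv[-1])
    return np.asarray(kt), np.asarray(kv), events, intervals, pauses, clamped


def simulate_unwinding_trajectory(cfg: SimConfig,
                                  rng: Optional[np.random.Generator] = None):
    """Simulate one bead trajectory; returns (BeadTrajectory, GroundTruth).

    Camera integration is approximated by boxcar-averaging a 10x
    supersampled version of the true signal over each frame.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    kt, kv, events, intervals, pauses, clamped = _simulate_truth_knots(cfg, rng)

    fr = cfg.frame_rate_hz
    n_frames = int(round(cfg.duration_s * fr))
    if n_frames < 1:
        raise InputError("duration too short for a single frame")
    frame_t = np.arange(n_frames) / fr
    oversample = 10
    sub = (np.arange(n_frames * oversample) + 0.5) / (fr * oversample)
    n_sub = np.interp(sub, kt, kv)
    n_true = n_sub.reshape(n_frames, oversample).mean(axis=1)

    delta = bp_step_signal_nm(cfg.force_pN, cfg.polymer)
    baseline = tether_baseline_nm(cfg.force_pN, cfg.polymer, cfg.geometry)
    z = baseline + n_true * delta + cfg.drift_nm_per_s * frame_t
    if cfg.noise_sd_nm > 0:
        z = z + rng.normal(0.0, cfg.noise_sd_nm, size=n_frames)

    traj = BeadTrajectory(
        time_s=frame_t,
        extension_nm=z,
        force_pN=cfg.force_pN,
        frame_rate_hz=fr,
        label=f"sim-seed{cfg.seed}",
    )
    truth = GroundTruth(
        time_s=frame_t,
        true_unwound_bp=n_true,
        event_processivities_bp=events,
        event_intervals_s=intervals,
        pause_intervals_s=pauses,
        force_pN=cfg.force_pN,
        baseline_nm=baseline,
        bp_step_signal_nm=delta,
        clamped=clamped,
    )
    return traj, truth


def simulate_condition(cfg: SimConfig):
    """Simulate ``cfg.n_traces`` independent beads from one master seed."""
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_traces)
    out = []
    for i, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        traj, truth = simulate_unwinding_trajectory(cfg, rng=rng)
        traj.label = f"sim-seed{cfg.seed}-trace{i}"
        out.append((traj, truth))
    return out


def simulate_transverse_fluctuations(force_pN: float, tether_length_nm: float,
                                     kBT_pN_nm: float, n: int, seed: int,
                                     corner_frequency_hz: Optional[float] = None,
                                     frame_rate_hz: float = 30.0) -> np.ndarray:
    """Transverse bead positions with equipartition variance kBT*L/F.

    i.i.d. Gaussian by default; with ``corner_frequency_hz`` an
    Ornstein-Uhlenbeck sequence of the same stationary variance.
    """
    if force_pN <= 0:
        raise InputError("force must be positive")
    if tether_length_nm <= 0 or kBT_pN_nm <= 0:
        raise InputError("tether length and kBT must be positive")
    var = kBT_pN_nm * tether_length_nm / force_pN
    rng = np.random.default_rng(seed)
    if corner_frequency_hz is None:
        return rng.normal(0.0, math.sqrt(var), size=n)
    rho = math.exp(-2.0 * math.pi * corner_frequency_hz / frame_rate_hz)
    x = np.empty(n)
    x[0] = rng.normal(0.0, math.sqrt(var))
    innov = rng.normal(0.0, math.sqrt(var * (1 - rho**2)), size=n - 1)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + innov[i - 1]
    return x


def simulate_mass_events(components: Sequence[Tuple[float, float, float]],
                         n: int, calibration: MassCalibration, seed: int,
                         standard_masses_kDa: Sequence[float] = (66, 146, 480, 1048),
                         standard_events: int = 200,
                         standard_contrast_sd: float = 0.0):
    """Draw mass-photometry landings from a Gaussian mixture.

    ``components`` is a list of ``(mean_kDa, weight, sd_kDa)``.  Masses
    are converted to contrasts through the inverse calibration.  Also
    emits synthetic standards (dict mass -> contrasts) suitable for
    :func:`unwindkit.massphot.calibrate_contrast`, and the component
    labels drawn for each event.
    """
    components = list(components)
    weights = np.array([w for _, w, _ in components], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise InputError(f"component weights must sum to 1, got {weights.sum()}")
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(components), size=n, p=weights)
    means = np.array([m for m, _, _ in components])
    sds = np.array([s for _, _, s in components])
    masses = rng.normal(means[labels], sds[labels])
    contrasts = calibration.to_contrast(masses)
    events = MassEventSet(contrasts=contrasts, condition="simulated")

    standards = {}
    for mass in standard_masses_kDa:
        base = float(calibration.to_contrast(mass))
        jitter = rng.normal(0.0, standard_contrast_sd, size=standard_events) \
            if standard_contrast_sd > 0 else np.zeros(standard_events)
        standards[float(mass)] = base + jitter
    return standards, events, labels


def simulate_binding_assay(K_nM: float, hill_n: float, concentrations_nM,
                           noise_sd: float, seed: int) -> BindingCurve:
    """Hill-curve titration with truncated Gaussian noise, clipped to [0,1]."""
    if K_nM <= 0:
        raise InputError("K must be positive")
    c = np.asarray(concentrations_nM, dtype=float)
    with np.errstate(divide="ignore"):
        cn = np.power(c, hill_n)
        f = np.where(c > 0, cn / (cn + K_nM**hill_n), 0.0)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, size=c.size)
    return BindingCurve(concentrations_nM=c, fraction=np.clip(f, 0.0, 1.0))


def simulate_atpase_timecourse(kcat_per_s: float, enzyme_M: float,
                               epsilon_M_cm: float, path_cm: float,
                               duration_s: float, noise_sd: float, seed: int,
                               a0: float = 1.0, dt_s: float = 1.0):
    """NADH absorbance decay A(t) = A0 - kcat*[E]*eps*l*t (+noise, floored at 0)."""
    if enzyme_M < 0 or kcat_per_s < 0:
        raise InputError("kcat and enzyme concentration must be non-negative")
    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    a = a0 - kcat_per_s * enzyme_M * epsilon_M_cm * path_cm * t
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        a = a + rng.normal(0.0, noise_sd, size=t.size)
    return t, np.maximum(a, 0.0)
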