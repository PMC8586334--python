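"""Mass photometry: contrast calibration, mixture fitting, species assignment.

Per-landing interferometric contrasts are mapped to molecular mass by a
line through standards of known mass; mass distributions are fitted as
1-D Gaussian mixtures by expectation-maximization (BIC model selection);
peaks are assigned to complex compositions by exhaustive subset search
over user-supplied component masses.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import ConvergenceError, InputError

__all__ = [
    "MassEventSet",
    "MassCalibration",
    "MassPeak",
    "SpeciesAssignment",
    "MixtureFit",
    "calibrate_contrast",
    "contrasts_to_masses",
    "fit_mass_mixture",
    "fit_mass_peaks",
    "assign_species",
]


@dataclass
class MassEventSet:
    """Per-landing contrasts and (after calibration) masses."""

    contrasts: np.ndarray
    masses_kDa: Optional[np.ndarray] = None
    condition: str = ""

    def __post_init__(self) -> None:
        self.contrasts = np.asarray(self.contrasts, dtype=float)
        if not np.all(np.isfinite(self.contrasts)):
            raise InputError("contrasts contain non-finite values")
        if self.masses_kDa is not None:
            self.masses_kDa = np.asarray(self.masses_kDa, dtype=float)
            if self.masses_kDa.shape != self.contrasts.shape:
                raise InputError("masses_kDa length differs from contrasts")

    def __len__(self) -> int:
        return self.contrasts.size


@dataclass(frozen=True)
class MassCalibration:
    """Affine contrast-to-mass map ``mass = slope * contrast + intercept``."""

    slope_kDa_per_contrast: float
    intercept_kDa: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope_kDa_per_contrast == 0:
            raise InputError("calibration slope must be non-zero")

    def to_mass(self, contrast):
        return self.slope_kDa_per_contrast * np.asarray(contrast, float) + self.intercept_kDa

    def to_contrast(self, mass_kDa):
        return (np.asarray(mass_kDa, float) - self.intercept_kDa) / self.slope_kDa_per_contrast


@dataclass(frozen=True)
class MassPeak:
    mean_kDa: float
    sd_kDa: float
    weight: float
    n_events: int

    def __post_init__(self) -> None:
        if self.sd_kDa <= 0:
            raise InputError("peak sd must be positive")


@dataclass(frozen=True)
class SpeciesAssignment:
    peak: MassPeak
    components: tuple
    theoretical_sum_kDa: float
    deviation_kDa: float


@dataclass
class MixtureFit:
    """Full EM fit: peaks plus diagnostics."""

    peaks: list
    log_likelihood: float
    loglik_trace: np.ndarray
    bic: float
    n_iter: int
    converged: bool


def calibrate_contrast(standards: Mapping[float, Sequence[float]]) -> MassCalibration:
    """Fit the contrast-to-mass line through measured standards.

    ``standards`` maps each known standard mass (kDa) to the landing
    contrasts measured for it; the line goes through (median contrast,
    mass) per standard. The median guards against outlier landings.
    """
    if len(standards) < 2:
        raise InputError(
            f"need at least 2 distinct standard masses, got {len(standards)}"
        )
    masses = np.array(sorted(standards), dtype=float)
    med = np.array([np.median(np.asarray(standards[m], float)) for m in masses])
    if np.ptp(med) == 0:
        raise InputError("standard contrasts are all identical")
    slope, intercept = np.polyfit(med, masses, 1)
    pred = slope * med + intercept
    ss_res = float(np.sum((masses - pred) ** 2))
    ss_tot = float(np.sum((masses - masses.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return MassCalibration(float(slope), float(intercept), min(max(r2, 0.0), 1.0))


def contrasts_to_masses(events: MassEventSet, cal: MassCalibration) -> MassEventSet:
    """Apply the calibration elementwise; returns a new event set."""
    return MassEventSet(
        contrasts=events.contrasts.copy(),
        masses_kDa=cal.to_mass(events.contrasts),
        condition=events.condition,
    )


# ---------------------------------------------------------------------------
# Gaussian mixture EM

_LOG_2PI = math.log(2.0 * math.pi)


def _kmeanspp_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ style seeding of component means on 1-D data."""
    means = np.empty(k)
    means[0] = x[rng.integers(x.size)]
    for j in range(1, k):
        d2 = np.min((x[:, None] - means[None, :j]) ** 2, axis=1)
        total = d2.sum()
        if total == 0:
            means[j] = x[rng.integers(x.size)]
            continue
        means[j] = x[rng.choice(x.size, p=d2 / total)]
    return means


def _em_once(x: np.ndarray, k: int, rng: np.random.Generator, max_iter: int,
             tol: float):
    n = x.size
    means = _kmeanspp_init(x, k, rng)
    sds = np.full(k, max(x.std(), 1e-6))
    weights = np.full(k, 1.0 / k)
    min_sd = max(1e-6 * max(x.std(), 1.0), 1e-9)

    loglik_trace = []
    prev = -np.inf
    converged = False
    for it in range(max_iter):
        # E step: log responsibilities
        logpdf = (
            -0.5 * ((x[:, None] - means[None, :]) / sds[None, :]) ** 2
            - np.log(sds[None, :])
            - 0.5 * _LOG_2PI
            + np.log(weights[None, :])
        )
        m = logpdf.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logpdf - m).sum(axis=1))
        loglik = float(lse.sum())
        loglik_trace.append(loglik)
        resp = np.exp(logpdf - lse[:, None])

        # M step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.sqrt(np.maximum(var, min_sd**2))

        if loglik - prev < tol and it > 0:
            converged = True
            break
        prev = loglik
    return means, sds, weights, resp, np.array(loglik_trace), converged


def fit_mass_mixture(masses, k: int = 1, seed: int = 0, n_init: int = 5,
                     max_iter: int = 1000, tol: float = 1e-6) -> MixtureFit:
    """Fit a k-component Gaussian mixture to 1-D masses by EM.

    Deterministic given ``seed`` (k-means++ initialisation drawn from a
    seeded generator; best of ``n_init`` restarts by final likelihood).
    """
    x = np.asarray(masses, dtype=float)
    if x.size < 50 * k:
        raise InputError(
            f"need at least {50 * k} events for {k} components, got {x.size}"
        )
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        result = _em_once(x, k, rng, max_iter, tol)
        if best is None or result[4][-1] > best[4][-1]:
            best = result
    means, sds, weights, resp, trace, converged = best
    if not converged:
        raise ConvergenceError(
            f"EM did not converge in {max_iter} iterations "
            f"(last loglik change {trace[-1] - trace[-2]:.3g})"
        )
    order = np.argsort(means)
    hard = resp.argmax(axis=1)
    peaks = [
        MassPeak(
            mean_kDa=float(means[j]),
            sd_kDa=float(sds[j]),
            weight=float(weights[j]),
            n_events=int((hard == j).sum()),
        )
        for j in order
    ]
    loglik = float(trace[-1])
    n_params = 3 * k - 1
    bic = n_params * math.log(x.size) - 2.0 * loglik
    return MixtureFit(peaks, loglik, trace, bic, len(trace), converged)


def fit_mass_peaks(masses, k="auto", k_max: int = 5, seed: int = 0,
                   **em_kwargs):
    """Fit mass peaks; ``k='auto'`` selects the component count by
    minimum BIC over 1..k_max (capped by the event count).

    Returns the peaks sorted by mean.
    """
    x = np.asarray(masses, dtype=float)
    if k == "auto":
        k_cap = min(k_max, max(1, x.size // 50))
        fits = []
        for kk in range(1, k_cap + 1):
            try:
                fits.append(fit_mass_mixture(x, k=kk, seed=seed, **em_kwargs))
            except ConvergenceError:
                continue  # overparameterized k may cycle; BIC would reject it
        if not fits:
            raise ConvergenceError("no component count converged")
        best = min(fits, key=lambda f: f.bic)
        return best.peaks
    return fit_mass_mixture(x, k=int(k), seed=seed, **em_kwargs).peaks


def assign_species(peaks: Sequence[MassPeak], components: Mapping[str, float],
                   tolerance_kDa: Optional[float] = None):
    """Assign each peak the component subset whose summed mass is closest.

    Exhaustive search over all non-empty subsets; a peak is assigned only
    if the best deviation is within the tolerance (default: one fitted sd
    of that peak). Ties break toward fewer components. Unassignable peaks
    come back with an empty component tuple.
    """
    if not components:
        raise InputError("components must be non-empty")
    if tolerance_kDa is not None and tolerance_kDa <= 0:
        raise InputError(f"tolerance must be positive, got {tolerance_kDa}")
    names = sorted(components)
    out = []
    for peak in peaks:
        tol = peak.sd_kDa if tolerance_kDa is None else tolerance_kDa
        best_subset = ()
        best_sum = math.nan
        best_dev = math.inf
        for r in range(1, len(names) + 1):
            for subset in itertools.combinations(names, r):
                total = sum(components[name] for name in subset)
                dev = abs(peak.mean_kDa - total)
                if dev < best_dev:  # strict: ties keep the smaller subset
                    best_dev = dev
                    best_subset = subset
                    best_sum = total
        if best_dev <= tol:
            out.append(SpeciesAssignment(peak, best_subset, best_sum, best_dev))
        else:
            out.append(SpeciesAssignment(peak, (), math.nan, math.nan))
    return out
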