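"""Ensemble-assay quantification.

Fraction product from background-subtracted band intensities, the 50%
binding constant from a Hill fit of titration curves, and the apparent
ATP turnover number from NADH absorbance decay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .errors import (
    ConvergenceError,
    ExtrapolationWarning,
    InputError,
    SlopeSignWarning,
)

__all__ = [
    "BindingCurve",
    "KdEstimate",
    "LaneQuant",
    "AtpaseResult",
    "fraction_product",
    "quantify_lane",
    "hill",
    "fit_kd",
    "kd_by_interpolation",
    "atpase_kcat",
    "NADH_EPSILON_340_M_CM",
]

#: Molar extinction coefficient of NADH at 340 nm (M^-1 cm^-1).
NADH_EPSILON_340_M_CM = 6220.0


@dataclass
class BindingCurve:
    """Concentration-response data from a binding titration."""

    concentrations_nM: np.ndarray
    fraction: np.ndarray
    replicate_sem: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.concentrations_nM = np.asarray(self.concentrations_nM, dtype=float)
        self.fraction = np.asarray(self.fraction, dtype=float)
        if self.concentrations_nM.shape != self.fraction.shape:
            raise InputError("concentrations and fractions have different lengths")
        if np.any(self.concentrations_nM < 0):
            raise InputError("concentrations must be non-negative")
        if np.any((self.fraction < 0) | (self.fraction > 1)):
            raise InputError("fractions must lie within [0, 1]")
        order = np.argsort(self.concentrations_nM)
        self.concentrations_nM = self.concentrations_nM[order]
        self.fraction = self.fraction[order]
        if self.replicate_sem is not None:
            self.replicate_sem = np.asarray(self.replicate_sem, dtype=float)[order]


@dataclass(frozen=True)
class KdEstimate:
    """Hill-fit result; ``kd_nM`` is the 50%-binding concentration."""

    kd_nM: float
    hill_n: float
    fit_rss: float
    converged: bool

    def __post_init__(self) -> None:
        if self.kd_nM <= 0 or self.hill_n <= 0:
            raise InputError("kd and hill coefficient must be positive")


@dataclass
class LaneQuant:
    band_intensities: dict
    background: float
    fraction_product: float


@dataclass(frozen=True)
class AtpaseResult:
    slope_abs_per_s: float
    kcat_per_s: float
    epsilon_M_cm: float
    path_cm: float
    enzyme_M: float


def fraction_product(band_intensities: Mapping[str, float], background: float = 0.0,
                     substrate_key: str = "substrate") -> float:
    """Fraction of substrate converted to product(s).

    ``band_intensities`` maps band names to raw intensities; every band
    other than ``substrate_key`` counts as product.  The background is
    subtracted per band and negative results are clipped at zero before
    forming ``products / (substrate + products)``.
    """
    if substrate_key not in band_intensities:
        raise InputError(f"missing substrate band {substrate_key!r}")
    if len(band_intensities) < 2:
        raise InputError("need at least one product band besides the substrate")
    corrected = {
        name: max(float(value) - background, 0.0)
        for name, value in band_intensities.items()
    }
    substrate = corrected[substrate_key]
    products = sum(v for k, v in corrected.items() if k != substrate_key)
    total = substrate + products
    if total == 0:
        raise InputError("all bands are zero after background subtraction")
    return products / total


def quantify_lane(band_intensities: Mapping[str, float], background: float = 0.0,
                  substrate_key: str = "substrate") -> LaneQuant:
    """Lane record bundling intensities with the computed fraction."""
    frac = fraction_product(band_intensities, background, substrate_key)
    return LaneQuant(dict(band_intensities), background, frac)


def hill(c, kd: float, n: float):
    """Hill binding isotherm with unit saturation: f = c^n / (c^n + K^n)."""
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        cn = np.power(c, n)
        return np.where(c > 0, cn / (cn + kd**n), 0.0)


def fit_kd(curve: BindingCurve) -> KdEstimate:
    """Least-squares Hill fit with saturation fixed at 1.

    ``kd_nM`` equals the concentration giving 50% binding for any Hill
    coefficient.  Multistart over n in {0.5, 1, 2, 4}; warns when the
    data never reach 50% response (the K_D is then an extrapolation).
    """
    c = curve.concentrations_nM
    f = curve.fraction
    if c.size < 4:
        raise InputError(f"need at least 4 concentrations, got {c.size}")
    if f.max() < 0.5:
        warnings.warn(
            "response never reaches 50% within the data range; "
            "K_D is an extrapolation",
            ExtrapolationWarning,
            stacklevel=2,
        )
    positive = c[c > 0]
    if positive.size == 0:
        raise InputError("all concentrations are zero")
    k0 = float(np.interp(0.5, f, c)) if f.max() >= 0.5 else float(positive.max())
    k0 = max(k0, float(positive.min()) * 1e-3)

    best: Optional[Tuple[float, float, float]] = None
    for n0 in (0.5, 1.0, 2.0, 4.0):
        try:
            popt, _ = curve_fit(
                hill, c, f, p0=[k0, n0],
                bounds=([1e-12, 1e-3], [np.inf, 50.0]),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        rss = float(np.sum((hill(c, *popt) - f) ** 2))
        if best is None or rss < best[2]:
            best = (float(popt[0]), float(popt[1]), rss)
    if best is None:
        raise ConvergenceError("Hill fit failed from every start")
    kd, n, rss = best
    return KdEstimate(kd_nM=kd, hill_n=n, fit_rss=rss, converged=True)


def kd_by_interpolation(curve: BindingCurve) -> float:
    """Model-free 50%-binding concentration by linear interpolation.

    Provided for exact replication of 50%-crossing readings; requires the
    data to bracket 0.5.
    """
    c = curve.concentrations_nM
    f = curve.fraction
    above = np.nonzero(f >= 0.5)[0]
    if above.size == 0 or above[0] == 0:
        raise InputError("data do not bracket 50% binding from below")
    j = above[0]
    c0, c1 = c[j - 1], c[j]
    f0, f1 = f[j - 1], f[j]
    return float(c0 + (0.5 - f0) * (c1 - c0) / (f1 - f0))


def atpase_kcat(time_s, absorbance, enzyme_M: float,
                epsilon_M_cm: float = NADH_EPSILON_340_M_CM,
                path_cm: float = 1.0,
                window: Optional[Tuple[float, float]] = None) -> AtpaseResult:
    """Apparent ATP turnover from NADH absorbance decay at 340 nm.

    One NADH is oxidized per ATP hydrolyzed, so
    ``kcat = |slope| / (epsilon * path * [E])`` in s^-1, with the slope
    from an OLS fit of absorbance versus time over ``window`` (seconds,
    inclusive; default: the whole series).
    """
    t = np.asarray(time_s, dtype=float)
    a = np.asarray(absorbance, dtype=float)
    if t.shape != a.shape:
        raise InputError("time and absorbance have different lengths")
    if enzyme_M <= 0:
        raise InputError(f"enzyme concentration must be positive, got {enzyme_M}")
    if epsilon_M_cm <= 0 or path_cm <= 0:
        raise InputError("epsilon and path length must be positive")
    if window is not None:
        lo, hi = window
        keep = (t >= lo) & (t <= hi)
        t, a = t[keep], a[keep]
    if t.size < 10:
        raise InputError(f"need at least 10 time points, got {t.size}")
    slope = float(np.polyfit(t, a, 1)[0])
    if slope > 0:
        warnings.warn(
            "absorbance rises over the fit window; NADH-coupled ATPase "
            "should consume NADH",
            SlopeSignWarning,
            stacklevel=2,
        )
    kcat = abs(slope) / (epsilon_M_cm * path_cm * enzyme_M)
    return AtpaseResult(
        slope_abs_per_s=slope,
        kcat_per_s=kcat,
        epsilon_M_cm=epsilon_M_cm,
        path_cm=path_cm,
        enzyme_M=enzyme_M,
    )
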