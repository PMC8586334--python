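"""Polymer elasticity of the bead tether.

Converts applied force into relative extension of the double-stranded
(worm-like chain, Marko-Siggia interpolation) and single-stranded
(freely-jointed chain) portions of the tether, and inverts measured
extension changes into base pairs unwound.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.constants import k as _BOLTZMANN_J_PER_K
from scipy.optimize import brentq

from .errors import DegenerateForceError, InputError

__all__ = [
    "BOLTZMANN_PN_NM_PER_K",
    "PolymerParams",
    "TetherGeometry",
    "ds_relative_extension",
    "ss_relative_extension",
    "bp_step_signal_nm",
    "extension_to_unwound_bp",
    "unwound_bp_to_extension",
]

#: Boltzmann constant in pN nm / K (1 J = 1e21 pN nm).
BOLTZMANN_PN_NM_PER_K = _BOLTZMANN_J_PER_K * 1e21


@dataclass(frozen=True)
class PolymerParams:
    """Elastic parameters of the dsDNA/ssDNA tether segments.

    ``kBT_pN_nm`` is derived from ``temperature_K`` when not given
    explicitly; if given, it must agree with the temperature to 0.1%.
    """

    ds_persistence_nm: float = 45.0
    ds_rise_nm_per_bp: float = 0.338
    ss_kuhn_nm: float = 1.5
    ss_contour_nm_per_nt: float = 0.56
    temperature_K: float = 298.0
    kBT_pN_nm: float = field(default=None)  # type: ignore[assignment]
    nt_gained_per_bp: float = 1.0

    def __post_init__(self) -> None:
        if self.kBT_pN_nm is None:
            object.__setattr__(
                self, "kBT_pN_nm", BOLTZMANN_PN_NM_PER_K * self.temperature_K
            )
        for name in (
            "ds_persistence_nm",
            "ds_rise_nm_per_bp",
            "ss_kuhn_nm",
            "ss_contour_nm_per_nt",
            "temperature_K",
            "kBT_pN_nm",
        ):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise InputError(f"{name} must be strictly positive, got {value!r}")
        if self.nt_gained_per_bp < 0 or not np.isfinite(self.nt_gained_per_bp):
            raise InputError(
                f"nt_gained_per_bp must be non-negative, got {self.nt_gained_per_bp!r}"
            )
        expected = BOLTZMANN_PN_NM_PER_K * self.temperature_K
        if abs(self.kBT_pN_nm - expected) > 1e-3 * expected:
            raise InputError(
                f"kBT_pN_nm={self.kBT_pN_nm} inconsistent with "
                f"temperature_K={self.temperature_K} (expected {expected:.4f})"
            )

    def with_(self, **changes) -> "PolymerParams":
        """Return a copy with ``changes`` applied (kBT re-derived if only
        the temperature changes)."""
        if "temperature_K" in changes and "kBT_pN_nm" not in changes:
            changes["kBT_pN_nm"] = None
        return replace(self, **changes)


@dataclass(frozen=True)
class TetherGeometry:
    """Composition of the tether construct."""

    ds_bp_total: int = 6600
    flap_nt: int = 40
    handle_contribution_nm: float = 0.0

    def __post_init__(self) -> None:
        if self.ds_bp_total <= 0:
            raise InputError(f"ds_bp_total must be positive, got {self.ds_bp_total}")
        if self.flap_nt < 0:
            raise InputError(f"flap_nt must be non-negative, got {self.flap_nt}")


def _validate_force(force_pN: float) -> float:
    force = float(force_pN)
    if not np.isfinite(force) or force < 0:
        raise InputError(f"force must be finite and non-negative, got {force_pN!r}")
    return force


def ds_relative_extension(force_pN: float, params: PolymerParams) -> float:
    """Relative extension x/L of dsDNA at a given force.

    Solves the Marko-Siggia interpolation
    ``F = kBT/P * [1/(4(1-r)^2) - 1/4 + r]`` for ``r`` by bracketed
    root finding on ``r in [0, 1)``.
    """
    force = _validate_force(force_pN)
    if force == 0.0:
        return 0.0
    scale = params.kBT_pN_nm / params.ds_persistence_nm

    def residual(r: float) -> float:
        return scale * (1.0 / (4.0 * (1.0 - r) ** 2) - 0.25 + r) - force

    return brentq(residual, 0.0, 1.0 - 1e-9, xtol=1e-12, rtol=8.9e-16)


def ss_relative_extension(force_pN: float, params: PolymerParams) -> float:
    """Relative extension of ssDNA via the freely-jointed chain.

    ``r = coth(x) - 1/x`` with ``x = F b / kBT`` (Langevin function),
    continuously extended to 0 at zero force.
    """
    force = _validate_force(force_pN)
    x = force * params.ss_kuhn_nm / params.kBT_pN_nm
    if x < 1e-4:
        # series: L(x) = x/3 - x^3/45 + O(x^5); avoids coth cancellation
        return x / 3.0 - x**3 / 45.0
    return 1.0 / np.tanh(x) - 1.0 / x


def bp_step_signal_nm(force_pN: float, params: PolymerParams) -> float:
    """Extension change per base pair unwound, at constant force.

    One bp unwound removes one bp of dsDNA from the tether and adds
    ``nt_gained_per_bp`` nucleotides of ssDNA. May be negative at low
    force where ssDNA is more compact than dsDNA.
    """
    ss = params.nt_gained_per_bp * params.ss_contour_nm_per_nt * ss_relative_extension(
        force_pN, params
    )
    ds = params.ds_rise_nm_per_bp * ds_relative_extension(force_pN, params)
    return ss - ds


def extension_to_unwound_bp(traj, params: PolymerParams, baseline_nm: float,
                            min_abs_step_nm: float = 1e-4):
    """Convert a bead trajectory into base pairs unwound.

    ``n(t) = (z(t) - baseline_nm) / delta(F)`` with ``delta`` the per-bp
    extension signal at the trajectory's recorded force.  Raises
    :class:`DegenerateForceError` when ``|delta|`` is below
    ``min_abs_step_nm`` (unwinding then produces no measurable signal).
    """
    from .trace import UnwindingTrace  # local import to avoid cycle

    delta = bp_step_signal_nm(traj.force_pN, params)
    if abs(delta) < min_abs_step_nm:
        raise DegenerateForceError(
            f"per-bp extension signal {delta:.3g} nm at {traj.force_pN} pN is "
            f"below {min_abs_step_nm} nm; unwinding is unobservable"
        )
    unwound = (np.asarray(traj.extension_nm, dtype=float) - baseline_nm) / delta
    return UnwindingTrace(
        time_s=np.asarray(traj.time_s, dtype=float),
        unwound_bp=unwound,
        force_pN=traj.force_pN,
    )


def unwound_bp_to_extension(unwound_bp, force_pN: float, params: PolymerParams,
                            baseline_nm: float):
    """Forward model: extension from base pairs unwound (inverse of
    :func:`extension_to_unwound_bp`)."""
    delta = bp_step_signal_nm(force_pN, params)
    return baseline_nm + np.asarray(unwound_bp, dtype=float) * delta
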