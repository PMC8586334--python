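"""File formats, run configuration, and deterministic JSON output.

Trajectories travel as headered TSV (``time_s``, ``extension_nm``,
optional ``transverse_nm``), tabular assay data as headered CSV, run
configuration as TOML validated against a strict schema, and results as
JSON with floats fixed to 12 significant digits so identical runs are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import tomllib
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError, ParseError
from .massphot import MassEventSet
from .quantify import BindingCurve
from .simulate import SimConfig
from .tether import PolymerParams, TetherGeometry
from .trace import AnalysisConfig, BeadTrajectory

__all__ = [
    "read_trajectory",
    "write_trajectory",
    "read_mass_events",
    "write_mass_events",
    "read_standards",
    "write_standards",
    "read_binding_curve",
    "write_binding_curve",
    "read_timecourse",
    "write_timecourse",
    "read_lanes",
    "RunConfig",
    "load_config",
    "dumps_stable",
    "dump_json",
    "config_hash",
]

_TRAJ_REQUIRED = ("time_s", "extension_nm")
_TRAJ_OPTIONAL = ("transverse_nm",)


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _locate_bad_row(path: Path, sep: str, n_cols: int) -> Optional[int]:
    """Best-effort scan for the first malformed data row (1-based line)."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno == 1 or not line.strip():
                continue
            parts = line.rstrip("\n").split(sep)
            if len(parts) != n_cols:
                return lineno
            for part in parts:
                try:
                    float(part)
                except ValueError:
                    return lineno
    return None


def read_trajectory(path, force_pN: float = math.nan,
                    frame_rate_hz: Optional[float] = None,
                    label: str = "") -> BeadTrajectory:
    """Read a bead trajectory from headered TSV/CSV.

    The force is per-condition metadata (from the manifest or caller),
    not a file column.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    for col in _TRAJ_REQUIRED:
        if col not in header:
            raise ParseError(f"missing required column {col!r} in {path}", line=1)
    unknown = [c for c in header if c not in _TRAJ_REQUIRED + _TRAJ_OPTIONAL]
    if unknown:
        raise ParseError(f"unknown trajectory columns {unknown} in {path}", line=1)
    try:
        df = pd.read_csv(path, sep=sep, dtype=float, float_precision="round_trip")
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(
            f"malformed trajectory file {path}: {exc}",
            line=_locate_bad_row(path, sep, len(header)),
        ) from exc
    if frame_rate_hz is None:
        dt = np.diff(df["time_s"].to_numpy())
        frame_rate_hz = 1.0 / float(np.median(dt)) if dt.size else 30.0
    return BeadTrajectory(
        time_s=df["time_s"].to_numpy(),
        extension_nm=df["extension_nm"].to_numpy(),
        transverse_nm=df["transverse_nm"].to_numpy() if "transverse_nm" in df else None,
        force_pN=force_pN,
        frame_rate_hz=frame_rate_hz,
        label=label or path.stem,
    )


def write_trajectory(traj: BeadTrajectory, path) -> None:
    """Write a trajectory losslessly (17 significant digits)."""
    path = Path(path)
    sep = _sep_for(path)
    cols = {"time_s": traj.time_s, "extension_nm": traj.extension_nm}
    if traj.transverse_nm is not None:
        cols["transverse_nm"] = traj.transverse_nm
    with open(path, "w") as fh:
        fh.write(sep.join(cols) + "\n")
        arrays = list(cols.values())
        for row in zip(*arrays):
            fh.write(sep.join(f"{v:.17g}" for v in row) + "\n")


def read_mass_events(path, condition: str = "") -> MassEventSet:
    df = _read_table(path, required=("contrast",), optional=("mass_kDa",))
    return MassEventSet(
        contrasts=df["contrast"].to_numpy(),
        masses_kDa=df["mass_kDa"].to_numpy() if "mass_kDa" in df else None,
        condition=condition or Path(path).stem,
    )


def write_mass_events(events: MassEventSet, path) -> None:
    cols = {"contrast": events.contrasts}
    if events.masses_kDa is not None:
        cols["mass_kDa"] = events.masses_kDa
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def read_standards(path) -> dict:
    """Standards CSV ``contrast,standard_mass_kDa`` -> {mass: contrasts}."""
    df = _read_table(path, required=("contrast", "standard_mass_kDa"))
    return {
        float(mass): grp["contrast"].to_numpy()
        for mass, grp in df.groupby("standard_mass_kDa")
    }


def write_standards(standards: dict, path) -> None:
    rows = [
        {"contrast": c, "standard_mass_kDa": mass}
        for mass, contrasts in sorted(standards.items())
        for c in np.asarray(contrasts, float)
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_binding_curve(path) -> BindingCurve:
    df = _read_table(path, required=("concentration_nM", "fraction"),
                     optional=("sem",))
    return BindingCurve(
        concentrations_nM=df["concentration_nM"].to_numpy(),
        fraction=df["fraction"].to_numpy(),
        replicate_sem=df["sem"].to_numpy() if "sem" in df else None,
    )


def write_binding_curve(curve: BindingCurve, path) -> None:
    cols = {
        "concentration_nM": curve.concentrations_nM,
        "fraction": curve.fraction,
    }
    if curve.replicate_sem is not None:
        cols["sem"] = curve.replicate_sem
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def read_timecourse(path):
    """ATPase CSV ``time_s,absorbance`` -> (time, absorbance) arrays."""
    df = _read_table(path, required=("time_s", "absorbance"))
    return df["time_s"].to_numpy(), df["absorbance"].to_numpy()


def write_timecourse(time_s, absorbance, path) -> None:
    pd.DataFrame({"time_s": time_s, "absorbance": absorbance}).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_lanes(path):
    """Gel CSV ``lane,band,intensity`` -> {lane: {band: intensity}}."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    df = pd.read_csv(path)
    for col in ("lane", "band", "intensity"):
        if col not in df.columns:
            raise ParseError(f"missing required column {col!r} in {path}", line=1)
    lanes: dict = {}
    for _, row in df.iterrows():
        lanes.setdefault(str(row["lane"]), {})[str(row["band"])] = float(row["intensity"])
    return lanes


def _read_table(path, required, optional=()):
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    for col in required:
        if col not in header:
            raise ParseError(f"missing required column {col!r} in {path}", line=1)
    unknown = [c for c in header if c not in tuple(required) + tuple(optional)]
    if unknown:
        raise ParseError(f"unknown columns {unknown} in {path}", line=1)
    try:
        return pd.read_csv(path, sep=sep, dtype=float, float_precision="round_trip")
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(
            f"malformed file {path}: {exc}",
            line=_locate_bad_row(path, sep, len(header)),
        ) from exc


# ---------------------------------------------------------------------------
# run configuration


@dataclasses.dataclass
class RunConfig:
    """Validated top-level run configuration."""

    seed: int = 0
    out_dir: str = "out"
    log_level: str = "INFO"
    baseline_nm: Optional[float] = None
    simulate: Optional[SimConfig] = None
    analysis: AnalysisConfig = dataclasses.field(default_factory=AnalysisConfig)
    polymer: PolymerParams = dataclasses.field(default_factory=PolymerParams)
    geometry: TetherGeometry = dataclasses.field(default_factory=TetherGeometry)
    mass_components: dict = dataclasses.field(default_factory=dict)
    mass_tolerance_kDa: Optional[float] = None


_TOP_KEYS = {"seed", "out_dir", "log_level", "baseline_nm",
             "simulate", "analysis", "polymer", "geometry", "mass"}
_MASS_KEYS = {"components", "tolerance_kDa"}


def _build_dataclass(cls, section: dict, name: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in [{name}]: {sorted(unknown)}")
    try:
        return cls(**section)
    except (TypeError, InputError) as exc:
        raise ConfigError(f"invalid [{name}] section: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load and validate a TOML run configuration; unknown keys reject."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")

    polymer = _build_dataclass(PolymerParams, raw.get("polymer", {}), "polymer")
    geometry = _build_dataclass(TetherGeometry, raw.get("geometry", {}), "geometry")
    analysis = _build_dataclass(AnalysisConfig, raw.get("analysis", {}), "analysis")

    simulate = None
    if "simulate" in raw:
        section = dict(raw["simulate"])
        section.setdefault("seed", raw.get("seed", 0))
        section["polymer"] = polymer
        section["geometry"] = geometry
        simulate = _build_dataclass(SimConfig, section, "simulate")

    mass = raw.get("mass", {})
    unknown = set(mass) - _MASS_KEYS
    if unknown:
        raise ConfigError(f"unknown keys in [mass]: {sorted(unknown)}")
    components = {str(k): float(v) for k, v in mass.get("components", {}).items()}

    cfg = RunConfig(
        seed=int(raw.get("seed", 0)),
        out_dir=str(raw.get("out_dir", "out")),
        log_level=str(raw.get("log_level", "INFO")),
        baseline_nm=raw.get("baseline_nm"),
        simulate=simulate,
        analysis=analysis,
        polymer=polymer,
        geometry=geometry,
        mass_components=components,
        mass_tolerance_kDa=mass.get("tolerance_kDa"),
    )
    return cfg


# ---------------------------------------------------------------------------
# deterministic JSON


def _stable(obj: Any) -> str:
    if obj is None:
        return "null"
    if obj is True:
        return "true"
    if obj is False:
        return "false"
    if isinstance(obj, (int, np.integer)):
        return str(int(obj))
    if isinstance(obj, (float, np.floating)):
        x = float(obj)
        if math.isnan(x):
            return "null"
        if math.isinf(x):
            return '"Infinity"' if x > 0 else '"-Infinity"'
        return f"{x:.12g}"
    if isinstance(obj, str):
        return json.dumps(obj)
    if isinstance(obj, np.ndarray):
        return _stable(obj.tolist())
    if isinstance(obj, (list, tuple)):
        return "[" + ", ".join(_stable(v) for v in obj) + "]"
    if isinstance(obj, dict):
        items = sorted(obj.items(), key=lambda kv: str(kv[0]))
        return "{" + ", ".join(
            f"{json.dumps(str(k))}: {_stable(v)}" for k, v in items
        ) + "}"
    if dataclasses.is_dataclass(obj):
        return _stable(dataclasses.asdict(obj))
    raise TypeError(f"cannot serialize {type(obj)!r}")


def dumps_stable(obj: Any) -> str:
    """JSON with sorted keys and floats at 12 significant digits, so the
    same data always yields identical bytes."""
    return _stable(obj) + "\n"


def dump_json(obj: Any, path) -> None:
    Path(path).write_text(dumps_stable(obj))


def config_hash(obj: Any) -> str:
    """SHA-256 of the stable JSON rendering of a config-like object."""
    return hashlib.sha256(dumps_stable(obj).encode()).hexdigest()
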