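"""Data model and CSV input/output for the signal-disruption assay.

The assay exposes reporter cells to a chemical at -1 h, stimulates with
bFGF at 0 h and monitors live-cell luminescence over 0-24 h.  Three well
roles exist on a plate:

* ``background``   -- vehicle only, no bFGF (background luminescence),
* ``vehicle_bfgf`` -- vehicle plus bFGF (the fold-change reference),
* ``chemical_bfgf`` -- chemical plus bFGF at one concentration.

All tables are plain comma-separated UTF-8 files with a mandatory header,
'.' decimal separator and times in hours.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, SchemaError, GridError

logger = logging.getLogger(__name__)

#: Reserved chemical name for vehicle-treated wells.
VEHICLE = "VEHICLE"

ROLE_BACKGROUND = "background"
ROLE_VEHICLE_BFGF = "vehicle_bfgf"
ROLE_CHEMICAL_BFGF = "chemical_bfgf"
ROLES = (ROLE_BACKGROUND, ROLE_VEHICLE_BFGF, ROLE_CHEMICAL_BFGF)

PLATE_COLUMNS = [
    "plate_id",
    "well",
    "time_h",
    "chemical",
    "concentration_ug_ml",
    "role",
    "replicate",
    "luminescence",
]

VIABILITY_COLUMNS = [
    "chemical",
    "concentration_ug_ml",
    "replicate",
    "abs_sample",
    "abs_blank",
    "abs_vehicle",
]

VALIDATION_COLUMNS = ["chemical", "abbreviation", "sum_abc", "animal_label", "limb_flag"]


@dataclass(frozen=True)
class RunConfig:
    """Analysis configuration.

    Parameters
    ----------
    spline_df
        Effective degrees of freedom of the smoothing splines fitted to
        log fold-change time courses (trace of the smoother matrix).
    eval_grid_step_h
        Step of the spline evaluation grid on which the area between
        curves is accumulated, in hours.
    window
        Analysis window in hours; the monitored interval after bFGF
        stimulation.
    log_base
        Base of the fold-change logarithm: ``"natural"``, ``"2"`` or
        ``"10"``.  Changing the base rescales every ABC value by a
        constant.
    epsilon_ratio_floor
        Additive floor applied to min-max-scaled values before taking
        the chemical/vehicle ratio, in units of the scaled range.  The
        scaled minimum maps to 0, so an unguarded ratio can blow up.
    n_replicates
        Replicate wells per condition.
    rng_seed
        Seed for the synthetic-data generator.
    jt_alpha
        One-sided significance level of the Jonckheere-Terpstra
        concentration-trend test.
    hedges_g_min_effect
        Minimum Hedges' g (score distribution vs. the classification
        threshold) regarded as a meaningful effect.
    control_curve
        ``"fitted"`` fits the control spline to vehicle-replicate log
        fold changes (near zero but not identically zero); ``"zero"``
        uses the flat zero line instead.
    """

    spline_df: float = 6.0
    eval_grid_step_h: float = 0.5
    window: tuple[float, float] = (0.0, 24.0)
    log_base: str = "natural"
    epsilon_ratio_floor: float = 1e-3
    n_replicates: int = 3
    rng_seed: int = 0
    jt_alpha: float = 0.001
    hedges_g_min_effect: float = 0.2
    control_curve: str = "fitted"

    def __post_init__(self) -> None:
        if self.spline_df < 2:
            raise ParameterError(f"spline_df must be >= 2, got {self.spline_df}")
        if self.log_base not in ("natural", "2", "10"):
            raise ParameterError(f"log_base must be 'natural', '2' or '10', got {self.log_base!r}")
        lo, hi = self.window
        if not hi > lo:
            raise ParameterError(f"window must be increasing, got {self.window}")
        span = hi - lo
        n_steps = span / self.eval_grid_step_h
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ParameterError(
                f"eval_grid_step_h={self.eval_grid_step_h} does not divide the window {self.window}"
            )
        if self.n_replicates < 1:
            raise ParameterError("n_replicates must be >= 1")
        if self.control_curve not in ("fitted", "zero"):
            raise ParameterError("control_curve must be 'fitted' or 'zero'")

    @property
    def log_divisor(self) -> float:
        """Divide natural log by this to obtain the configured base."""
        return {"natural": 1.0, "2": math.log(2.0), "10": math.log(10.0)}[self.log_base]

    @property
    def eval_grid(self) -> np.ndarray:
        lo, hi = self.window
        n = int(round((hi - lo) / self.eval_grid_step_h))
        return lo + self.eval_grid_step_h * np.arange(n + 1)

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "window":
                v = f"{v[0]},{v[1]}"
            lines.append(f"{f.name}={v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kv: dict[str, object] = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise SchemaError(f"config line not in key=value form: {line!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            kv[key] = value
        casts = {
            "spline_df": float,
            "eval_grid_step_h": float,
            "epsilon_ratio_floor": float,
            "jt_alpha": float,
            "hedges_g_min_effect": float,
            "n_replicates": int,
            "rng_seed": int,
        }
        parsed: dict[str, object] = {}
        valid = {f.name for f in fields(cls)}
        for key, value in kv.items():
            if key not in valid:
                raise SchemaError(f"unknown config key {key!r}")
            if key == "window":
                lo, hi = (float(x) for x in str(value).split(","))
                parsed[key] = (lo, hi)
            elif key in casts:
                parsed[key] = casts[key](value)  # type: ignore[operator]
            else:
                parsed[key] = value
        return cls(**parsed)  # type: ignore[arg-type]


@dataclass(frozen=True)
class StudyDesign:
    """Exposure design for one chemical.

    ``concentration_series`` is a descending serial dilution, all values
    at or below ``max_concentration`` (itself either the IC50 or the
    solubility cap, see :mod:`abcscreen.doseresponse`).
    """

    chemical: str
    vehicle: str = "PBS"  # PBS or DMSO
    max_concentration: float = 100.0
    animal_label: str | None = None  # P / N from animal studies
    limb_flag: bool = False
    concentration_series: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.chemical.upper() == VEHICLE:
            raise ParameterError(f"{self.chemical!r} clashes with the reserved vehicle sentinel")
        if self.vehicle not in ("PBS", "DMSO"):
            raise ParameterError(f"vehicle must be PBS or DMSO, got {self.vehicle!r}")
        if self.max_concentration <= 0:
            raise ParameterError("max_concentration must be positive")
        series = self.concentration_series or serial_dilution(self.max_concentration)
        object.__setattr__(self, "concentration_series", tuple(series))
        arr = np.asarray(self.concentration_series, dtype=float)
        if arr.size == 0:
            raise ParameterError("concentration_series must be nonempty")
        if np.any(arr <= 0):
            raise ParameterError("concentrations must be positive")
        if np.any(np.diff(arr) >= 0):
            raise ParameterError("concentration_series must be strictly descending")
        if arr[0] > self.max_concentration * (1 + 1e-12):
            raise ParameterError("concentrations exceed max_concentration")


def serial_dilution(max_concentration: float, n: int = 5, factor: float = 2.0) -> tuple[float, ...]:
    """Descending ``n``-point serial dilution starting at ``max_concentration``."""
    return tuple(max_concentration / factor**k for k in range(n))


@dataclass(frozen=True)
class ViabilityRecord:
    """One endpoint absorbance read of the cell-viability assay."""

    chemical: str
    concentration: float
    abs_sample: float
    abs_blank: float
    abs_vehicle: float
    replicate: int = 1


class PlateTimeSeries:
    """Validated collection of plate-reader luminescence reads.

    Wraps a long-format :class:`pandas.DataFrame` with the columns of
    ``PLATE_COLUMNS``; rows are grouped by (chemical, concentration,
    replicate, role) and all wells of one plate share a common time grid.
    """

    def __init__(self, df: pd.DataFrame):
        self.df = _validate_plate_df(df)

    @property
    def time_grid(self) -> np.ndarray:
        return np.unique(self.df["time_h"].to_numpy(dtype=float))

    @property
    def chemicals(self) -> list[str]:
        chems = self.df.loc[self.df["role"] == ROLE_CHEMICAL_BFGF, "chemical"]
        return sorted(chems.unique())

    @property
    def n_records(self) -> int:
        return len(self.df)

    def conditions(self) -> pd.DataFrame:
        """Distinct (chemical, concentration, replicate, role) combinations."""
        cols = ["chemical", "concentration_ug_ml", "replicate", "role"]
        return self.df[cols].drop_duplicates().reset_index(drop=True)

    def subset(self, chemicals: Iterable[str]) -> "PlateTimeSeries":
        """Plate restricted to the given chemicals plus all control wells."""
        keep = set(chemicals)
        mask = self.df["chemical"].isin(keep) | (self.df["role"] != ROLE_CHEMICAL_BFGF)
        return PlateTimeSeries(self.df.loc[mask].reset_index(drop=True))

    def __repr__(self) -> str:  # pragma: no cover
        grid = self.time_grid
        return (
            f"PlateTimeSeries({self.n_records} records, {len(self.chemicals)} chemicals, "
            f"grid [{grid.min():g}..{grid.max():g}] h)"
        )


def _validate_plate_df(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"plate table is missing columns: {missing}")
    df = df[PLATE_COLUMNS].copy()
    if df.empty:
        logger.warning("plate table is empty (header only)")
        return df
    for col in ("time_h", "concentration_ug_ml", "luminescence"):
        df[col] = pd.to_numeric(df[col])
    df["replicate"] = df["replicate"].astype(int)

    bad_role = ~df["role"].isin(ROLES)
    if bad_role.any():
        raise SchemaError(f"unknown role values: {sorted(df.loc[bad_role, 'role'].unique())}")
    nonpos = df["luminescence"] <= 0
    if nonpos.any():
        row = int(df.index[nonpos][0])
        raise ValueError(f"non-positive luminescence at row {row}: {df.loc[row, 'luminescence']}")
    if (df["time_h"] < -1).any():
        raise ValueError("time_h below -1 h (exposure time) is not part of the design")
    if (df["concentration_ug_ml"] < 0).any():
        raise ValueError("negative concentration")
    if (df["replicate"] < 1).any():
        raise ValueError("replicate indices must be positive")

    ctrl = df["role"].isin((ROLE_BACKGROUND, ROLE_VEHICLE_BFGF))
    if (df.loc[ctrl, "concentration_ug_ml"] != 0).any():
        raise ValueError("control wells must have concentration 0")
    if (df.loc[ctrl, "chemical"] != VEHICLE).any():
        raise ValueError(f"control wells must carry the chemical sentinel {VEHICLE!r}")
    fake_vehicle = (~ctrl) & (df["chemical"].str.upper() == VEHICLE)
    if fake_vehicle.any():
        raise ValueError(f"{VEHICLE!r} (any case) is reserved for control wells")

    # shared time grid within each plate: every well sees the same times
    for plate_id, sub in df.groupby("plate_id"):
        grids = sub.groupby("well")["time_h"].apply(lambda s: tuple(sorted(s)))
        if grids.nunique() > 1:
            raise GridError(f"plate {plate_id!r}: wells have ragged time grids")
    return df.sort_values(["plate_id", "chemical", "concentration_ug_ml", "replicate", "time_h"]).reset_index(
        drop=True
    )


def read_plate_csv(path: str | Path) -> PlateTimeSeries:
    """Read a plate luminescence CSV into a validated :class:`PlateTimeSeries`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: file has no header") from exc
    plate = PlateTimeSeries(df)
    logger.info("read %d plate records from %s", plate.n_records, path)
    return plate


def write_plate_csv(plate: PlateTimeSeries, path: str | Path) -> None:
    plate.df.to_csv(path, index=False)


def read_viability_csv(path: str | Path) -> pd.DataFrame:
    """Read endpoint viability absorbance reads (long format)."""
    df = pd.read_csv(path)
    missing = [c for c in VIABILITY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"viability table is missing columns: {missing}")
    return df[VIABILITY_COLUMNS].copy()


def write_viability_csv(records: Sequence[ViabilityRecord] | pd.DataFrame, path: str | Path) -> None:
    df = viability_frame(records) if not isinstance(records, pd.DataFrame) else records
    df.to_csv(path, index=False)


def viability_frame(records: Sequence[ViabilityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chemical": [r.chemical for r in records],
            "concentration_ug_ml": [r.concentration for r in records],
            "replicate": [r.replicate for r in records],
            "abs_sample": [r.abs_sample for r in records],
            "abs_blank": [r.abs_blank for r in records],
            "abs_vehicle": [r.abs_vehicle for r in records],
        }
    )


def read_validation_table(path: str | Path | None = None) -> pd.DataFrame:
    """Read the bundled (or an external) chemical validation table.

    The packaged table lists the 18 ECVAM reference chemicals with their
    published sum-of-ABC score, the P/N developmental-toxicity label from
    animal studies and a flag for limb/digit malformation toxicants.
    """
    if path is None:
        src = resources.files("abcscreen.data").joinpath("ecvam_table2.csv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    missing = [c for c in VALIDATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"validation table is missing columns: {missing}")
    dup = df["chemical"].duplicated() | df["abbreviation"].duplicated()
    if dup.any():
        raise SchemaError(f"duplicate chemical entries: {sorted(df.loc[dup, 'chemical'])}")
    bad = ~df["animal_label"].isin(("P", "N"))
    if bad.any():
        raise SchemaError("animal_label must be P or N")
    df = df[VALIDATION_COLUMNS].copy()
    df["sum_abc"] = df["sum_abc"].astype(float)
    df["limb_flag"] = df["limb_flag"].astype(bool)
    return df


__all__ = [
    "PLATE_COLUMNS",
    "VIABILITY_COLUMNS",
    "VALIDATION_COLUMNS",
    "VEHICLE",
    "ROLE_BACKGROUND",
    "ROLE_VEHICLE_BFGF",
    "ROLE_CHEMICAL_BFGF",
    "RunConfig",
    "StudyDesign",
    "ViabilityRecord",
    "PlateTimeSeries",
    "serial_dilution",
    "read_plate_csv",
    "write_plate_csv",
    "read_viability_csv",
    "write_viability_csv",
    "viability_frame",
    "read_validation_table",
]
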