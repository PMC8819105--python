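"""Raw luminescence to vehicle-normalized log fold change, and viability.

Normalization chain for one experiment (plate): raw reads are divided by
the mean background (vehicle, no bFGF) signal at the same time point to
give relative light units (RLU); RLU are min-max scaled over the whole
experiment pooled (all wells, replicates and times) so experiments share
a common [0, 1] scale; each chemical series is then divided by the mean
scaled vehicle+bFGF series at the same time point and log-transformed.
A small additive floor guards the ratio because the scaled minimum maps
exactly to 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateScaleError, DenominatorError, GridError
from .io import (
    ROLE_BACKGROUND,
    ROLE_CHEMICAL_BFGF,
    ROLE_VEHICLE_BFGF,
    PlateTimeSeries,
    RunConfig,
    ViabilityRecord,
)

__all__ = [
    "compute_rlu",
    "min_max_scale",
    "fold_change",
    "normalize_plate",
    "cell_viability",
    "viability_fractions",
    "NormalizationMeta",
]


@dataclass(frozen=True)
class NormalizationMeta:
    """Provenance of one plate normalization (recorded in outputs)."""

    x_min: float
    x_max: float
    epsilon: float
    log_base: str


def compute_rlu(plate: PlateTimeSeries) -> pd.DataFrame:
    """Relative light units: reads divided by the background mean per time point.

    Returns the plate table with an ``rlu`` column, background wells
    included (their RLU hovers around 1).
    """
    df = plate.df
    bg = df[df["role"] == ROLE_BACKGROUND]
    if bg.empty:
        raise DenominatorError("plate has no background wells")
    bg_mean = bg.groupby("time_h")["luminescence"].mean()
    times = df["time_h"].unique()
    missing = set(times) - set(bg_mean.index)
    if missing:
        raise DenominatorError(f"no background reads at time points {sorted(missing)}")
    if (bg_mean <= 0).any():
        raise DenominatorError("background mean luminescence is zero or negative")
    out = df.copy()
    out["rlu"] = out["luminescence"].to_numpy() / bg_mean.reindex(out["time_h"]).to_numpy()
    return out


def min_max_scale(values: np.ndarray | pd.Series) -> np.ndarray:
    """Min-max scaling ``(x - x_min) / (x_max - x_min)`` over the pooled values."""
    x = np.asarray(values, dtype=float)
    x_min, x_max = float(np.min(x)), float(np.max(x))
    if x_max == x_min:
        raise DegenerateScaleError("all values equal; min-max scale undefined")
    return (x - x_min) / (x_max - x_min)


def fold_change(
    rlu_scaled: pd.DataFrame,
    config: RunConfig,
) -> pd.DataFrame:
    """Per-series fold change against the mean scaled vehicle+bFGF signal.

    ``fc(t) = (s(t) + eps) / (mean s_vehicle(t) + eps)`` with the
    configured floor ``eps``; ``log_fc`` is in the configured base.
    Chemical series and the individual vehicle replicates (used for the
    control spline) are both returned; background wells are dropped.
    """
    eps = config.epsilon_ratio_floor
    veh = rlu_scaled[rlu_scaled["role"] == ROLE_VEHICLE_BFGF]
    if veh.empty:
        raise GridError("no vehicle+bFGF wells to normalize against")
    veh_mean = veh.groupby("time_h")["scaled"].mean()

    keep = rlu_scaled["role"].isin((ROLE_CHEMICAL_BFGF, ROLE_VEHICLE_BFGF))
    out = rlu_scaled.loc[keep].copy()
    missing = set(out["time_h"].unique()) - set(veh_mean.index)
    if missing:
        raise GridError(f"vehicle reference missing at time points {sorted(missing)}")
    ref = veh_mean.reindex(out["time_h"]).to_numpy()
    fc = (out["scaled"].to_numpy() + eps) / (ref + eps)
    if np.any(fc <= 0) or not np.all(np.isfinite(fc)):
        raise DegenerateScaleError("fold change non-positive or non-finite; raise epsilon_ratio_floor")
    out["fold_change"] = fc
    out["log_fc"] = np.log(fc) / config.log_divisor
    return out


def normalize_plate(plate: PlateTimeSeries, config: RunConfig) -> tuple[pd.DataFrame, NormalizationMeta]:
    """Full normalization of one experiment within the analysis window.

    Returns the long fold-change table (chemical wells plus vehicle
    replicates) and the scaling metadata.
    """
    lo, hi = config.window
    rlu = compute_rlu(plate)
    rlu = rlu[(rlu["time_h"] >= lo) & (rlu["time_h"] <= hi)].reset_index(drop=True)
    pooled = rlu["rlu"].to_numpy()
    rlu["scaled"] = min_max_scale(pooled)
    meta = NormalizationMeta(
        x_min=float(pooled.min()),
        x_max=float(pooled.max()),
        epsilon=config.epsilon_ratio_floor,
        log_base=config.log_base,
    )
    return fold_change(rlu, config), meta


def cell_viability(record: ViabilityRecord) -> float:
    """Viability fraction ``(Abs_sample - Abs_blank) / (Abs_vehicle - Abs_blank)``.

    May exceed 1 (wells outgrowing the vehicle control); values are not
    clipped.
    """
    denom = record.abs_vehicle - record.abs_blank
    if denom <= 0:
        raise DenominatorError(
            f"abs_vehicle ({record.abs_vehicle}) must exceed abs_blank ({record.abs_blank})"
        )
    return (record.abs_sample - record.abs_blank) / denom


def viability_fractions(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized viability over a viability table (see io.VIABILITY_COLUMNS)."""
    denom = df["abs_vehicle"] - df["abs_blank"]
    if (denom <= 0).any():
        bad = df.index[denom <= 0][0]
        raise DenominatorError(f"abs_vehicle <= abs_blank at row {bad}")
    out = df.copy()
    out["viability"] = (df["abs_sample"] - df["abs_blank"]) / denom
    return out
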