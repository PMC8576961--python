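"""The HEPE indicator: population-share weights, hourly fields, decomposition.

HEPE (hourly exceedance PM2.5 exposure) at grid cell i is

    HEPE_i = share_i × EP_i

where EP_i is the exceedance concentration (µg/m³ above the guideline) and
share_i is the cell's normalized population share: raster values are min-max
normalized to [0, 1] and then divided by their sum, so Σ share_i = 1. The
normalization makes the two population sources — hourly social-media density
(sm) and the modelled older-adult raster (psd) — dimensionally comparable,
and makes HEPE invariant under positive rescaling of either raster. HEPE is
therefore a *relative* exposure-risk surface (share × µg/m³), not a head
count.

The contribution field decomposes the total risk HEPE_sm + HEPE_psd into the
percentage carried by one source at each cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceedance import ExceedanceField
from .grid import GridSpec, PopulationRaster

EQUAL_SHARE_TOL = 1e-12


@dataclass
class HepeField:
    """Per-cell HEPE (share × µg/m³) for one source and hour."""

    grid: GridSpec
    values: np.ndarray
    source_tag: str
    hour: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("HEPE values must be finite and >= 0")

    @property
    def total(self) -> float:
        return float(self.values.sum())


@dataclass
class ContributionField:
    """Percentage share of one source in the total HEPE; NaN where total is 0."""

    grid: GridSpec
    pct: np.ndarray
    hour: int

    def __post_init__(self) -> None:
        self.pct = np.asarray(self.pct, dtype=float)
        if self.pct.shape != self.grid.shape:
            raise ValueError("pct shape does not match grid")
        defined = np.isfinite(self.pct)
        if np.any(self.pct[defined] < -1e-9) or np.any(self.pct[defined] > 100 + 1e-9):
            raise ValueError("defined contributions must lie in [0, 100]")

    @property
    def defined_mask(self) -> np.ndarray:
        return np.isfinite(self.pct)


def normalize_population(pop: PopulationRaster) -> np.ndarray:
    """Two-step normalization to population shares summing to 1.

    Step 1: min-max normalize values to [0, 1]; step 2: divide by the sum.
    A constant raster (max == min) degenerates to equal shares 1/n.
    """
    v = pop.values
    if not np.any(v > 0):
        raise ValueError("population raster is all zero; shares undefined")
    mn, mx = float(v.min()), float(v.max())
    if mx - mn <= EQUAL_SHARE_TOL * max(mx, 1.0):
        return np.full(v.shape, 1.0 / v.size)
    n = (v - mn) / (mx - mn)
    return n / n.sum()


def compute_hepe(weights: np.ndarray, ep: ExceedanceField, source_tag: str) -> HepeField:
    """HEPE_i = share_i × EP_i on the shared analysis grid."""
    weights = np.asarray(weights, dtype=float)
    if weights.shape != ep.grid.shape:
        raise ValueError("weights and exceedance field are on different grids")
    if abs(weights.sum() - 1.0) > 1e-6:
        raise ValueError("weights must sum to 1")
    return HepeField(grid=ep.grid, values=weights * ep.ep, source_tag=source_tag, hour=ep.hour)


def daily_accumulate(fields: Sequence[HepeField]) -> HepeField:
    """Cell-wise sum of hourly HEPE fields of one source over the day."""
    if not fields:
        raise ValueError("no fields to accumulate")
    tags = {f.source_tag for f in fields}
    if len(tags) > 1:
        raise ValueError(f"cannot accumulate mixed sources {tags}")
    grid = fields[0].grid
    if any(f.grid != grid for f in fields):
        raise ValueError("fields are on different grids")
    acc = np.sum([f.values for f in fields], axis=0)
    return HepeField(grid=grid, values=acc, source_tag=fields[0].source_tag, hour=-1)


def find_peak_hours(hours: Sequence[int], means: Sequence[float]) -> list[int]:
    """Hours whose mean strictly exceeds both neighbors (endpoints: the one)."""
    hours = list(hours)
    m = np.asarray(means, dtype=float)
    peaks = []
    for i, h in enumerate(hours):
        left_ok = i == 0 or m[i] > m[i - 1]
        right_ok = i == len(hours) - 1 or m[i] > m[i + 1]
        if left_ok and right_ok and len(hours) > 1:
            peaks.append(h)
    return peaks


def temporal_profile(fields: Sequence[HepeField]) -> pd.DataFrame:
    """Per-hour spatial mean and peak of a HEPE source; peak hours in attrs."""
    if not fields:
        raise ValueError("no fields given")
    rows = [
        {"hour": f.hour, "mean": float(f.values.mean()), "peak": float(f.values.max())}
        for f in sorted(fields, key=lambda f: f.hour)
    ]
    df = pd.DataFrame(rows)
    df.attrs["peak_hours"] = find_peak_hours(df["hour"].tolist(), df["mean"].to_numpy())
    return df


def contribution(psd: HepeField, sm: HepeField) -> ContributionField:
    """Percentage of the total HEPE (psd + sm) carried by psd at each cell.

    Undefined (NaN) exactly where both fields are zero; pure-psd cells read
    100% and pure-sm cells 0%.
    """
    if psd.grid != sm.grid:
        raise ValueError("fields are on different grids")
    if psd.hour != sm.hour:
        raise ValueError(f"hour mismatch: {psd.hour} vs {sm.hour}")
    total = psd.values + sm.values
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, 100.0 * psd.values / total, np.nan)
    pct = np.clip(pct, 0.0, 100.0)  # guard float overshoot at pure-psd cells
    return ContributionField(grid=psd.grid, pct=pct, hour=psd.hour)


def contribution_summary(fields: Sequence[ContributionField]) -> pd.DataFrame:
    """Per-hour mean/sd/min/max of the contribution over defined cells only."""
    if not fields:
        raise ValueError("no contribution fields given")
    rows = []
    for f in sorted(fields, key=lambda f: f.hour):
        vals = f.pct[f.defined_mask]
        if vals.size:
            rows.append(
                {
                    "hour": f.hour,
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=0)),
                    "min": float(vals.min()),
                    "max": float(vals.max()),
                    "n_defined": int(vals.size),
                }
            )
        else:
            rows.append(
                {"hour": f.hour, "mean": np.nan, "sd": np.nan, "min": np.nan,
                 "max": np.nan, "n_defined": 0}
            )
    return pd.DataFrame(rows)
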