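"""Station QC, station-to-grid interpolation, exceedance thresholding, trends.

The exceedance concentration EP at a cell is the positive part of the
interpolated PM2.5 concentration minus the health-guideline threshold
(25 µg/m³, the WHO short-term guideline level): EP = max(c − 25, 0).
Cells meeting the guideline contribute zero risk regardless of population.

Station-to-grid spatialization uses inverse-distance weighting (IDW), the
minimal-assumption deterministic interpolator; it is isolated behind
``interpolate_hour`` so a geostatistical method can be swapped in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .grid import GridSpec, StationSeries

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 25.0  # µg/m³


@dataclass
class ExceedanceField:
    """Per-cell exceedance concentration EP >= 0 (µg/m³) at one hour."""

    grid: GridSpec
    ep: np.ndarray
    hour: int
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        self.ep = np.asarray(self.ep, dtype=float)
        if self.ep.shape != self.grid.shape:
            raise ValueError("ep shape does not match grid")
        if np.any(self.ep < 0) or not np.all(np.isfinite(self.ep)):
            raise ValueError("ep must be finite and >= 0")

    @property
    def any_exceedance(self) -> bool:
        return bool(np.any(self.ep > 0))


@dataclass
class QcReport:
    """Counts of entries removed during station quality control."""

    n_stations_in: int = 0
    n_stations_out: int = 0
    n_values_removed: int = 0
    dropped_stations: list[str] = dc_field(default_factory=list)
    hours_without_data: list[int] = dc_field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_stations_in": self.n_stations_in,
            "n_stations_out": self.n_stations_out,
            "n_values_removed": self.n_values_removed,
            "dropped_stations": list(self.dropped_stations),
            "hours_without_data": list(self.hours_without_data),
        }


def qc_stations(series: Sequence[StationSeries]) -> tuple[list[StationSeries], QcReport]:
    """Delete invalid and missing entries; drop stations with no valid hour.

    Missing values stay NaN inside the surviving series (per-hour validity is
    decided at interpolation time); hours at which *no* station is valid are
    listed in the report so the pipeline can skip them.
    """
    report = QcReport(n_stations_in=len(series))
    kept: list[StationSeries] = []
    for s in series:
        invalid = ~np.isfinite(s.conc)
        report.n_values_removed += int(invalid.sum())
        if invalid.all():
            report.dropped_stations.append(s.station_id)
            continue
        kept.append(s)
    report.n_stations_out = len(kept)
    all_hours = sorted({int(h) for s in kept for h in s.hours})
    for h in all_hours:
        if not any(np.isfinite(s.value_at(h)) for s in kept):
            report.hours_without_data.append(h)
    if report.n_values_removed or report.dropped_stations:
        logger.info(
            "QC removed %d values, dropped stations %s",
            report.n_values_removed,
            report.dropped_stations,
        )
    return kept, report


def valid_at_hour(series: Sequence[StationSeries], hour: int) -> list[StationSeries]:
    return [s for s in series if np.isfinite(s.value_at(hour))]


def interpolate_hour(
    stations: Sequence[StationSeries],
    grid: GridSpec,
    hour: int,
    power: float = 2.0,
) -> np.ndarray:
    """IDW-interpolate station concentrations at ``hour`` onto the grid.

    A cell whose center lies within half a cell of a station takes that
    station's value exactly (this also guards the 1/d^p weight against
    near-zero distances). The result is bounded by the min/max of the
    participating station values.
    """
    valid = valid_at_hour(stations, hour)
    if not valid:
        raise ValueError(f"no station has a valid value at hour {hour}")
    pts = np.array([[s.x, s.y] for s in valid])
    vals = np.array([s.value_at(hour) for s in valid])
    X, Y = grid.cell_centers()
    centers = np.column_stack([X.ravel(), Y.ravel()])
    d = cdist(centers, pts)
    near = d < grid.cell_size / 2.0
    with np.errstate(divide="ignore"):
        w = d ** (-power)
    w[near] = 0.0  # replaced by exact assignment below
    out = np.full(len(centers), np.nan)
    wsum = w.sum(axis=1)
    ok = wsum > 0
    out[ok] = (w[ok] @ vals) / wsum[ok]
    coincident = near.any(axis=1)
    if coincident.any():
        out[coincident] = vals[np.argmin(d[coincident], axis=1)]
    return out.reshape(grid.shape)


def exceedance_field(
    conc: np.ndarray,
    grid: GridSpec,
    hour: int,
    threshold: float = DEFAULT_THRESHOLD,
) -> ExceedanceField:
    """Threshold a concentration field: EP = max(conc − threshold, 0)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    conc = np.asarray(conc, dtype=float)
    ep = np.maximum(conc - threshold, 0.0)
    return ExceedanceField(grid=grid, ep=ep, hour=hour, threshold=threshold)


def hourly_trend_slope(hours: Sequence[float], values: Sequence[float]) -> tuple[float, float]:
    """OLS slope (µg/m³ per hour) and intercept of concentration on hour index."""
    hours = np.asarray(hours, dtype=float)
    values = np.asarray(values, dtype=float)
    if hours.size < 2:
        raise ValueError("need at least two hourly points for a trend")
    if np.ptp(hours) == 0:
        raise ValueError("hours are all identical")
    res = stats.linregress(hours, values)
    return float(res.slope), float(res.intercept)


def exceedance_profile(
    fields: Sequence[ExceedanceField],
    stations: Sequence[StationSeries],
) -> pd.DataFrame:
    """Per-hour mean exceedance sampled at the station cells.

    Returns a frame (hour, mean_ep) whose ``attrs`` carry the first hour with
    positive exceedance and the hours of minimum/maximum mean exceedance among
    exceedance hours (None when the day never exceeds).
    """
    if not fields:
        raise ValueError("no exceedance fields given")
    rows = []
    for f in sorted(fields, key=lambda f: f.hour):
        samples = []
        for s in stations:
            try:
                r, c = f.grid.cell_of(s.x, s.y)
            except ValueError:
                continue
            samples.append(f.ep[r, c])
        rows.append({"hour": f.hour, "mean_ep": float(np.mean(samples)) if samples else np.nan})
    df = pd.DataFrame(rows)
    pos = df[df["mean_ep"] > 0]
    df.attrs["first_exceedance_hour"] = int(pos["hour"].iloc[0]) if len(pos) else None
    df.attrs["min_hour"] = int(pos.loc[pos["mean_ep"].idxmin(), "hour"]) if len(pos) else None
    df.attrs["max_hour"] = int(pos.loc[pos["mean_ep"].idxmax(), "hour"]) if len(pos) else None
    return df
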