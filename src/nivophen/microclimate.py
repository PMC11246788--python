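"""Microclimate covariates from plot-level soil-temperature loggers.

Snowbed plots sit under an insulating snowpack for most of the year, which
pins soil temperature near 0 °C.  The first sustained rise of the daily mean
above a threshold (2 °C by default) therefore marks the day of snowmelt
(DOSM).  From that day onward the thermal sum of daily means above a base
temperature (0 °C) gives growing degree days (GDD), and calendar offsets give
days from snowmelt (DFSM).  These three covariates — DOY, DFSM, GDD — are the
candidate predictors for the downstream phenology models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel returned when a series never qualifies as snow-free.
NO_SNOWMELT = -1

#: Fraction of a day's 24 hourly records that must be present before the
#: day's mean is trusted; sparser days are interpolated from neighbours.
MIN_HOUR_FRACTION = 0.75


class MicroclimateError(ValueError):
    """Raised for invalid temperature series or out-of-range requests."""


@dataclass
class TemperatureSeries:
    """Hourly soil temperature for one plot.

    Parameters
    ----------
    plot_id
        Identifier of the plot the logger sits in.
    timestamps
        Strictly increasing hourly instants (``DatetimeIndex``-coercible).
    temp_c
        Soil temperature in °C, one value per timestamp.
    gap_tolerance_h
        Largest permissible gap between consecutive records, in hours.
    """

    plot_id: str
    timestamps: pd.DatetimeIndex
    temp_c: np.ndarray
    gap_tolerance_h: float = 6.0

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.temp_c = np.asarray(self.temp_c, dtype=float)
        if len(self.timestamps) != len(self.temp_c):
            raise MicroclimateError("timestamps and temp_c differ in length")
        if len(self.timestamps) == 0:
            raise MicroclimateError("empty temperature series")
        diffs = np.diff(self.timestamps.asi8)
        if np.any(diffs <= 0):
            raise MicroclimateError("timestamps must be strictly increasing")
        max_gap_h = diffs.max(initial=0) / 3.6e12
        if max_gap_h > self.gap_tolerance_h:
            logger.warning(
                "plot %s: gap of %.1f h exceeds tolerance %.1f h",
                self.plot_id, max_gap_h, self.gap_tolerance_h,
            )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, plot_id: str = "",
                   **kwargs) -> "TemperatureSeries":
        """Build from a two-column frame (timestamp, temp_c)."""
        ts = pd.DatetimeIndex(pd.to_datetime(frame["timestamp"]))
        return cls(plot_id=plot_id, timestamps=ts,
                   temp_c=frame["temp_c"].to_numpy(float), **kwargs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"timestamp": self.timestamps, "temp_c": self.temp_c})

    def daily_means(self) -> pd.Series:
        """Daily mean temperature indexed by date.

        Days with fewer than 75 % of the expected 24 hourly records are
        treated as missing and linearly interpolated from neighbouring days
        (field loggers drop records); the interpolation is logged.
        """
        s = pd.Series(self.temp_c, index=self.timestamps)
        by_day = s.groupby(s.index.date)
        means = by_day.mean()
        counts = by_day.count()
        means.index = pd.to_datetime(means.index)
        sparse = counts.to_numpy() < MIN_HOUR_FRACTION * 24
        # single-day series from tests are exempt when fully sampled days
        # are absent altogether
        if sparse.any() and not sparse.all():
            filled = means.copy()
            filled[sparse] = np.nan
            filled = filled.interpolate(limit_direction="both")
            n_bad = int(sparse.sum())
            logger.info("plot %s: interpolated %d sparse day(s)", self.plot_id, n_bad)
            means = filled
        return means


@dataclass
class SnowSeason:
    """Per-plot, per-year snow season summary."""

    plot_id: str
    year: int
    dosm: int
    snow_cover_days: int
    mean_soil_temp: float
    site: str = ""

    def __post_init__(self) -> None:
        if self.dosm != NO_SNOWMELT and not 1 <= self.dosm <= 366:
            raise MicroclimateError(f"dosm {self.dosm} outside [1, 366]")
        if self.snow_cover_days < 0:
            raise MicroclimateError("snow_cover_days must be >= 0")


def detect_snowmelt_day(series: TemperatureSeries, threshold_c: float = 2.0,
                        persistence_days: int = 1) -> int:
    """Day of year on which the plot becomes snow-free.

    The plot counts as snow-free on the first day whose daily mean soil
    temperature exceeds ``threshold_c`` and stays above it for
    ``persistence_days`` consecutive days.  Daily means rather than raw
    hourly values are used so that a single hourly spike under snow cannot
    trigger a false melt date.

    Returns
    -------
    int
        1-based day of year, or :data:`NO_SNOWMELT` if no day qualifies.
    """
    if persistence_days < 1:
        raise MicroclimateError("persistence_days must be >= 1")
    means = series.daily_means()
    above = (means.to_numpy() > threshold_c).astype(int)
    if len(above) < persistence_days:
        return NO_SNOWMELT
    run = np.convolve(above, np.ones(persistence_days, dtype=int), mode="valid")
    hits = np.nonzero(run == persistence_days)[0]
    if hits.size == 0:
        return NO_SNOWMELT
    return int(means.index[hits[0]].dayofyear)


def compute_gdd(series: TemperatureSeries, start_doy: int,
                base_c: float = 0.0) -> pd.DataFrame:
    """Cumulative growing degree days from ``start_doy`` onward.

    ``gdd(d) = sum over days start_doy..d of max(daily_mean - base_c, 0)``.

    Returns a climate-alignment table with one row per calendar day from
    ``start_doy`` to the end of the series, columns
    ``date, doy, dfsm, gdd`` where ``dfsm = doy - start_doy``.
    """
    means = series.daily_means()
    doys = means.index.dayofyear.to_numpy()
    if start_doy < doys.min() or start_doy > doys.max():
        raise MicroclimateError(
            f"start_doy {start_doy} outside series span "
            f"[{doys.min()}, {doys.max()}]")
    keep = doys >= start_doy
    means = means[keep]
    doys = doys[keep]
    increments = np.maximum(means.to_numpy() - base_c, 0.0)
    return pd.DataFrame({
        "date": means.index,
        "doy": doys,
        "dfsm": doys - start_doy,
        "gdd": np.cumsum(increments),
    })


def align_climate(series: TemperatureSeries, threshold_c: float = 2.0,
                  base_c: float = 0.0, persistence_days: int = 1,
                  include_premelt: bool = False) -> pd.DataFrame:
    """Snowmelt detection + GDD accumulation in one call.

    Convenience wrapper returning the alignment table for the plot's own
    detected melt day; the table additionally carries ``plot_id`` and
    ``dosm`` columns so several plots can be concatenated.  With
    ``include_premelt`` the table extends back to the series start with
    ``gdd = 0`` and negative DFSM, so that snow-covered observation dates
    can still be joined (and flagged) downstream.
    """
    dosm = detect_snowmelt_day(series, threshold_c, persistence_days)
    if dosm == NO_SNOWMELT:
        raise MicroclimateError(f"plot {series.plot_id}: no snowmelt detected")
    table = compute_gdd(series, start_doy=dosm, base_c=base_c)
    if include_premelt:
        means = series.daily_means()
        doys = means.index.dayofyear.to_numpy()
        pre = doys < dosm
        if pre.any():
            pre_table = pd.DataFrame({
                "date": means.index[pre],
                "doy": doys[pre],
                "dfsm": doys[pre] - dosm,
                "gdd": 0.0,
            })
            table = pd.concat([pre_table, table], ignore_index=True)
    table.insert(0, "plot_id", series.plot_id)
    table["dosm"] = dosm
    return table


def mean_soil_temperature(series: TemperatureSeries,
                          window: tuple | None = None) -> float:
    """Arithmetic mean of hourly soil temperature, reported to 0.1 °C.

    ``window`` is an optional ``(start, end)`` pair of datetimes (inclusive);
    by default the whole series is averaged.
    """
    temps = series.temp_c
    if window is not None:
        start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
        mask = (series.timestamps >= start) & (series.timestamps <= end)
        if not mask.any():
            raise MicroclimateError("empty averaging window")
        temps = temps[mask]
    return round(float(np.mean(temps)), 1)


def summarize_dosm(seasons: list[SnowSeason]) -> dict:
    """Site-level DOSM summary and the early-vs-late mean yearly offset.

    For each site: the mean DOSM rounded to the nearest day, the min–max
    range, and the per-year values.  When exactly two sites are present the
    summary also reports the mean of the yearly signed differences between
    them (second site minus first, in the site order of first appearance),
    rounded to the nearest day.
    """
    if not seasons:
        raise MicroclimateError("no snow seasons supplied")
    frame = pd.DataFrame(
        [{"site": s.site, "year": s.year, "dosm": s.dosm} for s in seasons])
    if (frame["dosm"] == NO_SNOWMELT).any():
        raise MicroclimateError("summary includes a no-snowmelt season")
    out: dict = {"sites": {}}
    site_order = list(dict.fromkeys(frame["site"]))
    for site in site_order:
        sub = frame[frame["site"] == site]
        if sub.empty:
            raise MicroclimateError(f"empty site group {site!r}")
        per_year = (sub.groupby("year")["dosm"].mean()).to_dict()
        vals = np.array(list(per_year.values()), dtype=float)
        out["sites"][site] = {
            "mean_dosm": int(round(vals.mean())),
            "range": (int(vals.min()), int(vals.max())),
            "per_year": {int(y): float(v) for y, v in per_year.items()},
        }
    if len(site_order) == 2:
        a, b = site_order
        ya = out["sites"][a]["per_year"]
        yb = out["sites"][b]["per_year"]
        shared = sorted(set(ya) & set(yb))
        if shared:
            diffs = [yb[y] - ya[y] for y in shared]
            out["mean_yearly_difference"] = int(round(float(np.mean(diffs))))
            out["difference_order"] = f"{b} - {a}"
    return out


def summarize_seasons(series_by_plot: dict[str, TemperatureSeries],
                      site_of_plot: dict[str, str],
                      year: int,
                      threshold_c: float = 2.0,
                      persistence_days: int = 1) -> list[SnowSeason]:
    """Build :class:`SnowSeason` records for a set of plots in one year.

    Snow-cover days are counted as calendar days before the detected melt
    day within the series span; the mean soil temperature is taken over the
    snow-free period (melt day to end of series).
    """
    seasons = []
    for plot_id, series in series_by_plot.items():
        dosm = detect_snowmelt_day(series, threshold_c, persistence_days)
        means = series.daily_means()
        doys = means.index.dayofyear.to_numpy()
        if dosm == NO_SNOWMELT:
            snow_days = len(means)
            t_mean = round(float(means.mean()), 1)
        else:
            snow_days = int((doys < dosm).sum())
            t_mean = round(float(means[doys >= dosm].mean()), 1)
        seasons.append(SnowSeason(plot_id=plot_id, year=year, dosm=dosm,
                                  snow_cover_days=snow_days,
                                  mean_soil_temp=t_mean,
                                  site=site_of_plot.get(plot_id, "")))
    return seasons
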