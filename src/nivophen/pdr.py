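"""Phenological development rate (PDR) per species, plot and year.

The PDR measures how fast a species advances through its developmental
stages once emerged: the ordinary-least-squares slope of median phenophase
against accumulated growing degree days, over the observations between the
first record at or beyond emergence (BBCH >= 09) and the last record before
cycle completion (BBCH < 59), endpoints inclusive.  Typical snowbed values
run 0.06-0.095 BBCH units per GDD — about 50 units of development spread
over 600-800 degree-days.  A per-calendar-day axis and a two-point
(chord) mode are available as variants.

Plot-year estimates aggregate to per-species site means (M) and standard
deviations (SD); sites are compared with a two-sided Welch two-sample test
(or a year-paired test, since the field design's unit of replication is
ambiguous between plot-years and years).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

EMERGENCE_CODE = 9       # first "relevant" phenophase
COMPLETION_CODE = 59     # fully senescent


class PDRError(ValueError):
    """Raised when a development rate or comparison cannot be computed."""


@dataclass
class PDREstimate:
    """Slope of phenophase vs. thermal (or calendar) time for one plot-year."""

    species: str
    site: str
    plot: str
    year: int
    slope: float
    axis: str                      # "gdd" or "day"
    n_obs_in_window: int
    window: tuple                  # (first in-window date, last in-window date)

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope):
            raise PDRError("PDR slope must be finite")
        if self.n_obs_in_window < 2:
            raise PDRError("PDR needs >= 2 in-window observations")


def development_window(phases: np.ndarray) -> tuple[int, int] | None:
    """Index span [first phase >= 09, last phase < 59], endpoints inclusive.

    Returns None when no observation qualifies.  Pre-emergence (phase < 9)
    and completed (phase >= 59) records fall outside the window, so adding
    them to a series never changes the estimate.
    """
    phases = np.asarray(phases, dtype=float)
    emerged = np.nonzero(phases >= EMERGENCE_CODE)[0]
    developing = np.nonzero(phases < COMPLETION_CODE)[0]
    if emerged.size == 0 or developing.size == 0:
        return None
    start, end = emerged[0], developing[-1]
    if end < start:
        return None
    return int(start), int(end)


def compute_pdr(series: pd.DataFrame, axis: str = "gdd",
                mode: str = "ols") -> PDREstimate:
    """PDR for one plot/species/year from an aligned median-phase series.

    ``series`` columns: date, median_phase, gdd (and doy when
    ``axis='day'``), plus species/site/plot/year identifiers (taken from the
    first row; single-group input expected).  ``mode='ols'`` regresses over
    all in-window observations; ``mode='two-point'`` uses only the chord
    between the window endpoints (the two agree on two-point windows).
    """
    if axis not in ("gdd", "day"):
        raise PDRError(f"unknown axis {axis!r}")
    if mode not in ("ols", "two-point"):
        raise PDRError(f"unknown mode {mode!r}")
    df = series.sort_values("date" if "date" in series.columns else "gdd")
    phases = df["median_phase"].to_numpy(float)
    win = development_window(phases)
    if win is None:
        raise PDRError("no observations in the development window")
    i0, i1 = win
    sub = df.iloc[i0:i1 + 1]
    if len(sub) < 2:
        raise PDRError("fewer than 2 in-window observations")
    x = sub["gdd"].to_numpy(float) if axis == "gdd" \
        else sub["doy"].to_numpy(float)
    y = sub["median_phase"].to_numpy(float)
    if mode == "two-point":
        if x[-1] == x[0]:
            raise PDRError("degenerate window: zero covariate span")
        slope = (y[-1] - y[0]) / (x[-1] - x[0])
    else:
        if np.std(x) == 0:
            raise PDRError("degenerate window: constant covariate")
        slope = float(np.polyfit(x, y, 1)[0])

    def _get(col, default=""):
        return df[col].iloc[0] if col in df.columns else default

    year = _get("year", None)
    if year is None and "date" in df.columns:
        year = pd.Timestamp(df["date"].iloc[0]).year
    dates = sub["date"].tolist() if "date" in sub.columns else [None, None]
    return PDREstimate(
        species=str(_get("species")), site=str(_get("site")),
        plot=str(_get("plot")), year=int(year), slope=float(slope),
        axis=axis, n_obs_in_window=len(sub),
        window=(dates[0], dates[-1]),
    )


def compute_pdr_table(aligned: pd.DataFrame, axis: str = "gdd",
                      mode: str = "ols") -> pd.DataFrame:
    """PDR per (species, site, plot, year) group of an aligned table.

    Groups whose window holds fewer than two observations are skipped (they
    carry no rate information); the returned frame has one row per estimate.
    """
    df = aligned.copy()
    if "year" not in df.columns:
        df["year"] = pd.to_datetime(df["date"]).dt.year
    rows = []
    for (species, site, plot, year), g in df.groupby(
            ["species", "site", "plot", "year"], sort=True):
        try:
            est = compute_pdr(g, axis=axis, mode=mode)
        except PDRError:
            continue
        rows.append({"species": species, "site": site, "plot": plot,
                     "year": year, "slope": est.slope,
                     "n_obs": est.n_obs_in_window})
    return pd.DataFrame(rows)


def aggregate_pdr(estimates: pd.DataFrame) -> pd.DataFrame:
    """Per species/site mean (M) and sample SD over plot-year estimates.

    Singleton groups get a missing SD.
    """
    if estimates.empty:
        raise PDRError("no PDR estimates to aggregate")
    agg = (estimates.groupby(["species", "site"])["slope"]
           .agg(M="mean", SD=lambda s: s.std(ddof=1), n="count")
           .reset_index())
    return agg


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_sites(group_a: np.ndarray, group_b: np.ndarray,
                  test: str = "welch") -> dict:
    """Two-sided test of a site difference in PDR.

    ``test='welch'`` treats plot-years as the unit of replication (unequal
    group sizes and variances); ``test='paired'`` expects per-year values in
    matching order and runs a paired t-test.  Two groups with zero variance
    and equal means give p = 1 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise PDRError("each group needs >= 2 estimates")
    if np.std(a) == 0 and np.std(b) == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
    elif test == "welch":
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    elif test == "paired":
        if len(a) != len(b):
            raise PDRError("paired test needs equal-length groups")
        p = float(stats.ttest_rel(a, b).pvalue)
    else:
        raise PDRError(f"unknown test {test!r}")
    return {
        "p": p, "stars": _stars(p),
        "mean_a": float(a.mean()), "mean_b": float(b.mean()),
        "sd_a": float(a.std(ddof=1)), "sd_b": float(b.std(ddof=1)),
        "mean_difference": float(a.mean() - b.mean()),
        "test": test,
    }


def compare_sites_table(estimates: pd.DataFrame, site_a: str, site_b: str,
                        test: str = "welch") -> pd.DataFrame:
    """Per-species site comparison mirroring the (species, site, p, M, SD) layout."""
    rows = []
    for species, g in estimates.groupby("species", sort=True):
        a = g.loc[g["site"] == site_a, "slope"].to_numpy()
        b = g.loc[g["site"] == site_b, "slope"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            continue
        res = compare_sites(a, b, test=test)
        rows.append({"species": species, "site": site_a, "p": res["p"],
                     "stars": res["stars"], "M": res["mean_a"],
                     "SD": res["sd_a"]})
        rows.append({"species": species, "site": site_b, "p": np.nan,
                     "stars": "", "M": res["mean_b"], "SD": res["sd_b"]})
    return pd.DataFrame(rows)
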