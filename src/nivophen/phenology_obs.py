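"""Snowbed-adapted BBCH phenophase scale and observation processing.

The ordinal scale is a snowbed adaptation of the standard BBCH plant
development coding, restricted to codes 0 (plant not visible) through 59
(completely senescent) across six principal growth stages (germination, leaf
development, inflorescence emergence, flowering, fruit development,
dissemination).  Descriptions differ by morphotype: annual forb (A),
perennial forb (P) or graminoid (G); code 47 ("late milk") exists only for
graminoids.  Field protocol records, per 1 m² subplot, the most advanced
individual of each monitored species; the plot-level statistic is the median
code across the plot's subplots, treated downstream as quasi-continuous.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

MORPHOTYPES = ("A", "P", "G")

#: Default species -> morphotype assignment for the five monitored species.
DEFAULT_MORPHOTYPE_MAP = {
    "Euphrasia minima": "A",
    "Salix herbacea": "P",
    "Gnaphalium supinum": "P",
    "Veronica alpina": "P",
    "Poa alpina": "G",
}


class ScaleError(ValueError):
    """Raised when an observation does not conform to the phenophase scale."""


@dataclass(frozen=True)
class PhenophaseScale:
    """The ordered set of valid codes and their per-morphotype descriptions."""

    codes: tuple[int, ...]
    descriptions: dict  # (code, morphotype) -> text

    @classmethod
    @lru_cache(maxsize=1)
    def default(cls) -> "PhenophaseScale":
        """Load the packaged snowbed scale (shipped as a CSV data file)."""
        ref = importlib.resources.files("nivophen") / "data" / "bbch_scale.csv"
        with importlib.resources.as_file(ref) as path:
            table = pd.read_csv(path)
        codes = tuple(sorted(table["code"].unique()))
        desc = {(int(r.code), r.morphotype): r.description
                for r in table.itertuples()}
        return cls(codes=codes, descriptions=desc)

    def codes_for(self, morphotype: str) -> np.ndarray:
        """Valid codes for one morphotype (drops 47 for non-graminoids)."""
        if morphotype not in MORPHOTYPES:
            raise ScaleError(f"unknown morphotype {morphotype!r}")
        return np.array([c for c in self.codes
                         if (c, morphotype) in self.descriptions])

    def is_valid(self, code: int, morphotype: str) -> bool:
        return (int(code), morphotype) in self.descriptions

    def nearest(self, value: float, morphotype: str = "P") -> int:
        """Snap a real-valued development level to the nearest valid code.

        Ties (value exactly between two codes) resolve to the lower code, so
        snapping never anticipates a stage that has not been reached.
        """
        codes = self.codes_for(morphotype)
        dist = np.abs(codes - value)
        return int(codes[np.argmin(dist)])  # argmin takes first = lower code


@dataclass
class PhenoObservation:
    """One field record: the most advanced BBCH code in one subplot."""

    site: str
    plot: str
    subplot: int
    species: str
    date: pd.Timestamp
    bbch: int

    def __post_init__(self) -> None:
        self.date = pd.Timestamp(self.date)
        self.bbch = int(self.bbch)


def validate_observation(obs: PhenoObservation, scale: PhenophaseScale | None = None,
                         morphotype_map: dict | None = None) -> PhenoObservation:
    """Check a record's BBCH code against the scale and species morphotype.

    Raises :class:`ScaleError` naming the offending code and the nearest
    valid codes when the code is not part of the scale (or not defined for
    the species' morphotype, e.g. 47 for a forb).
    """
    scale = scale or PhenophaseScale.default()
    morphotype_map = morphotype_map or DEFAULT_MORPHOTYPE_MAP
    morph = morphotype_map.get(obs.species, "P")
    if not scale.is_valid(obs.bbch, morph):
        valid = scale.codes_for(morph)
        below = valid[valid < obs.bbch]
        above = valid[valid > obs.bbch]
        nearest = [int(below[-1])] if below.size else []
        nearest += [int(above[0])] if above.size else []
        raise ScaleError(
            f"BBCH code {obs.bbch} invalid for {obs.species} "
            f"(morphotype {morph}); nearest valid codes: {nearest}")
    return obs


def median_phenophase(observations: list[PhenoObservation] | list[int]) -> float:
    """Sample median of the subplot codes for one plot/species/date.

    With an even subplot count the mean of the two central codes is taken,
    which may fall between valid codes (e.g. 31 from {29, 33}); the value is
    kept real-valued because the models treat the scale as quasi-continuous.
    """
    if not len(observations):
        raise ScaleError("median of empty observation set")
    codes = np.array([o.bbch if isinstance(o, PhenoObservation) else o
                      for o in observations], dtype=float)
    return float(np.median(codes))


def plot_medians(obs_table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a subplot-level observation table to plot-level medians.

    ``obs_table`` columns: site, plot, subplot, species, date, bbch.
    Returns one row per (site, plot, species, date) with ``median_phase``.
    All subplots present on the date enter the median, including zeros for
    subplots where the species had not emerged.
    """
    required = {"site", "plot", "species", "date", "bbch"}
    missing = required - set(obs_table.columns)
    if missing:
        raise ScaleError(f"observation table missing columns {sorted(missing)}")
    out = (obs_table
           .groupby(["site", "plot", "species", "date"], sort=True)["bbch"]
           .median()
           .rename("median_phase")
           .reset_index())
    out["date"] = pd.to_datetime(out["date"])
    return out


def align_observations(medians: pd.DataFrame, climate: pd.DataFrame) -> pd.DataFrame:
    """Attach DOY/DFSM/GDD covariates to plot-level median records.

    ``climate`` is a concatenated climate-alignment table with columns
    ``plot_id, date, doy, dfsm, gdd`` (one row per plot-day).  Every
    (plot, date) pair in ``medians`` must be covered; uncovered pairs are
    reported together in the raised error.  Records dated before the plot's
    snowmelt are not produced by the climate table and therefore surface as
    coverage errors unless the caller extends the table; the returned frame
    flags any non-positive DFSM explicitly.
    """
    med = medians.copy()
    med["date"] = pd.to_datetime(med["date"]).dt.normalize()
    cli = climate.copy()
    cli["date"] = pd.to_datetime(cli["date"]).dt.normalize()
    merged = med.merge(cli[["plot_id", "date", "doy", "dfsm", "gdd"]],
                       left_on=["plot", "date"], right_on=["plot_id", "date"],
                       how="left").drop(columns="plot_id")
    bad = merged["gdd"].isna()
    if bad.any():
        pairs = merged.loc[bad, ["plot", "date"]].drop_duplicates()
        listing = "; ".join(f"{r.plot}@{r.date.date()}" for r in pairs.itertuples())
        raise ScaleError(f"no climate coverage for: {listing}")
    merged["pre_melt"] = merged["dfsm"] < 0
    return merged
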