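"""Season phenometrics from a daily greenness series.

The seasonal GCC trajectory of a snowbed rises steeply after melt-out,
plateaus during the main phenological season and declines to the baseline
with autumn browning.  Five event days partition it:

* SOS / EOS — start and end of season: first / last day on which the series
  reaches ``baseline + baseline_frac * (max - baseline)``; the baseline is
  the pre-season greenness floor (grey soil sits near GCC = 1/3).
* SPS / EPS — start and end of peak: first / last day with GCC within 95 %
  of the seasonal maximum (``gcc >= 0.95 * gcc_max``).
* POS — peak of season: the day attaining the maximum (earliest on ties).

Both rules are relative, so event days are invariant to rescaling the whole
series and equivariant under time shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class PhenometricsError(ValueError):
    """Raised for unusable greenness series or inconsistent event sets."""


@dataclass
class SeasonMetrics:
    """The five event days (day-of-year) plus the seasonal maximum."""

    sos: int | None
    sps: int | None
    pos: int | None
    eps: int | None
    eos: int | None
    gcc_max: float = float("nan")
    flags: tuple = ()

    def __post_init__(self) -> None:
        events = [self.sos, self.sps, self.pos, self.eps, self.eos]
        present = [e for e in events if e is not None]
        if any(b < a for a, b in zip(present, present[1:])):
            raise PhenometricsError(
                f"event days must be ordered SOS<=SPS<=POS<=EPS<=EOS, got {events}")

    @property
    def season_length_days(self) -> int | None:
        if self.sos is None or self.eos is None:
            return None
        return int(self.eos - self.sos)

    def as_dict(self) -> dict:
        return {"sos": self.sos, "sps": self.sps, "pos": self.pos,
                "eps": self.eps, "eos": self.eos, "gcc_max": self.gcc_max,
                "season_length_days": self.season_length_days}


def extract_season_metrics(daily: pd.DataFrame, baseline_frac: float = 0.1,
                           peak_frac: float = 0.95,
                           baseline_days: int = 5) -> SeasonMetrics:
    """Partition a smoothed daily GCC series into the five season events.

    ``daily`` needs columns ``doy`` (or ``date``) and ``gcc_smoothed``.
    The baseline is the median of the first ``baseline_days`` non-missing
    values (the early snow-free days, before green-up).  A series that never
    falls back to the SOS/EOS threshold after its maximum yields partial
    metrics with EOS missing and a ``no_fall`` flag; a peak plateau broken
    by dips below the 95 % line is reported with a ``fragmented_peak`` flag
    (first/last crossing semantics, no contiguity required).
    """
    df = daily.dropna(subset=["gcc_smoothed"]).copy()
    if df.empty:
        raise PhenometricsError("no non-missing GCC values")
    if "doy" not in df.columns:
        df["doy"] = pd.to_datetime(df["date"]).dt.dayofyear
    df = df.sort_values("doy")
    doy = df["doy"].to_numpy()
    gcc = df["gcc_smoothed"].to_numpy(float)

    gcc_max = float(gcc.max())
    pos_i = int(np.argmax(gcc))           # earliest day on ties
    pos = int(doy[pos_i])

    base = float(np.median(gcc[:baseline_days]))
    flags: list[str] = []
    if gcc_max <= base:
        raise PhenometricsError("series has no rise above its baseline")

    peak_thr = peak_frac * gcc_max
    in_peak = gcc >= peak_thr
    sps = int(doy[np.argmax(in_peak)])
    eps = int(doy[len(in_peak) - 1 - np.argmax(in_peak[::-1])])
    peak_span = in_peak[(doy >= sps) & (doy <= eps)]
    if not peak_span.all():
        flags.append("fragmented_peak")

    sos_thr = base + baseline_frac * (gcc_max - base)
    above = gcc >= sos_thr
    sos = int(doy[np.argmax(above)])
    eos_i = len(above) - 1 - np.argmax(above[::-1])
    eos: int | None = int(doy[eos_i])
    # monotone rise with no return to threshold: EOS is not observable
    if eos_i == len(above) - 1 and gcc[-1] >= sos_thr and pos_i == len(gcc) - 1:
        eos = None
        flags.append("no_fall")

    return SeasonMetrics(sos=sos, sps=sps, pos=pos, eps=eps, eos=eos,
                         gcc_max=gcc_max, flags=tuple(flags))


def season_intervals(metrics: SeasonMetrics,
                     other: SeasonMetrics | None = None) -> dict:
    """Within-season intervals and, optionally, between-site event offsets.

    Within-site: SOS→POS (green-up length), SPS→EPS (peak duration),
    SOS→EOS (season length).  With a second site's metrics, the per-event
    offsets ``other − metrics`` are reported; intervals touching a missing
    event come back as ``None``.
    """
    def span(a, b):
        return None if a is None or b is None else int(b - a)

    out = {
        "sos_to_pos": span(metrics.sos, metrics.pos),
        "sps_to_eps": span(metrics.sps, metrics.eps),
        "sos_to_eos": span(metrics.sos, metrics.eos),
    }
    if other is not None:
        out["between_site_offsets"] = {
            name: span(getattr(metrics, name), getattr(other, name))
            for name in ("sos", "sps", "pos", "eps", "eos")
        }
    return out
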