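"""Green-chromatic-coordinate extraction from time-lapse camera imagery.

A fixed phenocam captures RGB images hourly through the season.  Canopy
greenness is summarised as the green chromatic coordinate

    GCC = G / (R + G + B)

of the mean RGB over a region of interest (ROI).  Raw archives are noisy —
over-exposed frames, fog, rain, twilight shots — so a cascade of quality
filters runs before smoothing:

1. metadata rules: exposure time <= 50 s, exposure ratio >= 2, local
   acquisition time within 10:00-17:00;
2. brightness rule: mean ROI luminance within a configurable quantile band
   of the surviving population;
3. cluster rule: 2-means on (luminance, GCC) per image, dropping the
   brighter / less-green cluster (snow or fog frames) when it is separable.

The retained per-image GCC values are then reduced to a daily series by a
percentile over a moving window (90th percentile, 4-day trailing window by
default); with window 1 and percentile 100 the reduction is the daily
maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

# Brightness = channel-mean of the ROI RGB.  Exposure-driven artifacts
# (over-exposure, fog, snow) move all channels together, so the mean flags
# them without confounding greenness, which only shifts channel composition.
BRIGHTNESS_WEIGHTS = np.array([1.0, 1.0, 1.0]) / 3.0


class PhenocamError(ValueError):
    """Raised for undefined pixels, mask mismatches and bad QC parameters."""


@dataclass
class ImageRecord:
    """One camera frame, either with pixels or with a precomputed ROI mean."""

    filename: str
    timestamp: pd.Timestamp
    exposure_time_s: float
    exposure_ratio: float
    pixels: np.ndarray | None = None          # (H, W, 3)
    roi_mean_rgb: tuple | None = None

    def __post_init__(self) -> None:
        self.timestamp = pd.Timestamp(self.timestamp)
        if self.exposure_time_s < 0:
            raise PhenocamError("exposure_time_s must be >= 0")
        if self.pixels is None and self.roi_mean_rgb is None:
            raise PhenocamError("record needs pixels or roi_mean_rgb")


@dataclass
class ROIMask:
    """Boolean grid marking the region of interest; at least one pixel true."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise PhenocamError("ROI mask selects no pixels")


@dataclass
class QCRules:
    """Thresholds of the quality-control cascade.

    ``None`` disables the corresponding rule.  ``time_window`` is a pair of
    local hours (inclusive start, inclusive end).  ``brightness_band`` is the
    (low, high) quantile pair of the luminance filter.  ``lenient_time``
    keeps outside-window frames whose exposure is short (below
    ``lenient_exposure_s``); the default is the hard window.
    """

    max_exposure_s: float | None = 50.0
    min_exposure_ratio: float | None = 2.0
    time_window: tuple | None = (10, 17)
    lenient_time: bool = False
    lenient_exposure_s: float = 1.0
    brightness_band: tuple | None = (0.025, 0.975)
    cluster_filter: bool = True


def compute_gcc(roi_mean_rgb: tuple) -> float:
    """Green chromatic coordinate G/(R+G+B) of a mean-RGB triple.

    Evaluated as ``1 / ((R+B)/G + 1)``, which is algebraically identical but
    bit-exact on grey pixels: any (c, c, c) yields exactly 1/3.
    """
    r, g, b = (float(v) for v in roi_mean_rgb)
    if min(r, g, b) < 0:
        raise PhenocamError("negative channel value")
    if r + g + b <= 0:
        raise PhenocamError("undefined GCC: R+G+B must be positive")
    if g == 0:
        return 0.0
    return 1.0 / ((r + b) / g + 1.0)


def extract_roi_mean(image: ImageRecord, mask: ROIMask | None = None) -> tuple:
    """Channel-wise mean RGB over the true pixels of the ROI mask."""
    if image.pixels is None:
        if image.roi_mean_rgb is None:
            raise PhenocamError("record has neither pixels nor roi_mean_rgb")
        return tuple(float(v) for v in image.roi_mean_rgb)
    px = np.asarray(image.pixels, dtype=float)
    if px.ndim != 3 or px.shape[2] != 3:
        raise PhenocamError("pixel array must be (H, W, 3)")
    if mask is None:
        sel = px.reshape(-1, 3)
    else:
        if mask.mask.shape != px.shape[:2]:
            raise PhenocamError(
                f"mask shape {mask.mask.shape} != image shape {px.shape[:2]}")
        sel = px[mask.mask]
    return tuple(float(v) for v in sel.mean(axis=0))


def _image_features(records: list[ImageRecord],
                    mask: ROIMask | None) -> pd.DataFrame:
    rows = []
    for i, rec in enumerate(records):
        rgb = extract_roi_mean(rec, mask)
        rows.append({
            "index": i,
            "filename": rec.filename,
            "timestamp": rec.timestamp,
            "exposure_time_s": rec.exposure_time_s,
            "exposure_ratio": rec.exposure_ratio,
            "gcc": compute_gcc(rgb),
            "luminance": float(np.dot(BRIGHTNESS_WEIGHTS, rgb)),
        })
    return pd.DataFrame(rows)


def qc_filter(records: list[ImageRecord], rules: QCRules | None = None,
              mask: ROIMask | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the QC cascade; return (retained frame, rejection log).

    The retained frame carries timestamp, per-image GCC and luminance; the
    log has one row per rejected image with the name of the rule that fired
    first.  The metadata rules are evaluated per record; the brightness and
    cluster rules are population statistics recomputed on the survivors of
    the metadata stage.
    """
    rules = rules or QCRules()
    feats = _image_features(records, mask)
    if feats.empty:
        return feats, pd.DataFrame(columns=["filename", "timestamp", "rule"])
    rejections = []

    def reject(sub: pd.DataFrame, rule: str) -> None:
        for r in sub.itertuples():
            rejections.append({"filename": r.filename,
                               "timestamp": r.timestamp, "rule": rule})

    keep = pd.Series(True, index=feats.index)
    if rules.max_exposure_s is not None:
        bad = feats["exposure_time_s"] > rules.max_exposure_s
        reject(feats[keep & bad], "exposure_time")
        keep &= ~bad
    if rules.min_exposure_ratio is not None:
        bad = feats["exposure_ratio"] < rules.min_exposure_ratio
        reject(feats[keep & bad], "exposure_ratio")
        keep &= ~bad
    if rules.time_window is not None:
        lo, hi = rules.time_window
        hours = feats["timestamp"].dt.hour + feats["timestamp"].dt.minute / 60.0
        outside = (hours < lo) | (hours > hi)
        if rules.lenient_time:
            outside &= feats["exposure_time_s"] > rules.lenient_exposure_s
        reject(feats[keep & outside], "time_of_day")
        keep &= ~outside

    if rules.brightness_band is not None and keep.sum() > 3:
        lum = feats.loc[keep, "luminance"]
        lo_q, hi_q = rules.brightness_band
        lo_v, hi_v = lum.quantile(lo_q), lum.quantile(hi_q)
        bad = keep & ((feats["luminance"] < lo_v) | (feats["luminance"] > hi_v))
        reject(feats[bad], "brightness")
        keep &= ~bad

    if rules.cluster_filter and keep.sum() > 3:
        sub = feats[keep]
        X = np.column_stack([
            (sub["luminance"] - sub["luminance"].mean())
            / (sub["luminance"].std() or 1.0),
            (sub["gcc"] - sub["gcc"].mean()) / (sub["gcc"].std() or 1.0),
        ])
        km = KMeans(n_clusters=2, n_init=4, random_state=0).fit(X)
        labels = km.labels_
        lum_c = [sub["luminance"][labels == k].mean() for k in (0, 1)]
        gcc_c = [sub["gcc"][labels == k].mean() for k in (0, 1)]
        # drop the snow/fog cluster only when it is brighter AND less green
        drop_k = None
        for k in (0, 1):
            other = 1 - k
            if lum_c[k] > lum_c[other] and gcc_c[k] < gcc_c[other]:
                drop_k = k
        if drop_k is not None:
            bad_idx = sub.index[labels == drop_k]
            reject(feats.loc[bad_idx], "cluster")
            keep.loc[bad_idx] = False

    retained = feats[keep].drop(columns="index").reset_index(drop=True)
    log = pd.DataFrame(rejections, columns=["filename", "timestamp", "rule"])
    return retained, log


def percentile_smooth(retained: pd.DataFrame, window_days: int = 4,
                      percentile: float = 90.0,
                      anchor: str = "trailing") -> pd.DataFrame:
    """Daily GCC series as a moving-window percentile of per-image values.

    For each calendar day ``d`` the smoothed value is the ``percentile``-th
    percentile (linear interpolation between order statistics) of all
    retained per-image GCC values whose timestamp falls in the window —
    trailing ``[d - window_days + 1, d]`` by default, or centred when
    ``anchor='centered'``.  Days whose window holds no retained image get a
    missing value.
    """
    if window_days < 1:
        raise PhenocamError("window_days must be >= 1")
    if not 0 <= percentile <= 100:
        raise PhenocamError("percentile must lie in [0, 100]")
    if retained.empty:
        return pd.DataFrame(columns=["date", "gcc_smoothed", "n_images"])
    days = retained["timestamp"].dt.normalize()
    values = retained["gcc"].to_numpy()
    all_days = pd.date_range(days.min(), days.max(), freq="D")
    if anchor == "trailing":
        lo_off, hi_off = -(window_days - 1), 0
    elif anchor == "centered":
        lo_off = -((window_days - 1) // 2)
        hi_off = window_days - 1 + lo_off
    else:
        raise PhenocamError(f"unknown anchor {anchor!r}")
    rows = []
    day_arr = days.to_numpy()
    for d in all_days:
        lo = (d + pd.Timedelta(days=lo_off)).to_numpy()
        hi = (d + pd.Timedelta(days=hi_off)).to_numpy()
        sel = (day_arr >= lo) & (day_arr <= hi)
        n = int(sel.sum())
        val = float(np.percentile(values[sel], percentile)) if n else np.nan
        rows.append({"date": d, "gcc_smoothed": val, "n_images": n})
    return pd.DataFrame(rows)


def daily_maximum(retained: pd.DataFrame) -> pd.DataFrame:
    """Daily maximum GCC series (window 1, percentile 100)."""
    return percentile_smooth(retained, window_days=1, percentile=100.0)


def extract_gcc_series(records: list[ImageRecord], mask: ROIMask | None = None,
                       rules: QCRules | None = None, window_days: int = 4,
                       percentile: float = 90.0) -> dict:
    """Full extraction: QC, per-image GCC, smoothed daily series.

    Returns a dict with ``images`` (retained per-image frame), ``daily``
    (smoothed series), ``daily_max`` and ``rejections``.
    """
    retained, log = qc_filter(records, rules, mask)
    daily = percentile_smooth(retained, window_days, percentile)
    return {"images": retained, "daily": daily,
            "daily_max": daily_maximum(retained), "rejections": log}
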