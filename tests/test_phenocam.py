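"""GCC arithmetic, ROI means, QC filtering and percentile smoothing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nivophen.phenocam import (ImageRecord, PhenocamError, QCRules, ROIMask,
                               compute_gcc, daily_maximum, extract_roi_mean,
                               percentile_smooth, qc_filter)


def record(ts="2020-07-15 12:00", exposure=0.1, ratio=5.0, rgb=(60, 90, 60),
           name="img.png"):
    return ImageRecord(filename=name, timestamp=ts, exposure_time_s=exposure,
                       exposure_ratio=ratio, roi_mean_rgb=rgb)


class TestGCC:
    @pytest.mark.parametrize("c", [1.0, 17.5, 255.0])
    def test_grey_pixel_is_exactly_one_third(self, c):
        assert compute_gcc((c, c, c)) == pytest.approx(1.0 / 3.0, abs=0)

    def test_pure_green_is_one(self):
        assert compute_gcc((0.0, 42.0, 0.0)) == 1.0

    def test_direct_arithmetic(self):
        assert compute_gcc((30, 60, 10)) == pytest.approx(0.6)

    def test_zero_sum_is_undefined(self):
        with pytest.raises(PhenocamError):
            compute_gcc((0.0, 0.0, 0.0))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(r=st.floats(0.01, 250), g=st.floats(0.01, 250),
           b=st.floats(0.01, 250), k=st.floats(0.01, 100))
    def test_scale_invariance_and_open_unit_interval(self, r, g, b, k):
        v = compute_gcc((r, g, b))
        assert 0 < v < 1
        assert compute_gcc((k * r, k * g, k * b)) == pytest.approx(v, rel=1e-9)


class TestROIMean:
    def test_uniform_image(self):
        px = np.tile(np.array([10.0, 20.0, 30.0]), (4, 4, 1))
        rec = ImageRecord("u.png", "2020-07-01 12:00", 0.1, 5.0, pixels=px)
        assert extract_roi_mean(rec) == (10.0, 20.0, 30.0)

    def test_mask_excludes_pixels(self):
        px = np.zeros((1, 2, 3))
        px[0, 1] = (9.0, 9.0, 9.0)
        mask = ROIMask(np.array([[False, True]]))
        rec = ImageRecord("m.png", "2020-07-01 12:00", 0.1, 5.0, pixels=px)
        assert extract_roi_mean(rec, mask) == (9.0, 9.0, 9.0)

    def test_matches_per_channel_loop_oracle(self, rng):
        px = rng.uniform(0, 255, size=(8, 8, 3))
        mask = ROIMask(rng.random((8, 8)) > 0.4)
        rec = ImageRecord("o.png", "2020-07-01 12:00", 0.1, 5.0, pixels=px)
        got = extract_roi_mean(rec, mask)
        for ch in range(3):
            vals = [px[i, j, ch] for i in range(8) for j in range(8)
                    if mask.mask[i, j]]
            assert got[ch] == pytest.approx(np.mean(vals))

    def test_dimension_mismatch_raises(self):
        rec = ImageRecord("d.png", "2020-07-01 12:00", 0.1, 5.0,
                          pixels=np.zeros((4, 4, 3)))
        with pytest.raises(PhenocamError):
            extract_roi_mean(rec, ROIMask(np.ones((5, 5), dtype=bool)))

    def test_empty_mask_rejected(self):
        with pytest.raises(PhenocamError):
            ROIMask(np.zeros((4, 4), dtype=bool))


class TestQCFilter:
    def test_long_exposure_rejected(self):
        retained, log = qc_filter([record(exposure=60.0)])
        assert retained.empty
        assert log["rule"].tolist() == ["exposure_time"]

    def test_low_exposure_ratio_rejected(self):
        _, log = qc_filter([record(ratio=1.5)])
        assert log["rule"].tolist() == ["exposure_ratio"]

    def test_early_morning_rejected(self):
        _, log = qc_filter([record(ts="2020-07-15 09:00")])
        assert log["rule"].tolist() == ["time_of_day"]

    def test_typical_image_retained(self):
        retained, log = qc_filter([record(exposure=10.0, ratio=5.0,
                                          ts="2020-07-15 12:00")])
        assert len(retained) == 1 and log.empty

    def test_lenient_mode_keeps_short_exposure_outside_window(self):
        rules = QCRules(lenient_time=True)
        retained, _ = qc_filter([record(ts="2020-07-15 08:00", exposure=0.05)],
                                rules)
        assert len(retained) == 1

    def test_metadata_rules_monotone_under_relaxation(self, rng):
        records = [record(ts=f"2020-07-{d:02d} {h:02d}:00",
                          exposure=float(e), ratio=float(r),
                          name=f"i{d}{h}.png")
                   for d, h, e, r in zip(
                       rng.integers(1, 28, 60), rng.integers(6, 20, 60),
                       rng.uniform(0, 80, 60), rng.uniform(0, 10, 60))]
        # statistical filters off: monotonicity is a per-record guarantee
        base = QCRules(brightness_band=None, cluster_filter=False)
        kept_base, _ = qc_filter(records, base)
        relaxations = [
            QCRules(max_exposure_s=80.0, brightness_band=None,
                    cluster_filter=False),
            QCRules(min_exposure_ratio=0.0, brightness_band=None,
                    cluster_filter=False),
            QCRules(time_window=(6, 20), brightness_band=None,
                    cluster_filter=False),
        ]
        for rules in relaxations:
            kept, _ = qc_filter(records, rules)
            assert set(kept_base["filename"]) <= set(kept["filename"])

    def test_cluster_filter_drops_bright_grey_group(self, rng):
        normal = [record(ts=f"2020-07-01 {h:02d}:00", rgb=(55, 95, 60),
                         name=f"n{h}{i}.png")
                  for h in range(10, 17) for i in range(3)]
        foggy = [record(ts=f"2020-07-02 {h:02d}:00", rgb=(180, 182, 178),
                        name=f"f{h}.png") for h in range(10, 14)]
        rules = QCRules(brightness_band=None)   # isolate the cluster rule
        retained, log = qc_filter(normal + foggy, rules)
        assert set(log["rule"]) == {"cluster"}
        assert not any(f.startswith("f") for f in retained["filename"])


class TestPercentileSmooth:
    def make_frame(self, values, start="2020-07-01 12:00", freq="D"):
        ts = pd.date_range(start, periods=len(values), freq=freq)
        return pd.DataFrame({"timestamp": ts, "gcc": values})

    def test_constant_series_unchanged(self):
        out = percentile_smooth(self.make_frame([0.40] * 10))
        assert np.allclose(out["gcc_smoothed"], 0.40)

    def test_window_one_single_image_identity(self):
        vals = [0.35, 0.40, 0.42, 0.38]
        out = percentile_smooth(self.make_frame(vals), window_days=1)
        assert np.allclose(out["gcc_smoothed"], vals)

    def test_matches_brute_force_percentile_oracle(self, rng):
        n = 120
        ts = pd.to_datetime("2020-07-01") + pd.to_timedelta(
            rng.uniform(0, 20 * 24, n), unit="h")
        frame = pd.DataFrame({"timestamp": ts,
                              "gcc": rng.uniform(0.3, 0.5, n)})
        out = percentile_smooth(frame, window_days=4, percentile=90)
        for r in out.itertuples():
            d = pd.Timestamp(r.date)
            sel = [g for t, g in zip(frame["timestamp"], frame["gcc"])
                   if d - pd.Timedelta(days=3) <= t.normalize() <= d]
            if sel:
                assert r.gcc_smoothed == pytest.approx(
                    float(np.percentile(sel, 90)))
            else:
                assert np.isnan(r.gcc_smoothed)

    def test_window_one_percentile_100_is_daily_maximum(self, rng):
        n = 80
        ts = pd.to_datetime("2020-07-01") + pd.to_timedelta(
            rng.uniform(0, 10 * 24, n), unit="h")
        frame = pd.DataFrame({"timestamp": ts,
                              "gcc": rng.uniform(0.3, 0.5, n)})
        p100 = percentile_smooth(frame, window_days=1, percentile=100)
        dmax = daily_maximum(frame)
        assert np.allclose(p100["gcc_smoothed"], dmax["gcc_smoothed"],
                           equal_nan=True)
        by_day = frame.groupby(frame["timestamp"].dt.normalize())["gcc"].max()
        got = p100.dropna(subset=["gcc_smoothed"]).set_index("date")
        assert np.allclose(got["gcc_smoothed"], by_day.loc[got.index])

    def test_gap_days_marked_missing(self):
        frame = self.make_frame([0.4, 0.41])
        frame.loc[1, "timestamp"] += pd.Timedelta(days=10)
        out = percentile_smooth(frame, window_days=1)
        assert out["gcc_smoothed"].isna().sum() == 10
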