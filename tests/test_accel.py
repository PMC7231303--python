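import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from movecomp import accel
from movecomp.accel import (DailySummary, EpochSeries, classify_epoch,
                            impute_nonwear, spectrum_bin, summarize_day,
                            weight_week)


def make_series(n_days=3, epoch_s=3600, enmo=10.0, start="2015-01-05"):
    """Coarse hourly series helper for imputation tests."""
    per_day = 86400 // epoch_s
    ts = pd.Timestamp(start) + pd.to_timedelta(
        np.arange(n_days * per_day) * epoch_s, unit="s")
    df = pd.DataFrame({"timestamp": ts,
                       "enmo_mg": np.full(n_days * per_day, float(enmo)),
                       "wear": True, "sleep": False})
    return df, per_day


class TestClassify:
    @pytest.mark.parametrize("enmo,expected", [
        (30, "SED"), (0, "SED"), (34.999, "SED"),
        (35, "LPA"), (100, "LPA"), (200, "LPA"),
        (200.001, "MVPA"), (250, "MVPA"),
    ])
    def test_thresholds(self, enmo, expected):
        assert classify_epoch(enmo) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_epoch(-1.0)


class TestSpectrumBin:
    @pytest.mark.parametrize("enmo,band", [
        (10, 0), (24.999, 0), (25, 1), (30, 1), (799.9, 31),
        (800, 32), (900, 32), (5000, 32),
    ])
    def test_bins(self, enmo, band):
        assert spectrum_bin(enmo) == band

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            spectrum_bin(-0.1)

    @given(st.floats(min_value=0, max_value=2000, allow_nan=False))
    def test_band_contains_value(self, enmo):
        b = spectrum_bin(enmo)
        lo, hi = accel.band_edges()[b]
        assert lo <= enmo < hi or (b == accel.N_BANDS - 1 and enmo >= lo)


class TestImputeNonwear:
    def test_hand_computed_mean(self):
        df, per_day = make_series(n_days=3)
        df.loc[df.index[10], "enmo_mg"] = 20.0            # day 1, 10:00
        df.loc[df.index[per_day + 10], "enmo_mg"] = 40.0  # day 2, 10:00
        i3 = 2 * per_day + 10                             # day 3, 10:00
        df.loc[df.index[i3], ["wear", "enmo_mg"]] = [False, 0.0]
        out = impute_nonwear(EpochSeries("p", df, 3600))
        assert out.data.loc[i3, "enmo_mg"] == pytest.approx(30.0)
        assert out.data.loc[i3, "imputed"]

    def test_no_nonwear_is_identity(self):
        df, _ = make_series()
        out = impute_nonwear(EpochSeries("p", df, 3600))
        pd.testing.assert_frame_equal(out.data.drop(columns="imputed"), df)

    def test_untouched_epochs_bit_identical(self):
        df, per_day = make_series(n_days=3)
        df["enmo_mg"] = np.arange(len(df), dtype=float)
        df.loc[df.index[5], ["wear", "enmo_mg"]] = [False, 0.0]
        out = impute_nonwear(EpochSeries("p", df, 3600))
        mask = out.data.index != 5
        assert (out.data.loc[mask, "enmo_mg"].to_numpy()
                == df.loc[mask, "enmo_mg"].to_numpy()).all()

    def test_slot_nonwear_everywhere_unimputable(self):
        df, per_day = make_series(n_days=3)
        for d in range(3):
            df.loc[df.index[d * per_day + 3], ["wear", "enmo_mg"]] = [False, 0.0]
        out = impute_nonwear(EpochSeries("p", df, 3600))
        at3 = out.data.iloc[[d * per_day + 3 for d in range(3)]]
        assert not at3["imputed"].any()
        # excluded from summaries: one hour missing from each day's classes
        day = summarize_day(out.data.iloc[:per_day], 3600)
        assert day.sed_min + day.lpa_min + day.mvpa_min == pytest.approx(23 * 60.0)

    def test_idempotent(self):
        df, per_day = make_series(n_days=3)
        df.loc[df.index[7], ["wear", "enmo_mg"]] = [False, 0.0]
        once = impute_nonwear(EpochSeries("p", df, 3600))
        twice = impute_nonwear(once)
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_single_day_with_nonwear_rejected(self):
        df, _ = make_series(n_days=1)
        df.loc[df.index[0], ["wear", "enmo_mg"]] = [False, 0.0]
        with pytest.raises(ValueError):
            impute_nonwear(EpochSeries("p", df, 3600))


class TestSummarizeDay:
    def test_all_sleep_day(self):
        df, _ = make_series(n_days=1)
        df["sleep"] = True
        day = summarize_day(df, 3600)
        assert day.sed_min == day.lpa_min == day.mvpa_min == 0
        assert day.sleep_min == pytest.approx(1440.0)
        assert day.spectrum.sum() == 0

    def test_twelve_lpa_epochs_at_5s(self):
        ts = pd.Timestamp("2015-01-05") + pd.to_timedelta(np.arange(12) * 5, unit="s")
        df = pd.DataFrame({"timestamp": ts, "enmo_mg": 100.0,
                           "wear": True, "sleep": False})
        day = summarize_day(df, 5)
        assert day.lpa_min == pytest.approx(1.0)
        assert day.sed_min == day.mvpa_min == 0

    def test_empty_day_rejected(self):
        with pytest.raises(ValueError):
            summarize_day(pd.DataFrame(columns=["timestamp", "enmo_mg",
                                                "wear", "sleep"]), 5)

    def test_partition_of_awake_worn_minutes(self, rng):
        per_day = 86400 // 60
        ts = pd.Timestamp("2015-01-05") + pd.to_timedelta(
            np.arange(per_day) * 60, unit="s")
        df = pd.DataFrame({"timestamp": ts,
                           "enmo_mg": rng.uniform(0, 900, per_day),
                           "wear": rng.random(per_day) > 0.1,
                           "sleep": np.arange(per_day) < 500})
        day = summarize_day(df, 60)
        awake_worn = ((~df["sleep"]) & df["wear"]).sum()
        classified = day.sed_min + day.lpa_min + day.mvpa_min
        assert classified == pytest.approx(awake_worn * 1.0)
        assert day.spectrum.sum() == pytest.approx(classified)

    def test_spectrum_mvpa_consistency(self, rng):
        # away from the 200 m*g* boundary, bands >=200 add up to MVPA minutes
        n = 600
        ts = pd.Timestamp("2015-01-05") + pd.to_timedelta(np.arange(n) * 60, unit="s")
        enmo = rng.uniform(0, 900, n)
        enmo = enmo[np.abs(enmo - 200) > 5][:500]
        df = pd.DataFrame({"timestamp": ts[:len(enmo)], "enmo_mg": enmo,
                           "wear": True, "sleep": False})
        day = summarize_day(df, 60)
        high = day.spectrum[8:].sum()  # bands with lower edge >= 200
        assert high == pytest.approx(day.mvpa_min)


def _day(date, wear_h, sed, weekend=False):
    return DailySummary(date=pd.Timestamp(date), is_weekend=weekend,
                        wear_hours=wear_h, sleep_min=500.0, sed_min=sed,
                        lpa_min=250.0, mvpa_min=50.0,
                        spectrum=np.full(accel.N_BANDS, sed / accel.N_BANDS))


class TestWeightWeek:
    def test_printed_weighting_formula(self):
        days = ([_day(f"2015-01-0{d}", 20, 500.0) for d in range(5, 10)]
                + [_day("2015-01-10", 20, 570.0, weekend=True),
                   _day("2015-01-11", 20, 570.0, weekend=True)])
        out = weight_week(days)
        assert out.sed_min == pytest.approx((500 * 5 + 570 * 2) / 7)
        assert out.valid

    def test_identical_days_identity(self):
        days = [_day(f"2015-01-{d:02d}", 20, 540.0, weekend=d >= 10)
                for d in range(5, 12)]
        out = weight_week(days)
        assert out.sed_min == pytest.approx(540.0)

    def test_three_valid_days_invalid(self):
        days = [_day("2015-01-05", 20, 500.0),
                _day("2015-01-06", 20, 500.0),
                _day("2015-01-10", 20, 500.0, weekend=True),
                _day("2015-01-07", 10, 500.0)]  # short wear: not valid
        out = weight_week(days)
        assert out.n_valid_days == 3
        assert not out.valid

    def test_no_weekend_day_invalid(self):
        days = [_day(f"2015-01-0{d}", 20, 500.0) for d in range(5, 10)]
        out = weight_week(days)
        assert out.n_valid_weekend_days == 0
        assert not out.valid

    def test_validity_rule(self):
        days = ([_day(f"2015-01-0{d}", 17, 500.0) for d in range(5, 8)]
                + [_day("2015-01-10", 17, 500.0, weekend=True)])
        out = weight_week(days)
        assert out.n_valid_days == 4 and out.n_valid_weekend_days == 1
        assert out.valid


class TestEpochSeriesValidation:
    def test_irregular_timestamps_rejected(self):
        df, _ = make_series(n_days=1)
        df.loc[df.index[3], "timestamp"] += pd.Timedelta(seconds=5)
        with pytest.raises(ValueError):
            EpochSeries("p", df, 3600)

    def test_negative_worn_enmo_rejected(self):
        df, _ = make_series(n_days=1)
        df.loc[df.index[0], "enmo_mg"] = -5.0
        with pytest.raises(ValueError):
            EpochSeries("p", df, 3600)


def test_epoch_csv_round_trip(tmp_path):
    df, _ = make_series(n_days=2)
    df.loc[df.index[4], ["wear", "enmo_mg"]] = [False, 0.0]
    series = EpochSeries("p01", df, 3600)
    path = tmp_path / "epochs.csv"
    accel.write_epochs_csv([series], path)
    back = accel.read_epochs_csv(path)
    assert len(back) == 1
    assert back[0].participant_id == "p01"
    assert back[0].epoch_s == 3600
    pd.testing.assert_frame_equal(back[0].data, df.reset_index(drop=True))


def test_summaries_to_frame_columns():
    days = ([_day(f"2015-01-0{d}", 20, 500.0) for d in range(5, 9)]
            + [_day("2015-01-10", 20, 570.0, weekend=True)])
    frame = accel.summaries_to_frame([weight_week(days, participant_id="x")])
    for col in ("sleep_min", "sed_min", "lpa_min", "mvpa_min",
                "n_valid_days", "valid", "spec_000_025", "spec_800_plus"):
        assert col in frame.columns
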