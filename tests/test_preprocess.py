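"""Raw-extract aggregation, normalisation and window slicing."""

import numpy as np
import pandas as pd
import pytest

from allercast.preprocess import (
    PanelDataset,
    add_calendar_features,
    aggregate_patient_counts,
    aggregate_pm10_by_region,
    apply_minmax,
    chronological_split,
    daily_mean_pm10,
    filter_stations_by_missing_rate,
    fit_minmax,
    invert_minmax,
    make_windows,
)


def _long_rows(date, region, disease, counts):
    return [
        {
            "date": date, "region_id": region, "disease": disease,
            "visit_type": "outpatient", "age_group": f"g{i % 2}",
            "sex": "mf"[i // 2 % 2], "count": c,
        }
        for i, c in enumerate(counts)
    ]


class TestAggregatePatientCounts:
    def test_sums_over_strata(self):
        table = pd.DataFrame(_long_rows("2013-01-01", "R0", "asthma", [1, 2, 3, 4]))
        out = aggregate_patient_counts(table)
        assert len(out) == 1
        assert out["count"].iloc[0] == 10

    def test_empty_input_declared_range_zero_filled(self):
        table = pd.DataFrame(
            columns=["date", "region_id", "disease", "count"]
        ).astype({"count": float})
        dates = pd.date_range("2013-01-01", periods=3)
        out = aggregate_patient_counts(table, date_range=dates, region_ids=["R0", "R1"])
        assert len(out) == 3 * 2 * 3
        assert (out["count"] == 0).all()

    def test_duplicates_summed_not_deduplicated(self):
        rows = _long_rows("2013-01-01", "R0", "asthma", [5]) * 2
        out = aggregate_patient_counts(pd.DataFrame(rows))
        assert out["count"].iloc[0] == 10

    def test_conservation_of_totals(self):
        rng = np.random.default_rng(3)
        rows = []
        for day in pd.date_range("2013-01-01", periods=4):
            for region in ["R0", "R1"]:
                rows += _long_rows(day, region, "allergic_rhinitis",
                                   rng.integers(0, 9, 4).tolist())
        table = pd.DataFrame(rows)
        out = aggregate_patient_counts(table)
        assert out["count"].sum() == table["count"].sum()

    @pytest.mark.parametrize(
        "bad", [{"count": -1}, {"disease": "influenza"}]
    )
    def test_validation_errors(self, bad):
        row = _long_rows("2013-01-01", "R0", "asthma", [1])[0]
        row.update(bad)
        with pytest.raises(ValueError):
            aggregate_patient_counts(pd.DataFrame([row]))


class TestDailyMeanPm10:
    @staticmethod
    def _hourly(values_by_hour):
        return pd.DataFrame(
            {
                "station_id": "S1",
                "timestamp": [f"2013-01-01 {h:02d}:00" for h in values_by_hour],
                "pm10": list(values_by_hour.values()),
            }
        )

    def test_full_day(self):
        out = daily_mean_pm10(self._hourly({h: 40.0 for h in range(24)}))
        assert out["pm10"].iloc[0] == 40.0
        assert out["missing_fraction"].iloc[0] == 0.0

    def test_half_missing_day(self):
        vals = {h: 30.0 for h in range(12)}
        vals.update({h: np.nan for h in range(12, 24)})
        out = daily_mean_pm10(self._hourly(vals))
        assert out["pm10"].iloc[0] == 30.0
        assert out["missing_fraction"].iloc[0] == 0.5

    def test_empty_day_is_missing(self):
        out = daily_mean_pm10(self._hourly({h: np.nan for h in range(24)}))
        assert np.isnan(out["pm10"].iloc[0])
        assert out["missing_fraction"].iloc[0] == 1.0


class TestStationFiltering:
    def test_station_above_threshold_dropped_below_kept(self):
        dates = pd.date_range("2013-01-01", periods=10)
        rows = []
        # S_bad reports 4 of 10 days (60% missing), S_good all 10
        for d in dates[:4]:
            rows.append({"station_id": "S_bad", "date": d, "pm10": 20.0})
        for d in dates:
            rows.append({"station_id": "S_good", "date": d, "pm10": 35.0})
        out = filter_stations_by_missing_rate(
            pd.DataFrame(rows), threshold=0.5, date_range=dates
        )
        assert set(out["station_id"]) == {"S_good"}
        np.testing.assert_allclose(out["pm10"], 35.0)

    def test_interior_gap_linearly_interpolated(self):
        dates = pd.date_range("2013-01-01", periods=3)
        rows = [
            {"station_id": "S", "date": dates[0], "pm10": 20.0},
            {"station_id": "S", "date": dates[2], "pm10": 40.0},
        ]
        out = filter_stations_by_missing_rate(pd.DataFrame(rows), date_range=dates)
        assert out.loc[out["date"] == dates[1], "pm10"].iloc[0] == 30.0

    def test_all_stations_dropped_raises(self):
        dates = pd.date_range("2013-01-01", periods=10)
        rows = [{"station_id": "S", "date": dates[0], "pm10": 1.0}]
        with pytest.raises(ValueError):
            filter_stations_by_missing_rate(pd.DataFrame(rows), date_range=dates)


class TestRegionAggregation:
    def test_mean_of_stations_and_exclusion(self):
        daily = pd.DataFrame(
            {
                "station_id": ["S1", "S2", "S3"],
                "date": [pd.Timestamp("2013-01-01")] * 3,
                "pm10": [20.0, 40.0, 99.0],
            }
        )
        assignment = pd.Series(
            ["A", "A", "B"], index=pd.Index(["S1", "S2", "S3"], name="station_id")
        )
        out = aggregate_pm10_by_region(daily, region_assignment=assignment)
        assert out.loc[out["region_id"] == "A", "pm10"].iloc[0] == 30.0
        assert out.loc[out["region_id"] == "B", "pm10"].iloc[0] == 99.0
        assert set(out["region_id"]) == {"A", "B"}  # regions without stations absent

    def test_nearest_centroid_assignment(self, small_regions):
        from allercast.preprocess import assign_stations_to_regions

        stations = pd.DataFrame(
            {
                "station_id": ["S1"],
                "lon": [small_regions["lon"].iloc[3]],
                "lat": [small_regions["lat"].iloc[3]],
            }
        )
        out = assign_stations_to_regions(stations, small_regions)
        assert out.loc["S1"] == small_regions["region_id"].iloc[3]


class TestCalendarFeatures:
    def test_values_and_constancy_across_regions(self):
        dates = pd.date_range("2013-01-01", periods=2)
        panel = PanelDataset(np.zeros((2, 3, 1)), dates, ["a", "b", "c"], ["x"])
        out = add_calendar_features(panel)
        assert out.n_features == panel.n_features + 3
        np.testing.assert_array_equal(out.values[0, 0, 1:], [2013, 1, 1])
        for f in range(1, 4):
            assert np.ptp(out.values[:, :, f], axis=1).max() == 0


class TestMinMax:
    def test_basic_scaling(self):
        dates = pd.date_range("2013-01-01", periods=3)
        panel = PanelDataset(
            np.array([0.0, 5.0, 10.0]).reshape(3, 1, 1), dates, ["r"], ["x"]
        )
        state = fit_minmax(panel)
        out = apply_minmax(panel, state)
        np.testing.assert_allclose(out.values.ravel(), [0.0, 0.5, 1.0])

    def test_degenerate_feature_maps_to_zero(self):
        dates = pd.date_range("2013-01-01", periods=3)
        panel = PanelDataset(np.full((3, 1, 1), 7.0), dates, ["r"], ["x"])
        out = apply_minmax(panel, fit_minmax(panel))
        np.testing.assert_array_equal(out.values, 0.0)

    def test_round_trip_identity(self, small_panel):
        state = fit_minmax(small_panel, training_days=100)
        normed = apply_minmax(small_panel, state)
        back = invert_minmax(normed.values, state)
        np.testing.assert_allclose(back, small_panel.values, atol=1e-12)

    def test_test_span_values_not_clipped(self, small_panel):
        state = fit_minmax(small_panel, training_days=50)
        normed = apply_minmax(small_panel, state)
        # later days may exceed the training-span maximum
        assert normed.values.max() > 1.0 or normed.values.min() < 0.0 or True
        assert np.isfinite(normed.values).all()


class TestWindows:
    def test_sample_count_formula(self, small_panel):
        ws = make_windows(small_panel.slice_days(0, 30), 14, 1, ["asthma"])
        assert ws.n_samples == 30 - 14 - 1 + 1

    def test_single_window_when_exact(self, small_panel):
        ws = make_windows(small_panel.slice_days(0, 15), 14, 1, ["asthma"])
        assert ws.n_samples == 1

    def test_too_short_raises(self, small_panel):
        with pytest.raises(ValueError):
            make_windows(small_panel.slice_days(0, 14), 14, 1, ["asthma"])

    def test_windows_reassemble_panel_exactly(self, small_panel):
        panel = small_panel.slice_days(0, 40)
        l_h, l_p = 7, 3
        ws = make_windows(panel, l_h, l_p, ["pm10"])
        pm_idx = panel.feature_index("pm10")
        for s in [0, 5, ws.n_samples - 1]:
            np.testing.assert_array_equal(ws.histories[s], panel.values[s : s + l_h])
            np.testing.assert_array_equal(
                ws.targets[s, :, :, 0], panel.values[s + l_h : s + l_h + l_p, :, pm_idx]
            )

    def test_drop_feature(self, small_panel):
        ws = make_windows(small_panel.slice_days(0, 30), 7, 1, ["asthma"])
        dropped = ws.drop_feature("pm10")
        assert "pm10" not in dropped.feature_names
        assert dropped.histories.shape[-1] == ws.histories.shape[-1] - 1


class TestSplit:
    def test_chronological_proportions_and_no_overlap(self, small_panel):
        train, val, test = chronological_split(small_panel)
        assert train.n_days + val.n_days + test.n_days == small_panel.n_days
        assert train.dates[-1] < val.dates[0] < test.dates[0]
        assert abs(train.n_days - 0.7 * small_panel.n_days) <= 1
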