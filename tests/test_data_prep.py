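import calendar
import io
from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from airseg.data_prep import (
    CaseTable,
    MonitoringSeries,
    VariableSpec,
    apportion,
    build_case_table,
    encode_time,
    expected_case_count,
    read_monitoring_csv,
    split_train_valid_test,
)
from airseg.errors import SchemaError


def csv_of(text: str) -> io.StringIO:
    return io.StringIO(text.strip() + "\n")


class TestReadMonitoringCsv:
    def test_blank_cell_becomes_missing(self):
        buf = csv_of(
            "timestamp,so2_col,o3_col\n"
            "2011-01-01T00:00:00,5.0,40\n"
            "2011-01-01T01:00:00,,41\n"
            "2011-01-01T02:00:00,6.0,42"
        )
        s = read_monitoring_csv(buf, {"SO2": "so2_col", "O3": "o3_col"})
        assert len(s) == 3
        assert np.isnan(s.data["SO2"].iloc[1])
        assert s.data["O3"].notna().all()

    def test_grid_gap_filled_with_missing_row(self):
        buf = csv_of(
            "timestamp,O3\n2011-01-01T00:00:00,40\n2011-01-01T02:00:00,42"
        )
        s = read_monitoring_csv(buf, {"O3": "O3"})
        assert len(s) == 3
        assert np.isnan(s.data["O3"].iloc[1])

    def test_duplicate_timestamp_is_named(self):
        buf = csv_of(
            "timestamp,O3\n"
            "2011-01-01T04:00:00,1\n2011-01-01T05:00:00,2\n"
            "2011-01-01T05:00:00,3"
        )
        with pytest.raises(SchemaError, match="05:00"):
            read_monitoring_csv(buf, {"O3": "O3"})

    def test_unknown_schema_variable_rejected(self):
        buf = csv_of("timestamp,x\n2011-01-01T00:00:00,1")
        with pytest.raises(SchemaError, match="NOX"):
            read_monitoring_csv(buf, {"NOX": "x"})

    def test_negative_concentration_cell_rejected_not_clipped(self):
        buf = csv_of(
            "timestamp,NO,T\n2011-01-01T00:00:00,-3.0,-5.0\n"
            "2011-01-01T01:00:00,2.0,-4.0"
        )
        s = read_monitoring_csv(buf, {"NO": "NO", "T": "T"})
        assert np.isnan(s.data["NO"].iloc[0])
        assert s.data["T"].iloc[0] == -5.0  # temperature may be negative

    def test_non_numeric_cell_becomes_missing(self):
        buf = csv_of(
            "timestamp,O3\n2011-01-01T00:00:00,NA\n2011-01-01T01:00:00,40"
        )
        s = read_monitoring_csv(buf, {"O3": "O3"})
        assert np.isnan(s.data["O3"].iloc[0])


class TestMonitoringSeriesInvariants:
    def _frame(self, values, var="O3"):
        idx = pd.date_range("2011-01-01", periods=len(values), freq="h")
        return pd.DataFrame({var: values}, index=idx)

    def test_negative_concentration_invalid(self):
        with pytest.raises(SchemaError, match="negative"):
            MonitoringSeries("s", self._frame([1.0, -2.0]))

    def test_rh_out_of_range_invalid(self):
        with pytest.raises(SchemaError, match="RH"):
            MonitoringSeries("s", self._frame([50.0, 101.0], var="RH"))

    def test_unknown_column_invalid(self):
        idx = pd.date_range("2011-01-01", periods=2, freq="h")
        with pytest.raises(SchemaError, match="unknown"):
            MonitoringSeries("s", pd.DataFrame({"XX": [1, 2]}, index=idx))

    def test_non_hourly_spacing_invalid(self):
        idx = pd.DatetimeIndex(["2011-01-01 00:00", "2011-01-01 02:00"])
        with pytest.raises(SchemaError, match="1 h"):
            MonitoringSeries("s", pd.DataFrame({"O3": [1.0, 2.0]}, index=idx))


class TestEncodeTime:
    def test_linear_new_year(self):
        assert encode_time("2011-01-01T00:00", "linear") == (1.0, 0.0)

    def test_linear_mid_june(self):
        # calendar oracle: 31+28+31+30+31+15 = 166
        assert encode_time("2011-06-15T13:00", "linear") == (166.0, 13.0)

    def test_cosine_no_midnight_discontinuity(self):
        h = [encode_time(f"2011-01-01T{hr:02d}:00", "cosine")[1] for hr in range(24)]
        # wrap-around step equals its mirror-image step by cosine symmetry
        assert abs(h[23] - h[0]) == pytest.approx(abs(h[0] - h[1]))
        assert all(-1.0 <= v <= 1.0 for v in h)

    def test_cosine_day_peaks_mid_year(self):
        d_jan = encode_time("2011-01-01T00:00", "cosine")[0]
        d_jul = encode_time("2011-07-02T00:00", "cosine")[0]
        assert d_jul > 0.99 > abs(d_jul) - 0.02
        assert d_jan < -0.99

    def test_unknown_convention(self):
        with pytest.raises(ValueError):
            encode_time("2011-01-01T00:00", "sincos")


class TestExpectedCaseCount:
    def test_six_year_span(self):
        assert expected_case_count(date(2011, 1, 1), date(2016, 12, 31)) == 52_608

    def test_common_year(self):
        assert expected_case_count(date(2011, 1, 1), date(2011, 12, 31)) == 8_760

    def test_leap_year(self):
        assert expected_case_count(date(2012, 1, 1), date(2012, 12, 31)) == 8_784

    def test_start_after_end_rejected(self):
        with pytest.raises(ValueError):
            expected_case_count(date(2012, 1, 2), date(2012, 1, 1))

    @pytest.mark.parametrize("year", range(1901, 2100, 7))
    def test_every_year_matches_leap_rule(self, year):
        expected = 8_760 + 24 * calendar.isleap(year)
        assert expected_case_count(date(year, 1, 1), date(year, 12, 31)) == expected


def toy_series(n_hours=10, missing_at=(), var_names=("O3", "NO", "T")):
    idx = pd.date_range("2011-01-01", periods=n_hours, freq="h")
    rng = np.random.default_rng(0)
    data = pd.DataFrame(
        {v: rng.uniform(1, 10, size=n_hours) for v in var_names}, index=idx
    )
    for hour, var in missing_at:
        data.iloc[hour, data.columns.get_loc(var)] = np.nan
    return MonitoringSeries("toy", data)


class TestBuildCaseTable:
    spec = VariableSpec("O3", ("D", "H", "NO", "T"))

    def test_incomplete_hours_dropped(self):
        series = toy_series(10, missing_at=[(2, "NO"), (7, "O3")])
        table = build_case_table(series, self.spec)
        assert table.n == 8

    def test_missing_required_variable_rejected(self):
        series = toy_series(10)
        spec = VariableSpec("O3", ("D", "H", "CO"))
        with pytest.raises(SchemaError, match="CO"):
            build_case_table(series, spec)

    def test_complete_day_keeps_chronological_order(self):
        series = toy_series(24)
        table = build_case_table(series, self.spec)
        assert table.n == 24
        assert list(table.frame["H"]) == list(range(24))

    def test_zero_surviving_cases_rejected(self):
        series = toy_series(3, missing_at=[(0, "O3"), (1, "O3"), (2, "O3")])
        with pytest.raises(SchemaError, match="no complete cases"):
            build_case_table(series, self.spec)

    def test_kept_plus_removed_equals_source_length(self):
        for miss in ([], [(0, "NO")], [(1, "T"), (5, "O3"), (5, "NO")]):
            series = toy_series(12, missing_at=miss)
            table = build_case_table(series, self.spec)
            removed = len({h for h, _ in miss})
            assert table.n + removed == len(series)

    def test_convention_recorded_in_provenance(self):
        table = build_case_table(toy_series(24), self.spec, convention="cosine")
        assert table.provenance["time_encoding"] == "cosine"
        assert table.frame["H"].between(-1, 1).all()


class TestVariableSpec:
    def test_target_cannot_be_predictor(self):
        with pytest.raises(SchemaError):
            VariableSpec("O3", ("O3", "T"))

    def test_empty_predictors_rejected(self):
        with pytest.raises(SchemaError):
            VariableSpec("O3", ())

    def test_rural_o3_setup_has_11_predictors(self):
        spec = VariableSpec(
            "O3", ("H", "D", "NO", "NO2", "SO2", "CO", "PM10", "WS", "T", "I", "RH")
        )
        assert len(spec.predictors) == 11


class TestSplit:
    def test_exact_fractions_at_n100(self):
        table = toy_series(100).data
        ct = build_case_table(toy_series(100), TestBuildCaseTable.spec)
        split = split_train_valid_test(ct, seed=3)
        assert split.counts == (70, 15, 15)

    def test_largest_remainder_at_n20(self):
        ct = build_case_table(toy_series(20), TestBuildCaseTable.spec)
        split = split_train_valid_test(ct, seed=3)
        assert split.counts == (14, 3, 3)

    def test_deterministic(self):
        ct = build_case_table(toy_series(50), TestBuildCaseTable.spec)
        a = split_train_valid_test(ct, seed=9)
        b = split_train_valid_test(ct, seed=9)
        assert (a.labels == b.labels).all()

    def test_different_seed_differs(self):
        ct = build_case_table(toy_series(200), TestBuildCaseTable.spec)
        a = split_train_valid_test(ct, seed=1)
        b = split_train_valid_test(ct, seed=2)
        assert (a.labels != b.labels).any()

    def test_too_small_rejected(self):
        ct = build_case_table(toy_series(6), TestBuildCaseTable.spec)
        with pytest.raises(ValueError):
            split_train_valid_test(ct, seed=0)

    @given(n=st.integers(min_value=7, max_value=400), seed=st.integers(0, 2**31))
    @settings(max_examples=40, deadline=None)
    def test_partition_within_one_of_fractions(self, n, seed):
        counts = apportion(n, (0.70, 0.15, 0.15))
        assert sum(counts) == n
        for c, f in zip(counts, (0.70, 0.15, 0.15)):
            assert abs(c - n * f) <= 1
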