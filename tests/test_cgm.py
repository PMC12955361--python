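"""CGM ingestion, wear QC, and consensus glycemic metrics."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp

from pa1c.cgm import (
    GlucoseTrace,
    compute_metrics,
    convert_glucose,
    metrics_table,
    pool_metrics,
    qc_wearset,
    read_readings,
    traces_from_frame,
)
from conftest import make_trace_frame, regular_times


def trace(subject="S1", sensor=1, start="2024-01-01", days=12.0, glucose=150.0):
    n = int(days * 96) + 1
    times = regular_times(start, n)
    g = np.full(n, float(glucose)) if np.isscalar(glucose) else np.asarray(glucose)
    return GlucoseTrace(subject, sensor, times, g[:n] if not np.isscalar(glucose) else g)


class TestComputeMetrics:
    def test_constant_trace(self):
        m = compute_metrics(np.full(96, 100.0))
        assert m.mean_glucose == 100.0
        assert m.cv == 0.0
        assert m.pct_in_70_180 == 100.0

    def test_hand_count_five_readings(self):
        m = compute_metrics([50.0, 60.0, 100.0, 200.0, 300.0])
        assert m.pct_below_54 == 20.0
        assert m.pct_below_70 == 40.0
        assert m.pct_in_70_180 == 20.0
        assert m.pct_above_180 == 40.0
        assert m.pct_above_250 == 20.0

    def test_population_sd(self):
        m = compute_metrics([100.0, 300.0])
        assert m.mean_glucose == 200.0
        assert m.sd_glucose == 100.0  # divisor n, not n-1
        assert m.cv == 50.0

    def test_boundary_membership(self):
        # 70 and 180 are in-range; 54/250 band edges are strict
        m = compute_metrics([54.0, 70.0, 180.0, 250.0])
        assert m.pct_below_54 == 0.0
        assert m.pct_below_70 == 25.0
        assert m.pct_in_70_180 == 50.0
        assert m.pct_above_180 == 25.0
        assert m.pct_above_250 == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([])

    @given(
        g=hnp.arrays(
            float,
            st.integers(min_value=1, max_value=300),
            elements=st.floats(min_value=40.0, max_value=500.0),
        )
    )
    def test_band_partition_sums_to_100(self, g):
        m = compute_metrics(g)
        assert m.pct_below_70 + m.pct_in_70_180 + m.pct_above_180 == pytest.approx(
            100.0, abs=1e-9
        )
        assert m.pct_below_54 <= m.pct_below_70
        assert m.pct_above_250 <= m.pct_above_180
        assert m.cv == pytest.approx(100.0 * m.sd_glucose / m.mean_glucose)

    @given(
        g=hnp.arrays(
            float,
            st.integers(min_value=2, max_value=100),
            elements=st.floats(min_value=40.0, max_value=500.0),
        )
    )
    def test_permutation_invariance(self, g):
        a, b = compute_metrics(g), compute_metrics(g[::-1])
        assert a.mean_glucose == pytest.approx(b.mean_glucose)
        assert a.pct_in_70_180 == b.pct_in_70_180


class TestQcWearset:
    def test_three_good_wears_valid(self):
        wears = []
        start = pd.Timestamp("2024-01-01", tz="UTC")
        for k in (1, 2, 3):
            wears.append(trace(sensor=k, start=start, days=12))
            start = wears[-1].times[-1] + pd.Timedelta(hours=24)
        ws = qc_wearset(wears)
        assert ws.protocol_valid
        assert ws.days_covered == pytest.approx([12.0, 12.0, 12.0])
        assert ws.gaps_between_wears == pytest.approx([24.0, 24.0])

    def test_short_wear_invalidates(self):
        wears = []
        start = pd.Timestamp("2024-01-01", tz="UTC")
        for k, d in zip((1, 2, 3), (12, 9.5, 12)):
            wears.append(trace(sensor=k, start=start, days=d))
            start = wears[-1].times[-1] + pd.Timedelta(hours=24)
        ws = qc_wearset(wears)
        assert ws.wear_valid == [True, False, True]
        assert not ws.protocol_valid

    @pytest.mark.parametrize("gap_h, ok", [(48.0, True), (49.0, False)])
    def test_gap_boundary(self, gap_h, ok):
        w1 = trace(sensor=1, days=12)
        w2 = trace(sensor=2, start=w1.times[-1] + pd.Timedelta(hours=gap_h), days=12)
        w3 = trace(sensor=3, start=w2.times[-1] + pd.Timedelta(hours=24), days=12)
        assert qc_wearset([w1, w2, w3]).protocol_valid is ok

    def test_fewer_than_three_wears_invalid(self):
        assert not qc_wearset([trace(sensor=1, days=12)]).protocol_valid

    def test_mixed_subjects_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            qc_wearset([trace(subject="A"), trace(subject="B", sensor=2)])


class TestPooling:
    def test_identical_wears_idempotent(self):
        g = np.linspace(60, 300, 1153)
        w1 = trace(sensor=1, days=12, glucose=g)
        w2 = trace(sensor=2, start=w1.times[-1] + pd.Timedelta(hours=6), days=12, glucose=g)
        w3 = trace(sensor=3, start=w2.times[-1] + pd.Timedelta(hours=6), days=12, glucose=g)
        ws = qc_wearset([w1, w2, w3])
        pooled = pool_metrics(ws, {1, 2})
        single = compute_metrics(g)
        assert pooled.mean_glucose == pytest.approx(single.mean_glucose)
        assert pooled.cv == pytest.approx(single.cv)
        assert pooled.days == pytest.approx(24.0)

    def test_reading_weighted_mean(self):
        # wear1 constant 100 (n readings), wear2 constant 200 (3n readings)
        w1 = trace(sensor=1, days=10, glucose=100.0)
        g2 = np.full(4 * (len(w1.glucose) - 1) + 1, 200.0)
        n2 = len(g2)
        times2 = regular_times(
            w1.times[-1] + pd.Timedelta(hours=6), n2
        )
        w2 = GlucoseTrace("S1", 2, times2, g2)
        ws = qc_wearset([w1, w2])
        n1 = len(w1.glucose)
        expected = (100.0 * n1 + 200.0 * n2) / (n1 + n2)
        assert pool_metrics(ws, {1, 2}).mean_glucose == pytest.approx(expected)

    def test_pool_equals_concatenation_oracle(self):
        rng = np.random.default_rng(0)
        gs = [rng.uniform(50, 400, 1057) for _ in range(3)]
        wears, start = [], pd.Timestamp("2024-01-01", tz="UTC")
        for k, g in enumerate(gs, start=1):
            wears.append(trace(sensor=k, start=start, days=11, glucose=g))
            start = wears[-1].times[-1] + pd.Timedelta(hours=12)
        ws = qc_wearset(wears)
        pooled = pool_metrics(ws, {1, 2, 3})
        oracle = compute_metrics(np.concatenate([w.glucose for w in wears]))
        for f in ("mean_glucose", "sd_glucose", "cv", "pct_below_54", "pct_in_70_180"):
            assert getattr(pooled, f) == pytest.approx(getattr(oracle, f))

    def test_calibration_scope_uses_wears_12_only(self):
        w1 = trace(sensor=1, days=12, glucose=100.0)
        w2 = trace(sensor=2, start=w1.times[-1] + pd.Timedelta(hours=6), days=12, glucose=100.0)
        w3 = trace(sensor=3, start=w2.times[-1] + pd.Timedelta(hours=6), days=12, glucose=400.0)
        ws = qc_wearset([w1, w2, w3])
        assert pool_metrics(ws, {1, 2}).mean_glucose == pytest.approx(100.0)

    def test_missing_or_invalid_wear_rejected(self):
        ws = qc_wearset([trace(sensor=1, days=12)])
        with pytest.raises(ValueError, match="missing"):
            pool_metrics(ws, {1, 2})
        ws_short = qc_wearset([trace(sensor=1, days=5)])
        with pytest.raises(ValueError, match="QC"):
            pool_metrics(ws_short, {1})


class TestReadReadings:
    def _frame(self):
        rows = []
        for sid in ("A", "B"):
            for sensor in (1, 2, 3):
                times = regular_times(f"2024-0{sensor}-01", 8)
                for t, g in zip(times, np.linspace(90, 200, 8)):
                    rows.append((sid, sensor, t.isoformat(), g))
        return make_trace_frame(rows)

    def test_well_formed_file(self, tmp_path):
        path = tmp_path / "readings.csv"
        self._frame().to_csv(path, index=False)
        traces = read_readings(path)
        assert len(traces) == 6
        assert all(t.times.is_monotonic_increasing for t in traces)

    def test_out_of_range_clamped_and_counted(self):
        df = self._frame()
        df.loc[0, "glucose_mgdl"] = 520.0
        traces = traces_from_frame(df)
        clamped = [t for t in traces if t.n_clamped]
        assert len(clamped) == 1 and clamped[0].n_clamped == 1
        assert clamped[0].glucose.max() <= 500.0
        assert 500.0 in clamped[0].glucose

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        self._frame().drop(columns="glucose_mgdl").to_csv(path, index=False)
        with pytest.raises(ValueError, match="glucose_mgdl"):
            read_readings(path)

    def test_duplicate_row_named(self):
        df = self._frame()
        df = pd.concat([df, df.iloc[[3]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            traces_from_frame(df)

    def test_unparseable_timestamp(self):
        df = self._frame()
        df.loc[1, "timestamp"] = "not-a-time"
        with pytest.raises(ValueError, match="timestamp"):
            traces_from_frame(df)

    def test_strictly_increasing_enforced(self):
        times = regular_times("2024-01-01", 4)
        with pytest.raises(ValueError, match="increasing"):
            GlucoseTrace("A", 1, times[[0, 2, 1, 3]], np.full(4, 100.0))


class TestConvertGlucose:
    @pytest.mark.parametrize(
        "mgdl, mmoll", [(250.0, 13.9), (54.0, 3.0), (70.0, 3.9), (180.0, 10.0), (0.0, 0.0)]
    )
    def test_printed_pairs(self, mgdl, mmoll):
        assert round(convert_glucose(mgdl, "mgdl_to_mmoll"), 1) == mmoll

    def test_round_trip(self):
        assert convert_glucose(
            convert_glucose(257.0, "mgdl_to_mmoll"), "mmoll_to_mgdl"
        ) == pytest.approx(257.0, rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            convert_glucose(-5.0, "mgdl_to_mmoll")


def test_metrics_table_scopes():
    wears, start = [], pd.Timestamp("2024-01-01", tz="UTC")
    for k in (1, 2, 3):
        wears.append(trace(sensor=k, start=start, days=12))
        start = wears[-1].times[-1] + pd.Timedelta(hours=24)
    table = metrics_table([qc_wearset(wears)])
    assert set(table["scope"]) == {"wear1", "wear2", "wear3", "wears12", "all"}
    assert (table["pct_in_70_180"] == 100.0).all()
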