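"""CGM ingestion, wear-protocol QC, and consensus glycemic metrics.

The wear protocol is three consecutive blinded sensor wears of 10–14 days
each at a 15-minute cadence, with no more than 48 h between wears; a
subject's protocol is valid only if all three wears cover at least 10 days
and every inter-wear gap is ≤ 48 h.  Metrics follow the international
consensus bands: % time < 54, < 70, 70–180 (inclusive), > 180 and
> 250 mg/dL, plus mean glucose, population SD and CV = 100·SD/mean.

Band boundary convention (ties are unstated in the consensus standard and
pinned here): 70 and 180 are counted in-range; the < and > bands are strict.
Each reading carries equal weight, which at a fixed cadence equals time
weighting; pooling across wears concatenates readings (reading-weighted),
not per-wear means.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GlucoseTrace",
    "WearSet",
    "GlycemicMetrics",
    "SENSOR_MIN",
    "SENSOR_MAX",
    "MGDL_PER_MMOLL",
    "read_readings",
    "traces_from_frame",
    "qc_wearset",
    "compute_metrics",
    "pool_metrics",
    "convert_glucose",
    "metrics_table",
]

logger = logging.getLogger(__name__)

#: Sensor-reportable glucose range, mg/dL.
SENSOR_MIN = 40.0
SENSOR_MAX = 500.0

#: Glucose molar mass / 10: mmol/L = mg/dL / 18.016.
MGDL_PER_MMOLL = 18.016

#: Protocol QC thresholds: minimum days per wear, maximum hours between wears.
MIN_WEAR_DAYS = 10.0
MAX_GAP_HOURS = 48.0

REQUIRED_READING_COLUMNS = ("subject_id", "sensor_index", "timestamp", "glucose_mgdl")


@dataclass
class GlucoseTrace:
    """Timestamped glucose readings for one sensor wear of one subject."""

    subject_id: str
    sensor_index: int
    times: pd.DatetimeIndex
    glucose: np.ndarray
    #: values before clamping to the sensor range, when known
    glucose_preclamp: np.ndarray | None = None
    n_clamped: int = 0

    def __post_init__(self) -> None:
        self.times = pd.DatetimeIndex(self.times)
        self.glucose = np.asarray(self.glucose, dtype=float)
        if not 1 <= int(self.sensor_index) <= 3:
            raise ValueError(f"sensor_index must be 1..3, got {self.sensor_index}")
        if len(self.times) != len(self.glucose):
            raise ValueError("times and glucose must have equal length")
        if len(self.times) == 0:
            raise ValueError("empty trace")
        if not self.times.is_monotonic_increasing or self.times.has_duplicates:
            raise ValueError(
                f"{self.subject_id} wear {self.sensor_index}: "
                "timestamps must be strictly increasing"
            )

    @property
    def days_covered(self) -> float:
        """Timestamp span of the wear in days (gaps inside do not subtract)."""
        span = self.times[-1] - self.times[0]
        return span / pd.Timedelta(days=1)


@dataclass
class WearSet:
    """The ordered ≤3-wear protocol of one subject with QC status."""

    subject_id: str
    wears: list[GlucoseTrace]
    days_covered: list[float]
    wear_valid: list[bool]
    gaps_between_wears: list[float]  # hours
    protocol_valid: bool

    def wear(self, index: int) -> GlucoseTrace:
        for tr in self.wears:
            if tr.sensor_index == index:
                return tr
        raise KeyError(f"{self.subject_id}: wear {index} not present")


@dataclass(frozen=True)
class GlycemicMetrics:
    """Consensus CGM summary for one reading set (a wear or a pool)."""

    mean_glucose: float
    sd_glucose: float
    cv: float
    pct_below_54: float
    pct_below_70: float
    pct_in_70_180: float
    pct_above_180: float
    pct_above_250: float
    n_readings: int
    days: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def clamp_glucose(values, lo: float = SENSOR_MIN, hi: float = SENSOR_MAX) -> np.ndarray:
    """Clamp readings to the sensor-reportable range [lo, hi]."""
    return np.clip(np.asarray(values, dtype=float), lo, hi)


def read_readings(path) -> list[GlucoseTrace]:
    """Read a readings.csv file into per-(subject, sensor) traces.

    Out-of-range glucose is clamped to [40, 500] with the count logged and
    recorded per trace; duplicate (subject, sensor, timestamp) rows and
    missing columns are errors.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_READING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {', '.join(missing)}")
    return traces_from_frame(df, source=str(path))


def traces_from_frame(df: pd.DataFrame, source: str = "<frame>") -> list[GlucoseTrace]:
    """Build sorted, clamped traces from a readings table in memory."""
    missing = [c for c in REQUIRED_READING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{source}: missing required column(s) {', '.join(missing)}")
    df = df.copy()
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{source}: unparseable timestamp: {exc}") from exc
    dup = df.duplicated(subset=["subject_id", "sensor_index", "timestamp"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"{source}: duplicate reading for subject {row['subject_id']} "
            f"sensor {row['sensor_index']} at {row['timestamp']}"
        )
    traces: list[GlucoseTrace] = []
    total_clamped = 0
    for (sid, sensor), grp in df.groupby(["subject_id", "sensor_index"], sort=True):
        grp = grp.sort_values("timestamp")
        raw = grp["glucose_mgdl"].to_numpy(dtype=float)
        clamped = clamp_glucose(raw)
        n_clamped = int(np.sum(clamped != raw))
        total_clamped += n_clamped
        traces.append(
            GlucoseTrace(
                subject_id=str(sid),
                sensor_index=int(sensor),
                times=pd.DatetimeIndex(grp["timestamp"]),
                glucose=clamped,
                glucose_preclamp=raw,
                n_clamped=n_clamped,
            )
        )
    if total_clamped:
        logger.info("clamped %d reading(s) to [%g, %g] mg/dL", total_clamped, SENSOR_MIN, SENSOR_MAX)
    return traces


def qc_wearset(
    traces: list[GlucoseTrace],
    min_days: float = MIN_WEAR_DAYS,
    max_gap_hours: float = MAX_GAP_HOURS,
) -> WearSet:
    """Assemble and QC one subject's wear protocol.

    A wear is valid when its timestamp span is at least ``min_days``; the
    protocol is valid when all three wears are present and valid and every
    gap (end of wear k to start of wear k+1) is at most ``max_gap_hours``.
    """
    if not 1 <= len(traces) <= 3:
        raise ValueError("expected 1–3 traces for one subject")
    subjects = {tr.subject_id for tr in traces}
    if len(subjects) != 1:
        raise ValueError(f"traces from mixed subjects: {sorted(subjects)}")
    sensors = [tr.sensor_index for tr in traces]
    if len(set(sensors)) != len(sensors):
        raise ValueError(f"duplicate sensor_index in {sorted(sensors)}")
    wears = sorted(traces, key=lambda tr: tr.sensor_index)
    days = [tr.days_covered for tr in wears]
    valid = [d >= min_days for d in days]
    gaps = [
        (nxt.times[0] - cur.times[-1]) / pd.Timedelta(hours=1)
        for cur, nxt in zip(wears, wears[1:])
    ]
    protocol_valid = (
        len(wears) == 3 and all(valid) and all(g <= max_gap_hours for g in gaps)
    )
    return WearSet(
        subject_id=wears[0].subject_id,
        wears=wears,
        days_covered=days,
        wear_valid=valid,
        gaps_between_wears=gaps,
        protocol_valid=protocol_valid,
    )


def compute_metrics(glucose, times=None, days: float | None = None) -> GlycemicMetrics:
    """Consensus metrics over a set of readings, each with equal weight.

    ``days`` may be supplied directly (e.g. a sum of per-wear spans when
    pooling); otherwise it is the timestamp span when ``times`` is given,
    else NaN.
    """
    g = np.asarray(glucose, dtype=float)
    if g.size == 0:
        raise ValueError("cannot compute metrics on an empty reading set")
    mean = float(np.mean(g))
    sd = float(np.std(g))  # population SD, divisor n
    pct = lambda mask: 100.0 * float(np.count_nonzero(mask)) / g.size
    if days is None:
        if times is not None:
            times = pd.DatetimeIndex(times)
            days = (times.max() - times.min()) / pd.Timedelta(days=1)
        else:
            days = float("nan")
    return GlycemicMetrics(
        mean_glucose=mean,
        sd_glucose=sd,
        cv=100.0 * sd / mean,
        pct_below_54=pct(g < 54.0),
        pct_below_70=pct(g < 70.0),
        pct_in_70_180=pct((g >= 70.0) & (g <= 180.0)),
        pct_above_180=pct(g > 180.0),
        pct_above_250=pct(g > 250.0),
        n_readings=int(g.size),
        days=float(days),
    )


def pool_metrics(wearset: WearSet, wears_used) -> GlycemicMetrics:
    """Metrics over the concatenated readings of the selected wears.

    Reading-weighted pooling: identical to computing metrics on the
    concatenated reading list.  ``days`` is the sum of per-wear spans (gaps
    between wears are not counted).
    """
    wanted = sorted(set(wears_used))
    if not wanted:
        raise ValueError("wears_used must be non-empty")
    present = {tr.sensor_index: tr for tr in wearset.wears}
    chunks, days = [], 0.0
    for idx in wanted:
        if idx not in present:
            raise ValueError(f"{wearset.subject_id}: wear {idx} missing")
        pos = [tr.sensor_index for tr in wearset.wears].index(idx)
        if not wearset.wear_valid[pos]:
            raise ValueError(f"{wearset.subject_id}: wear {idx} failed QC")
        chunks.append(present[idx].glucose)
        days += wearset.days_covered[pos]
    return compute_metrics(np.concatenate(chunks), days=days)


def convert_glucose(value, direction: str):
    """Convert glucose between mg/dL and mmol/L (divisor 18.016).

    Reporting conventionally rounds mmol/L to one decimal; the unrounded
    value is returned.
    """
    v = np.asarray(value, dtype=float)
    if np.any(v < 0):
        raise ValueError("glucose must be non-negative")
    if direction == "mgdl_to_mmoll":
        out = v / MGDL_PER_MMOLL
    elif direction == "mmoll_to_mgdl":
        out = v * MGDL_PER_MMOLL
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return float(out) if np.ndim(out) == 0 else out


_SCOPES: dict[str, tuple[int, ...]] = {
    "wear1": (1,),
    "wear2": (2,),
    "wear3": (3,),
    "wears12": (1, 2),
    "all": (1, 2, 3),
}


def metrics_table(wearsets: list[WearSet]) -> pd.DataFrame:
    """Tidy per-subject metrics at every computable scope.

    Scopes: wear1..wear3 (always computed when the wear is present) and the
    pooled wears12 / all scopes (only when the constituent wears pass QC).
    """
    rows = []
    for ws in wearsets:
        for scope, idxs in _SCOPES.items():
            present = {tr.sensor_index for tr in ws.wears}
            if not set(idxs) <= present:
                continue
            if len(idxs) == 1:
                tr = ws.wear(idxs[0])
                m = compute_metrics(tr.glucose, times=tr.times)
            else:
                try:
                    m = pool_metrics(ws, idxs)
                except ValueError:
                    continue
            rows.append({"subject_id": ws.subject_id, "scope": scope, **m.to_dict()})
    return pd.DataFrame(rows)
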