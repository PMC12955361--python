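"""Synthetic cohort generator with known ground-truth glycation parameters.

Emulates the study conditions: ~64 subjects whose per-subject mean glucose
is drawn from a truncated Normal(257, 57) mg/dL, glucose CV from a truncated
Normal(44, 10)% on [23, 62]%, and apparent glycation ratio (AGR) from a
Normal centered at the 65.1 mL/mg reference constant.  Each subject wears
three consecutive sensors of 10–14 days at 15-minute cadence with ≤48 h
gaps; glucose traces combine a mean-reverting (Ornstein–Uhlenbeck)
component, a diurnal sinusoid, and Poisson meal excursions, affinely
rescaled so the pre-clamp mean and CV hit the subject's targets exactly,
then clamped to the 40–500 mg/dL sensor range.  A1c at the end of each wear
follows the forward kinetic model at the subject's true AGR plus
multiplicative lognormal assay noise.

All randomness flows from one master seed; per-subject and per-wear
substreams are derived by stable hashing of (subject_id, wear_index), so
any trace can be regenerated in isolation.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import signal, stats

from .cgm import GlucoseTrace, clamp_glucose
from .config import SimulationConfig
from .kinetics import forward_a1c

__all__ = [
    "SubjectProfile",
    "CohortTables",
    "draw_profiles",
    "simulate_trace",
    "simulate_a1c",
    "simulate_cohort",
]

INCOME_LEVELS = ("very_poor", "poor", "low", "mid_high")
#: Category frequencies mirroring the reported cohort: 29/64 children,
#: 48% female, income 14/25/22/39%, 13% hemoglobin AS, 10% low G6PD.
P_CHILD = 29 / 64
P_FEMALE = 0.48
P_INCOME = (0.14, 0.25, 0.22, 0.39)
P_HB_AS = 0.13
P_G6PD_LOW = 0.10
#: Tanner stage frequencies among children (mostly prepubertal).
P_TANNER_CHILD = (0.52, 0.31, 0.10, 0.05, 0.02)

_BASE_START = pd.Timestamp("2024-01-08 08:00:00", tz="UTC")


@dataclass
class SubjectProfile:
    """Ground-truth parameters and covariates for one synthetic subject."""

    subject_id: str
    target_mg: float
    target_cv: float
    true_agr: float
    age_group: str
    sex: str
    tanner: int
    income: str
    hb_as: bool
    g6pd_low: bool
    ferritin: float
    hemoglobin: float
    rdw_cv: float

    def __post_init__(self) -> None:
        if self.target_mg <= 0:
            raise ValueError(f"{self.subject_id}: target_mg must be positive")
        # 0 is allowed as the degenerate constant-trace case
        if not 0.0 <= self.target_cv < 100.0:
            raise ValueError(f"{self.subject_id}: target_cv must be in [0, 100)")
        if self.true_agr <= 0:
            raise ValueError(f"{self.subject_id}: true_agr must be positive")
        if self.age_group not in ("child", "young_adult"):
            raise ValueError(f"{self.subject_id}: bad age_group {self.age_group!r}")
        if self.sex not in ("F", "M"):
            raise ValueError(f"{self.subject_id}: bad sex {self.sex!r}")
        if not 1 <= int(self.tanner) <= 5:
            raise ValueError(f"{self.subject_id}: tanner must be 1–5")
        if self.income not in INCOME_LEVELS:
            raise ValueError(f"{self.subject_id}: bad income {self.income!r}")


class CohortTables(NamedTuple):
    readings: pd.DataFrame
    visits: pd.DataFrame
    covariates: pd.DataFrame
    truth: pd.DataFrame


def _hash_id(subject_id: str) -> int:
    """Stable 31-bit hash of a subject id for seed derivation."""
    return zlib.crc32(subject_id.encode("utf-8")) & 0x7FFFFFFF


def _rng(*keys) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(keys)))


def _truncnorm(rng, mean, sd, lo, hi, size):
    if sd == 0:
        return np.full(size, float(mean))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def draw_profiles(config: SimulationConfig) -> list[SubjectProfile]:
    """Draw the subject-level ground truth for a cohort (deterministic in seed)."""
    n = config.n_subjects
    if n < 1:
        raise ValueError("n_subjects must be at least 1")
    rng = _rng(config.seed, 0)
    target_mg = _truncnorm(rng, config.mg_mean, config.mg_sd, config.mg_min, config.mg_max, n)
    target_cv = _truncnorm(rng, config.cv_mean, config.cv_sd, config.cv_min, config.cv_max, n)
    true_agr = _truncnorm(rng, config.agr_mean, config.agr_sd, 1e-6, np.inf, n)
    child = rng.random(n) < P_CHILD
    female = rng.random(n) < P_FEMALE
    income = rng.choice(len(INCOME_LEVELS), size=n, p=P_INCOME)
    hb_as = rng.random(n) < P_HB_AS
    g6pd = rng.random(n) < P_G6PD_LOW
    tanner_child = rng.choice(np.arange(1, 6), size=n, p=P_TANNER_CHILD)
    ferritin = np.exp(rng.normal(np.log(45.0), 0.7, n))
    hemoglobin = _truncnorm(rng, 13.2, 1.4, 8.0, 18.0, n)
    rdw = _truncnorm(rng, 13.5, 1.5, 11.0, 22.0, n)
    profiles = []
    for i in range(n):
        profiles.append(
            SubjectProfile(
                subject_id=f"S{i + 1:03d}",
                target_mg=float(target_mg[i]),
                target_cv=float(target_cv[i]),
                true_agr=float(true_agr[i]),
                age_group="child" if child[i] else "young_adult",
                sex="F" if female[i] else "M",
                tanner=int(tanner_child[i]) if child[i] else 5,
                income=INCOME_LEVELS[int(income[i])],
                hb_as=bool(hb_as[i]),
                g6pd_low=bool(g6pd[i]),
                ferritin=float(ferritin[i]),
                hemoglobin=float(hemoglobin[i]),
                rdw_cv=float(rdw[i]),
            )
        )
    return profiles


def _ou_path(rng, n: int, phi: float) -> np.ndarray:
    """Stationary unit-variance AR(1) path, the exact OU discretization."""
    eps = rng.normal(0.0, np.sqrt(1.0 - phi**2), n)
    x0 = rng.normal()
    x = signal.lfilter([1.0], [1.0, -phi], eps)
    return x + x0 * phi ** np.arange(1, n + 1)


def simulate_trace(
    profile: SubjectProfile,
    wear_index: int,
    config: SimulationConfig,
    start: pd.Timestamp | None = None,
    seed: int | None = None,
) -> GlucoseTrace:
    """Simulate one sensor wear for one subject.

    The raw process is baseline + OU noise + diurnal sinusoid + meal pulses;
    it is affinely rescaled so the pre-clamp mean and CV equal the subject's
    targets exactly, then clamped to the sensor range.  The pre-clamp values
    are retained on the returned trace.
    """
    if not 1 <= wear_index <= 3:
        raise ValueError("wear_index must be in 1..3")
    seed = config.seed if seed is None else seed
    rng = _rng(seed, _hash_id(profile.subject_id), wear_index)
    days = int(rng.integers(config.wear_days_min, config.wear_days_max + 1))
    dt_h = config.cadence_minutes / 60.0
    # inclusive endpoints so the wear's timestamp span is exactly `days` days
    n = int(round(days * 24 / dt_h)) + 1
    t_hours = np.arange(n) * dt_h
    start = _BASE_START if start is None else pd.Timestamp(start)
    times = start + pd.to_timedelta(t_hours, unit="h")

    target_sd = profile.target_cv / 100.0 * profile.target_mg
    if target_sd == 0.0:
        pre = np.full(n, profile.target_mg)
    else:
        phi = np.exp(-config.ou_mean_reversion * dt_h)
        ou = _ou_path(rng, n, phi) * 0.6 * target_sd
        phase = rng.uniform(0.0, 24.0)
        clock = (start.hour + start.minute / 60.0 + t_hours) % 24.0
        diurnal = (
            config.diurnal_amplitude_frac
            * profile.target_mg
            * np.sin(2.0 * np.pi * (clock - phase) / 24.0)
        )
        n_meals = rng.poisson(3.2 * days)
        meal_t = np.sort(rng.uniform(0.0, days * 24.0, n_meals))
        meal_amp = rng.uniform(40.0, 140.0, n_meals)
        tau = 1.5  # hours to excursion peak
        meals = np.zeros(n)
        for tm, amp in zip(meal_t, meal_amp):
            rel = (t_hours - tm) / tau
            mask = rel > 0
            meals[mask] += amp * rel[mask] * np.exp(1.0 - rel[mask])
        raw = profile.target_mg + ou + diurnal + meals
        pre = profile.target_mg + (raw - raw.mean()) * (target_sd / raw.std())

    clamped = clamp_glucose(pre, config.sensor_min, config.sensor_max)
    return GlucoseTrace(
        subject_id=profile.subject_id,
        sensor_index=wear_index,
        times=pd.DatetimeIndex(times),
        glucose=clamped,
        glucose_preclamp=pre,
        n_clamped=int(np.sum(clamped != pre)),
    )


_ASSAY_STREAM = {"lab": 7, "poc": 8}


def simulate_a1c(
    profile: SubjectProfile,
    trailing_mg: float,
    config: SimulationConfig,
    assay: str = "lab",
    seed: int | None = None,
) -> float:
    """A1c measurement (NGSP %) for a visit, given trailing mean glucose.

    Noise-free value from the forward kinetic model at the subject's true
    AGR; multiplicative lognormal noise (unit mean) with the configured
    assay CV is then applied.  An assay CV of 0 disables noise.
    """
    if trailing_mg <= 0:
        raise ValueError("trailing_mg must be positive")
    if assay not in _ASSAY_STREAM:
        raise ValueError(f"assay must be 'lab' or 'poc', got {assay!r}")
    a1c = forward_a1c(trailing_mg, profile.true_agr)
    cv = (config.a1c_assay_cv_lab if assay == "lab" else config.a1c_assay_cv_poc) / 100.0
    if cv > 0:
        seed = config.seed if seed is None else seed
        rng = _rng(seed, _hash_id(profile.subject_id), _ASSAY_STREAM[assay])
        sigma = np.sqrt(np.log1p(cv**2))
        a1c *= np.exp(rng.normal(-0.5 * sigma**2, sigma))
    return float(a1c)


def simulate_cohort(config: SimulationConfig, out_dir=None) -> CohortTables:
    """Simulate a full cohort and assemble the standard tables.

    Per subject: three consecutive wears (gaps drawn in (0, gap_hours_max]),
    A1c by both assays at the end of each wear with trailing mean glucose
    pooled over wears 1..k, covariates, and a ground-truth row.  When
    ``out_dir`` is given, writes readings.csv, visits.csv, covariates.csv
    and truth.csv there (deterministic byte content for a fixed config).
    """
    profiles = draw_profiles(config)
    readings_rows, visits_rows, cov_rows, truth_rows = [], [], [], []
    for profile in profiles:
        sid = profile.subject_id
        srng = _rng(config.seed, _hash_id(sid), 99)
        start = _BASE_START + pd.Timedelta(hours=float(srng.uniform(0.0, 72.0)))
        pooled: list[np.ndarray] = []
        for wear in (1, 2, 3):
            trace = simulate_trace(profile, wear, config, start=start)
            readings_rows.append(
                pd.DataFrame(
                    {
                        "subject_id": sid,
                        "sensor_index": wear,
                        "timestamp": trace.times.strftime("%Y-%m-%dT%H:%M:%S+00:00"),
                        "glucose_mgdl": trace.glucose,
                    }
                )
            )
            pooled.append(trace.glucose)
            trailing_mg = float(np.mean(np.concatenate(pooled)))
            visit_date = trace.times[-1]
            for assay in ("lab", "poc"):
                a1c = simulate_a1c(
                    profile, trailing_mg, config, assay=assay, seed=config.seed + wear
                )
                visits_rows.append(
                    {
                        "subject_id": sid,
                        "visit": wear,
                        "assay": assay,
                        "a1c_percent": a1c,
                        "date": visit_date.strftime("%Y-%m-%d"),
                    }
                )
            # inter-wear gap in (0, gap_hours_max]; QC measures end-to-start
            gap_h = config.gap_hours_max * (1.0 - float(srng.random()))
            start = trace.times[-1] + pd.Timedelta(hours=gap_h)
        cov_rows.append(
            {
                "subject_id": sid,
                "age_group": profile.age_group,
                "sex": profile.sex,
                "tanner": profile.tanner,
                "income": profile.income,
                "hb_as": profile.hb_as,
                "g6pd_low": profile.g6pd_low,
                "ferritin": profile.ferritin,
                "hemoglobin": profile.hemoglobin,
                "rdw_cv": profile.rdw_cv,
            }
        )
        truth_rows.append(
            {
                "subject_id": sid,
                "true_agr": profile.true_agr,
                "target_mg": profile.target_mg,
                "target_cv": profile.target_cv,
            }
        )
    tables = CohortTables(
        readings=pd.concat(readings_rows, ignore_index=True),
        visits=pd.DataFrame(visits_rows),
        covariates=pd.DataFrame(cov_rows),
        truth=pd.DataFrame(truth_rows),
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables._asdict().items():
            try:
                df.to_csv(out / f"{name}.csv", index=False)
            except OSError as exc:
                raise OSError(f"failed writing {out / (name + '.csv')}: {exc}") from exc
    return tables
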