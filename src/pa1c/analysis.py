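"""Cohort-level statistics: predictor comparison, correlations, tests,
stepwise-AIC covariate adjustment, power, and the end-to-end pipeline.

The headline comparison mirrors the study design: simple linear fits of
evaluation mean glucose (all three wears pooled) against laboratory A1c,
point-of-care A1c, and the personalized A1c, all on the identical subject
set, summarized by slope/intercept/R²/r/RMSE.  The pA1c–MG relationship is
mildly nonlinear through the kinetic model; a straight-line fit is used for
comparison regardless, with the exact consistency check carried out on the
reference-curve scale (see ``run_pipeline``).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import cgm
from .cgm import qc_wearset, pool_metrics, traces_from_frame
from .kinetics import (
    DEFAULT_CONSTANTS,
    GlycationConstants,
    compute_agr,
    compute_pa1c,
    reference_ea1c,
)

__all__ = [
    "FitSummary",
    "PowerSpec",
    "StepwiseResult",
    "fit_simple",
    "compare_predictors",
    "spearman",
    "welch_t",
    "stepwise_aic",
    "correlation_power",
    "run_pipeline",
]


@dataclass(frozen=True)
class FitSummary:
    """Simple-linear-regression summary of y on one predictor."""

    predictor_name: str
    slope: float
    intercept: float
    r_squared: float
    pearson_r: float
    rmse: float
    n: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class PowerSpec:
    """Specification of a one-correlation power calculation."""

    rho: float
    n: int
    alpha: float = 0.05
    method: str = "fisher_z"
    n_sims: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.rho < 1.0:
            raise ValueError("rho must be in (0, 1)")
        if self.n < 4:
            raise ValueError("n must be at least 4")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.method not in ("fisher_z", "monte_carlo"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.n_sims < 1:
            raise ValueError("n_sims must be positive")


def fit_simple(x, y, predictor_name: str = "x") -> FitSummary:
    """Ordinary least squares of y on x; R² = 1 − RSS/TSS, RMSE = √(RSS/n)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: slope undefined")
    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    rmse = float(np.sqrt(np.mean(resid**2)))
    return FitSummary(
        predictor_name=predictor_name,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        pearson_r=float(res.rvalue),
        rmse=rmse,
        n=int(n),
    )


_PREDICTOR_COLUMNS = ("visit3_a1c_lab", "visit3_a1c_poc", "pa1c", "evaluation_mg")


def compare_predictors(records) -> dict[str, FitSummary]:
    """Fit evaluation MG against each A1c variant on the identical subject set.

    Returns four fits: MG vs laboratory A1c, MG vs POC A1c, MG vs pA1c, and
    POC A1c vs laboratory A1c.  ``records`` is a list of
    :class:`~pa1c.kinetics.GlycationRecord` or an equivalent DataFrame.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame([vars(r) for r in records])
    missing = [c for c in _PREDICTOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"records missing field(s): {', '.join(missing)}")
    if len(df) < 3:
        raise ValueError("need at least 3 records")
    mg = df["evaluation_mg"].to_numpy(dtype=float)
    return {
        "mg_vs_lab_a1c": fit_simple(df["visit3_a1c_lab"], mg, "visit3_a1c_lab"),
        "mg_vs_poc_a1c": fit_simple(df["visit3_a1c_poc"], mg, "visit3_a1c_poc"),
        "mg_vs_pa1c": fit_simple(df["pa1c"], mg, "pa1c"),
        "poc_vs_lab_a1c": fit_simple(
            df["visit3_a1c_lab"], df["visit3_a1c_poc"].to_numpy(dtype=float), "visit3_a1c_lab"
        ),
    }


def spearman(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Ties receive average ranks.  If either variable is entirely tied the
    correlation is undefined; 0.0 is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        warnings.warn("all-tied variable: Spearman correlation undefined, returning 0")
        return 0.0
    return float(np.corrcoef(rx, ry)[0, 1])


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Welch unequal-variance two-sample t-test.

    Returns (t, Satterthwaite df, two-sided p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


@dataclass
class StepwiseResult:
    """Outcome of bidirectional stepwise-AIC selection."""

    forced: list[str]
    selected: list[str]
    aic: float
    r_squared: float
    rmse: float
    n: int
    coefficients: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "forced": list(self.forced),
            "selected": list(self.selected),
            "aic": self.aic,
            "r_squared": self.r_squared,
            "rmse": self.rmse,
            "n": self.n,
            "coefficients": dict(self.coefficients),
        }


_CATEGORICAL = ("age_group", "sex", "income")
_BOOLEAN = ("hb_as", "g6pd_low")


def expand_covariates(table: pd.DataFrame) -> pd.DataFrame:
    """Expand the covariate table to a numeric design block.

    Categorical covariates become 0/1 indicators (first level dropped, with
    a fixed level order so column naming is deterministic); booleans become
    0/1; Tanner stage is kept as a numeric ordinal.
    """
    out = {}
    for col in table.columns:
        if col == "subject_id":
            continue
        s = table[col]
        if col in _CATEGORICAL or (s.dtype == object and col not in _BOOLEAN):
            levels = sorted(s.astype(str).unique())
            for lv in levels[1:]:
                out[f"{col}[{lv}]"] = (s.astype(str) == lv).astype(float)
        elif col in _BOOLEAN or s.dtype == bool:
            out[col] = s.astype(float)
        else:
            out[col] = pd.to_numeric(s).astype(float)
    return pd.DataFrame(out, index=table.index)


def _aic(rss: float, n: int, p: int) -> float:
    """Pinned AIC convention: n·ln(RSS/n) + 2·(p+1), p = slope count."""
    return n * np.log(rss / n) + 2.0 * (p + 1)


def _ols_rss(y: np.ndarray, X: np.ndarray) -> float:
    model = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    return float(model.ssr)


def stepwise_aic(
    response,
    covariate_table: pd.DataFrame,
    candidates: list[str],
    forced: list[str] | tuple[str, ...] = (),
) -> StepwiseResult:
    """Bidirectional stepwise selection minimizing AIC = n·ln(RSS/n) + 2(p+1).

    Starts from the intercept-plus-forced model (the primary predictor is
    passed in ``forced`` and is never dropped); at each step the single add
    or drop that lowers AIC the most is applied, with ties broken by
    candidate list order (adds considered before drops at equal AIC).
    Complete cases only; a rank-deficient design is an error naming the
    aliased columns.
    """
    y = np.asarray(response, dtype=float)
    forced = list(forced)
    cols = forced + [c for c in candidates if c not in forced]
    missing = [c for c in cols if c not in covariate_table.columns]
    if missing:
        raise ValueError(f"covariate table missing column(s): {', '.join(missing)}")
    data = covariate_table[cols].apply(pd.to_numeric).astype(float)
    keep = ~(data.isna().any(axis=1) | np.isnan(y))
    data, y = data.loc[keep], y[keep.to_numpy()]
    n = len(data)
    if n < len(forced) + 3:
        raise ValueError("too few complete cases")

    # alias detection on the full design, when n permits fitting it at all;
    # for smaller n, collinear candidates are simply never addable below
    if n >= len(cols) + 2:
        full = data.to_numpy()
        if np.linalg.matrix_rank(np.column_stack([np.ones(n), full])) < full.shape[1] + 1:
            aliased = []
            base = [np.ones(n)]
            for name in cols:
                trial = np.column_stack(base + [data[name].to_numpy()])
                if np.linalg.matrix_rank(trial) < trial.shape[1]:
                    aliased.append(name)
                else:
                    base.append(data[name].to_numpy())
            raise ValueError(
                f"rank-deficient design; aliased column(s): {', '.join(aliased)}"
            )

    def score(names: list[str]) -> float:
        X = data[names].to_numpy() if names else np.empty((n, 0))
        return _aic(_ols_rss(y, X), n, len(names))

    def addable(names: list[str], c: str) -> bool:
        if len(names) + 3 > n:  # keep at least one residual df
            return False
        X = np.column_stack([np.ones(n), data[names + [c]].to_numpy()])
        return np.linalg.matrix_rank(X) == X.shape[1]

    current = list(forced)
    current_aic = score(current)
    free = [c for c in candidates if c not in forced]
    while True:
        best_move, best_aic = None, current_aic
        for c in free:  # additions, in candidate order
            if c in current or not addable(current, c):
                continue
            a = score(current + [c])
            if a < best_aic - 1e-12:
                best_move, best_aic = ("add", c), a
        for c in free:  # drops
            if c not in current:
                continue
            a = score([k for k in current if k != c])
            if a < best_aic - 1e-12:
                best_move, best_aic = ("drop", c), a
        if best_move is None:
            break
        op, c = best_move
        current = current + [c] if op == "add" else [k for k in current if k != c]
        current_aic = best_aic

    X = data[current].to_numpy() if current else np.empty((n, 0))
    model = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    rss = float(model.ssr)
    tss = float(np.sum((y - y.mean()) ** 2))
    names = ["intercept"] + current
    return StepwiseResult(
        forced=forced,
        selected=[c for c in current if c not in forced],
        aic=current_aic,
        r_squared=1.0 - rss / tss if tss > 0 else float("nan"),
        rmse=float(np.sqrt(rss / n)),
        n=n,
        coefficients=dict(zip(names, (float(b) for b in model.params))),
    )


def correlation_power(spec: PowerSpec) -> float:
    """Power to detect a nonzero correlation at two-sided alpha.

    ``fisher_z``: Φ(√(n−3)·atanh(ρ) − z_{1−α/2}) — the standard normal
    approximation on the variance-stabilized scale.  ``monte_carlo``: the
    rejection fraction of the exact t-test for Pearson's r over ``n_sims``
    bivariate-normal cohorts of size n with true correlation ρ.
    """
    if spec.method == "fisher_z":
        z_crit = stats.norm.ppf(1.0 - spec.alpha / 2.0)
        return float(stats.norm.cdf(np.sqrt(spec.n - 3) * np.arctanh(spec.rho) - z_crit))
    rng = np.random.default_rng(spec.seed)
    n, sims = spec.n, spec.n_sims
    # correlated pair via shared component; Pearson r is scale-invariant
    u = rng.standard_normal((sims, n))
    v = rng.standard_normal((sims, n))
    x = u
    y = spec.rho * u + np.sqrt(1.0 - spec.rho**2) * v
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    r = (xc * yc).sum(axis=1) / np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    t_crit = stats.t.ppf(1.0 - spec.alpha / 2.0, df=n - 2)
    return float(np.mean(np.abs(t) > t_crit))


def _require_visit(visits: pd.DataFrame, sid: str, visit: int, assay: str) -> float:
    sel = visits[
        (visits["subject_id"] == sid)
        & (visits["visit"] == visit)
        & (visits["assay"] == assay)
    ]
    if len(sel) != 1:
        raise ValueError(f"subject {sid}: expected one visit-{visit} {assay} A1c, found {len(sel)}")
    return float(sel["a1c_percent"].iloc[0])


def run_pipeline(
    readings,
    visits,
    covariates,
    constants: GlycationConstants = DEFAULT_CONSTANTS,
    alpha: float = 0.05,
    power_rho: float = 0.52,
    power_n: int = 60,
    power_seed: int = 0,
) -> tuple[dict, pd.DataFrame]:
    """Run the full analysis: QC → metrics → AGR → pA1c → cohort statistics.

    ``readings``/``visits``/``covariates`` may be paths or DataFrames.
    Subjects failing the wear protocol (or missing required A1c visits) are
    excluded with a logged reason.  Returns ``(result, records)`` where
    ``result`` is a JSON-serializable dict (fits, correlations, tests,
    stepwise models, power, exclusions) and ``records`` the per-subject
    AGR/pA1c table.
    """
    if not isinstance(readings, pd.DataFrame):
        traces = cgm.read_readings(readings)
    else:
        traces = traces_from_frame(readings)
    visits = visits if isinstance(visits, pd.DataFrame) else pd.read_csv(visits)
    covariates = (
        covariates if isinstance(covariates, pd.DataFrame) else pd.read_csv(covariates)
    )
    for col in ("subject_id", "visit", "assay", "a1c_percent"):
        if col not in visits.columns:
            raise ValueError(f"visits table missing column {col}")

    by_subject: dict[str, list] = {}
    for tr in traces:
        by_subject.setdefault(tr.subject_id, []).append(tr)

    exclusions: list[dict] = []
    records: list[dict] = []
    for sid in sorted(by_subject):
        try:
            ws = qc_wearset(by_subject[sid])
        except ValueError as exc:
            raise ValueError(f"stage qc, subject {sid}: {exc}") from exc
        if not ws.protocol_valid:
            short = [i + 1 for i, ok in enumerate(ws.wear_valid) if not ok]
            reason = (
                f"wear(s) {short} under 10 days" if short else
                "missing wear or inter-wear gap over 48 h"
                if len(ws.wears) == 3
                else f"only {len(ws.wears)} wear(s) present"
            )
            exclusions.append({"subject_id": sid, "reason": reason})
            continue
        try:
            calib = pool_metrics(ws, (1, 2))
            evalm = pool_metrics(ws, (1, 2, 3))
            a1c2_lab = _require_visit(visits, sid, 2, "lab")
            a1c3_lab = _require_visit(visits, sid, 3, "lab")
            a1c3_poc = _require_visit(visits, sid, 3, "poc")
            agr = compute_agr(calib.mean_glucose, a1c2_lab, constants)
            pa1c = compute_pa1c(a1c3_lab, agr, constants)
        except ValueError as exc:
            raise ValueError(f"stage agr/pa1c, subject {sid}: {exc}") from exc
        records.append(
            {
                "subject_id": sid,
                "calibration_mg": calib.mean_glucose,
                "calibration_a1c": a1c2_lab,
                "agr": agr,
                "visit3_a1c_lab": a1c3_lab,
                "visit3_a1c_poc": a1c3_poc,
                "pa1c": pa1c,
                "evaluation_mg": evalm.mean_glucose,
                "cv": evalm.cv,
                "pct_below_54": evalm.pct_below_54,
                "pct_below_70": evalm.pct_below_70,
            }
        )

    rec = pd.DataFrame(records)
    if len(rec) < 3:
        raise ValueError("stage analysis: fewer than 3 protocol-valid subjects")

    fits = compare_predictors(rec)
    # exact-consistency fit on the reference-curve scale: for a perfectly
    # calibrated cohort pA1c equals reference_ea1c(evaluation MG) identically
    ref_fit = fit_simple(
        rec["pa1c"], reference_ea1c(rec["evaluation_mg"].to_numpy(), constants), "pa1c"
    )
    rho_cv_hypo = spearman(rec["cv"], rec["pct_below_54"])

    cov = covariates.set_index("subject_id").loc[rec["subject_id"]].reset_index()
    tests = {}
    child = (cov["age_group"] == "child").to_numpy()
    if 2 <= child.sum() and 2 <= (~child).sum():
        for var in ("evaluation_mg", "cv", "pct_below_70"):
            t, df_, p = welch_t(rec[var][child], rec[var][~child])
            tests[f"{var}_child_vs_adult"] = {"t": t, "df": df_, "p": p}

    design = expand_covariates(cov)
    candidates = [c for c in design.columns]
    stepwise = {}
    for primary in ("visit3_a1c_lab", "pa1c"):
        design_p = design.copy()
        design_p[primary] = rec[primary].to_numpy(dtype=float)
        stepwise[f"mg_on_{primary}"] = stepwise_aic(
            rec["evaluation_mg"].to_numpy(dtype=float),
            design_p,
            candidates,
            forced=[primary],
        ).to_dict()

    power = correlation_power(
        PowerSpec(rho=power_rho, n=power_n, alpha=alpha, method="fisher_z", seed=power_seed)
    )

    result = {
        "n_subjects": int(len(rec)),
        "n_excluded": int(len(exclusions)),
        "exclusions": exclusions,
        "fits": {k: v.to_dict() for k, v in fits.items()},
        "fit_reference_scale_pa1c": ref_fit.to_dict(),
        "spearman_cv_vs_pct_below_54": rho_cv_hypo,
        "welch_tests": tests,
        "stepwise": stepwise,
        "power_r052_n60": power,
        "constants": {"k_m": constants.k_m, "agr_ref": constants.agr_ref},
    }
    return result, rec
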