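"""Human-readable markdown report with dual-unit rendering.

Rendering rules: glucose is shown as mg/dL with mmol/L (divisor 18.016) to
one decimal in parentheses; A1c as NGSP % with IFCC mmol/mol (master
equation) rounded half-up to an integer.
"""
from __future__ import annotations

from .cgm import convert_glucose
from .kinetics import convert_a1c

__all__ = ["format_glucose", "format_a1c", "render_report"]


def _round_half_up(x: float, ndigits: int = 0) -> float:
    import math

    scale = 10**ndigits
    return math.floor(x * scale + 0.5) / scale


def format_glucose(mgdl: float) -> str:
    mmol = convert_glucose(mgdl, "mgdl_to_mmoll")
    return f"{mgdl:.0f} mg/dL ({_round_half_up(mmol, 1):.1f} mmol/L)"


def format_a1c(ngsp: float) -> str:
    ifcc = convert_a1c(ngsp, "ngsp_to_ifcc")
    return f"{ngsp:.1f}% ({_round_half_up(ifcc):.0f} mmol/mol)"


def _fit_row(name: str, f: dict) -> str:
    return (
        f"| {name} | {f['slope']:.2f} | {f['intercept']:.1f} | "
        f"{f['r_squared']:.2f} | {f['pearson_r']:.2f} | {f['rmse']:.1f} | {f['n']} |"
    )


def render_report(analysis: dict) -> str:
    """Render the analysis.json payload as a markdown report."""
    lines = [
        "# Personalized A1c cohort report",
        "",
        f"Subjects analyzed: {analysis['n_subjects']} "
        f"(excluded: {analysis['n_excluded']})",
        "",
        "## Mean glucose vs A1c variants (simple linear fits)",
        "",
        "| fit | slope | intercept | R² | r | RMSE | n |",
        "|---|---|---|---|---|---|---|",
    ]
    for name, f in analysis["fits"].items():
        lines.append(_fit_row(name, f))
    ref = analysis.get("fit_reference_scale_pa1c")
    if ref:
        lines += [
            "",
            f"Reference-scale consistency fit (reference-glycator A1c at evaluation "
            f"MG vs pA1c): R² = {ref['r_squared']:.4f}, RMSE = {ref['rmse']:.3f} %-points.",
        ]
    lines += [
        "",
        "## Variability and hypoglycemia",
        "",
        f"Spearman correlation of glucose CV with % time < {format_glucose(54)}: "
        f"{analysis['spearman_cv_vs_pct_below_54']:.2f}.",
        "",
        "## Children vs young adults (Welch t-tests)",
        "",
    ]
    tests = analysis.get("welch_tests", {})
    if tests:
        lines += ["| variable | t | df | p |", "|---|---|---|---|"]
        for name, t in tests.items():
            lines.append(f"| {name} | {t['t']:.2f} | {t['df']:.1f} | {t['p']:.3f} |")
    else:
        lines.append("Not computed (one age group too small).")
    lines += ["", "## Covariate-adjusted models (stepwise AIC)", ""]
    for name, swa in analysis.get("stepwise", {}).items():
        sel = ", ".join(swa["selected"]) or "none"
        lines.append(
            f"- {name}: forced {', '.join(swa['forced'])}; selected covariates: {sel}; "
            f"R² = {swa['r_squared']:.2f}, AIC = {swa['aic']:.1f}."
        )
    lines += [
        "",
        "## Design power",
        "",
        f"Power to detect r = 0.52 at n = 60 (two-sided α = 0.05): "
        f"{100 * analysis['power_r052_n60']:.1f}%.",
        "",
        "## Exclusions",
        "",
    ]
    if analysis["exclusions"]:
        for e in analysis["exclusions"]:
            lines.append(f"- {e['subject_id']}: {e['reason']}")
    else:
        lines.append("None.")
    return "\n".join(lines) + "\n"
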