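# pa1c — personalized HbA1c from CGM via the glycation kinetic model

Hemoglobin A1c is routinely read as a proxy for mean glucose (MG), but the
A1c–MG relationship varies substantially between people: red-cell lifespan
and glycation tendency differ, so two patients with the same MG can differ
by percentage points of A1c. Where continuous glucose monitoring (CGM) is
unaffordable and insulin is dosed from A1c alone — as in much of sub-Saharan
Africa — that variability translates directly into dosing error.

`pa1c` implements a personalization pipeline built on a steady-state
glycation kinetic model. Red-cell glucose exposure saturates through a
Michaelis–Menten transport term with constant K_M = 472 mg/dL, giving the
*apparent glucose* composite

```
X(MG) = 1/MG + 1/K_M
```

and a steady-state relationship between MG and A1c governed by a per-person
**apparent glycation ratio** (AGR, mL/mg):

```
A1c  = 100 / (1 + 1e5 · X(MG) / AGR)             (forward model)
AGR  = 1e5 · X(MG) / (100/A1c − 1)               (calibration)
pA1c = 100 / (1 + (AGR/65.1) · (100/A1c − 1))    (personalization)
```

A brief calibration period (two 10–14-day sensor wears plus one laboratory
A1c) identifies a person's AGR; later A1c measurements are then mapped onto
the scale of a *reference glycator* (AGR = 65.1 mL/mg, the standard
red-cell-lifespan glycation rate constant), producing a personalized A1c
(pA1c) that tracks MG more faithfully. The key identity — pA1c computed from
any calibration pair (A1c, AGR(MG, A1c)) equals the reference curve at MG,
independent of the A1c level — is property-tested to 1e-12.

The package is aimed at biostatisticians and diabetes researchers who want
to study this estimator's behaviour. Because cohort CGM data of this kind
are rarely shareable, a synthetic-cohort generator with known ground-truth
glycation parameters is a first-class module: every downstream stage is
testable, and parameter recovery can be checked exactly.

## What's in the box

| module | role |
|---|---|
| `pa1c.simulate` | synthetic subjects, OU + diurnal + meal-pulse glucose traces, assay-noisy A1c |
| `pa1c.cgm` | readings ingestion, three-wear protocol QC (≥10 days/wear, ≤48 h gaps), consensus metrics (% time <54, <70, 70–180, >180, >250 mg/dL; CV) |
| `pa1c.kinetics` | AGR estimation, pA1c, reference-glycator curve, MG inversion, NGSP↔IFCC conversion |
| `pa1c.analysis` | MG-vs-A1c fit comparison (R²/r/RMSE), Spearman CV–hypoglycemia, Welch tests, stepwise-AIC covariate adjustment, correlation power |
| `pa1c.cli` | `pa1c simulate / qc / metrics / agr / pa1c / analyze / report` |

## Worked example

```sh
pa1c simulate --n 64 --seed 7 --out demo/
pa1c analyze  --in demo/ --out demo/
pa1c report   --in demo/analysis.json --out demo/report.md
```

On this seeded 64-subject cohort (default study conditions: MG ~ 257 ± 57
mg/dL, CV ~ 44 ± 10 %, AGR ~ 65.1 ± 6 mL/mg, lab/POC assay CV 2%/4%), the
analysis prints:

```
| fit            | slope | intercept | R²   | r    | RMSE | n  |
| mg_vs_lab_a1c  | 29.73 | -34.0     | 0.70 | 0.83 | 30.3 | 64 |
| mg_vs_poc_a1c  | 29.08 | -25.5     | 0.70 | 0.83 | 30.3 | 64 |
| mg_vs_pa1c     | 39.35 | -122.8    | 0.92 | 0.96 | 15.7 | 64 |
| poc_vs_lab_a1c | 0.98  | 0.1       | 0.93 | 0.96 | 0.4  | 64 |
```

Reading this: measured A1c (laboratory or point-of-care) explains ~70% of
the between-subject variance in mean glucose here, with an RMSE of ~30
mg/dL; after personalization the same A1c measurements explain 92% with
half the error — the between-subject glycation variance that pA1c removes.
The report also shows the Spearman correlation of glucose CV with % time
< 54 mg/dL (0.96 in this cohort: more variable glucose means more
hypoglycemia at any mean), Welch child-vs-young-adult comparisons, the
stepwise-AIC covariate models, and the design power (99.2% to detect
r = 0.52 at n = 60, two-sided α = 0.05).

As a library:

```python
from pa1c import compute_agr, compute_pa1c

agr = compute_agr(mg=154, a1c=7.0)      # 64.82 mL/mg — a near-reference glycator
pa1c = compute_pa1c(10.1, agr=67.52)    # 9.77 % — high glycator revised downward
```

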