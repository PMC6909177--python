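# srspre — knowledge-based pre-planning for single-isocenter SRS

In stereotactic radiosurgery (SRS) of solitary intracranial lesions, the
volume of normal brain receiving at least 12 Gy (**V12**) is the standard
surrogate for radiation-necrosis risk, and a V12 planning goal that turns
out to be unattainable wastes a full planning cycle.  `srspre` gives the
prescribing physician a calculated estimate of V12 *before* any treatment
planning, from three things they control: the planning target volume (PTV),
the prescription dose (PD), and the delivery technique — circular cone arcs
(CAT) or dynamic conformal arcs (DCAT).

The core is a closed-form surface for the total 12 Gy volume
TV12 (the 12 Gy volume including the target; V12 = TV12 − GTV), obtained by
a two-stage hierarchical fit of cohort dosimetry:

1. per (plan type, PD) category, an ordinary least-squares line in log space
   — log₁₀(TV12/1 cc) = m·log₁₀(PTV/1 cc) + b;
2. across PDs, per plan type, m = a·(PD/1 Gy)^c (nonlinear least squares)
   and 10^b = n·(PD/1 Gy) + d (linear least squares).

Substitution gives the prediction surface

```
TV12/1cc = (n·PD/1Gy + d) · (PTV/1cc)^(a·PD/1Gy^c)
```

with one dimensionless parameter set (a, c, n, d) per delivery type.
Around it the package provides:

- **plan records & goals** — validated cohort CSV I/O, V12 derivation,
  strict evaluation of the nominal goals COV > 99 %, CI < 1.5, V12 < 3.3 cc,
  and an ellipsoid surface-area descriptor from principal-axis diameters
  (Thomsen approximation);
- **dose rescaling** — changing only the PD leaves the relative dose
  distribution (hence COV, CI, PIDL) untouched, so TV12 at any PD is read
  off the plan's isodose-volume curve at the mapped percent; one cohort
  expands to a plans × doses grid with no dose recalculation;
- **prediction & advice** — forward TV12/V12 evaluation, closed-form
  inversion for the largest admissible PTV, bracketed root-finding for the
  highest admissible PD, and the printed RTOG 90-05 / RTOG 1270
  diameter-to-dose guideline tables;
- **plan comparison** — paired percent differences
  ΔCI = 100·(CI_DCAT − CI_CAT)/CI_CAT and likewise ΔTV12, per-PD summaries,
  and the CAT/DCAT crossover PTV below which DCAT predicts the larger TV12;
- **synthetic cohorts** — a generator that emulates the clinical data
  structure (log-uniform small-target PTVs ≤ 2.43 cc, log-normal TV12
  scatter with plan-level residuals, paired re-plans), used for end-to-end
  parameter-recovery validation.

Published reference fit parameters for a 50-plan clinical cohort ship as
package data (`srspre.reference`) and serve as the default surfaces.

## Worked example

Predict for a 0.8 cc lesion with a 1.2 cc PTV at 24 Gy, both techniques:

```
$ srspre predict --plan-type CAT --ptv 1.2 --pd 24 --gtv 0.8
predicted TV12 = 5.190 cc
predicted V12  = 4.390 cc

$ srspre predict --plan-type DCAT --ptv 1.2 --pd 24 --gtv 0.8
predicted TV12 = 5.471 cc
predicted V12  = 4.671 cc
```

At this small PTV the more conformal DCAT technique is predicted to spill
*more* 12 Gy dose (5.47 vs 5.19 cc) — the mMLC penumbra effect.  Both
predictions miss the 3.3 cc V12 goal, so ask what prescription would meet it:

```
$ srspre advise --plan-type CAT --gtv 0.8 --margin-ptv 1.2 --pd 24 --v12-goal 3.3
PD 24 Gy: predicted V12 = 4.390 cc (MISSES the 3.3 cc goal)
highest PD meeting the goal: 19.96 Gy
```

i.e. this PTV/technique combination supports at most ≈20 Gy at the 3.3 cc
goal; the physician can lower the PD, trim the margin (the `advise` report
also carries the largest admissible PTV per dose), or fractionate.

The full pipeline runs on synthetic data end to end:

```
$ srspre simulate --n 50 --seed 7 --paired --out cohort.csv
wrote 400 records to cohort.csv
$ srspre fit cohort.csv --out model.json
CAT: a=1.2085 c=-0.1396 n=0.2328 d=-1.1738 ...
DCAT: a=1.4747 c=-0.2289 n=0.2619 d=-1.6505 ...
$ srspre compare cohort.csv
PD = 15 Gy  (n = 50): dTV12 max +43.1% min -26.3% median -1.9%  [22 up / 28 down / 0 unchanged]
PD = 18 Gy  (n = 50): dTV12 max +49.9% min -23.3% median +0.9%  [27 up / 23 down / 0 unchanged]
PD = 21 Gy  (n = 50): dTV12 max +54.6% min -21.3% median +2.8%  [32 up / 18 down / 0 unchanged]
PD = 24 Gy  (n = 50): dTV12 max +58.1% min -19.8% median +4.0%  [36 up / 14 down / 0 unchanged]
```

The refit parameters land close to the truth surfaces the cohort was drawn
from, and the comparison shows the expected trend: the higher the
prescription, the more re-plans gain TV12 under DCAT and the larger the
median gain, while ΔCI is independent of PD.

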