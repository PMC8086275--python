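# equimort

Infant-mortality inequality analysis for DHS-style survey data.

Health-equity monitoring asks not just *what* a country's infant
mortality rate (IMR) is, but *who* bears it: do infants of the poorest
households, of mothers with no schooling, or of rural areas die more
often than their better-off counterparts?  `equimort` implements the
standard monitoring workflow for analysts working with Demographic and
Health Survey (DHS) style full birth histories or with published
disaggregated tables:

1. **Estimate** the IMR (deaths before the first birthday per 1000 live
   births) from a birth-recode table with the synthetic-cohort
   component method — infancy split into the DHS age segments
   [0,1), [1,3), [3,6), [6,12) months, a conditional death probability
   `q_a` per segment, and `IMR = 1000·(1 − Π_a (1 − q_a))` — with
   cluster-bootstrap confidence intervals.
2. **Disaggregate** it by equity stratifiers: wealth quintile,
   maternal education, urban/rural residence, child sex, subnational
   region.
3. **Summarise** the inequality with four measures, each with a 95% CI:

   | measure | definition | null value |
   |---|---|---|
   | Difference | `D = μ_disadvantaged − μ_advantaged` | 0 |
   | Ratio | `R = μ_disadvantaged / μ_advantaged` | 1 |
   | PAR / PAF | `PAR = μ_ref − μ`, `PAF = 100·PAR/μ`, reference = best-performing subgroup | 0 |
   | Absolute concentration index | `ACI = Σ_j p_j μ_j (2x_j − 1)` with midpoint ranks `x_j = c_{j−1} + p_j/2` | 0 |

   For an adverse indicator like IMR, PAF ≤ 0 and a negative ACI means
   the burden concentrates among the disadvantaged.

A synthetic birth-history generator with known subgroup-specific
mortality (piecewise-constant hazards over the same age segments,
censoring at the interview date, gamma sampling weights, Gaussian-copula
association between stratifiers) makes the whole pipeline testable
without access to restricted survey microdata.

## Worked example

Simulate a survey with a rural/urban mortality gap, estimate the
national rate, and summarise the residence inequality:

```python
import equimort as eq

cfg = eq.SyntheticConfig(
    n_births=50_000,
    target_q1={"residence": {"rural": 0.0508, "urban": 0.0357}},
    seed=1,
)
births = eq.generate_births(cfg)

res = eq.SyntheticCohortIMR(births).fit(ci="bootstrap", n_boot=500, seed=1)
print(res.summary())
```

```
Synthetic-cohort infant mortality estimate
--------------------------------------------
IMR (per 1000 live births)       46.70
Births in window                 50000
Weighted births                50000.0
95% CI (cluster bootstrap)  [44.60, 49.13]
Bootstrap SE                      1.08
Segment probabilities       q[0,1)=0.02162, q[1,3)=0.01018, q[3,6)=0.00841, q[6,12)=0.00726
```

The estimate recovers the population-average death probability implied
by the generating rural/urban mix (0.73·50.8 + 0.27·35.7 ≈ 46.7 per
1000), with the cluster-bootstrap interval quantifying the survey
design's sampling noise.

Summary measures can also be computed straight from a published
disaggregated table.  The bundled 2013 Yemen DHS table (per-1000
estimates, 95% CIs and birth counts for five stratifiers, national
average µ = 46.73) gives:

```python
tables = eq.load_yemen_2013_table1()
print(eq.InequalityAnalysis(tables).fit(seed=1).summary())
```

```
Inequality summary measures
==========================================================
dimension         measure    estimate  95% CI
----------------------------------------------------------
wealth_quintile   ACI           -4.69  (-6.56, -2.78)
wealth_quintile   D             20.20  (9.54, 30.86)
wealth_quintile   PAF          -29.32  (-45.45, -18.05)
wealth_quintile   R              1.61  (1.24, 2.10)
education         ACI           -2.17  (-3.78, -0.66)
education         D             15.59  (5.64, 25.54)
education         PAF          -26.92  (-45.61, -9.87)
education         R              1.46  (1.11, 1.91)
residence         D             15.08  (8.03, 22.13)
residence         PAF          -23.58  (-35.13, -11.55)
residence         R              1.42  (1.19, 1.70)
sex               D              3.35  (-3.10, 9.80)
sex               PAF           -3.66  (-12.84, 4.17)
sex               R              1.07  (0.94, 1.23)
note: region: no summary measure for unordered dimension
```

Reading: infant deaths are 20.2 per 1000 more frequent in the poorest
than in the richest quintile (R = 1.61), the negative wealth ACI shows
the burden concentrated toward the poor across all five quintiles, and
the PAF says the national IMR would fall by about 29% if every quintile
matched the richest.  ACI applies only to dimensions with a natural
ordering, so it is not computed for residence or sex, and no summary
measure is computed for the unordered region dimension.

## Command line

```bash
equimort simulate --n-births 50000 --seed 1 --out births.csv
equimort estimate --births births.csv --bootstrap 1000 --seed 1
equimort disaggregate --births births.csv --dimension residence --out residence.csv
equimort measures --table residence.csv --ci parametric --out summary.csv
equimort validate --births births.csv
equimort report --config pipeline.yaml
```

## Data notes

Per-subgroup IMR estimates in the bundled table are published inputs,
not outputs of this package: recomputing them requires the survey
microdata, which is not redistributable.  The package's estimation
path is instead validated by parameter recovery on the synthetic
generator (see `docs/methods.md`).  Canonical subgroup labels are
wealth quintiles `"1"`–`"5"` (poorest → richest), education
`none` / `primary` / `secondary+`, residence `rural` / `urban`, sex
`male` / `female`.
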