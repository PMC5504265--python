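# fetalcentiles

Normative biometry of the fetal brain from MRI: construction of
gestational-age-conditional reference centiles for 2D and 3D measurements,
growth-rate analysis, cohort inclusion/exclusion auditing, rater-agreement
statistics, and a centile calculator. The package is aimed at perinatal
imaging researchers who need tested, scriptable machinery for building and
applying growth references of intracranial structures (supratentorial brain
tissue, lateral ventricles, cortex, cerebellum, extra-cerebral CSF, and the
standard 2D skull/brain diameters).

No individual-level data are deposited for the underlying cohort, so the
pipeline ships with a seeded synthetic-cohort generator that emulates the
study's statistical structure (108 fetuses / 127 scans across 21.3–38.9
gestational weeks, quadratic mean growth with widening spread, exponential
cortical growth, left > right ventricular asymmetry, and labelled exclusion
subjects), letting every stage run and be tested end to end.

## The model

Reference intervals follow the Royston–Wright mean-and-SD construction.
For a measurement *y* at gestational age *t* (decimal weeks, centered at 30):

1. **Mean curve** — ordinary least squares, *mean(t) = a + b·t + c·t²*
   for all measurements except cortical volume, which grows
   multiplicatively: *mean(t) = exp(α + k·t)* (OLS of ln *y* on *t*).
2. **SD curve** — the scaled absolute residuals *|r|·√(π/2)* are regressed
   on *t* (straight line; quadratic for cortical volume). The √(π/2)
   factor is the half-normal mean correction, so the fitted curve
   estimates the age-varying SD.
3. **Centiles** — *centile_p(t) = mean(t) + K(p)·SD(t)* with *K(p)* the
   standard-normal quantile; z-scores are *(y − mean(t))/SD(t)*.

Growth is summarised by the absolute rate (the analytic derivative of the
mean curve, units/week) and the relative growth rate
*RGR = 100·(ln V₂ − ln V₁)/(t₂ − t₁)* in %/week. Allometric scaling between
structures is the slope of ln *y* on ln *x*. Agreement between raters or
measurement techniques uses the absolute-agreement single-measure ICC
(ICC(A,1)), Bland–Altman limits of agreement (bias ± 1.96·SD of paired
differences) and per-pair percentage error.

## Worked example

The analysis is organised as numbered drivers over the library:

```bash
python analysis/01_simulate_cohort.py --seed 1   # synthetic study cohort
python analysis/02_filter_cohort.py              # exclusion audit
python analysis/03_fit_centiles.py               # reference models
python analysis/04_growth_tables.py              # growth rates + scaling
python analysis/05_agreement.py                  # rater agreement
python analysis/06_calculator_demo.py            # centile calculator
```

The filtering stage prints the cohort audit:

```
128 evaluated -> 20 excluded ({'chromosomal_abnormality': 1, 'delivery_complications': 2,
'developmental_delay': 2, 'inadequate_image_quality': 1, 'infection': 9, 'iugr': 1,
'no_contact': 3, 'seizures': 1})
included: 108 fetuses / 127 scans (scans-per-subject {1: 90, 2: 17, 3: 1})
follow-up: 81/108 (75%)
```

i.e. of 128 evaluated fetuses, 20 are removed by the first-matching
exclusion rule and 108 remain, carrying 127 usable scans; 81 have a
developmental follow-up (75%). The growth stage then reports, per
structure, the endpoint relative growth rate and the absolute rate at 30
weeks, plus log–log scaling against supratentorial brain tissue:

```
supratentorial: endpoint relative growth rate 13.37 %/week; absolute rate at 30 GW 16.43 cm^3/week
cerebellum: endpoint relative growth rate 16.09 %/week; absolute rate at 30 GW 1.08 cm^3/week
cortex ~ supratentorial^1.07 (allometric exponent)
cerebellum ~ supratentorial^1.20 (allometric exponent)
mean left-right ventricular asymmetry: 18.68%
```

Finally the calculator dates a scan from the expected date of delivery and
places measurements on the fitted references:

```
GA at scan: 29.57 weeks
  cerebellum: 9.1 cm^3 -> centile 95.3 (z = +1.67)
  supratentorial: 170 cm^3 -> centile 86.1 (z = +1.09)
  ventricles_total: 4.2 cm^3 -> centile 48.8 (z = -0.03)
```

A cerebellar volume of 9.1 cm³ at 29.57 weeks sits on the 95th centile of
this synthetic reference (z = +1.67); the ventricular volume is median.
The same operations are available from the `fetal-centiles` CLI
(`simulate`, `filter`, `fit`, `growth-table`, `agree`, `calc`).

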