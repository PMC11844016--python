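# petsurv

Quantitative FDG-PET biomarkers and their survival analysis, end to end:
from a 3D PET volume in SUV units to a validated imaging biomarker for a
time-to-event endpoint.

## The problem

In oropharyngeal carcinoma treated with definitive (chemo)radiation,
loco-regional control is good but a subset of patients later develops
distant metastases; identifying them before treatment is the clinical
goal.  Quantitative parameters of the pre-treatment FDG-PET scan are
candidate biomarkers.  For each delineated lesion:

* **SUV_max / SUV_mean** — maximum / mean standardized uptake value,
* **MTV** — metabolic tumor volume (ml),
* **TLG = MTV × SUV_mean** — total lesion glycolysis.

Each parameter comes in two per-patient flavors: `_prim` (primary tumor
only) and `_all` (primary plus all PET-positive lymph nodes), where
SUV_all is the overall maximum, MTV_all the cumulative volume, and the
overall SUV_mean is volume-weighted so that TLG_all equals the sum of
per-lesion TLG.  The scientific question the pipeline answers: does
including the nodal disease (`_all`) improve the prediction of freedom
from distant metastases (FFDM) over the primary tumor alone (`_prim`)?

## What the package provides

* `petsurv.lesions` — background-adaptive lesion delineation
  (`T = BG + β·(max − BG)`, iterated with a local background shell) and
  the SUV/MTV/TLG parameters per lesion and per patient.
* `petsurv.cox` — Cox proportional-hazards regression written from the
  partial likelihood up (Newton with step-halving, Efron/Breslow ties,
  Wald inference), Kaplan–Meier estimation, collinearity screening.
* `petsurv.cutpoint` — exhaustive optimal-cutpoint search (fit
  `parameter > v` for every observed v, keep the most significant
  admissible cutoff) and a paired bootstrap test on the difference of two
  hazard ratios, HR₁ − HR₂, across resampled patients.
* `petsurv.pipeline` — the two-cohort protocol: explorative analysis
  (metric Cox screen → binarization → prim-vs-all bootstrap →
  multivariate adjustment → KM curves), frozen-cutoff validation on an
  independent cohort, subgroup analyses, cohort summary tables.
* `petsurv.phantom` / `petsurv.cohort` — synthetic PET phantoms with
  ground-truth masks and synthetic survival cohorts with a known
  proportional-hazards structure, so the whole pipeline is testable
  without any patient data.
* `petsurv.io` — NIfTI volumes/masks, cohort CSV with a documented
  schema, YAML configs, KM plots; plus a thin `petsurv` CLI
  (`phantom`, `cohort`, `quantify`, `explore`, `validate`, `subgroup`,
  `summary`).

Intended users: imaging biostatisticians and medical-physics researchers
who want a reproducible, tested implementation of this biomarker workflow
— primarily as a Python library (see `examples/`), with the CLI for
shell-driven runs.

## Worked example

```python
import petsurv as ps

records = ps.generate_cohort(ps.CohortConfig(rng_seed=42))
metric = ps.cox_fit(records, ["tlg_all"])          # metric Cox, per ml
binar  = ps.cox_fit(records, ["tlg_all>290"])      # binarized at 290 ml
```

prints (via `examples/02_cohort_and_cox.py`):

```
cohort: 431 patients, 60 FFDM events
metric Cox, TLG_all per ml: HR = 1.0008 [1.0005, 1.0012], p = 1.2e-06
binarized at the true 290 ml step: HR = 4.44 [2.66, 7.40], p = 1.1e-08  (true HR = 4)
```

The per-ml hazard ratio looks tiny (1.0008) because TLG spans hundreds of
ml; binarized at the generating model's true 290 ml step the effect is a
hazard ratio of 4.4 with a CI comfortably covering the true value 4.  The
full protocol (`examples/04_full_study.py`) splits 431 synthetic patients
366/65, learns cutoffs on the explorative cohort and applies them frozen
to the validation cohort:

```
validation with frozen cutoffs (no re-optimization):
parameter       hr  ci_lower  ci_upper        p  n  n_events  risk
  tlg_all 4.976835  1.238886 19.992862 0.023704 65         9  > 318.507
```

Only the frozen-cutoff fit on independent data is calibrated evidence:
the explorative cutoff p-values are maximally selected and
anti-conservative — `examples/05_cutpoint_inflation.py` measures a ~7×
inflation of the nominal 5% level under the null, which is exactly why
the validation stage exists.

Each script in `examples/` is a short narrative of one capability:
phantom generation and quantification, cohort simulation and Cox fits,
cutoff search and bootstrap comparison, the full study, and the
cutpoint-inflation demonstration.

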