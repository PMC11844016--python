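"""End-to-end study orchestration: explorative analysis, frozen-cutoff

validation, subgroup analyses, and cohort summaries.

The protocol mirrors the standard explorative/validation biomarker design:

1. univariate metric Cox regression of all clinical and PET parameters;
2. PET parameters reaching at least a trend for significance advance to
   exhaustive cutoff optimization and are refitted binarized;
3. paired bootstrap comparison of the binarized hazard ratios of each
   primary-tumor parameter against its all-lesion counterpart;
4. multivariate Cox of each advancing PET parameter (one at a time —
   the parameters of the MTV/TLG family are strongly collinear) with the
   clinical covariates significant in step 1;
5. Kaplan-Meier curves of the binarized groups.

Cutoffs learned in the explorative stage can then be applied frozen to an
independent validation cohort; the validation stage performs no cutoff
search at all.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cox import (
    CoxFit,
    KMCurve,
    cox_fit,
    cox_fit_multivariate,
    km_curve,
)
from .cutpoint import (
    Admissibility,
    BootstrapComparison,
    CutoffResult,
    bootstrap_hr_compare,
    optimize_cutoff,
)
from .errors import NoEventsError, PetsurvError
from .records import NA, PET_PARAMS, PatientRecord, cohort_frame
from . import errors as _errors

logger = logging.getLogger("petsurv")

#: Default Table-2-style clinical covariate roster (binarization rules).
DEFAULT_CLINICAL_COVARIATES = [
    "sex=male",
    "age>61",
    "t_stage>2",
    "n_stage>1",
    "uicc_stage>3",
    "chemo=no",
    "hpv=negative",
]


@dataclass
class StudyConfig:
    endpoint: str = "ffdm"                     # "ffdm" | "os"
    significance_threshold: float = 0.05
    trend_threshold: float = 0.1
    pet_params: list[str] = field(default_factory=lambda: list(PET_PARAMS))
    clinical_covariates: list[str] = field(
        default_factory=lambda: list(DEFAULT_CLINICAL_COVARIATES)
    )
    bootstrap_samples: int = 100_000
    bootstrap_seed: int = 0
    admissibility: Admissibility = field(default_factory=Admissibility)
    ties: str = "efron"

    def __post_init__(self):
        if not (0 < self.significance_threshold < 1) or not (
            0 < self.trend_threshold < 1
        ):
            raise _errors.ConfigError("thresholds must lie in (0, 1)")
        if self.trend_threshold < self.significance_threshold:
            raise _errors.ConfigError(
                "trend threshold must be >= significance threshold"
            )

    def hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class StudyReport:
    """All artifacts of one pipeline stage; every table row carries the

    number of patients and events it was computed on."""

    stage: str                                   # explorative | validation | ...
    endpoint: str
    metric_table: pd.DataFrame | None = None
    binarized_table: pd.DataFrame | None = None
    cutoffs: dict[str, CutoffResult] = field(default_factory=dict)
    bootstrap_comparisons: list[BootstrapComparison] = field(default_factory=list)
    multivariate: dict[str, pd.DataFrame] = field(default_factory=dict)
    km_curves: dict[str, list[KMCurve]] = field(default_factory=dict)
    summary: pd.DataFrame | None = None
    advancing_params: list[str] = field(default_factory=list)
    dropped_params: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def frozen_cutoff_values(self) -> dict[str, float]:
        return {p: r.cutoff for p, r in self.cutoffs.items()}

    def save(self, outdir) -> None:
        """Write tables as CSV and scalar results as JSON under ``outdir``."""
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("metric_table", "binarized_table", "summary"):
            tab = getattr(self, name)
            if tab is not None:
                tab.to_csv(out / f"{self.stage}_{name}.csv", index=False)
        for param, tab in self.multivariate.items():
            tab.to_csv(out / f"{self.stage}_multivariate_{param}.csv", index=False)
        blob = {
            "stage": self.stage,
            "endpoint": self.endpoint,
            "advancing_params": self.advancing_params,
            "dropped_params": self.dropped_params,
            "cutoffs": {p: r.to_dict() for p, r in self.cutoffs.items()},
            "bootstrap_comparisons": [
                c.to_dict() for c in self.bootstrap_comparisons
            ],
            "provenance": self.provenance,
        }
        (out / f"{self.stage}_report.json").write_text(
            json.dumps(blob, indent=2, default=str)
        )
        for name, curves in self.km_curves.items():
            for curve in curves:
                safe = re.sub(r"[^\w.-]+", "_", curve.label or "all")
                fn = out / f"{self.stage}_km_{name}_{safe}.csv"
                curve.to_frame().to_csv(fn, index=False)


def _fit_row(fit_or_error, parameter: str) -> dict:
    if isinstance(fit_or_error, CoxFit):
        f = fit_or_error
        return {
            "parameter": parameter,
            "hr": float(f.hr[0]),
            "ci_lower": float(f.ci_lower[0]),
            "ci_upper": float(f.ci_upper[0]),
            "p": float(f.p[0]),
            "n": f.n,
            "n_events": f.n_events,
            "note": "",
        }
    return {
        "parameter": parameter,
        "hr": np.nan,
        "ci_lower": np.nan,
        "ci_upper": np.nan,
        "p": np.nan,
        "n": 0,
        "n_events": 0,
        "note": f"{type(fit_or_error).__name__}: {fit_or_error}",
    }


_ROW_DEGENERACIES = (
    _errors.NoEventsError,
    _errors.DegenerateCovariateError,
    _errors.MonotoneLikelihoodError,
    _errors.CollinearDesignError,
    _errors.ConvergenceError,
)


def _univariate_metric_table(df, params, config) -> pd.DataFrame:
    rows = []
    for p in params:
        try:
            fit = cox_fit(df, [p], ties=config.ties, endpoint=config.endpoint)
            rows.append(_fit_row(fit, p))
        except _ROW_DEGENERACIES as exc:
            rows.append(_fit_row(exc, p))
    return pd.DataFrame(rows)


def _binarized_groups(df, param, cutoff, endpoint):
    x = pd.to_numeric(df[param], errors="coerce")
    t = pd.to_numeric(df[f"{endpoint}_time"], errors="coerce")
    e = pd.to_numeric(df[f"{endpoint}_event"], errors="coerce")
    keep = x.notna() & t.notna() & e.notna()
    x, t, e = x[keep], t[keep], e[keep]
    high = x > cutoff
    return t.to_numpy(float), e.to_numpy(int), high.to_numpy(bool)


def _km_pair(df, param, cutoff, endpoint) -> list[KMCurve]:
    t, e, high = _binarized_groups(df, param, cutoff, endpoint)
    curves = []
    for sel, label in ((~high, f"<= {cutoff:g}"), (high, f"> {cutoff:g}")):
        if sel.sum():
            curves.append(km_curve(t[sel], e[sel], label=label))
    return curves


def run_explorative(
    records: list[PatientRecord] | pd.DataFrame, config: StudyConfig | None = None
) -> StudyReport:
    """Run the full explorative protocol (steps 1-5 above).

    PET parameters with a metric-Cox Wald p below the trend threshold
    advance to cutoff optimization; the rest (typically the SUV
    parameters) are dropped from all further stages.
    """
    if config is None:
        config = StudyConfig()
    df = records if isinstance(records, pd.DataFrame) else cohort_frame(records)
    n_events = int(pd.to_numeric(df[f"{config.endpoint}_event"]).sum())
    if n_events < 2:
        raise NoEventsError(
            f"explorative stage step 1 (metric Cox): {n_events} events; "
            "need at least 2"
        )
    report = StudyReport(
        stage="explorative",
        endpoint=config.endpoint,
        provenance={
            "config_hash": config.hash(),
            "bootstrap_seed": config.bootstrap_seed,
            "n": int(len(df)),
            "n_events": n_events,
        },
    )

    # step 1: metric univariate Cox, clinical + PET
    all_params = list(config.clinical_covariates) + list(config.pet_params)
    report.metric_table = _univariate_metric_table(df, all_params, config)
    tab = report.metric_table.set_index("parameter")

    pet_p = tab.loc[[p for p in config.pet_params if p in tab.index], "p"]
    advancing = [p for p, pv in pet_p.items() if pv < config.trend_threshold]
    report.advancing_params = advancing
    report.dropped_params = [p for p in config.pet_params if p not in advancing]
    logger.info(
        "explorative: advancing %s, dropped %s", advancing, report.dropped_params
    )

    clin_p = tab.loc[
        [c for c in config.clinical_covariates if c in tab.index], "p"
    ]
    significant_clinical = [
        c for c, pv in clin_p.items() if pv < config.significance_threshold
    ]

    # step 2: cutoff optimization + binarized univariate Cox
    bin_rows = []
    for param in advancing:
        try:
            res = optimize_cutoff(
                df,
                param,
                endpoint=config.endpoint,
                admissibility=config.admissibility,
                ties=config.ties,
            )
        except _errors.NoAdmissibleCutoffError as exc:
            logger.warning("cutoff search failed for %s: %s", param, exc)
            bin_rows.append(_fit_row(exc, param))
            continue
        report.cutoffs[param] = res
        bin_rows.append(
            {
                "parameter": param,
                "risk": f"> {res.cutoff:g}",
                "hr": res.hr,
                "ci_lower": res.ci_lower,
                "ci_upper": res.ci_upper,
                "p": res.p,
                "n": res.n,
                "n_events": res.n_events,
                "note": "",
            }
        )
        # step 5: KM curves of the binarized groups
        report.km_curves[param] = _km_pair(
            df, param, res.cutoff, config.endpoint
        )
    report.binarized_table = pd.DataFrame(bin_rows)

    # step 3: paired bootstrap prim vs all per parameter family
    families = sorted({p.rsplit("_", 1)[0] for p in report.cutoffs})
    for fam in families:
        p_all, p_prim = f"{fam}_all", f"{fam}_prim"
        if p_all in report.cutoffs and p_prim in report.cutoffs:
            try:
                comp = bootstrap_hr_compare(
                    df,
                    (p_all, report.cutoffs[p_all].cutoff),
                    (p_prim, report.cutoffs[p_prim].cutoff),
                    n_samples=config.bootstrap_samples,
                    rng_seed=config.bootstrap_seed,
                    endpoint=config.endpoint,
                    ties=config.ties,
                )
            except _errors.DegenerateResamplesError as exc:
                logger.warning("bootstrap %s vs %s failed: %s", p_all, p_prim, exc)
                continue
            report.bootstrap_comparisons.append(comp)

    # step 4: multivariate, one PET parameter at a time (collinear family)
    for param in advancing:
        try:
            fit = cox_fit_multivariate(
                df,
                param,
                significant_clinical,
                ties=config.ties,
                endpoint=config.endpoint,
            )
            report.multivariate[param] = fit.summary()
        except (_errors.PetsurvError) as exc:
            logger.warning("multivariate fit failed for %s: %s", param, exc)
            report.multivariate[param] = pd.DataFrame([_fit_row(exc, param)])
    report.provenance["significant_clinical"] = significant_clinical
    return report


def run_validation(
    records: list[PatientRecord] | pd.DataFrame,
    frozen_cutoffs: dict[str, float],
    config: StudyConfig | None = None,
) -> StudyReport:
    """Apply externally learned cutoffs to an independent cohort.

    Only univariate binarized Cox fits and Kaplan-Meier curves are
    computed; no cutoff search of any kind takes place (the report's
    provenance carries the frozen values verbatim and no candidate grid).
    A cutoff that leaves a group empty or event-free is reported as a
    degenerate row, not raised.
    """
    if config is None:
        config = StudyConfig()
    df = records if isinstance(records, pd.DataFrame) else cohort_frame(records)
    report = StudyReport(
        stage="validation",
        endpoint=config.endpoint,
        provenance={
            "config_hash": config.hash(),
            "frozen_cutoffs": dict(frozen_cutoffs),
            "n": int(len(df)),
            "n_events": int(pd.to_numeric(df[f"{config.endpoint}_event"]).sum()),
        },
    )
    rows = []
    for param, cutoff in frozen_cutoffs.items():
        try:
            fit = cox_fit(
                df, [f"{param}>{cutoff}"], ties=config.ties, endpoint=config.endpoint
            )
            row = _fit_row(fit, param)
        except (_errors.NoEventsError, *_ROW_DEGENERACIES) as exc:
            row = _fit_row(exc, param)
        row["risk"] = f"> {cutoff:g}"
        rows.append(row)
        report.km_curves[param] = _km_pair(df, param, cutoff, config.endpoint)
    report.binarized_table = pd.DataFrame(rows)
    return report


def subgroup_analysis(
    records: list[PatientRecord] | pd.DataFrame,
    stratum_covariate: str = "hpv",
    config: StudyConfig | None = None,
) -> dict[str, StudyReport]:
    """Explorative protocol per stratum of a categorical covariate.

    Patients with the ``"n/a"`` sentinel in the stratum covariate are
    excluded from every stratum.  Strata with fewer than 2 events are
    skipped (logged).  Within a stratum the multivariate step runs only
    when some clinical covariate is significant there.
    """
    if config is None:
        config = StudyConfig()
    df = records if isinstance(records, pd.DataFrame) else cohort_frame(records)
    out: dict[str, StudyReport] = {}
    for value in sorted(df[stratum_covariate].astype(str).unique()):
        if value == NA:
            continue
        sub = df[df[stratum_covariate].astype(str) == value]
        n_events = int(pd.to_numeric(sub[f"{config.endpoint}_event"]).sum())
        if len(sub) < 2 or n_events < 2:
            logger.info(
                "skipping stratum %s=%s (n=%d, events=%d)",
                stratum_covariate, value, len(sub), n_events,
            )
            continue
        # within-stratum covariate is constant; drop it from the roster
        sub_config = StudyConfig(
            endpoint=config.endpoint,
            significance_threshold=config.significance_threshold,
            trend_threshold=config.trend_threshold,
            pet_params=config.pet_params,
            clinical_covariates=[
                c
                for c in config.clinical_covariates
                if not c.startswith(f"{stratum_covariate}=")
            ],
            bootstrap_samples=config.bootstrap_samples,
            bootstrap_seed=config.bootstrap_seed,
            admissibility=config.admissibility,
            ties=config.ties,
        )
        report = run_explorative(sub, sub_config)
        report.stage = f"subgroup_{stratum_covariate}_{value}"
        report.provenance["stratum"] = {stratum_covariate: value}
        report.provenance["independently_validated"] = False
        out[value] = report
    return out


#: Covariates summarized by Table-1-style counts.
SUMMARY_CATEGORICALS = ["sex", "t_stage", "n_stage", "uicc_stage", "chemo", "hpv"]


def cohort_summary(
    records: list[PatientRecord] | pd.DataFrame,
    categoricals: list[str] | None = None,
) -> pd.DataFrame:
    """Patient-characteristics table: counts with percentages of total n

    (one decimal) per categorical covariate; mean +/- SD and median for
    age."""
    df = records if isinstance(records, pd.DataFrame) else cohort_frame(records)
    if len(df) == 0:
        raise PetsurvError("cannot summarize an empty cohort")
    if categoricals is None:
        categoricals = SUMMARY_CATEGORICALS
    n = len(df)
    rows = []
    age = pd.to_numeric(df["age"], errors="coerce").dropna()
    if len(age):
        rows.append(
            {
                "characteristic": "age",
                "category": "mean±sd",
                "value": f"{age.mean():.0f} ± {age.std(ddof=1):.0f}",
                "count": len(age),
                "percent": np.nan,
            }
        )
        rows.append(
            {
                "characteristic": "age",
                "category": "median",
                "value": f"{age.median():.0f}",
                "count": len(age),
                "percent": np.nan,
            }
        )
    for cov in categoricals:
        counts = df[cov].astype(str).value_counts()
        for cat, cnt in counts.items():
            pct = round(100.0 * cnt / n, 1)
            rows.append(
                {
                    "characteristic": cov,
                    "category": cat,
                    "value": f"{cnt} ({pct})",
                    "count": int(cnt),
                    "percent": pct,
                }
            )
    return pd.DataFrame(rows)
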