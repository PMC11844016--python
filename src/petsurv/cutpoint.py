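"""Optimal Cox cutpoint search and bootstrap hazard-ratio comparison.

``optimize_cutoff`` binarizes a metric biomarker at every observed value,
fits a univariate Cox model per candidate, and returns the admissible
cutoff with the most significant Wald p-value.  This is a maximally
selected statistic: the returned p-value is anti-conservative under the
null and must be validated on independent data (see the study pipeline's
frozen-cutoff validation stage).

``bootstrap_hr_compare`` tests whether one binarized biomarker carries a
larger hazard ratio than another on the same patients: patients are
resampled with replacement (paired — the same bootstrap indices for both
biomarkers), both binarized Cox models are refitted per resample, and the
p-value is derived from the percentile position of 0 in the resampled
distribution of HR1 - HR2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cox import CoxFit, binary_cox
from .errors import (
    CollinearDesignError,
    ConvergenceError,
    DegenerateCovariateError,
    DegenerateResamplesError,
    MonotoneLikelihoodError,
    NoAdmissibleCutoffError,
    NoEventsError,
    PetsurvError,
)
from .records import cohort_frame

_FIT_DEGENERACIES = (
    NoEventsError,
    DegenerateCovariateError,
    MonotoneLikelihoodError,
    ConvergenceError,
    CollinearDesignError,
)


@dataclass
class Admissibility:
    """Constraints a candidate cutoff must satisfy on each side.

    An unconstrained search degenerates at extreme values (a one-patient
    group can yield an arbitrarily significant fit); requiring at least
    ``min_fraction`` of the patients and ``min_events`` events on each
    side keeps candidates interpretable.
    """

    min_fraction: float = 0.10
    min_events: int = 3


@dataclass
class CutoffResult:
    parameter: str
    cutoff: float          # one of the observed parameter values
    coef: float
    hr: float
    ci_lower: float
    ci_upper: float
    p: float
    n: int
    n_events: int
    grid_size: int         # number of candidate values examined
    admissibility: Admissibility

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "risk": f"> {self.cutoff:g}",
            "cutoff": self.cutoff,
            "hr": self.hr,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "p": self.p,
            "n": self.n,
            "n_events": self.n_events,
            "grid_size": self.grid_size,
        }


@dataclass
class BootstrapComparison:
    parameter1: str
    parameter2: str
    cutoff1: float
    cutoff2: float
    n_samples: int
    rng_seed: int
    n_degenerate_resamples: int
    mean_difference: float     # mean of HR1 - HR2 over retained resamples
    q025: float
    q975: float
    p: float

    def to_dict(self) -> dict:
        return {
            "parameter1": self.parameter1,
            "parameter2": self.parameter2,
            "cutoff1": self.cutoff1,
            "cutoff2": self.cutoff2,
            "n_samples": self.n_samples,
            "rng_seed": self.rng_seed,
            "n_degenerate_resamples": self.n_degenerate_resamples,
            "mean_difference": self.mean_difference,
            "q025": self.q025,
            "q975": self.q975,
            "p": self.p,
        }


def _extract(records, parameter: str, endpoint: str):
    df = records if isinstance(records, pd.DataFrame) else cohort_frame(records)
    x = pd.to_numeric(df[parameter], errors="coerce")
    t = pd.to_numeric(df[f"{endpoint}_time"], errors="coerce")
    e = pd.to_numeric(df[f"{endpoint}_event"], errors="coerce")
    keep = x.notna() & t.notna() & e.notna()
    return (
        x[keep].to_numpy(dtype=float),
        t[keep].to_numpy(dtype=float),
        e[keep].to_numpy(dtype=int),
    )


def _binary_fit(group, time, event, ties="efron") -> CoxFit:
    """Univariate Cox on a 0/1 indicator via the fast exact binary path."""
    coef, se = binary_cox(time, event, group, ties=ties)
    return CoxFit(
        names=["high"],
        coef=np.array([coef]),
        se=np.array([se]),
        n=len(time),
        n_events=int(np.asarray(event).sum()),
        ties=ties,
        n_iter=-1,
        log_likelihood=np.nan,
    )


def optimize_cutoff(
    records,
    parameter: str,
    endpoint: str = "ffdm",
    admissibility: Admissibility | None = None,
    ties: str = "efron",
) -> CutoffResult:
    """Exhaustive Cox-significance cutoff search over observed values.

    For every observed value v of ``parameter``, a univariate Cox model is
    fitted on the indicator ``parameter > v``; the admissible v with the
    smallest Wald p-value is returned.  Ties on p are broken toward the
    larger hazard ratio, then toward the smaller cutoff.

    Raises
    ------
    NoAdmissibleCutoffError
        If no candidate satisfies the admissibility rule (e.g. a constant
        parameter) or every admissible fit is degenerate.
    """
    if admissibility is None:
        admissibility = Admissibility()
    x, time, event, = _extract(records, parameter, endpoint)
    n = len(x)
    if n == 0:
        raise NoAdmissibleCutoffError(f"no complete cases for {parameter!r}")
    candidates = np.unique(x)
    min_side = max(int(np.ceil(admissibility.min_fraction * n)), 1)
    best = None
    grid = 0
    for v in candidates:
        high = x > v
        n_high = int(high.sum())
        if n_high < min_side or n - n_high < min_side:
            continue
        ev_high = int(event[high].sum())
        ev_low = int(event[~high].sum())
        if ev_high < admissibility.min_events or ev_low < admissibility.min_events:
            continue
        grid += 1
        try:
            fit = _binary_fit(high.astype(float), time, event, ties)
        except _FIT_DEGENERACIES:
            continue
        key = (fit.p[0], -fit.hr[0], v)  # min p, then max HR, then min cutoff
        if best is None or key < best[0]:
            best = (key, v, fit)
    if best is None:
        raise NoAdmissibleCutoffError(
            f"no admissible cutoff for {parameter!r} "
            f"(n={n}, events={int(event.sum())}, rule={admissibility})"
        )
    _, v, fit = best
    return CutoffResult(
        parameter=parameter,
        cutoff=float(v),
        coef=float(fit.coef[0]),
        hr=float(fit.hr[0]),
        ci_lower=float(fit.ci_lower[0]),
        ci_upper=float(fit.ci_upper[0]),
        p=float(fit.p[0]),
        n=fit.n,
        n_events=fit.n_events,
        grid_size=grid,
        admissibility=admissibility,
    )


def _resample_hr(group, time, event, idx, ties):
    """HR of a binarized fit on one bootstrap resample, or None if degenerate.

    A resample is degenerate when either group is empty or event-free, or
    when the fit itself fails (monotone likelihood, non-convergence).
    """
    g, t, e = group[idx], time[idx], event[idx]
    n_high = int(g.sum())
    if n_high == 0 or n_high == len(g):
        return None
    if e[g > 0.5].sum() == 0 or e[g < 0.5].sum() == 0:
        return None
    try:
        fit = _binary_fit(g, t, e, ties)
    except _FIT_DEGENERACIES:
        return None
    return float(fit.hr[0])


def bootstrap_hr_compare(
    records,
    spec1: tuple[str, float],
    spec2: tuple[str, float],
    n_samples: int = 100_000,
    rng_seed: int = 0,
    endpoint: str = "ffdm",
    alternative: str = "two-sided",
    ties: str = "efron",
    max_degenerate_fraction: float = 0.20,
    return_distribution: bool = False,
):
    """Paired bootstrap test on the difference of two binarized-Cox HRs.

    ``spec1``/``spec2`` are ``(parameter, cutoff)`` pairs; both must be
    admissible (both groups non-empty with events) on the full data.  Per
    resample the SAME patient indices are used for both biomarkers — the
    resampling stream is ``default_rng(rng_seed).integers(0, n, (n_samples,
    n))`` — and the difference HR1 - HR2 is recorded.  Degenerate resamples
    are excluded and counted.

    The two-sided p-value is ``min(1, 2 * min(P(D <= 0), P(D >= 0)))``
    over the retained differences D; one-sided alternatives ``"greater"``
    (HR1 > HR2) and ``"less"`` are available.

    Raises
    ------
    DegenerateResamplesError
        If more than ``max_degenerate_fraction`` of the resamples are
        degenerate — enlarge the cohort or move the cutoffs inward.
    """
    p1, c1 = spec1
    p2, c2 = spec2
    df = records if isinstance(records, pd.DataFrame) else cohort_frame(records)
    x1, t1, e1 = _extract(df, p1, endpoint)
    x2, t2, e2 = _extract(df, p2, endpoint)
    if len(x1) != len(x2) or not (np.array_equal(t1, t2) and np.array_equal(e1, e2)):
        raise PetsurvError(
            "paired bootstrap requires both parameters on the same patients "
            "(complete cases differ)"
        )
    n = len(x1)
    g1 = (x1 > c1).astype(float)
    g2 = (x2 > c2).astype(float)
    for name, g, e in ((p1, g1, e1), (p2, g2, e2)):
        if g.sum() in (0, n) or e[g > 0.5].sum() == 0 or e[g < 0.5].sum() == 0:
            raise PetsurvError(
                f"binarization of {name!r} is degenerate on the full data"
            )

    rng = np.random.default_rng(rng_seed)
    diffs = np.empty(n_samples)
    kept = 0
    degenerate = 0
    for b in range(n_samples):
        idx = rng.integers(0, n, size=n)
        hr1 = _resample_hr(g1, t1, e1, idx, ties)
        hr2 = _resample_hr(g2, t2, e2, idx, ties) if hr1 is not None else None
        if hr1 is None or hr2 is None:
            degenerate += 1
            continue
        diffs[kept] = hr1 - hr2
        kept += 1
    if degenerate > max_degenerate_fraction * n_samples:
        raise DegenerateResamplesError(
            f"{degenerate}/{n_samples} bootstrap resamples were degenerate; "
            "use a larger cohort or less extreme cutoffs"
        )
    d = diffs[:kept]
    q_le = float(np.mean(d <= 0.0))
    q_ge = float(np.mean(d >= 0.0))
    if alternative == "two-sided":
        p = min(1.0, 2.0 * min(q_le, q_ge))
    elif alternative == "greater":   # H1: HR1 > HR2
        p = q_le
    elif alternative == "less":
        p = q_ge
    else:
        raise PetsurvError(f"unknown alternative {alternative!r}")
    p = max(p, 1.0 / (kept + 1))  # never report exactly 0
    result = BootstrapComparison(
        parameter1=p1,
        parameter2=p2,
        cutoff1=float(c1),
        cutoff2=float(c2),
        n_samples=n_samples,
        rng_seed=rng_seed,
        n_degenerate_resamples=degenerate,
        mean_difference=float(d.mean()),
        q025=float(np.quantile(d, 0.025)),
        q975=float(np.quantile(d, 0.975)),
        p=float(p),
    )
    if return_distribution:
        return result, d.copy()
    return result
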