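"""Cox proportional-hazards regression and Kaplan-Meier estimation.

The Cox partial likelihood is maximized by Newton iteration with
step-halving, with Efron (default) or Breslow handling of tied event
times.  Standard errors come from the inverse observed information
(Wald); 95% confidence intervals are ``exp(coef +/- 1.96 * SE)``.

Let t_(1) < ... < t_(K) be the distinct event times, D_k the index set of
the d_k events at t_(k), R_k the risk set, and w_i = exp(x_i' beta).  The
Breslow log partial likelihood is

    l(beta) = sum_k [ sum_{i in D_k} x_i' beta - d_k log( sum_{R_k} w_i ) ]

Efron replaces the risk-set sum in the l-th of the d_k tied terms by
``S_Rk - (l/d_k) S_Dk`` (l = 0..d_k-1), which is exact when ties arise
from coarse time recording.

Covariates can be given as metric record fields ("tlg_all", "age") or as
binarization rules parsed from strings: ``"age>61"``, ``"t_stage>2"``
(ordinal stage comparison), ``"sex=male"`` (category indicator).  Records
with a missing value in any requested covariate are dropped (complete-case
analysis per fit).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    CollinearDesignError,
    ConvergenceError,
    DegenerateCovariateError,
    MonotoneLikelihoodError,
    NoEventsError,
    PetsurvError,
)
from .records import NA, PatientRecord, cohort_frame

_Z95 = stats.norm.ppf(0.975)
_BETA_DIVERGENCE = 15.0  # |coef| beyond this signals a monotone likelihood

#: Ordinal encodings for staged covariates ("t_stage>2" etc.).
STAGE_ORDINALS = {
    "t_stage": {"T1": 1, "T2": 2, "T3": 3, "T4": 4},  # Tx -> missing
    "n_stage": {"N0": 0, "N1": 1, "N2": 2, "N3": 3},
    "uicc_stage": {"I": 1, "II": 2, "III": 3, "IV": 4},
}


@dataclass
class CoxFit:
    """A fitted Cox model: one row of statistics per covariate."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    n: int
    n_events: int
    ties: str
    n_iter: int
    log_likelihood: float

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci_lower(self) -> np.ndarray:
        return np.exp(self.coef - _Z95 * self.se)

    @property
    def ci_upper(self) -> np.ndarray:
        return np.exp(self.coef + _Z95 * self.se)

    @property
    def z(self) -> np.ndarray:
        return self.coef / self.se

    @property
    def p(self) -> np.ndarray:
        """Two-sided Wald p-values."""
        return 2.0 * stats.norm.sf(np.abs(self.z))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": self.names,
                "coef": self.coef,
                "hr": self.hr,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "p": self.p,
                "n": self.n,
                "n_events": self.n_events,
            }
        )

    def to_dict(self) -> dict:
        df = self.summary()
        return {
            "ties": self.ties,
            "n": self.n,
            "n_events": self.n_events,
            "log_likelihood": self.log_likelihood,
            "covariates": df.to_dict(orient="records"),
        }


@dataclass
class KMCurve:
    """Product-limit survival estimate."""

    times: np.ndarray          # distinct event times, ascending
    survival: np.ndarray       # S(t) just after each event time
    at_risk: np.ndarray        # number at risk at each event time
    n_events: np.ndarray       # events at each time
    n: int
    label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "n_events": self.n_events,
            }
        )


# ---------------------------------------------------------------------------
# core partial-likelihood machinery (array interface)
# ---------------------------------------------------------------------------

def _loglik_grad_hess(beta, X, time, event, ties):
    """Log partial likelihood, gradient, and Hessian at ``beta``.

    Arrays must already be sorted by ascending time.  Fully vectorized over
    tie blocks (``np.add.reduceat``); the Efron correction is applied per
    event via its within-block event rank.  The overflow shift of eta
    cancels exactly in the log partial likelihood (each of the D log terms
    absorbs the shift once), so likelihood values remain comparable across
    beta for step-halving.
    """
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.max()
    w = np.exp(eta)
    xw = X * w[:, None]
    xxw = (X[:, :, None] * X[:, None, :]).reshape(n, p * p) * w[:, None]
    ev = event.astype(bool)

    new_block = np.empty(n, dtype=bool)
    new_block[0] = True
    np.not_equal(time[1:], time[:-1], out=new_block[1:])
    starts = np.flatnonzero(new_block)
    block_of = np.cumsum(new_block) - 1

    def suffix(arr):
        blk = np.add.reduceat(arr, starts, axis=0)
        return np.cumsum(blk[::-1], axis=0)[::-1]

    S0 = suffix(w)                # risk-set sums at each block's time
    S1 = suffix(xw)
    S2 = suffix(xxw)

    loglik = float(eta[ev].sum())
    grad = X[ev].sum(axis=0)
    hess_flat = np.zeros(p * p)

    if ties == "breslow":
        d_blk = np.add.reduceat(event.astype(float), starts)
        m = d_blk > 0
        d, s0, s1, s2 = d_blk[m], S0[m], S1[m], S2[m]
        loglik -= float((d * np.log(s0)).sum())
        grad -= (d[:, None] * s1 / s0[:, None]).sum(axis=0)
        outer = (s1[:, :, None] * s1[:, None, :]).reshape(-1, p * p)
        hess_flat -= (
            d[:, None] * (s2 / s0[:, None] - outer / (s0**2)[:, None])
        ).sum(axis=0)
    else:  # efron
        d_blk = np.add.reduceat(event.astype(float), starts)
        wd_blk = np.add.reduceat(w * event, starts)
        xwd_blk = np.add.reduceat(xw * event[:, None], starts, axis=0)
        xxwd_blk = np.add.reduceat(xxw * event[:, None], starts, axis=0)
        # per-event rank among the events of its own tie block
        ev_cum = np.cumsum(event)
        before = ev_cum[starts] - event[starts]
        rank = (ev_cum - 1 - before[block_of])[ev].astype(float)
        b = block_of[ev]
        f = (rank / d_blk[b])[:, None]
        a0 = S0[b] - f[:, 0] * wd_blk[b]
        a1 = S1[b] - f * xwd_blk[b]
        a2 = S2[b] - f * xxwd_blk[b]
        loglik -= float(np.log(a0).sum())
        grad -= (a1 / a0[:, None]).sum(axis=0)
        outer = (
            a1.reshape(-1, p, 1) * a1.reshape(-1, 1, p)
        ).reshape(-1, p * p)
        hess_flat -= (a2 / a0[:, None] - outer / (a0**2)[:, None]).sum(axis=0)

    return loglik, grad, hess_flat.reshape(p, p)


def cox_ph(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    names: list[str] | None = None,
    ties: str = "efron",
    tol: float = 1e-9,
    max_iter: int = 50,
) -> CoxFit:
    """Fit a Cox model on plain arrays (the engine behind :func:`cox_fit`).

    Newton iteration from beta = 0 with step-halving on any decrease of the
    partial likelihood; convergence when the coefficient change falls below
    ``tol`` in the max norm.

    Raises
    ------
    NoEventsError, DegenerateCovariateError, CollinearDesignError,
    MonotoneLikelihoodError, ConvergenceError
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(time) > 1:
        X = X.T
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n, p = X.shape
    if names is None:
        names = [f"x{i}" for i in range(p)]
    if event.sum() == 0:
        raise NoEventsError("no events in the data; Cox model is undefined")
    for j in range(p):
        if np.ptp(X[:, j]) == 0:
            raise DegenerateCovariateError(
                f"covariate {names[j]!r} is constant across all patients"
            )

    order = np.argsort(time, kind="stable")
    Xs, ts, es = X[order], time[order], event[order]

    beta = np.zeros(p)
    ll, grad, hess = _loglik_grad_hess(beta, Xs, ts, es, ties)
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            raise CollinearDesignError(
                "observed information is singular (collinear design)"
            ) from None
        # step-halving
        new_beta = beta + step
        new_ll, new_grad, new_hess = _loglik_grad_hess(new_beta, Xs, ts, es, ties)
        halvings = 0
        while not (new_ll >= ll - 1e-12) and halvings < 30:  # NaN counts as worse
            step = step / 2.0
            new_beta = beta + step
            new_ll, new_grad, new_hess = _loglik_grad_hess(
                new_beta, Xs, ts, es, ties
            )
            halvings += 1
        delta = np.abs(new_beta - beta).max()
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if np.abs(beta).max() > _BETA_DIVERGENCE:
            j = int(np.abs(beta).argmax())
            raise MonotoneLikelihoodError(names[j], 1 if beta[j] > 0 else -1)
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"Cox Newton iteration did not converge in {max_iter} steps "
            f"(last coefficient change {delta:.3g})"
        )

    info = -hess
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        raise CollinearDesignError(
            "observed information is singular at the optimum"
        ) from None
    diag = np.diag(cov)
    if np.any(diag <= 0):
        raise CollinearDesignError("non-positive variance estimate (collinearity)")
    return CoxFit(
        names=list(names),
        coef=beta,
        se=np.sqrt(diag),
        n=n,
        n_events=int(event.sum()),
        ties=ties,
        n_iter=it,
        log_likelihood=ll,
    )


def binary_cox(
    time: np.ndarray,
    event: np.ndarray,
    group: np.ndarray,
    ties: str = "efron",
    tol: float = 1e-9,
    max_iter: int = 50,
) -> tuple[float, float]:
    """Exact Cox fit for a single binary 0/1 covariate; returns (coef, se).

    Computes the same Efron/Breslow partial-likelihood maximizer as
    :func:`cox_ph` but exploits that for a binary covariate every risk-set
    quantity reduces to at-risk and event COUNTS per tie block, which do
    not depend on beta.  With r = exp(beta) and, per event term,
    ``a1 = (R1 - f d1) r`` and ``a0 = (R0 - f d0) + a1`` (f = l/d under
    Efron, 0 under Breslow), the score is ``D1 - sum a1/a0`` — a scalar
    Newton iteration over precomputed arrays.  Used by the cutoff search
    and the bootstrap, where hundreds of thousands of such fits occur.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group, dtype=float)
    n = len(time)
    d_total = int(event.sum())
    if d_total == 0:
        raise NoEventsError("no events in the data; Cox model is undefined")
    if group.min() == group.max():
        raise DegenerateCovariateError("binary covariate is constant")
    d1_total = int(event[group > 0.5].sum())
    if d1_total == 0 or d1_total == d_total:
        raise MonotoneLikelihoodError("high", 1 if d1_total else -1)

    order = np.argsort(time, kind="stable")
    t, e, g = time[order], event[order], group[order]

    new_block = np.empty(n, dtype=bool)
    new_block[0] = True
    np.not_equal(t[1:], t[:-1], out=new_block[1:])
    starts = np.flatnonzero(new_block)
    block_of = np.cumsum(new_block) - 1

    ones_blk = np.add.reduceat(np.ones(n), starts)
    g_blk = np.add.reduceat(g, starts)
    R = np.cumsum(ones_blk[::-1])[::-1]          # at risk per block
    R1 = np.cumsum(g_blk[::-1])[::-1]            # at risk in group 1
    d_blk = np.add.reduceat(e.astype(float), starts)
    d1_blk = np.add.reduceat(e * g, starts)

    ev = e.astype(bool)
    b = block_of[ev]
    if ties == "efron":
        ev_cum = np.cumsum(e)
        before = ev_cum[starts] - e[starts]
        f = (ev_cum - 1 - before[block_of])[ev] / d_blk[b]
    else:
        f = np.zeros(int(d_total))
    c1 = R1[b] - f * d1_blk[b]          # coefficient of r in a1
    c0 = (R[b] - R1[b]) - f * (d_blk[b] - d1_blk[b])

    def eval_at(beta):
        r = math.exp(beta)
        a1 = c1 * r
        a0 = c0 + a1
        ll = beta * d1_total - float(np.log(a0).sum())
        u = a1 / a0
        grad = d1_total - float(u.sum())
        hess = -float((u * (1.0 - u)).sum())
        return ll, grad, hess

    beta = 0.0
    ll, grad, hess = eval_at(beta)
    for _ in range(max_iter):
        step = -grad / hess
        nb = beta + step
        nll, ngrad, nhess = eval_at(nb)
        halvings = 0
        while not (nll >= ll - 1e-12) and halvings < 30:
            step /= 2.0
            nb = beta + step
            nll, ngrad, nhess = eval_at(nb)
            halvings += 1
        delta = abs(nb - beta)
        beta, ll, grad, hess = nb, nll, ngrad, nhess
        if abs(beta) > _BETA_DIVERGENCE:
            raise MonotoneLikelihoodError("high", 1 if beta > 0 else -1)
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"binary Cox Newton did not converge in {max_iter} steps"
        )
    if hess >= 0:
        raise CollinearDesignError("non-positive information in binary fit")
    return beta, 1.0 / math.sqrt(-hess)


# ---------------------------------------------------------------------------
# covariate encoding from patient records
# ---------------------------------------------------------------------------

_SPEC_RE = re.compile(r"^(?P<name>\w+)\s*(?P<op>[>=])\s*(?P<value>.+)$")


def encode_covariate(df: pd.DataFrame, spec: str) -> pd.Series:
    """Resolve a covariate spec string to a numeric column (NaN = missing).

    ``"tlg_all"`` — metric field as-is; ``"age>61"`` — indicator of a
    numeric or ordinal-stage comparison; ``"sex=male"`` — category
    indicator.  The ``"n/a"`` sentinel maps to NaN everywhere.
    """
    m = _SPEC_RE.match(spec)
    if m is None:
        if spec not in df.columns:
            raise PetsurvError(f"unknown covariate {spec!r}")
        col = pd.to_numeric(df[spec], errors="coerce")
        return col.rename(spec)
    name, op, value = m.group("name"), m.group("op"), m.group("value").strip()
    if name not in df.columns:
        raise PetsurvError(f"unknown covariate {name!r} in spec {spec!r}")
    raw = df[name]
    if op == "=":
        out = (raw.astype(str) == value).astype(float)
        out[raw.astype(str) == NA] = np.nan
        return out.rename(spec)
    # op == ">"
    if name in STAGE_ORDINALS:
        ordmap = STAGE_ORDINALS[name]
        level = float(value) if value.replace(".", "").isdigit() else float(
            ordmap[value]
        )
        num = raw.map(ordmap).astype(float)
    else:
        level = float(value)
        num = pd.to_numeric(raw, errors="coerce")
    out = (num > level).astype(float)
    out[num.isna()] = np.nan
    return out.rename(spec)


def design_matrix(
    records: list[PatientRecord] | pd.DataFrame,
    covariate_spec: list[str],
    endpoint: str = "ffdm",
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Build (X, time, event, names) from records; complete cases only."""
    df = records if isinstance(records, pd.DataFrame) else cohort_frame(records)
    cols = [encode_covariate(df, s) for s in covariate_spec]
    Xdf = pd.concat(cols, axis=1)
    time = pd.to_numeric(df[f"{endpoint}_time"], errors="coerce")
    event = pd.to_numeric(df[f"{endpoint}_event"], errors="coerce")
    keep = Xdf.notna().all(axis=1) & time.notna() & event.notna()
    return (
        Xdf[keep].to_numpy(dtype=float),
        time[keep].to_numpy(dtype=float),
        event[keep].to_numpy(dtype=int),
        list(Xdf.columns),
    )


def cox_fit(
    records,
    covariate_spec: list[str] | str,
    ties: str = "efron",
    endpoint: str = "ffdm",
) -> CoxFit:
    """Univariate or multivariate Cox fit on patient records."""
    if isinstance(covariate_spec, str):
        covariate_spec = [covariate_spec]
    X, time, event, names = design_matrix(records, covariate_spec, endpoint)
    if len(time) == 0:
        raise NoEventsError("no complete-case records for this covariate set")
    return cox_ph(X, time, event, names=names, ties=ties)


def cox_fit_multivariate(
    records,
    pet_param: str,
    confounders: list[str],
    ties: str = "efron",
    endpoint: str = "ffdm",
) -> CoxFit:
    """Joint fit of one PET parameter with clinical confounders.

    The PET parameter is entered one at a time (parameters of this family
    are strongly collinear); with an empty confounder list this reduces
    exactly to :func:`cox_fit`.
    """
    return cox_fit(records, [pet_param, *confounders], ties=ties, endpoint=endpoint)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def km_curve(
    time: np.ndarray, event: np.ndarray, label: str = ""
) -> KMCurve:
    """Product-limit estimator on arrays.

    Patients censored exactly at an event time count as at risk at that
    time (the standard convention).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(time) == 0:
        raise PetsurvError("empty input to the Kaplan-Meier estimator")
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    n = len(t)
    times, surv, risk, nev = [], [], [], []
    s = 1.0
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d = int(e[i:j].sum())
        if d > 0:
            at_risk = n - i
            s *= 1.0 - d / at_risk
            times.append(t[i])
            surv.append(s)
            risk.append(at_risk)
            nev.append(d)
        i = j
    return KMCurve(
        times=np.array(times),
        survival=np.array(surv),
        at_risk=np.array(risk, dtype=int),
        n_events=np.array(nev, dtype=int),
        n=n,
        label=label,
    )


def km_estimate(
    records, endpoint: str = "ffdm", label: str = ""
) -> KMCurve:
    """Kaplan-Meier estimate for one endpoint of a record list."""
    df = records if isinstance(records, pd.DataFrame) else cohort_frame(records)
    return km_curve(
        df[f"{endpoint}_time"].to_numpy(dtype=float),
        df[f"{endpoint}_event"].to_numpy(dtype=int),
        label=label,
    )


def collinearity_screen(
    records, param_list: list[str]
) -> pd.DataFrame:
    """Pairwise R^2 (squared Pearson correlation) between parameters.

    Zero-variance parameters yield NaN entries (flagged, not an error);
    complete cases are used per pair.
    """
    df = records if isinstance(records, pd.DataFrame) else cohort_frame(records)
    if len(df) < 3:
        raise PetsurvError("collinearity screen needs at least 3 records")
    k = len(param_list)
    out = np.full((k, k), np.nan)
    cols = [pd.to_numeric(df[p], errors="coerce") for p in param_list]
    for a in range(k):
        for b in range(a, k):
            pair = pd.concat([cols[a], cols[b]], axis=1).dropna()
            x, y = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            if len(x) < 3 or x.std() == 0 or y.std() == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            out[a, b] = out[b, a] = r * r
    return pd.DataFrame(out, index=param_list, columns=param_list)
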