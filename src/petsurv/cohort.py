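"""Synthetic survival cohorts with a known proportional-hazards structure.

Event times follow an exponential model whose rate is
``baseline_hazard * exp(beta_tlg * transform(TLG_all))``, with right
censoring from an administrative horizon plus uniform dropout.  Per-patient
PET parameters are built bottom-up from per-lesion volumes and uptakes (one
primary tumor plus 0-5 nodes), so the aggregation identities — TLG_all equal
to the sum of per-lesion TLG, SUV_all the overall maximum — hold exactly by
construction.

The default configuration emulates a head-and-neck chemoradiation cohort:
431 patients, covariate mix matching a typical stage-IV-dominated
oropharyngeal population, lognormal TLG_all with median 150 ml, and a
step hazard at TLG_all = 290 ml with hazard ratio 4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .records import NA, PatientRecord

#: Default category probabilities (typical oropharyngeal CRT cohort).
DEFAULT_COVARIATE_MIX: dict[str, dict[str, float]] = {
    "sex": {"male": 335 / 431, "female": 96 / 431},
    "t_stage": {
        "Tx": 1 / 429,
        "T1": 50 / 429,
        "T2": 143 / 429,
        "T3": 118 / 429,
        "T4": 117 / 429,
    },
    "n_stage": {"N0": 56 / 427, "N1": 51 / 427, "N2": 295 / 427, "N3": 25 / 427},
    "uicc_stage": {"I": 4 / 431, "II": 23 / 431, "III": 63 / 431, "IV": 341 / 431},
    "chemo": {"yes": 366 / 431, "no": 63 / 431, NA: 2 / 431},
    "hpv": {NA: 219 / 431, "negative": 89 / 431, "positive": 123 / 431},
}


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    ``tlg_transform`` selects the shape of the log-hazard in TLG_all:
    ``"identity"`` (per ml), ``"log"`` (per log-ml), or ``"threshold@V"``
    (step at V ml — the binarized-biomarker model).  ``beta_tlg`` is the
    log-hazard increment per unit of the transformed value; with the
    threshold transform, ``exp(beta_tlg)`` is the true hazard ratio of the
    high-TLG group.
    """

    n_patients: int = 431
    baseline_hazard: float = 0.002       # events per month
    beta_tlg: float = math.log(4.0)
    tlg_transform: str = "threshold@290"
    tlg_meanlog: float = math.log(150.0)  # lognormal location of TLG_all (ml)
    tlg_sdlog: float = 1.1
    censor_horizon: float = 60.0          # months, administrative
    dropout_rate: float = 0.25            # fraction with uniform(0,horizon) dropout
    covariate_mix: dict = field(default_factory=lambda: DEFAULT_COVARIATE_MIX)
    age_mean: float = 61.0
    age_sd: float = 9.0
    confounding_strength: float = 0.0     # shifts T-stage odds with log TLG_all
    os_beta_scale: float = 0.75           # OS linear predictor = scale * FFDM one
    os_baseline_hazard: float = 0.003
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if self.baseline_hazard <= 0 or self.os_baseline_hazard <= 0:
            raise ConfigError("baseline hazards must be > 0")
        if self.censor_horizon <= 0:
            raise ConfigError("censor_horizon must be > 0")
        if not 0 <= self.dropout_rate <= 1:
            raise ConfigError("dropout_rate must be in [0, 1]")
        if self.tlg_sdlog <= 0:
            raise ConfigError("tlg_sdlog must be > 0")
        _parse_transform(self.tlg_transform)
        for cov, probs in self.covariate_mix.items():
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(
                    f"covariate_mix[{cov!r}] probabilities sum to {total}, not 1"
                )


@dataclass
class CohortGroundTruth:
    """Per-patient simulation truth (before censoring)."""

    linear_predictor: np.ndarray   # beta_tlg * transform(TLG_all)
    event_time: np.ndarray         # months, uncensored (FFDM)


def _parse_transform(spec: str):
    if spec == "identity":
        return lambda x: x
    if spec == "log":
        return np.log
    if spec.startswith("threshold@"):
        try:
            v = float(spec.split("@", 1)[1])
        except ValueError as exc:
            raise ConfigError(f"bad tlg_transform {spec!r}") from exc
        return lambda x: (x > v).astype(float)
    raise ConfigError(f"unknown tlg_transform {spec!r}")


def _split_tlg_into_lesions(rng, tlg_all: float):
    """Distribute a patient's total TLG over one primary and 0-5 nodes.

    Returns per-patient PET parameters consistent with the aggregation
    rules (volume-weighted overall SUV_mean, overall SUV_max).
    """
    n_nodes = int(rng.integers(0, 6))
    # primary carries most of the burden
    prim_frac = rng.beta(6.0, 1.5) if n_nodes else 1.0
    parts = [prim_frac]
    if n_nodes:
        w = rng.dirichlet(np.ones(n_nodes))
        parts.extend((1.0 - prim_frac) * w)
    suv_means = rng.uniform(3.0, 9.0, size=n_nodes + 1)
    tlgs = np.asarray(parts) * tlg_all
    mtvs = tlgs / suv_means
    suv_maxs = suv_means * rng.uniform(1.5, 2.5, size=n_nodes + 1)
    mtv_all = float(mtvs.sum())
    tlg_sum = float(tlgs.sum())
    return {
        "suv_prim": float(suv_maxs[0]),
        "mtv_prim": float(mtvs[0]),
        "tlg_prim": float(tlgs[0]),
        "suv_all": float(suv_maxs.max()),
        "mtv_all": mtv_all,
        "tlg_all": tlg_sum,
    }


def _draw_category(rng, probs: dict[str, float]) -> str:
    cats = list(probs)
    p = np.array([probs[c] for c in cats])
    return cats[rng.choice(len(cats), p=p / p.sum())]


def generate_cohort(
    config: CohortConfig, return_truth: bool = False
) -> list[PatientRecord] | tuple[list[PatientRecord], CohortGroundTruth]:
    """Simulate a cohort of patients under the configured hazard model.

    Deterministic under a fixed ``rng_seed``: all randomness derives from a
    single ``numpy.random.default_rng`` stream.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    transform = _parse_transform(config.tlg_transform)
    n = config.n_patients

    tlg_all = rng.lognormal(config.tlg_meanlog, config.tlg_sdlog, size=n)
    pet = [_split_tlg_into_lesions(rng, t) for t in tlg_all]
    # use the summed per-lesion TLG as the authoritative TLG_all
    tlg_all = np.array([p["tlg_all"] for p in pet])

    lp = config.beta_tlg * transform(tlg_all)
    rate = config.baseline_hazard * np.exp(lp)
    event_time = rng.exponential(1.0 / rate)

    dropout = rng.random(n) < config.dropout_rate
    censor_time = np.where(
        dropout,
        rng.uniform(0.0, config.censor_horizon, size=n),
        config.censor_horizon,
    )
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    os_rate = config.os_baseline_hazard * np.exp(config.os_beta_scale * lp)
    os_event_time = rng.exponential(1.0 / os_rate)
    os_time = np.minimum(os_event_time, censor_time)
    os_event = (os_event_time <= censor_time).astype(int)

    ages = rng.normal(config.age_mean, config.age_sd, size=n)
    records = []
    for i in range(n):
        covs = {
            cov: _draw_category(rng, probs)
            for cov, probs in config.covariate_mix.items()
        }
        if config.confounding_strength > 0 and "t_stage" in covs:
            # confounded variant: large tumors drift toward high T stage
            z = config.confounding_strength * (
                math.log(tlg_all[i]) - config.tlg_meanlog
            )
            if rng.random() < 1.0 / (1.0 + math.exp(-z)):
                covs["t_stage"] = "T4"
        records.append(
            PatientRecord(
                patient_id=f"P{i:04d}",
                sex=covs.get("sex", NA),
                age=float(np.clip(ages[i], 18.0, 95.0)),
                t_stage=covs.get("t_stage", NA),
                n_stage=covs.get("n_stage", NA),
                uicc_stage=covs.get("uicc_stage", NA),
                chemo=covs.get("chemo", NA),
                hpv=covs.get("hpv", NA),
                ffdm_time=max(float(time[i]), 1e-6),
                ffdm_event=int(event[i]),
                os_time=max(float(os_time[i]), 1e-6),
                os_event=int(os_event[i]),
                **pet[i],
            )
        )
    if return_truth:
        return records, CohortGroundTruth(
            linear_predictor=lp, event_time=event_time
        )
    return records


def split_cohort(
    records: list[PatientRecord], fraction_explorative: float, rng_seed: int = 0
) -> tuple[list[PatientRecord], list[PatientRecord]]:
    """Random disjoint, exhaustive split into explorative and validation sets.

    ``fraction_explorative`` of the patients (rounded to the nearest count)
    go to the explorative group; with n = 431 and fraction 366/431 the sizes
    are exactly (366, 65).  Deterministic under a fixed seed.
    """
    if not 0 < fraction_explorative < 1:
        raise ConfigError("fraction_explorative must be in (0, 1)")
    n = len(records)
    if n < 2:
        raise ConfigError("need at least 2 records to split")
    k = int(round(fraction_explorative * n))
    k = min(max(k, 1), n - 1)
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(n)
    expl = [records[i] for i in sorted(perm[:k])]
    valid = [records[i] for i in sorted(perm[k:])]
    return expl, valid
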