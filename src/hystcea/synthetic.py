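"""Synthetic administrative cohorts with known generative truth.

The real inputs to the estimation stages — statewide hospital discharge
records and a registry linkage of occult-cancer survival — are restricted.
This module generates stand-ins whose generative models mirror the
regression forms the estimation stages fit, so every stage can be verified
by parameter recovery:

* discharge records: covariates drawn from configurable marginals
  (defaults approximate the postwarning sample composition), hysterectomy
  route from a multinomial logit, perioperative outcome from a per-route
  death probability plus a multinomial logit for major/minor/none, and
  episode cost from a gamma model with log-link mean;
* occult-cancer follow-up records: event times from Weibull accelerated-
  failure-time models (per histology, with morcellation/extent covariates)
  under independent uniform administrative censoring.

Covariates are generated independently given the age group (only marginal
frequencies are published); correlations can be injected through the truth
object if needed.  Identical truth + seed reproduces cohorts byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .parameters import AGE_GROUPS, REPRESENTATIVE_AGES, ROUTES

__all__ = [
    "GeneratorTruth",
    "default_truth",
    "generate_discharge_cohort",
    "generate_cancer_followup",
    "COVARIATE_COLUMNS",
    "covariate_design",
]

#: Covariate columns entering every regression, in fixed order.
COVARIATE_COLUMNS = (
    "age_c",
    "fibroids", "endometriosis", "prolapse", "menstrual_disorder",
    "other_indication", "smoking",
    "hypertension", "anemia", "obesity", "diabetes",
    "n_other_comorbidities",
    "concomitant_abdominopelvic", "concomitant_other",
)

#: Centred/scaled age used as a numeric covariate: (representative age − 45)/10.
AGE_C = {g: (REPRESENTATIVE_AGES[i] - 45.0) / 10.0
         for i, g in enumerate(AGE_GROUPS)}

# Marginal frequencies approximating the postwarning sample composition.
_DEFAULT_MARGINALS: dict[str, float] = {
    "fibroids": 0.578,
    "endometriosis": 0.316,
    "prolapse": 0.192,
    "menstrual_disorder": 0.544,
    "other_indication": 0.26,
    "smoking": 0.193,
    "hypertension": 0.222,
    "anemia": 0.154,
    "obesity": 0.129,
    "diabetes": 0.068,
    "concomitant_abdominopelvic": 0.158,
    "concomitant_other": 0.015,
}

# Five-bin postwarning age counts disaggregated like the model's default.
_DEFAULT_AGE_MASSES = (
    0.04795, 0.04795, 0.18908, 0.18908, 0.18517, 0.18517,
    0.04107, 0.04107, 0.02937, 0.02203, 0.02203,
)
_N_OTHER_COMORB_PROBS = (0.903, 0.084, 0.013)


@dataclass
class GeneratorTruth:
    """Ground-truth generative parameters for the synthetic cohorts."""

    n_patients: int = 20_000
    seed: int = 0
    age_masses: tuple[float, ...] = _DEFAULT_AGE_MASSES
    covariate_marginals: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MARGINALS))
    n_other_comorb_probs: tuple[float, ...] = _N_OTHER_COMORB_PROBS
    #: multinomial-logit coefficients for route (reference TAH):
    #: route -> {"const": .., covariate: ..}
    route_coef: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    #: per-route perioperative death probability
    p_death: Mapping[str, float] = field(default_factory=dict)
    #: multinomial-logit coefficients for outcome given survival
    #: (reference "none"): outcome -> {"const": .., "route_SAH": .., covariate: ..}
    outcome_coef: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    #: log-link gamma cost model: {"const", "route_*", "outcome_*", covariate}
    cost_coef: Mapping[str, float] = field(default_factory=dict)
    cost_dispersion: float = 20.0  # gamma shape; variance = mean^2 / shape

    # occult-cancer follow-up truth
    n_followup: int = 5_000
    p_endometrial: float = 0.78
    p_morcellated: float = 0.30
    p_supracervical: float = 0.30
    #: histology -> {"intercept", "inc_supracervical", "inc_total", "shape"}
    weibull: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    censor_window_months: float = 180.0

    def validate(self) -> None:
        for h, w in self.weibull.items():
            if w["shape"] <= 0:
                raise ValueError(f"{h}: Weibull shape must be > 0")
        if not math.isclose(sum(self.age_masses), 1.0, abs_tol=1e-3):
            raise ValueError("age masses must sum to 1")

    def to_dict(self) -> dict:
        return asdict(self)


def default_truth(n_patients: int = 20_000, seed: int = 0,
                  n_followup: int = 5_000) -> GeneratorTruth:
    """Truth mirroring the magnitudes of the published inputs.

    Route intercepts target roughly the prewarning route mix, outcome
    intercepts the published per-route complication risks, cost constants
    the published per-route episode costs, and the Weibull parameters the
    published occult-cancer survival fits.
    """
    route_coef = {
        # intercepts ≈ log(share_r / share_TAH) of the prewarning mix
        "SAH": {"const": -1.10, "age_c": -0.05, "fibroids": 0.10},
        "VH": {"const": -0.12, "prolapse": 0.90, "age_c": 0.10,
               "fibroids": -0.40},
        "TLH": {"const": 0.92, "age_c": -0.05, "obesity": -0.15,
                "concomitant_abdominopelvic": -0.20},
        "LSH": {"const": -0.23, "age_c": -0.15, "menstrual_disorder": 0.15},
    }
    outcome_coef = {
        "major": {"const": -1.72, "route_SAH": -0.13, "route_VH": -1.13,
                  "route_TLH": -1.39, "route_LSH": -1.69,
                  "age_c": 0.10, "anemia": 0.40, "diabetes": 0.20,
                  "concomitant_abdominopelvic": 0.25},
        "minor": {"const": -3.03, "route_SAH": -0.20, "route_VH": -0.79,
                  "route_TLH": -1.12, "route_LSH": -1.20,
                  "age_c": 0.08, "smoking": 0.15},
    }
    cost_coef = {
        "const": math.log(10_282.0),
        "route_SAH": -0.073, "route_VH": -0.217, "route_TLH": 0.124,
        "route_LSH": 0.076,
        "outcome_death": 1.045, "outcome_major": 0.344, "outcome_minor": 0.134,
        "age_c": 0.010, "obesity": 0.030, "concomitant_abdominopelvic": 0.060,
    }
    weibull = {
        "endometrial": {"intercept": 6.05, "inc_supracervical": 1.02,
                        "inc_total": 1.11, "shape": 0.82},
        "sarcoma": {"intercept": 4.41, "inc_supracervical": 0.78,
                    "inc_total": 1.02, "shape": 1.12},
    }
    return GeneratorTruth(
        n_patients=n_patients, seed=seed, n_followup=n_followup,
        route_coef=route_coef,
        p_death={"TAH": 0.0002, "SAH": 0.0002, "VH": 0.0001,
                 "TLH": 0.0001, "LSH": 0.0001},
        outcome_coef=outcome_coef, cost_coef=cost_coef, weibull=weibull,
    )


# ---------------------------------------------------------------------------
# Covariate machinery
# ---------------------------------------------------------------------------

def _draw_covariates(truth: GeneratorTruth, n: int,
                     rng: np.random.Generator) -> pd.DataFrame:
    masses = np.asarray(truth.age_masses, dtype=float)
    age_idx = rng.choice(len(AGE_GROUPS), size=n, p=masses / masses.sum())
    df = pd.DataFrame({"age_group": np.asarray(AGE_GROUPS)[age_idx]})
    df["age_c"] = df["age_group"].map(AGE_C)
    for name, p in truth.covariate_marginals.items():
        df[name] = rng.random(n) < p
    df["n_other_comorbidities"] = rng.choice(
        len(truth.n_other_comorb_probs), size=n,
        p=np.asarray(truth.n_other_comorb_probs))
    return df


def covariate_design(df: pd.DataFrame) -> pd.DataFrame:
    """Numeric covariate matrix in the canonical column order."""
    out = pd.DataFrame(index=df.index)
    if "age_c" in df.columns:
        out["age_c"] = df["age_c"].astype(float)
    else:
        out["age_c"] = df["age_group"].map(AGE_C).astype(float)
    for c in COVARIATE_COLUMNS[1:]:
        out[c] = df[c].astype(float)
    return out


def _linear_predictor(X: pd.DataFrame, coef: Mapping[str, float],
                      route_dummies: pd.DataFrame | None = None,
                      ) -> np.ndarray:
    eta = np.full(len(X), float(coef.get("const", 0.0)))
    for name, beta in coef.items():
        if name == "const":
            continue
        if name.startswith("route_"):
            eta += beta * route_dummies[name].to_numpy(dtype=float)
        elif name.startswith("outcome_"):
            continue  # handled by the caller
        else:
            eta += beta * X[name].to_numpy(dtype=float)
    return eta


def _softmax_sample(etas: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample category indices row-wise from logits (first column = ref = 0)."""
    z = etas - etas.max(axis=1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=1, keepdims=True)
    if not np.all(np.isfinite(p)):
        bad = int(np.flatnonzero(~np.isfinite(p).all(axis=1))[0])
        raise ValueError(f"invalid category probabilities at record {bad}")
    cdf = np.cumsum(p, axis=1)
    u = rng.random((len(p), 1))
    return (u > cdf[:, :-1]).sum(axis=1)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def generate_discharge_cohort(
    truth: GeneratorTruth,
    n: int | None = None,
    seed: int | None = None,
    period: str = "postwarning",
) -> pd.DataFrame:
    """Generate patient-level discharge records from the truth model.

    Columns: period, age group, indication/comorbidity/procedure flags,
    route, perioperative outcome and episode cost (2015 USD).
    """
    n = truth.n_patients if n is None else int(n)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    df = _draw_covariates(truth, n, rng)
    X = covariate_design(df)

    # route ~ multinomial logit, reference TAH
    etas = np.zeros((n, len(ROUTES)))
    for j, r in enumerate(ROUTES[1:], start=1):
        etas[:, j] = _linear_predictor(X, truth.route_coef.get(r, {}))
    route_idx = _softmax_sample(etas, rng)
    df["route"] = np.asarray(ROUTES)[route_idx]

    # outcome: per-route death probability, then logit over major/minor/none
    p_death = np.array([truth.p_death.get(r, 0.0) for r in ROUTES])[route_idx]
    died = rng.random(n) < p_death
    route_dummies = pd.DataFrame(
        {f"route_{r}": (df["route"] == r).astype(float) for r in ROUTES[1:]})
    out_etas = np.zeros((n, 3))  # none (ref), major, minor
    for j, o in enumerate(("major", "minor"), start=1):
        out_etas[:, j] = _linear_predictor(X, truth.outcome_coef.get(o, {}),
                                           route_dummies)
    out_idx = _softmax_sample(out_etas, rng)
    outcome = np.asarray(("none", "major", "minor"))[out_idx]
    outcome[died] = "death"
    df["outcome"] = outcome

    # episode cost ~ gamma, log-link mean
    eta_cost = _linear_predictor(X, truth.cost_coef, route_dummies)
    for o in ("death", "major", "minor"):
        beta = truth.cost_coef.get(f"outcome_{o}", 0.0)
        eta_cost += beta * (outcome == o)
    mean = np.exp(eta_cost)
    if not np.all(np.isfinite(mean)):
        bad = int(np.flatnonzero(~np.isfinite(mean))[0])
        raise ValueError(f"invalid cost mean at record {bad}")
    shape = truth.cost_dispersion
    df["episode_cost"] = rng.gamma(shape, mean / shape)
    df.insert(0, "period", period)
    return df


def generate_cancer_followup(
    truth: GeneratorTruth,
    n: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate occult-cancer follow-up records (time in months, censoring).

    Event times are Weibull with scale λ = exp(η), where η depends on the
    morcellation/extent stratum; censoring is independent uniform
    administrative censoring over ``censor_window_months``.
    """
    n = truth.n_followup if n is None else int(n)
    if n < 1:
        raise ValueError("n must be >= 1")
    truth.validate()
    rng = np.random.default_rng(truth.seed if seed is None else seed)

    hist = np.where(rng.random(n) < truth.p_endometrial,
                    "endometrial", "sarcoma")
    morcellated = rng.random(n) < truth.p_morcellated
    supracervical = rng.random(n) < truth.p_supracervical
    # morcellation happens in laparoscopic surgery of either extent; extent
    # matters for survival only in the non-morcellated strata
    extent = np.where(supracervical, "supracervical", "total")

    eta = np.empty(n)
    shape = np.empty(n)
    for h in np.unique(hist):
        w = truth.weibull[h]
        sel = hist == h
        inc = np.where(morcellated[sel], 0.0,
                       np.where(extent[sel] == "supracervical",
                                w["inc_supracervical"], w["inc_total"]))
        eta[sel] = w["intercept"] + inc
        shape[sel] = w["shape"]

    times = np.exp(eta) * rng.weibull(shape, size=n)
    censor_at = rng.uniform(0.0, truth.censor_window_months, size=n)
    event = times <= censor_at
    observed = np.minimum(times, censor_at)
    return pd.DataFrame({
        "histology": hist,
        "morcellated": morcellated,
        "extent": extent,
        "time_months": observed,
        "event": np.where(event, "cancer_death", "censored"),
    })
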