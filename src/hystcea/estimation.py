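"""Parameter-derivation stages: regressions feeding the decision model.

Four procedures turn patient-level records into decision-model inputs:

1. a multinomial logit of hysterectomy route on clinical characteristics,
   fit on prewarning records (:func:`fit_route_mix_model`);
2. counterfactual standardization — averaging that model's predicted route
   probabilities over the postwarning case mix to estimate the route
   distribution had practice not changed (:func:`predict_counterfactual_mix`);
3. a multinomial logit of perioperative outcome (major/minor/none, deaths
   excluded) on route and characteristics, summarised as expected risks per
   route at the mean covariate vector (:func:`fit_outcome_model`);
4. a log-link gamma GLM of episode cost on route, outcome indicators and
   characteristics, summarised as expected per-route costs and incremental
   dollar costs of death/major/minor events (:func:`fit_cost_model`);

plus a Weibull accelerated-failure-time fit of occult-cancer survival with
morcellation/extent covariates (:func:`fit_weibull_aft`).

"Mean characteristics" is implemented as the covariate-mean plug-in: one
prediction at the fractional means of the covariates.  The alternative —
averaging per-record predictions — is available via ``average="records"``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import WeibullAFTFitter

from .parameters import ROUTES
from .synthetic import covariate_design

__all__ = [
    "RouteMixModel",
    "RouteMixEstimate",
    "OutcomeModel",
    "CostModel",
    "WeibullFit",
    "fit_route_mix_model",
    "predict_counterfactual_mix",
    "fit_outcome_model",
    "fit_cost_model",
    "fit_weibull_aft",
    "weibull_aft_loglik",
    "estimates_to_parameter_rows",
]

logger = logging.getLogger(__name__)

_OUTCOME_LEVELS = ("none", "major", "minor")


def _exog(df: pd.DataFrame, route_dummies: bool = False) -> pd.DataFrame:
    X = covariate_design(df)
    if route_dummies:
        for r in ROUTES[1:]:
            X[f"route_{r}"] = (df["route"] == r).astype(float)
    return sm.add_constant(X, has_constant="add")


def _check_converged(res, what: str) -> None:
    retvals = getattr(res, "mle_retvals", None)
    if retvals is None or retvals.get("converged", True):
        return
    # Newton sometimes exhausts maxiter while oscillating at the optimum;
    # accept a vanishing score as convergence.
    score = np.asarray(retvals.get("score", [np.inf]))
    if np.all(np.abs(score) < 1e-6):
        return
    raise RuntimeError(
            f"{what}: optimizer failed to converge "
            f"(possible separation or singular design); retvals={retvals}"
        )


# ---------------------------------------------------------------------------
# 1-2. route model and counterfactual standardization
# ---------------------------------------------------------------------------

@dataclass
class RouteMixModel:
    """Fitted multinomial logit of route (reference category TAH)."""

    result: object
    categories: tuple[str, ...]

    @property
    def coefficients(self) -> pd.DataFrame:
        params = pd.DataFrame(self.result.params)
        params.columns = list(self.categories[1:])
        return params

    def predicted_probabilities(self, records: pd.DataFrame) -> pd.DataFrame:
        X = _exog(records)
        missing = [c for c in self.result.model.exog_names if c not in X.columns]
        if missing:
            raise ValueError(f"records lack model covariates: {missing}")
        probs = self.result.predict(X[self.result.model.exog_names])
        return pd.DataFrame(np.asarray(probs), columns=list(self.categories),
                            index=records.index)


def fit_route_mix_model(records: pd.DataFrame) -> RouteMixModel:
    """Maximum-likelihood multinomial logit of hysterectomy route."""
    observed = [r for r in ROUTES if (records["route"] == r).any()]
    if len(observed) < 2:
        raise ValueError("need at least two observed routes to fit a route model")
    cats = tuple(r for r in ROUTES if r in observed)
    endog = pd.Categorical(records["route"], categories=cats).codes
    X = _exog(records)
    model = sm.MNLogit(endog, X)
    res = model.fit(method="newton", maxiter=100, disp=False)
    _check_converged(res, "route model")
    return RouteMixModel(result=res, categories=cats)


@dataclass(frozen=True)
class RouteMixEstimate:
    """A route distribution with bootstrap CIs and its provenance."""

    shares: Mapping[str, float]
    ci: Mapping[str, tuple[float, float]]
    provenance: Literal["observed", "counterfactual-predicted"]

    def __post_init__(self):
        total = sum(self.shares.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(f"route shares sum to {total}")


def predict_counterfactual_mix(
    model: RouteMixModel,
    records: pd.DataFrame,
    n_boot: int = 200,
    seed: int = 0,
) -> RouteMixEstimate:
    """Standardized route mix: mean predicted probabilities over ``records``.

    CIs are percentile bootstrap over records (coefficients held fixed).
    """
    probs = model.predicted_probabilities(records).to_numpy()
    mean = probs.mean(axis=0)
    rng = np.random.default_rng(seed)
    n = len(probs)
    boot = np.empty((n_boot, probs.shape[1]))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot[b] = probs[idx].mean(axis=0)
    lo, hi = np.percentile(boot, [2.5, 97.5], axis=0)
    cats = model.categories
    return RouteMixEstimate(
        shares={c: float(m) for c, m in zip(cats, mean)},
        ci={c: (float(a), float(b)) for c, a, b in zip(cats, lo, hi)},
        provenance="counterfactual-predicted",
    )


# ---------------------------------------------------------------------------
# 3. perioperative outcome risks
# ---------------------------------------------------------------------------

@dataclass
class OutcomeModel:
    """Outcome multinomial logit and expected risks by route."""

    result: object
    expected_risks: Mapping[str, Mapping[str, float]]  # route -> outcome -> p

    @property
    def coefficients(self) -> pd.DataFrame:
        params = pd.DataFrame(self.result.params)
        params.columns = list(_OUTCOME_LEVELS[1:])
        return params


def fit_outcome_model(
    records: pd.DataFrame,
    average: Literal["plugin", "records"] = "plugin",
) -> OutcomeModel:
    """Expected major/minor complication risk per route.

    In-hospital deaths are removed before fitting.  Risks are evaluated at
    the sample-mean covariate vector (fractional means for binary
    covariates) with the route indicator switched per route.
    """
    alive = records[records["outcome"] != "death"]
    endog = pd.Categorical(alive["outcome"], categories=_OUTCOME_LEVELS).codes
    if (endog < 0).any():
        raise ValueError("unknown outcome level in records")
    X = _exog(alive, route_dummies=True)
    res = sm.MNLogit(endog, X).fit(method="newton", maxiter=100, disp=False)
    _check_converged(res, "outcome model")

    names = res.model.exog_names
    risks: dict[str, dict[str, float]] = {}
    base = (X.mean(axis=0) if average == "plugin" else None)
    for r in ROUTES:
        if average == "plugin":
            row = base.copy()
            for rr in ROUTES[1:]:
                row[f"route_{rr}"] = 1.0 if rr == r else 0.0
            p = np.asarray(res.predict(pd.DataFrame([row])[names]))[0]
        else:
            Xr = X.copy()
            for rr in ROUTES[1:]:
                Xr[f"route_{rr}"] = 1.0 if rr == r else 0.0
            p = np.asarray(res.predict(Xr[names])).mean(axis=0)
        risks[r] = {"major": float(p[1]), "minor": float(p[2])}
    if average == "plugin":
        # difference between plug-in and record-averaged predictions is of
        # interest diagnostically; report it at debug level
        logger.debug("outcome risks (plug-in at mean covariates): %s", risks)
    return OutcomeModel(result=res, expected_risks=risks)


# ---------------------------------------------------------------------------
# 4. cost model
# ---------------------------------------------------------------------------

@dataclass
class CostModel:
    """Log-link gamma GLM of episode cost with standardized summaries."""

    result: object
    expected_route_costs: Mapping[str, float]    # no complication, mean covariates
    incremental_costs: Mapping[str, float]       # death/major/minor, in dollars


def fit_cost_model(records: pd.DataFrame) -> CostModel:
    """Expected per-route costs and incremental event costs (2015 USD)."""
    if (records["episode_cost"] <= 0).any():
        raise ValueError("episode costs must be positive for a gamma model")
    X = _exog(records, route_dummies=True)
    for o in ("death", "major", "minor"):
        X[f"outcome_{o}"] = (records["outcome"] == o).astype(float)
    y = records["episode_cost"].astype(float)
    res = sm.GLM(y, X, family=sm.families.Gamma(link=sm.families.links.Log())
                 ).fit()

    names = list(res.model.exog_names)
    mean_row = X.mean(axis=0)
    route_costs = {}
    for r in ROUTES:
        row = mean_row.copy()
        for rr in ROUTES[1:]:
            row[f"route_{rr}"] = 1.0 if rr == r else 0.0
        for o in ("death", "major", "minor"):
            row[f"outcome_{o}"] = 0.0
        route_costs[r] = float(res.predict(pd.DataFrame([row])[names])[0])

    base_row = mean_row.copy()
    for o in ("death", "major", "minor"):
        base_row[f"outcome_{o}"] = 0.0
    base = float(res.predict(pd.DataFrame([base_row])[names])[0])
    incremental = {
        o: base * (math.exp(float(res.params[f"outcome_{o}"])) - 1.0)
        for o in ("death", "major", "minor")
    }
    return CostModel(result=res, expected_route_costs=route_costs,
                     incremental_costs=incremental)


# ---------------------------------------------------------------------------
# 5. Weibull AFT survival
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WeibullFit:
    """Weibull AFT fit for one histology.

    ``S(t) = exp(−(t/λ)^k)`` with ``λ = exp(η)`` and
    ``η = scale_morc + inc_supracervical·1[supracervical, no morcellation]
    + inc_total·1[total, no morcellation]``.
    """

    histology: str
    scale_morc: float
    inc_supracervical: float
    inc_total: float
    shape: float
    ci: Mapping[str, tuple[float, float]]
    log_likelihood: float

    def __post_init__(self):
        if self.shape <= 0:
            raise ValueError("fitted Weibull shape must be > 0")


def _aft_frame(records: pd.DataFrame) -> pd.DataFrame:
    morc = records["morcellated"].astype(bool)
    df = pd.DataFrame({
        "time_months": records["time_months"].astype(float).clip(lower=1e-6),
        "event": (records["event"] == "cancer_death").astype(int),
        "sc_nomorc": ((~morc) & (records["extent"] == "supracervical")).astype(float),
        "tot_nomorc": ((~morc) & (records["extent"] == "total")).astype(float),
    })
    return df


def fit_weibull_aft(records: pd.DataFrame,
                    histology: str | None = None) -> dict[str, WeibullFit] | WeibullFit:
    """Fit the Weibull AFT survival model, one fit per histology.

    Right-censoring enters the likelihood; strata with no observed events
    yield unbounded scale estimates and are flagged via a warning log, while
    a sample with no events at all raises.
    """
    if histology is None:
        return {h: fit_weibull_aft(records[records["histology"] == h], h)
                for h in sorted(records["histology"].unique())}
    df = _aft_frame(records)
    if df["event"].sum() == 0:
        raise ValueError(f"{histology}: no observed events; scale is unbounded")
    for col, label in (("sc_nomorc", "supracervical/no morcellation"),
                       ("tot_nomorc", "total/no morcellation")):
        stratum = df[df[col] == 1.0]
        if len(stratum) and stratum["event"].sum() == 0:
            logger.warning("%s: stratum %s has no events; its increment is "
                           "weakly identified", histology, label)
    aft = WeibullAFTFitter()
    aft.fit(df, duration_col="time_months", event_col="event")
    lam = aft.params_["lambda_"]
    ci = aft.confidence_intervals_
    lo_col, hi_col = ci.columns[0], ci.columns[1]

    def _ci(group: str, name: str, transform=lambda x: x):
        row = ci.loc[(group, name)]
        return (transform(float(row[lo_col])), transform(float(row[hi_col])))

    return WeibullFit(
        histology=histology,
        scale_morc=float(lam["Intercept"]),
        inc_supracervical=float(lam["sc_nomorc"]),
        inc_total=float(lam["tot_nomorc"]),
        shape=float(np.exp(aft.params_[("rho_", "Intercept")])),
        ci={
            "scale_morc": _ci("lambda_", "Intercept"),
            "inc_supracervical": _ci("lambda_", "sc_nomorc"),
            "inc_total": _ci("lambda_", "tot_nomorc"),
            "shape": _ci("rho_", "Intercept", math.exp),
        },
        log_likelihood=float(aft.log_likelihood_),
    )


def weibull_aft_loglik(records: pd.DataFrame, scale_morc: float,
                       inc_supracervical: float, inc_total: float,
                       shape: float) -> float:
    """Right-censored Weibull AFT log-likelihood at given parameter values."""
    df = _aft_frame(records)
    eta = (scale_morc + inc_supracervical * df["sc_nomorc"]
           + inc_total * df["tot_nomorc"]).to_numpy()
    t = df["time_months"].to_numpy()
    event = df["event"].to_numpy().astype(bool)
    z = (t / np.exp(eta)) ** shape
    log_h = (math.log(shape) + (shape - 1.0) * np.log(t) - shape * eta)
    return float(np.sum(np.where(event, log_h, 0.0)) - np.sum(z))


# ---------------------------------------------------------------------------
# Export estimated quantities in the parameter-registry schema
# ---------------------------------------------------------------------------

def estimates_to_parameter_rows(
    counterfactual_mix: RouteMixEstimate | None = None,
    outcome_model: OutcomeModel | None = None,
    cost_model: CostModel | None = None,
    weibull_fits: Mapping[str, WeibullFit] | None = None,
) -> pd.DataFrame:
    """Estimated quantities as rows of the parameter-fixture CSV schema."""
    rows: list[dict] = []

    def add(pid, base, low, high, family, units):
        rows.append({"id": pid, "base": base, "low": low, "high": high,
                     "family": family, "units": units, "source": "estimated"})

    if counterfactual_mix is not None:
        for r, share in counterfactual_mix.shares.items():
            if r == "TAH":
                continue  # derived as the complement
            lo, hi = counterfactual_mix.ci[r]
            add(f"route_share_cf_{r.lower()}", share, lo, hi, "normal",
                "probability")
    if outcome_model is not None:
        for r, risks in outcome_model.expected_risks.items():
            add(f"p_major_{r.lower()}", risks["major"], None, None, "point",
                "probability")
            add(f"p_minor_{r.lower()}", risks["minor"], None, None, "point",
                "probability")
    if cost_model is not None:
        for r, c in cost_model.expected_route_costs.items():
            add(f"cost_hysterectomy_{r.lower()}", c, None, None, "point", "usd")
        for o, c in cost_model.incremental_costs.items():
            add(f"cost_inc_{o}", c, None, None, "point", "usd")
    if weibull_fits is not None:
        name_map = {"scale_morc": "scale_morc",
                    "inc_supracervical": "inc_supracervical",
                    "inc_total": "inc_total", "shape": "shape"}
        for h, fit in weibull_fits.items():
            for attr, suffix in name_map.items():
                lo, hi = fit.ci[attr]
                units = "shape" if attr == "shape" else "log_months"
                add(f"weibull_{h}_{suffix}", getattr(fit, attr), lo, hi,
                    "normal", units)
    return pd.DataFrame(rows)
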