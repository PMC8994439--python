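"""Decision tree with monthly Markov survival for hysterectomy practice.

The tree evaluated here follows one patient from surgery to death:

    route  →  uncontained morcellation (laparoscopic routes only)
           →  perioperative outcome (death / major / minor / none)
           →  occult-cancer status (endometrial carcinoma / sarcoma / none)
           →  monthly survival (Markov chain to age 100)

Perioperative deaths exit the tree immediately.  Cancer-free survivors face
other-cause mortality only; patients with an occult cancer face competing
cancer-specific (Weibull accelerated-failure-time) and other-cause hazards.
Costs are societal 2015 USD (surgery episode, complication increments,
phase-of-care cancer costs, productivity losses under age 65); QALYs accrue
monthly at the utility of the current health state.  Both are discounted at
the annual rate in the parameter set with monthly factors (1+r)^(−t/12).

Conventions (documented in the methods note):

* A patient alive at the start of a month accrues that month's full cost
  and utility; no half-cycle correction.
* The end-of-life phase (final 12 months before death) takes precedence
  over the initial phase when death occurs within 24 months of diagnosis.
* The <65 / ≥65 cancer-cost schedule switches at the attained-age month.
* For occult-cancer patients the cancer-phase utility schedule applies from
  the month after surgery, superseding the recovery-window utilities.
* Survivors reaching age 100 are absorbed as other-cause deaths.

Two evaluation engines share the same per-pathway value arrays: an exact
expectation engine (branch probabilities multiplied through the tree) and a
seeded microsimulation that samples each patient's pathway and death month.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np

from .parameters import (
    AGE_GROUPS,
    ROUTES,
    AgeDistribution,
    LifeTable,
    ParameterSet,
)

__all__ = [
    "Scenario",
    "PathwayValue",
    "ScenarioResult",
    "SurvivalTrajectory",
    "perioperative_outcome_distribution",
    "perioperative_value",
    "occult_cancer_probability",
    "cancer_survival_curve",
    "cancer_lifetime_value",
    "evaluate_scenario",
    "postwarning_scenario",
    "counterfactual_scenario",
    "PathwayTables",
]

HORIZON_AGE = 100
OUTCOMES = ("death", "major", "minor", "none")
HISTOLOGIES = ("endometrial", "sarcoma")

#: Hysterectomy extent by route; the vaginal route removes the cervix and is
#: mapped to "total" for the survival covariates.
EXTENT_BY_ROUTE = {"TAH": "total", "SAH": "supracervical", "VH": "total",
                   "TLH": "total", "LSH": "supracervical"}

_MONTHS_PER_WEEK = 12.0 / 52.0


# ---------------------------------------------------------------------------
# Scenario definition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scenario:
    """A hysterectomy-practice scenario: route mix + morcellation proportions."""

    label: str
    route_mix: Mapping[str, float]
    morcellation: Mapping[str, float]

    def __post_init__(self):
        total = sum(self.route_mix.get(r, 0.0) for r in ROUTES)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"{self.label}: route mix sums to {total}, expected 1")
        for r, p in self.morcellation.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{self.label}: morcellation proportion {p} for {r}")
            if p > 0 and r not in ("TLH", "LSH"):
                raise ValueError(
                    f"{self.label}: morcellation applies only to laparoscopic "
                    f"routes, got {r}"
                )

    def morc(self, route: str) -> float:
        return float(self.morcellation.get(route, 0.0))


def postwarning_scenario(params: ParameterSet) -> Scenario:
    return Scenario("postwarning", params.route_share_post, params.morc_prop_post)


def counterfactual_scenario(params: ParameterSet) -> Scenario:
    return Scenario("counterfactual", params.route_share_cf, params.morc_prop_cf)


# ---------------------------------------------------------------------------
# Node-level operations
# ---------------------------------------------------------------------------

def perioperative_outcome_distribution(
    route: str, params: ParameterSet
) -> dict[str, float]:
    """Probabilities of (death, major, minor, none) for one route; sums to 1."""
    if route not in ROUTES:
        raise ValueError(f"unknown route {route!r}")
    p_death = params.p_death(route)
    p_major = params.p_major(route)
    p_minor = params.p_minor(route)
    p_none = 1.0 - p_death - p_major - p_minor
    if p_none < 0:
        raise ValueError(f"{route}: outcome probabilities exceed 1")
    return {"death": p_death, "major": p_major, "minor": p_minor, "none": p_none}


@dataclass(frozen=True)
class PathwayValue:
    """Expected discounted lifetime cost (2015 USD) and QALY for one branch."""

    cost: float
    qaly: float

    def __add__(self, other: "PathwayValue") -> "PathwayValue":
        return PathwayValue(self.cost + other.cost, self.qaly + other.qaly)

    def scaled(self, w: float) -> "PathwayValue":
        return PathwayValue(w * self.cost, w * self.qaly)


def _periop_cost(route: str, outcome: str, age: float, params: ParameterSet) -> float:
    """Surgical episode cost + outcome increment + productivity loss (<65)."""
    cost = params.cost_surgery(route)
    if outcome == "death":
        return cost + params["cost_inc_death"]
    if outcome == "major":
        cost += params["cost_inc_major"]
    elif outcome == "minor":
        cost += params["cost_inc_minor"]
    if age < 65:
        cost += params["weekly_earnings"] * params.recovery_weeks(route)
    return cost


def _recovery_utility_profile(
    route: str, outcome: str, params: ParameterSet, T: int
) -> np.ndarray:
    """Monthly utility profile: recovery window, then full health (1.0).

    The route utility applies over the recovery window (weeks converted to
    months); a complication replaces the first month with the complication
    utility.  Fractional window months are blended linearly with utility 1.
    """
    u = np.ones(T)
    if T == 0:
        return u
    w = params.recovery_weeks(route) * _MONTHS_PER_WEEK
    u_route = params.utility_route(route)
    if outcome == "none":
        first = min(w, 1.0)
        u[0] = first * u_route + (1.0 - first) * 1.0
    elif outcome in ("major", "minor"):
        u[0] = params[f"utility_{outcome}_complication"]
    else:
        raise ValueError(f"no recovery profile for outcome {outcome!r}")
    if w > 1.0 and T > 1:
        u[1] = (w - 1.0) * u_route + (2.0 - w) * 1.0
    return u


def perioperative_value(
    route: str, outcome: str, age: float, params: ParameterSet
) -> PathwayValue:
    """Cost and QALY of the surgical episode and recovery window alone.

    Death yields zero QALY from surgery onward and adds the incremental
    mortality cost.  The QALY term covers only the recovery window (the
    months whose utility departs from full health); the remaining lifetime
    is valued by the survival engines.
    """
    cost = _periop_cost(route, outcome, age, params)
    if outcome == "death":
        return PathwayValue(cost, 0.0)
    w = params.recovery_weeks(route) * _MONTHS_PER_WEEK
    n_window = max(1, math.ceil(w))
    u = _recovery_utility_profile(route, outcome, params, n_window)
    d = _discount_factors(params.discount_rate, n_window)
    return PathwayValue(cost, float(np.sum(d * u) / 12.0))


def occult_cancer_probability(
    age_group: str, histology: str, params: ParameterSet
) -> float:
    """Printed prevalence of occult cancer for one age group and histology."""
    if age_group not in AGE_GROUPS:
        raise ValueError(f"unknown age group {age_group!r}")
    if histology not in HISTOLOGIES:
        raise ValueError(f"unknown histology {histology!r}")
    return float(params.prevalence(histology)[AGE_GROUPS.index(age_group)])


# ---------------------------------------------------------------------------
# Monthly survival machinery
# ---------------------------------------------------------------------------

def _discount_factors(rate: float, T: int) -> np.ndarray:
    t = np.arange(1, T + 1)
    return (1.0 + rate) ** (-t / 12.0)


def _horizon_months(age: int) -> int:
    return max((HORIZON_AGE - int(age)) * 12, 0)


def _monthly_other_hazard(lifetable: LifeTable, age: int, T: int) -> np.ndarray:
    """Other-cause monthly death probability for months 1..T at attained age."""
    attained = age + np.arange(T) // 12
    attained = np.clip(attained, lifetable.age_min, lifetable.age_max)
    q_ann = lifetable.q[attained - lifetable.age_min]
    return 1.0 - (1.0 - q_ann) ** (1.0 / 12.0)


@dataclass(frozen=True)
class SurvivalTrajectory:
    """Monthly trajectory of one occult-cancer stratum under competing risks."""

    month: np.ndarray           # 1..T
    alive_start: np.ndarray     # P(alive at start of month t)
    p_cancer_death: np.ndarray  # P(die of uterine cancer in month t)
    p_other_death: np.ndarray   # P(die of other causes in month t)
    cancer_specific_survival: np.ndarray  # Weibull S(t) ignoring other causes


def cancer_survival_curve(
    histology: str,
    morcellated: bool,
    extent: str,
    age: int,
    params: ParameterSet,
    lifetable: LifeTable,
) -> SurvivalTrajectory:
    """Competing-risk monthly trajectory for one occult-cancer stratum.

    The cancer-specific hazard comes from the stratum's Weibull AFT survival
    S(t) = exp(−(t/λ)^k) with λ = exp(η); other-cause hazards come from the
    life table at the attained age.  Within a cycle the cancer hazard is
    applied first, so a month's other-cause deaths are drawn from patients
    who did not die of cancer that month.  Any probability mass surviving to
    age 100 is absorbed as an other-cause death in the final month.
    """
    wp = params.weibull(histology)
    if wp.shape <= 0:
        raise ValueError("Weibull shape must be positive")
    T = _horizon_months(age)
    t = np.arange(T + 1, dtype=float)
    lam = math.exp(wp.log_scale(morcellated, extent))
    S_w = np.exp(-np.power(t / lam, wp.shape))
    h_c = 1.0 - S_w[1:] / S_w[:-1]
    h_o = _monthly_other_hazard(lifetable, age, T)
    surv_factor = (1.0 - h_c) * (1.0 - h_o)
    alive = np.concatenate(([1.0], np.cumprod(surv_factor)))
    p_cancer = alive[:-1] * h_c
    p_other = alive[:-1] * (1.0 - h_c) * h_o
    if T > 0:
        p_other[-1] += alive[-1]  # forced absorption at the horizon
    return SurvivalTrajectory(
        month=np.arange(1, T + 1),
        alive_start=alive[:-1],
        p_cancer_death=p_cancer,
        p_other_death=p_other,
        cancer_specific_survival=S_w[1:],
    )


def _cancer_value_given_death(
    histology: str, age: int, params: ParameterSet, T: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Discounted cost/QALY accrued through death month m, by cause.

    Returns ``(C_cancer, C_other, Q_cancer, Q_other)``, each indexed by death
    month m = 1..T.  Phase schedule: initial phase covers the first 12 months
    after diagnosis, the end-of-life phase the last 12 months before death
    (taking precedence on overlap), continuing phase in between.  Costs and
    productivity losses are monthly rates; utilities accrue as QALY/12 per
    month.  Productivity losses and the <65 cost schedule apply only while
    the attained age is below 65.
    """
    t = np.arange(1, T + 1)
    d = _discount_factors(params.discount_rate, T)
    lt65 = (age + (t - 1) / 12.0) < 65.0
    age_cls = np.where(lt65, 0, 1)

    def _rate(phase: str) -> np.ndarray:
        per_cls = np.array([params.cancer_cost(phase, "lt65"),
                            params.cancer_cost(phase, "ge65")])
        return per_cls[age_cls]

    base_cost = np.where(t <= 12, _rate("initial"), _rate("continuing"))
    eol_cost_cancer = _rate("eol_cancer")
    eol_cost_other = _rate("eol_other")
    # productivity losses, <65 only
    prod_base = np.where(t <= 12, params["prodloss_initial"],
                         params["prodloss_continuing"]) * lt65
    prod_eol_cancer = params["prodloss_eol_cancer"] * lt65
    prod_eol_other = params["prodloss_eol_other"] * lt65

    u_care = params[f"utility_{histology}_care"]
    u_eol_cancer = params[f"utility_{histology}_eol_cancer"]
    u_eol_other = params[f"utility_{histology}_eol_other"]

    def _prefix(x: np.ndarray) -> np.ndarray:
        return np.concatenate(([0.0], np.cumsum(d * x)))

    B = _prefix(base_cost + prod_base)
    Ec = _prefix(eol_cost_cancer + prod_eol_cancer)
    Eo = _prefix(eol_cost_other + prod_eol_other)
    qB = _prefix(np.full(T, u_care)) / 12.0
    qEc = _prefix(np.full(T, u_eol_cancer)) / 12.0
    qEo = _prefix(np.full(T, u_eol_other)) / 12.0

    k = np.maximum(t - 12, 0)  # months before the end-of-life window
    C_cancer = B[k] + Ec[t] - Ec[k]
    C_other = B[k] + Eo[t] - Eo[k]
    Q_cancer = qB[k] + qEc[t] - qEc[k]
    Q_other = qB[k] + qEo[t] - qEo[k]
    return C_cancer, C_other, Q_cancer, Q_other


def cancer_lifetime_value(
    histology: str,
    morcellated: bool,
    extent: str,
    age: int,
    params: ParameterSet,
    lifetable: LifeTable,
) -> PathwayValue:
    """Expected discounted cancer-care cost and QALY for one stratum.

    Expectation over death month and cause of the discounted sums of monthly
    phase costs, utilities, and productivity losses.  Excludes the surgical
    episode itself (valued by :func:`perioperative_value`).
    """
    T = _horizon_months(age)
    traj = cancer_survival_curve(histology, morcellated, extent, age, params,
                                 lifetable)
    C_c, C_o, Q_c, Q_o = _cancer_value_given_death(histology, age, params, T)
    cost = float(np.sum(traj.p_cancer_death * C_c + traj.p_other_death * C_o))
    qaly = float(np.sum(traj.p_cancer_death * Q_c + traj.p_other_death * Q_o))
    return PathwayValue(cost, qaly)


# ---------------------------------------------------------------------------
# Pathway tables: everything scenario-independent, computed once per draw
# ---------------------------------------------------------------------------

_ROUTE_CLASS = {"TAH": "TAH", "SAH": "TAH", "VH": "TLH", "TLH": "TLH", "LSH": "TLH"}
# representative route per class: abdominal classes share utility/recovery,
# as do the vaginal/laparoscopic ones (vaginal aliases are enforced at the
# parameter level).


@dataclass
class PathwayTables:
    """Scenario-independent pathway values for one resolved ParameterSet."""

    params: ParameterSet
    lifetable: LifeTable
    age_dist: AgeDistribution
    free_qaly: dict = field(default_factory=dict)       # (a, class, outcome) -> float
    free_month: dict = field(default_factory=dict)      # (a, class, outcome) -> (pmf, Q(m))
    cancer_value: dict = field(default_factory=dict)    # (a, hist, morc, extent) -> PathwayValue
    cancer_month: dict = field(default_factory=dict)    # same key -> (P_c, P_o, C_c, C_o, Q_c, Q_o)

    @classmethod
    def build(cls, params: ParameterSet, lifetable: LifeTable,
              age_dist: AgeDistribution) -> "PathwayTables":
        self = cls(params, lifetable, age_dist)
        for a, age in enumerate(age_dist.representative_ages):
            T = _horizon_months(age)
            d = _discount_factors(params.discount_rate, T)
            h_o = _monthly_other_hazard(lifetable, age, T)
            alive = np.concatenate(([1.0], np.cumprod(1.0 - h_o)))
            death_pmf = alive[:-1] * h_o
            if T > 0:
                death_pmf[-1] += alive[-1]
            for rclass in ("TAH", "TLH"):
                for outcome in ("none", "major", "minor"):
                    u = _recovery_utility_profile(rclass, outcome, params, T)
                    acc = np.concatenate(([0.0], np.cumsum(d * u))) / 12.0
                    self.free_qaly[(a, rclass, outcome)] = float(
                        np.sum(d * alive[:-1] * u) / 12.0
                    )
                    self.free_month[(a, rclass, outcome)] = (death_pmf, acc[1:])
            for hist in HISTOLOGIES:
                C_c, C_o, Q_c, Q_o = _cancer_value_given_death(hist, age, params, T)
                for morc, extent in ((True, "total"), (False, "total"),
                                     (False, "supracervical")):
                    traj = cancer_survival_curve(hist, morc, extent, age,
                                                 params, lifetable)
                    key = (a, hist, morc, extent)
                    self.cancer_month[key] = (
                        traj.p_cancer_death, traj.p_other_death, C_c, C_o, Q_c, Q_o
                    )
                    self.cancer_value[key] = PathwayValue(
                        float(np.sum(traj.p_cancer_death * C_c
                                     + traj.p_other_death * C_o)),
                        float(np.sum(traj.p_cancer_death * Q_c
                                     + traj.p_other_death * Q_o)),
                    )
        return self

    def cancer_pathway(self, a: int, hist: str, morcellated: bool,
                       route: str) -> PathwayValue:
        extent = "total" if morcellated else EXTENT_BY_ROUTE[route]
        # morcellated strata ignore extent: η is the morcellation scale alone
        return self.cancer_value[(a, hist, morcellated, "total" if morcellated
                                  else extent)]


# ---------------------------------------------------------------------------
# Scenario evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioResult:
    """Aggregate expected outcomes of one scenario over a national cohort."""

    label: str
    cohort_size: float
    total_cost: float
    total_qaly: float
    deaths: float
    majors: float
    minors: float
    morcellated_endometrial: float
    morcellated_sarcoma: float

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "cohort_size": self.cohort_size,
            "total_cost": self.total_cost,
            "total_qaly": self.total_qaly,
            "deaths": self.deaths,
            "majors": self.majors,
            "minors": self.minors,
            "morcellated_endometrial": self.morcellated_endometrial,
            "morcellated_sarcoma": self.morcellated_sarcoma,
        }


def evaluate_scenario(
    scenario: Scenario,
    age_distribution: AgeDistribution,
    cohort_size: float,
    params: ParameterSet,
    lifetable: LifeTable,
    mode: Literal["expectation", "microsim"] = "expectation",
    seed: int | None = None,
    tables: PathwayTables | None = None,
) -> ScenarioResult:
    """Evaluate the full decision tree for one scenario.

    ``expectation`` multiplies branch probabilities exactly; ``microsim``
    samples every patient's pathway and death month with the given seed.
    Both engines share the same per-pathway value arrays, so they agree in
    expectation.
    """
    if cohort_size < 0:
        raise ValueError("cohort_size must be nonnegative")
    if cohort_size == 0:
        return ScenarioResult(scenario.label, 0, 0, 0, 0, 0, 0, 0, 0)
    if tables is None:
        tables = PathwayTables.build(params, lifetable, age_distribution)
    if mode == "expectation":
        return _evaluate_expectation(scenario, cohort_size, tables)
    if mode == "microsim":
        if seed is None:
            raise ValueError("microsim mode requires a seed")
        return _evaluate_microsim(scenario, int(cohort_size), tables, seed)
    raise ValueError(f"unknown mode {mode!r}")


def _evaluate_expectation(scenario: Scenario, cohort_size: float,
                          tables: PathwayTables) -> ScenarioResult:
    params = tables.params
    masses = np.asarray(tables.age_dist.masses)
    prev = {h: params.prevalence(h) for h in HISTOLOGIES}

    cost = qaly = 0.0
    deaths = majors = minors = 0.0
    morc_counts = dict.fromkeys(HISTOLOGIES, 0.0)

    for r in ROUTES:
        share = scenario.route_mix.get(r, 0.0)
        if share == 0.0:
            continue
        out = perioperative_outcome_distribution(r, params)
        p_morc = scenario.morc(r)
        rclass = _ROUTE_CLASS[r]
        deaths += share * out["death"]
        majors += share * out["major"]
        minors += share * out["minor"]
        for a, mass in enumerate(masses):
            age = tables.age_dist.representative_ages[a]
            w_base = share * mass
            p_e, p_s = prev["endometrial"][a], prev["sarcoma"][a]
            p_free = 1.0 - p_e - p_s
            # perioperative death exits before cancer evaluation
            cost += w_base * out["death"] * _periop_cost(r, "death", age, params)
            survive = 1.0 - out["death"]
            for h, p_h in (("endometrial", p_e), ("sarcoma", p_s)):
                morc_counts[h] += w_base * survive * p_morc * p_h
            for o in ("major", "minor", "none"):
                w = w_base * out[o]
                if w == 0.0:
                    continue
                cost += w * _periop_cost(r, o, age, params)
                qaly += w * p_free * tables.free_qaly[(a, rclass, o)]
                for h, p_h in (("endometrial", p_e), ("sarcoma", p_s)):
                    if p_h == 0.0:
                        continue
                    v_m = tables.cancer_pathway(a, h, True, r)
                    v_n = tables.cancer_pathway(a, h, False, r)
                    v = v_m.scaled(p_morc) + v_n.scaled(1.0 - p_morc)
                    cost += w * p_h * v.cost
                    qaly += w * p_h * v.qaly

    n = cohort_size
    return ScenarioResult(
        label=scenario.label,
        cohort_size=n,
        total_cost=n * cost,
        total_qaly=n * qaly,
        deaths=n * deaths,
        majors=n * majors,
        minors=n * minors,
        morcellated_endometrial=n * morc_counts["endometrial"],
        morcellated_sarcoma=n * morc_counts["sarcoma"],
    )


def _sample_categorical(rng: np.random.Generator, probs: np.ndarray,
                        n: int) -> np.ndarray:
    cdf = np.cumsum(probs)
    cdf[-1] = 1.0
    return np.searchsorted(cdf, rng.random(n), side="right")


def _evaluate_microsim(scenario: Scenario, n: int, tables: PathwayTables,
                       seed: int) -> ScenarioResult:
    params = tables.params
    rng = np.random.default_rng(seed)
    masses = np.asarray(tables.age_dist.masses)
    mix = np.array([scenario.route_mix.get(r, 0.0) for r in ROUTES])

    age_idx = _sample_categorical(rng, masses, n)
    route_idx = _sample_categorical(rng, mix, n)

    out_code = np.empty(n, dtype=np.int8)  # 0 death, 1 major, 2 minor, 3 none
    morc = np.zeros(n, dtype=bool)
    for ri, r in enumerate(ROUTES):
        sel = route_idx == ri
        m = int(sel.sum())
        if m == 0:
            continue
        out = perioperative_outcome_distribution(r, params)
        probs = np.array([out[o] for o in OUTCOMES])
        out_code[sel] = _sample_categorical(rng, probs, m)
        p_m = scenario.morc(r)
        if p_m > 0:
            morc[sel] = rng.random(m) < p_m

    # occult-cancer status: 0 none, 1 endometrial, 2 sarcoma
    prev_e = params.prevalence("endometrial")[age_idx]
    prev_s = params.prevalence("sarcoma")[age_idx]
    u = rng.random(n)
    cancer = np.zeros(n, dtype=np.int8)
    cancer[u < prev_e] = 1
    cancer[(u >= prev_e) & (u < prev_e + prev_s)] = 2
    cancer[out_code == 0] = 0  # deaths exit before cancer evaluation

    cost = np.zeros(n)
    qaly = np.zeros(n)
    ages = np.array(tables.age_dist.representative_ages)[age_idx]
    for ri, r in enumerate(ROUTES):
        for oi, o in enumerate(OUTCOMES):
            sel = (route_idx == ri) & (out_code == oi)
            if not sel.any():
                continue
            lt = ages[sel] < 65
            base = params.cost_surgery(r)
            inc = {"death": params["cost_inc_death"],
                   "major": params["cost_inc_major"],
                   "minor": params["cost_inc_minor"], "none": 0.0}[o]
            prod = params["weekly_earnings"] * params.recovery_weeks(r)
            cost[sel] = base + inc + (0.0 if o == "death" else prod) * lt

    # survival sampling per pathway group
    for a in range(len(AGE_GROUPS)):
        in_age = age_idx == a
        if not in_age.any():
            continue
        # cancer-free survivors
        for rclass_i, rclass in ((0, "TAH"), (1, "TLH")):
            cls_match = np.isin(route_idx, [0, 1] if rclass == "TAH" else [2, 3, 4])
            for oi, o in ((1, "major"), (2, "minor"), (3, "none")):
                sel = in_age & cls_match & (out_code == oi) & (cancer == 0)
                m = int(sel.sum())
                if m == 0:
                    continue
                pmf, acc = tables.free_month[(a, rclass, o)]
                months = _sample_categorical(rng, pmf, m)
                qaly[sel] = acc[months]
        # occult-cancer patients
        for hist_i, hist in ((1, "endometrial"), (2, "sarcoma")):
            for ri, r in enumerate(ROUTES):
                for is_morc in (False, True):
                    sel = (in_age & (cancer == hist_i) & (route_idx == ri)
                           & (morc == is_morc) & (out_code != 0))
                    m = int(sel.sum())
                    if m == 0:
                        continue
                    extent = "total" if is_morc else EXTENT_BY_ROUTE[r]
                    P_c, P_o, C_c, C_o, Q_c, Q_o = tables.cancer_month[
                        (a, hist, is_morc, extent)
                    ]
                    T = len(P_c)
                    pmf = np.concatenate([P_c, P_o])
                    pick = _sample_categorical(rng, pmf / pmf.sum(), m)
                    month = pick % T
                    is_cancer_death = pick < T
                    cost[sel] += np.where(is_cancer_death, C_c[month], C_o[month])
                    qaly[sel] += np.where(is_cancer_death, Q_c[month], Q_o[month])

    return ScenarioResult(
        label=scenario.label,
        cohort_size=n,
        total_cost=float(cost.sum()),
        total_qaly=float(qaly.sum()),
        deaths=float((out_code == 0).sum()),
        majors=float((out_code == 1).sum()),
        minors=float((out_code == 2).sum()),
        morcellated_endometrial=float((morc & (cancer == 1)).sum()),
        morcellated_sarcoma=float((morc & (cancer == 2)).sum()),
    )
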