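"""Input-parameter registry for the hysterectomy cost-effectiveness model.

Every quantity the decision model conditions on lives here: route mixes for
the observed (postwarning) and counterfactual scenarios, per-route
perioperative risks, age-specific occult-cancer prevalences, Weibull
survival parameters for occult endometrial carcinoma and uterine sarcoma,
utility weights, costs (2015 USD, societal perspective), productivity-loss
inputs, and global settings (3% annual discount rate, the 29.89% national
scaling share, and the PSA iteration count).

Parameters are declared in a CSV fixture (one row per input with its base
value, distribution family and 95% CI or range), validated on load, and
resolved either to their base values or to a random draw for probabilistic
sensitivity analysis:

* ``normal``    — mean = base, sd = (high − low) / 3.92, truncated to the
  admissible domain of the quantity (probabilities/utilities to [0, 1]).
* ``lognormal`` — log-scale mean/sd moment-matched to the printed CI
  endpoints, so the 2.5/97.5 draw percentiles reproduce (low, high).
* ``beta``      — rescaled to [low, high] with the mode at the base value
  and a fixed concentration (alpha + beta, default 10).
* ``point``     — never perturbed.
* ``derived``   — recomputed from other parameters after every draw
  (counterfactual TAH share as the complement of the other four routes,
  vaginal-route aliases, end-of-life schedules that reuse the
  continuing-phase value).

The module also houses the age distribution at surgery (eleven five-year
groups, disaggregated from the five printed bins) and the annual life table
of death from causes other than uterine cancer (ages 18–100, with forced
absorption at 100).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ROUTES",
    "AGE_GROUPS",
    "ParameterSpec",
    "ParameterSet",
    "WeibullParams",
    "AgeDistribution",
    "LifeTable",
    "ParameterValidationError",
    "load_parameter_table",
    "resolve_base_case",
    "draw_parameter_set",
    "monthly_other_cause_death_prob",
    "load_default_parameter_table",
    "load_default_age_distribution",
    "load_default_lifetable",
]

# Hysterectomy routes: total/supracervical abdominal, vaginal,
# total/supracervical laparoscopic.
ROUTES = ("TAH", "SAH", "VH", "TLH", "LSH")

# Eleven prevalence age groups and their representative (midpoint) ages used
# for the Markov survival horizon.
AGE_GROUPS = (
    "18-29", "30-34", "35-39", "40-44", "45-49", "50-54",
    "55-59", "60-64", "65-69", "70-74", "75+",
)
REPRESENTATIVE_AGES = (24, 32, 37, 42, 47, 52, 57, 62, 67, 72, 80)

_GROUP_SUFFIX = (
    "18_29", "30_34", "35_39", "40_44", "45_49", "50_54",
    "55_59", "60_64", "65_69", "70_74", "75plus",
)

#: Default disaggregation of the five printed age bins into the eleven
#: prevalence groups (uniform within ten-year bins; 40:30:30 above 65).
FIVE_BIN_SPLIT: dict[str, dict[str, float]] = {
    "18-34": {"18-29": 0.5, "30-34": 0.5},
    "35-44": {"35-39": 0.5, "40-44": 0.5},
    "45-54": {"45-49": 0.5, "50-54": 0.5},
    "55-64": {"55-59": 0.5, "60-64": 0.5},
    "65+": {"65-69": 0.4, "70-74": 0.3, "75+": 0.3},
}

#: Concentration (alpha + beta) used when re-expressing a base value + range
#: as a beta distribution by mode matching.
BETA_CONCENTRATION = 10.0

_FAMILIES = {"normal", "lognormal", "beta", "point", "derived"}

# Domain constraints keyed by the units column of the fixture.
_UNIT_BOUNDS = {
    "probability": (0.0, 1.0),
    "utility": (0.0, 1.0),
    "fraction": (0.0, 1.0),
    "usd": (0.0, math.inf),
    "usd_per_month": (0.0, math.inf),
    "usd_per_week": (0.0, math.inf),
    "weeks": (1e-9, math.inf),
    "shape": (1e-9, math.inf),
    "count": (1.0, math.inf),
    "log_months": (-math.inf, math.inf),
}


class ParameterValidationError(ValueError):
    """Raised when a parameter row violates its declared constraints."""


@dataclass(frozen=True)
class ParameterSpec:
    """One model input: base value, distribution family and CI/range."""

    id: str
    base_value: float | None
    family: str
    low: float | None = None
    high: float | None = None
    units: str = ""
    source: str = ""

    def validate(self) -> None:
        if self.family not in _FAMILIES:
            raise ParameterValidationError(
                f"{self.id}: unknown distribution family {self.family!r}"
            )
        if self.family == "derived":
            return
        if self.base_value is None or not math.isfinite(self.base_value):
            raise ParameterValidationError(f"{self.id}: missing base value")
        lo, hi = _UNIT_BOUNDS.get(self.units, (-math.inf, math.inf))
        if not (lo <= self.base_value <= hi):
            raise ParameterValidationError(
                f"{self.id}: base {self.base_value} outside admissible "
                f"domain [{lo}, {hi}] for units {self.units!r}"
            )
        if self.family == "point":
            return
        if self.low is None or self.high is None:
            raise ParameterValidationError(
                f"{self.id}: family {self.family!r} requires low/high bounds"
            )
        if not (self.low <= self.base_value <= self.high):
            raise ParameterValidationError(
                f"{self.id}: base {self.base_value} outside "
                f"[{self.low}, {self.high}]"
            )
        if self.family == "lognormal" and self.low <= 0:
            raise ParameterValidationError(
                f"{self.id}: lognormal bounds must be positive"
            )
        if self.family == "beta" and self.high <= self.low:
            raise ParameterValidationError(f"{self.id}: empty beta range")


# ---------------------------------------------------------------------------
# Derivation rules applied after base-case resolution and after every draw.
# ---------------------------------------------------------------------------

def _cf_tah(v: dict[str, float]) -> float:
    return 1.0 - (
        v["route_share_cf_sah"] + v["route_share_cf_vh"]
        + v["route_share_cf_tlh"] + v["route_share_cf_lsh"]
    )


DERIVATIONS = {
    "route_share_cf_tah": _cf_tah,
    "p_death_vaginal": lambda v: v["p_death_laparoscopic"],
    "utility_vaginal": lambda v: v["utility_laparoscopic"],
    "utility_endometrial_eol_other": lambda v: v["utility_endometrial_care"],
    "utility_sarcoma_eol_other": lambda v: v["utility_sarcoma_care"],
    "prodloss_eol_other": lambda v: v["prodloss_continuing"],
}

_MANDATORY_IDS = (
    [f"route_share_post_{r.lower()}" for r in ROUTES]
    + [f"route_share_cf_{r.lower()}" for r in ("SAH", "VH", "TLH", "LSH")]
    + ["morc_prop_post_tlh", "morc_prop_post_lsh",
       "morc_prop_cf_tlh", "morc_prop_cf_lsh",
       "p_death_abdominal", "p_death_laparoscopic"]
    + [f"p_major_{r.lower()}" for r in ROUTES]
    + [f"p_minor_{r.lower()}" for r in ROUTES]
    + [f"prev_endometrial_{s}" for s in _GROUP_SUFFIX]
    + [f"prev_sarcoma_{s}" for s in _GROUP_SUFFIX]
    + [f"weibull_{h}_{p}" for h in ("endometrial", "sarcoma")
       for p in ("scale_morc", "inc_supracervical", "inc_total", "shape")]
    + ["utility_laparoscopic", "utility_abdominal",
       "utility_perioperative_death", "utility_major_complication",
       "utility_minor_complication",
       "utility_endometrial_care", "utility_endometrial_eol_cancer",
       "utility_sarcoma_care", "utility_sarcoma_eol_cancer"]
    + [f"cost_hysterectomy_{r.lower()}" for r in ROUTES]
    + ["cost_inc_death", "cost_inc_major", "cost_inc_minor"]
    + [f"cost_cancer_{p}_{a}" for a in ("lt65", "ge65")
       for p in ("initial", "continuing", "eol_cancer", "eol_other")]
    + ["weekly_earnings", "recovery_weeks_abdominal",
       "recovery_weeks_vaginal_laparoscopic",
       "prodloss_initial", "prodloss_continuing", "prodloss_eol_cancer",
       "discount_rate_annual", "national_share", "psa_iterations"]
)


def load_parameter_table(path: str | Path | None = None) -> list[ParameterSpec]:
    """Load and validate the parameter fixture (default: packaged table).

    Raises :class:`ParameterValidationError` naming the offending row when a
    mandatory id is missing, a base value falls outside its bounds, or the
    distribution family is unknown.
    """
    if path is None:
        path = resources.files("hystcea.data") / "input_parameters.csv"
    df = pd.read_csv(path, dtype={"id": str})
    specs = []
    for row in df.itertuples(index=False):
        def _f(x):
            return None if pd.isna(x) else float(x)

        spec = ParameterSpec(
            id=row.id,
            base_value=_f(row.base),
            family=str(row.family),
            low=_f(row.low),
            high=_f(row.high),
            units=str(row.units),
            source=str(row.source),
        )
        spec.validate()
        specs.append(spec)
    ids = {s.id for s in specs}
    missing = [i for i in _MANDATORY_IDS if i not in ids and i not in DERIVATIONS]
    missing += [i for i in DERIVATIONS if i not in ids]
    if missing:
        raise ParameterValidationError(f"missing parameter ids: {missing}")
    return specs


# ---------------------------------------------------------------------------
# Resolution and random draws
# ---------------------------------------------------------------------------

def _beta_shapes(base: float, low: float, high: float,
                 concentration: float = BETA_CONCENTRATION) -> tuple[float, float]:
    """Shape parameters with mode at ``base`` on the rescaled unit support."""
    mode = (base - low) / (high - low)
    a = 1.0 + mode * (concentration - 2.0)
    return a, concentration - a


def _draw_one(spec: ParameterSpec, rng: np.random.Generator) -> float:
    if spec.family == "point":
        return float(spec.base_value)
    lo_dom, hi_dom = _UNIT_BOUNDS.get(spec.units, (-math.inf, math.inf))
    if spec.family == "normal":
        sd = (spec.high - spec.low) / 3.92
        x = rng.normal(spec.base_value, sd)
        return float(min(max(x, lo_dom), hi_dom))
    if spec.family == "lognormal":
        mu = 0.5 * (math.log(spec.low) + math.log(spec.high))
        sigma = (math.log(spec.high) - math.log(spec.low)) / 3.92
        return float(math.exp(rng.normal(mu, sigma)))
    if spec.family == "beta":
        a, b = _beta_shapes(spec.base_value, spec.low, spec.high)
        return float(spec.low + (spec.high - spec.low) * rng.beta(a, b))
    raise ParameterValidationError(f"{spec.id}: cannot draw family {spec.family}")


def _finalize_values(values: dict[str, float]) -> dict[str, float]:
    """Apply derivations and joint constraints to a raw value mapping."""
    for pid, fn in DERIVATIONS.items():
        values[pid] = fn(values)
    # Postwarning route shares: printed percentages sum to 99.99%; rescale
    # jointly so the mix is an exact probability vector.
    post_keys = [f"route_share_post_{r.lower()}" for r in ROUTES]
    post_total = sum(values[k] for k in post_keys)
    for k in post_keys:
        values[k] = values[k] / post_total
    # Counterfactual route shares: TAH is the complement; floor at zero and
    # renormalize jointly so the mix is always a probability vector.
    keys = [f"route_share_cf_{r.lower()}" for r in ROUTES]
    shares = np.array([max(values[k], 0.0) for k in keys])
    total = shares.sum()
    if values["route_share_cf_tah"] >= 0.0:
        # complement already guarantees sum exactly 1
        shares[0] = values["route_share_cf_tah"]
    else:
        shares /= total
    for k, s in zip(keys, shares):
        values[k] = float(s)
    return values


@dataclass(frozen=True)
class WeibullParams:
    """Accelerated-failure-time Weibull S(t) = exp(−(t/λ)^k), λ = exp(η)."""

    scale_morcellated: float   # η for the uncontained-morcellation stratum
    inc_supracervical: float   # added to η for supracervical, no morcellation
    inc_total: float           # added to η for total hysterectomy, no morcellation
    shape: float               # k

    def log_scale(self, morcellated: bool, extent: str) -> float:
        if morcellated:
            return self.scale_morcellated
        if extent == "supracervical":
            return self.scale_morcellated + self.inc_supracervical
        if extent == "total":
            return self.scale_morcellated + self.inc_total
        raise ValueError(f"unknown hysterectomy extent {extent!r}")

    def survival(self, t: np.ndarray, morcellated: bool, extent: str) -> np.ndarray:
        lam = math.exp(self.log_scale(morcellated, extent))
        return np.exp(-np.power(np.asarray(t, dtype=float) / lam, self.shape))


_ABDOMINAL = ("TAH", "SAH")


@dataclass(frozen=True)
class ParameterSet:
    """A fully resolved set of model inputs (base case or one PSA draw)."""

    values: Mapping[str, float] = field(repr=False)

    # -- route mixes and morcellation -----------------------------------
    @property
    def route_share_post(self) -> dict[str, float]:
        return {r: self.values[f"route_share_post_{r.lower()}"] for r in ROUTES}

    @property
    def route_share_cf(self) -> dict[str, float]:
        return {r: self.values[f"route_share_cf_{r.lower()}"] for r in ROUTES}

    @property
    def morc_prop_post(self) -> dict[str, float]:
        return {"TLH": self.values["morc_prop_post_tlh"],
                "LSH": self.values["morc_prop_post_lsh"]}

    @property
    def morc_prop_cf(self) -> dict[str, float]:
        return {"TLH": self.values["morc_prop_cf_tlh"],
                "LSH": self.values["morc_prop_cf_lsh"]}

    # -- perioperative outcome probabilities ----------------------------
    def p_death(self, route: str) -> float:
        if route in _ABDOMINAL:
            return self.values["p_death_abdominal"]
        if route == "VH":
            return self.values["p_death_vaginal"]
        return self.values["p_death_laparoscopic"]

    def p_major(self, route: str) -> float:
        return self.values[f"p_major_{route.lower()}"]

    def p_minor(self, route: str) -> float:
        return self.values[f"p_minor_{route.lower()}"]

    # -- occult-cancer prevalence ---------------------------------------
    def prevalence(self, histology: str) -> np.ndarray:
        return np.array(
            [self.values[f"prev_{histology}_{s}"] for s in _GROUP_SUFFIX]
        )

    def weibull(self, histology: str) -> WeibullParams:
        v = self.values
        return WeibullParams(
            scale_morcellated=v[f"weibull_{histology}_scale_morc"],
            inc_supracervical=v[f"weibull_{histology}_inc_supracervical"],
            inc_total=v[f"weibull_{histology}_inc_total"],
            shape=v[f"weibull_{histology}_shape"],
        )

    # -- utilities -------------------------------------------------------
    def utility_route(self, route: str) -> float:
        if route in _ABDOMINAL:
            return self.values["utility_abdominal"]
        if route == "VH":
            return self.values["utility_vaginal"]
        return self.values["utility_laparoscopic"]

    # -- costs -----------------------------------------------------------
    def cost_surgery(self, route: str) -> float:
        return self.values[f"cost_hysterectomy_{route.lower()}"]

    def cancer_cost(self, phase: str, age_class: str) -> float:
        return self.values[f"cost_cancer_{phase}_{age_class}"]

    def recovery_weeks(self, route: str) -> float:
        if route in _ABDOMINAL:
            return self.values["recovery_weeks_abdominal"]
        return self.values["recovery_weeks_vaginal_laparoscopic"]

    def __getitem__(self, pid: str) -> float:
        return self.values[pid]

    @property
    def discount_rate(self) -> float:
        return self.values["discount_rate_annual"]

    @property
    def national_share(self) -> float:
        return self.values["national_share"]

    @property
    def psa_iterations(self) -> int:
        return int(self.values["psa_iterations"])

    def validate(self) -> None:
        v = self.values
        for name, mix in (("postwarning", self.route_share_post),
                          ("counterfactual", self.route_share_cf)):
            total = sum(mix.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ParameterValidationError(
                    f"{name} route shares sum to {total}, expected 1"
                )
        for r in ROUTES:
            if self.p_death(r) + self.p_major(r) + self.p_minor(r) >= 1.0:
                raise ParameterValidationError(
                    f"{r}: outcome probabilities sum to >= 1"
                )
        for h in ("endometrial", "sarcoma"):
            if np.any(self.prevalence(h) < 0) or np.any(self.prevalence(h) > 1):
                raise ParameterValidationError(f"{h} prevalence outside [0, 1]")
            if self.weibull(h).shape <= 0:
                raise ParameterValidationError(f"{h} Weibull shape must be > 0")
        for pid, x in v.items():
            if pid.startswith("utility_") and not (0.0 <= x <= 1.0):
                raise ParameterValidationError(f"{pid}: utility {x} outside [0, 1]")
            if pid.startswith("cost_") and x < 0:
                raise ParameterValidationError(f"{pid}: negative cost {x}")


def resolve_base_case(specs: Sequence[ParameterSpec]) -> ParameterSet:
    """Resolve every parameter to its base value (derived fields recomputed)."""
    values = {s.id: float(s.base_value) for s in specs if s.family != "derived"}
    ps = ParameterSet(values=_finalize_values(values))
    ps.validate()
    return ps


def draw_parameter_set(
    specs: Sequence[ParameterSpec],
    rng_seed: int | np.random.Generator,
) -> ParameterSet:
    """One random draw of all parameters per their declared distributions.

    Point-mass parameters are left at their base value; derived fields are
    recomputed after drawing.  Deterministic under ``rng_seed``.
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    values = {s.id: _draw_one(s, rng) for s in specs if s.family != "derived"}
    ps = ParameterSet(values=_finalize_values(values))
    ps.validate()
    return ps


# ---------------------------------------------------------------------------
# Age distribution and life table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgeDistribution:
    """Probability mass over the eleven age groups at the time of surgery."""

    masses: tuple[float, ...]
    representative_ages: tuple[int, ...] = REPRESENTATIVE_AGES

    def __post_init__(self):
        m = np.asarray(self.masses)
        if len(m) != len(AGE_GROUPS) or np.any(m < 0):
            raise ParameterValidationError("age masses must be 11 nonnegative values")
        if not math.isclose(m.sum(), 1.0, abs_tol=1e-9):
            raise ParameterValidationError(f"age masses sum to {m.sum()}, expected 1")

    @classmethod
    def from_five_bins(
        cls,
        counts: Mapping[str, float],
        split: Mapping[str, Mapping[str, float]] | None = None,
    ) -> "AgeDistribution":
        """Disaggregate the five printed age bins into the eleven groups."""
        split = split or FIVE_BIN_SPLIT
        total = sum(counts.values())
        mass = dict.fromkeys(AGE_GROUPS, 0.0)
        for bin_label, n in counts.items():
            for group, w in split[bin_label].items():
                mass[group] += w * n / total
        return cls(masses=tuple(mass[g] for g in AGE_GROUPS))

    @classmethod
    def from_csv(cls, path: str | Path) -> "AgeDistribution":
        df = pd.read_csv(path)
        return cls.from_five_bins(dict(zip(df["age_bin"], df["count"])))


@dataclass(frozen=True)
class LifeTable:
    """Annual probability of death from causes other than uterine cancer.

    Covers integer ages 18–100; the terminal age is forced to probability 1
    so every modeled lifetime is absorbed by age 100.
    """

    q: np.ndarray
    age_min: int = 18
    age_max: int = 100

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        if len(q) != self.age_max - self.age_min + 1:
            raise ParameterValidationError("life table must cover ages 18-100")
        if np.any((q < 0) | (q > 1)):
            raise ParameterValidationError("life-table probabilities outside [0, 1]")
        if q[-1] != 1.0:
            raise ParameterValidationError("terminal age must have q = 1")

    def annual_q(self, age: float) -> float:
        a = int(age)
        if not (self.age_min <= a <= self.age_max):
            raise ValueError(f"age {age} outside life table range")
        return float(self.q[a - self.age_min])

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        df = pd.read_csv(path)
        df = df.sort_values("age")
        return cls(q=df["annual_death_prob"].to_numpy())


def monthly_other_cause_death_prob(lifetable: LifeTable, age: float) -> float:
    """Convert the annual other-cause death risk at ``age`` to a monthly one.

    Uses the constant-hazard-within-year identity
    ``q_month = 1 − (1 − q_year)^(1/12)``.
    """
    q = lifetable.annual_q(age)
    return 1.0 - (1.0 - q) ** (1.0 / 12.0)


# ---------------------------------------------------------------------------
# Packaged fixture loaders
# ---------------------------------------------------------------------------

def load_default_parameter_table() -> list[ParameterSpec]:
    return load_parameter_table(None)


def load_default_age_distribution() -> AgeDistribution:
    path = resources.files("hystcea.data") / "age_distribution_postwarning.csv"
    return AgeDistribution.from_csv(path)


def load_default_lifetable() -> LifeTable:
    path = resources.files("hystcea.data") / "lifetable_female_synthetic.csv"
    return LifeTable.from_csv(path)
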