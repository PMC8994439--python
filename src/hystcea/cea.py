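"""Cost-effectiveness comparison engine: ICER, PSA, CEAC, influence ranking.

Compares the observed postwarning hysterectomy practice against the
counterfactual practice (no morcellation warning) on a national cohort:

* base-case report mirroring the expected-national-impact table
  (:func:`run_base_case`), with counts scaled to the nation by dividing by
  the study states' population share;
* probabilistic sensitivity analysis (:func:`run_psa`): per iteration one
  random parameter draw applied to *both* scenarios (common random
  parameters), expectation-mode evaluation, incremental cost and QALY
  recorded;
* cost-effectiveness acceptability curve (:func:`ceac`): fraction of
  iterations with incremental net monetary benefit λ·ΔQ − ΔC ≥ 0 at each
  willingness-to-pay λ (ties count as cost-effective);
* influence ranking (:func:`influence_analysis`): Spearman rank correlation
  of each drawn parameter with the INMB at a reference λ; partial rank
  correlation (PRCC) available as an option.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .decision import (
    Scenario,
    ScenarioResult,
    PathwayTables,
    counterfactual_scenario,
    evaluate_scenario,
    postwarning_scenario,
)
from .parameters import (
    AgeDistribution,
    LifeTable,
    ParameterSet,
    ParameterSpec,
    draw_parameter_set,
    resolve_base_case,
)

__all__ = [
    "IcerResult",
    "PsaIteration",
    "CeacPoint",
    "BaseCaseReport",
    "icer",
    "scale_to_national",
    "run_base_case",
    "run_psa",
    "ceac",
    "influence_analysis",
    "psa_to_frame",
    "DEFAULT_CEAC_THRESHOLDS",
]

logger = logging.getLogger(__name__)

#: Default willingness-to-pay grid: $0–$250,000/QALY in $10,000 steps.
DEFAULT_CEAC_THRESHOLDS = tuple(range(0, 250_001, 10_000))


@dataclass(frozen=True)
class IcerResult:
    """ICER ΔC/ΔQ, or a dominance flag when the ratio is not meaningful."""

    delta_cost: float
    delta_qaly: float
    value: float | None
    flag: Literal["ratio", "dominant", "dominated", "undefined"]

    def __str__(self) -> str:
        if self.flag == "ratio":
            return f"${self.value:,.0f}/QALY"
        return self.flag


def icer(delta_cost: float, delta_qaly: float) -> IcerResult:
    """Incremental cost-effectiveness ratio with dominance handling.

    ``dominant``: cheaper (ΔC ≤ 0) and more effective (ΔQ > 0);
    ``dominated``: costlier (ΔC ≥ 0) and less effective (ΔQ < 0);
    ``undefined``: ΔQ = 0.
    """
    if not (math.isfinite(delta_cost) and math.isfinite(delta_qaly)):
        raise ValueError("ICER inputs must be finite")
    if delta_qaly == 0.0:
        return IcerResult(delta_cost, delta_qaly, None, "undefined")
    if delta_qaly > 0 and delta_cost <= 0:
        return IcerResult(delta_cost, delta_qaly, None, "dominant")
    if delta_qaly < 0 and delta_cost >= 0:
        return IcerResult(delta_cost, delta_qaly, None, "dominated")
    return IcerResult(delta_cost, delta_qaly, delta_cost / delta_qaly, "ratio")


def scale_to_national(count: float, share: float) -> float:
    """Scale a study-states count to the nation by the population share."""
    if not (0.0 < share <= 1.0):
        raise ValueError("share must be in (0, 1]")
    return count / share


# ---------------------------------------------------------------------------
# Base case
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BaseCaseReport:
    """Per-scenario results, their differences, and the ICER."""

    postwarning: ScenarioResult
    counterfactual: ScenarioResult
    icer: IcerResult

    @property
    def differences(self) -> dict[str, float]:
        p, c = self.postwarning.as_dict(), self.counterfactual.as_dict()
        return {k: p[k] - c[k] for k in p if k not in ("label",)}

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "postwarning": self.postwarning.as_dict(),
            "counterfactual": self.counterfactual.as_dict(),
        }
        df = pd.DataFrame(rows).drop(index="label")
        df["difference"] = df["postwarning"] - df["counterfactual"]
        return df


def run_base_case(
    params: ParameterSet,
    age_distribution: AgeDistribution,
    lifetable: LifeTable,
    scenario_post: Scenario | None = None,
    scenario_cf: Scenario | None = None,
    study_count: float = 105_698,
    mode: Literal["expectation", "microsim"] = "expectation",
    seed: int | None = None,
) -> BaseCaseReport:
    """Evaluate both scenarios on the national cohort and report the ICER.

    The national cohort size is the study-states patient count divided by
    the national population share (29.89% at base case).
    """
    cohort = scale_to_national(study_count, params.national_share)
    scenario_post = scenario_post or postwarning_scenario(params)
    scenario_cf = scenario_cf or counterfactual_scenario(params)
    tables = PathwayTables.build(params, lifetable, age_distribution)
    post = evaluate_scenario(scenario_post, age_distribution, cohort, params,
                             lifetable, mode=mode, seed=seed, tables=tables)
    cf = evaluate_scenario(scenario_cf, age_distribution, cohort, params,
                           lifetable, mode=mode,
                           seed=None if seed is None else seed + 1,
                           tables=tables)
    ic = icer(post.total_cost - cf.total_cost, post.total_qaly - cf.total_qaly)
    return BaseCaseReport(postwarning=post, counterfactual=cf, icer=ic)


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PsaIteration:
    """One PSA draw: incremental cost/QALY and the drawn parameter values."""

    index: int
    seed: int
    delta_cost: float
    delta_qaly: float
    values: Mapping[str, float]


def run_psa(
    specs: Sequence[ParameterSpec],
    scenario_post: Callable[[ParameterSet], Scenario] | Scenario | None = None,
    scenario_cf: Callable[[ParameterSet], Scenario] | Scenario | None = None,
    n_iter: int | None = None,
    seed: int = 0,
    age_distribution: AgeDistribution | None = None,
    lifetable: LifeTable | None = None,
    study_count: float = 105_698,
) -> list[PsaIteration]:
    """Monte Carlo PSA: one parameter draw per iteration, shared by both arms.

    Scenario arguments may be fixed :class:`Scenario` objects or callables
    receiving the drawn :class:`ParameterSet` (the default rebuilds the
    postwarning/counterfactual scenarios from each draw, so route-mix and
    morcellation uncertainty propagates).  Reproducible under ``seed``;
    a failed iteration is re-raised with its seed attached.
    """
    if age_distribution is None or lifetable is None:
        raise ValueError("age_distribution and lifetable are required")
    if n_iter is None:
        n_iter = resolve_base_case(specs).psa_iterations
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    scenario_post = scenario_post or postwarning_scenario
    scenario_cf = scenario_cf or counterfactual_scenario

    ss = np.random.SeedSequence(seed)
    iter_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_iter)]
    iterations: list[PsaIteration] = []
    for i, it_seed in enumerate(iter_seeds):
        try:
            params = draw_parameter_set(specs, it_seed)
            cohort = scale_to_national(study_count, params.national_share)
            tables = PathwayTables.build(params, lifetable, age_distribution)
            post_sc = (scenario_post(params) if callable(scenario_post)
                       else scenario_post)
            cf_sc = (scenario_cf(params) if callable(scenario_cf)
                     else scenario_cf)
            post = evaluate_scenario(post_sc, age_distribution, cohort, params,
                                     lifetable, tables=tables)
            cf = evaluate_scenario(cf_sc, age_distribution, cohort, params,
                                   lifetable, tables=tables)
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise RuntimeError(f"PSA iteration {i} (seed {it_seed}) failed"
                               ) from exc
        iterations.append(PsaIteration(
            index=i,
            seed=it_seed,
            delta_cost=post.total_cost - cf.total_cost,
            delta_qaly=post.total_qaly - cf.total_qaly,
            values=dict(params.values),
        ))
    return iterations


def psa_to_frame(iterations: Sequence[PsaIteration]) -> pd.DataFrame:
    """Iteration table: index, seed, ΔC, ΔQ and every drawn parameter value."""
    rows = [
        {"iteration": it.index, "seed": it.seed,
         "delta_cost": it.delta_cost, "delta_qaly": it.delta_qaly,
         **it.values}
        for it in iterations
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CEAC and influence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CeacPoint:
    """Fraction of PSA iterations cost-effective at one WTP threshold."""

    threshold: float
    proportion: float

    def __post_init__(self):
        if not (0.0 <= self.proportion <= 1.0):
            raise ValueError("proportion must lie in [0, 1]")


def ceac(
    iterations: Sequence[PsaIteration],
    thresholds: Sequence[float] = DEFAULT_CEAC_THRESHOLDS,
) -> list[CeacPoint]:
    """Cost-effectiveness acceptability curve over WTP thresholds.

    An iteration counts as cost-effective at λ when its incremental net
    monetary benefit λ·ΔQ − ΔC is ≥ 0 (ties cost-effective).
    """
    if not iterations:
        raise ValueError("need at least one PSA iteration")
    dc = np.array([it.delta_cost for it in iterations])
    dq = np.array([it.delta_qaly for it in iterations])
    return [
        CeacPoint(float(lam), float(np.mean(lam * dq - dc >= 0.0)))
        for lam in thresholds
    ]


def influence_analysis(
    iterations: Sequence[PsaIteration],
    wtp: float = 50_000.0,
    method: Literal["spearman", "prcc"] = "spearman",
) -> pd.DataFrame:
    """Rank input parameters by their influence on the INMB at ``wtp``.

    Spearman: rank correlation between each drawn parameter and the INMB.
    PRCC: partial rank correlation controlling for all other varying
    parameters.  Point-mass (constant) parameters are excluded.
    Returns a DataFrame sorted by absolute correlation.
    """
    if len(iterations) < 100:
        raise ValueError("influence analysis needs at least 100 iterations")
    values = psa_to_frame(iterations)
    inmb = wtp * values["delta_qaly"] - values["delta_cost"]
    param_cols = [c for c in values.columns
                  if c not in ("iteration", "seed", "delta_cost", "delta_qaly")]
    varying = [c for c in param_cols if values[c].nunique() > 1]
    constant = sorted(set(param_cols) - set(varying))
    if constant:
        logger.info("influence analysis: excluding constant parameters %s",
                    constant)
    if method == "spearman":
        corr = {c: stats.spearmanr(values[c], inmb).statistic for c in varying}
    elif method == "prcc":
        R = values[varying].rank()
        ry = inmb.rank()
        corr = {}
        for c in varying:
            others = R.drop(columns=c)
            X = np.column_stack([np.ones(len(R)), others.to_numpy()])
            bx, *_ = np.linalg.lstsq(X, R[c].to_numpy(), rcond=None)
            by, *_ = np.linalg.lstsq(X, ry.to_numpy(), rcond=None)
            rx = R[c].to_numpy() - X @ bx
            ryy = ry.to_numpy() - X @ by
            corr[c] = float(np.corrcoef(rx, ryy)[0, 1])
    else:
        raise ValueError(f"unknown method {method!r}")
    out = pd.DataFrame({
        "parameter": list(corr),
        "correlation": [corr[c] for c in corr],
    })
    out["abs_correlation"] = out["correlation"].abs()
    out = out.sort_values("abs_correlation", ascending=False,
                          ignore_index=True)
    return out
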