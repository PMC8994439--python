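"""Decision tree and Markov survival: printed-value checks and invariants."""

import math

import numpy as np
import pytest

from hystcea.decision import (
    Scenario,
    _cancer_value_given_death,
    _horizon_months,
    cancer_lifetime_value,
    cancer_survival_curve,
    counterfactual_scenario,
    evaluate_scenario,
    occult_cancer_probability,
    perioperative_outcome_distribution,
    perioperative_value,
    postwarning_scenario,
)
from hystcea.parameters import ROUTES, ParameterSet, draw_parameter_set


def _with(params, **overrides):
    return ParameterSet(values={**params.values, **overrides})


class TestPerioperativeNodes:
    def test_tah_outcome_distribution_matches_printed_values(self, base_params):
        out = perioperative_outcome_distribution("TAH", base_params)
        assert out["death"] == pytest.approx(0.0002)
        assert out["major"] == pytest.approx(0.1462)
        assert out["minor"] == pytest.approx(0.0392)
        assert out["none"] == pytest.approx(0.8144)

    @pytest.mark.parametrize("route", ROUTES)
    def test_outcome_probabilities_sum_to_one(self, base_params, route):
        out = perioperative_outcome_distribution(route, base_params)
        assert sum(out.values()) == pytest.approx(1.0)
        assert all(p >= 0 for p in out.values())

    def test_vaginal_death_equals_laparoscopic(self, base_params):
        vh = perioperative_outcome_distribution("VH", base_params)
        tlh = perioperative_outcome_distribution("TLH", base_params)
        assert vh["death"] == tlh["death"] == pytest.approx(0.0001)

    def test_tlh_uncomplicated_cost_includes_productivity(self, base_params):
        # 11,641 surgery + 726/week x 3 recovery weeks = 13,819
        v = perioperative_value("TLH", "none", 40, base_params)
        assert v.cost == pytest.approx(11_641 + 726 * 3)

    def test_no_productivity_term_at_65_and_over(self, base_params):
        v = perioperative_value("TAH", "major", 70, base_params)
        assert v.cost == pytest.approx(10_282 + 4_205)

    def test_perioperative_death_accrues_zero_qaly(self, base_params):
        v = perioperative_value("LSH", "death", 45, base_params)
        assert v.qaly == 0.0
        assert v.cost == pytest.approx(11_099 + 18_957)


class TestOccultCancerPrevalence:
    def test_printed_prevalences(self, base_params):
        assert occult_cancer_probability("50-54", "endometrial",
                                         base_params) == pytest.approx(0.0069)
        assert occult_cancer_probability("18-29", "sarcoma", base_params) == 0.0

    def test_unknown_group_rejected(self, base_params):
        with pytest.raises(ValueError):
            occult_cancer_probability("17-18", "sarcoma", base_params)


class TestSurvivalCurve:
    def test_morcellated_sarcoma_median_matches_closed_form(
            self, base_params, lifetable):
        traj = cancer_survival_curve("sarcoma", True, "total", 45,
                                     base_params, lifetable)
        median_month = int(traj.month[traj.cancer_specific_survival < 0.5][0])
        expected = math.exp(4.41) * math.log(2) ** (1 / 1.12)  # ~59.3
        assert abs(median_month - expected) <= 1.0

    def test_aft_monotonicity_morcellation_lowers_survival(
            self, base_params, lifetable):
        morc = cancer_survival_curve("endometrial", True, "total", 45,
                                     base_params, lifetable)
        nomorc = cancer_survival_curve("endometrial", False, "total", 45,
                                       base_params, lifetable)
        assert np.all(nomorc.cancer_specific_survival
                      >= morc.cancer_specific_survival)
        assert np.any(nomorc.cancer_specific_survival
                      > morc.cancer_specific_survival)

    def test_death_cause_probabilities_sum_to_one(self, base_params, lifetable):
        traj = cancer_survival_curve("sarcoma", True, "total", 62,
                                     base_params, lifetable)
        assert traj.p_cancer_death.sum() + traj.p_other_death.sum() == \
            pytest.approx(1.0)
        assert traj.alive_start[0] == 1.0


class TestCancerLifetimeValue:
    def test_zero_discount_flat_utility_closed_form(self, base_params):
        # death at month m with utility u everywhere -> QALY = u * m / 12
        u = 0.7
        params = _with(base_params, discount_rate_annual=0.0,
                       utility_endometrial_care=u,
                       utility_endometrial_eol_cancer=u,
                       utility_endometrial_eol_other=u)
        T = _horizon_months(45)
        _, _, Q_c, Q_o = _cancer_value_given_death("endometrial", 45, params, T)
        for m in (1, 12, 24, 240):
            assert Q_c[m - 1] == pytest.approx(u * m / 12)
            assert Q_o[m - 1] == pytest.approx(u * m / 12)

    def test_death_at_twelve_months_is_all_end_of_life(self, base_params):
        # end-of-life precedence: a cancer death at month 12 (<65) bills all
        # 12 months at the end-of-life uterine-cancer rate of $10,089/month
        params = _with(base_params, discount_rate_annual=0.0,
                       prodloss_eol_cancer=0.0)
        T = _horizon_months(45)
        C_c, _, _, _ = _cancer_value_given_death("endometrial", 45, params, T)
        assert C_c[11] == pytest.approx(12 * 10_089)

    def test_discounting_reduces_value(self, base_params, lifetable):
        v = cancer_lifetime_value("endometrial", False, "total", 45,
                                  base_params, lifetable)
        v0 = cancer_lifetime_value(
            "endometrial", False, "total", 45,
            _with(base_params, discount_rate_annual=0.0), lifetable)
        years_to_horizon = 100 - 45
        assert 0 < v.qaly < v0.qaly < years_to_horizon

    def test_expectation_matches_brute_force_accumulator(
            self, base_params, lifetable):
        # zero discount rate: value arrays reproduced by an explicit
        # month-by-month python loop over randomly chosen death months
        params = _with(base_params, discount_rate_annual=0.0)
        age, hist = 52, "sarcoma"
        T = _horizon_months(age)
        C_c, C_o, Q_c, Q_o = _cancer_value_given_death(hist, age, params, T)
        rng = np.random.default_rng(0)
        for m in rng.integers(1, T + 1, size=100):
            cost_c = cost_o = qaly_c = qaly_o = 0.0
            for t in range(1, m + 1):
                lt65 = (age + (t - 1) / 12.0) < 65
                cls = "lt65" if lt65 else "ge65"
                if t > m - 12:
                    cost_c += params.cancer_cost("eol_cancer", cls)
                    cost_o += params.cancer_cost("eol_other", cls)
                    if lt65:
                        cost_c += params["prodloss_eol_cancer"]
                        cost_o += params["prodloss_eol_other"]
                    qaly_c += params[f"utility_{hist}_eol_cancer"] / 12
                    qaly_o += params[f"utility_{hist}_eol_other"] / 12
                else:
                    phase = "initial" if t <= 12 else "continuing"
                    cost_c += params.cancer_cost(phase, cls)
                    cost_o += params.cancer_cost(phase, cls)
                    if lt65:
                        pl = params["prodloss_initial" if t <= 12
                                    else "prodloss_continuing"]
                        cost_c += pl
                        cost_o += pl
                    qaly_c += params[f"utility_{hist}_care"] / 12
                    qaly_o += params[f"utility_{hist}_care"] / 12
            assert C_c[m - 1] == pytest.approx(cost_c)
            assert C_o[m - 1] == pytest.approx(cost_o)
            assert Q_c[m - 1] == pytest.approx(qaly_c)
            assert Q_o[m - 1] == pytest.approx(qaly_o)


class TestScenarioEvaluation:
    def test_scenario_validation(self, base_params):
        with pytest.raises(ValueError, match="sums to"):
            Scenario("bad", {"TAH": 0.5, "TLH": 0.4}, {})
        with pytest.raises(ValueError, match="laparoscopic"):
            Scenario("bad", {"TAH": 1.0}, {"VH": 0.5})

    def test_zero_cohort_gives_all_zero_result(self, base_params, age_dist,
                                               lifetable):
        res = evaluate_scenario(postwarning_scenario(base_params), age_dist, 0,
                                base_params, lifetable)
        assert res.total_cost == res.total_qaly == res.majors == 0

    def test_no_morcellation_means_no_morcellated_cancers(
            self, base_params, age_dist, lifetable):
        res = evaluate_scenario(postwarning_scenario(base_params), age_dist,
                                100_000, base_params, lifetable)
        assert res.morcellated_endometrial == 0.0
        assert res.morcellated_sarcoma == 0.0

    def test_raising_morcellation_increases_cases_and_lowers_qaly(
            self, base_params, age_dist, lifetable):
        base_sc = counterfactual_scenario(base_params)
        results = []
        for level in (0.0, 0.5, 1.0):
            sc = Scenario("cf", base_sc.route_mix,
                          {"TLH": level, "LSH": level})
            results.append(evaluate_scenario(sc, age_dist, 100_000,
                                             base_params, lifetable))
        counts = [r.morcellated_endometrial + r.morcellated_sarcoma
                  for r in results]
        qalys = [r.total_qaly for r in results]
        assert counts[0] < counts[1] < counts[2]
        assert qalys[0] > qalys[1] > qalys[2]

    def test_expectation_and_microsim_agree(self, base_params, age_dist,
                                            lifetable):
        sc = counterfactual_scenario(base_params)
        exp = evaluate_scenario(sc, age_dist, 50_000, base_params, lifetable)
        ms = evaluate_scenario(sc, age_dist, 50_000, base_params, lifetable,
                               mode="microsim", seed=3)
        assert ms.total_cost == pytest.approx(exp.total_cost, rel=0.02)
        assert ms.total_qaly == pytest.approx(exp.total_qaly, rel=0.02)
        assert ms.majors == pytest.approx(exp.majors, rel=0.10)

    def test_tree_conservation_under_random_draws(self, specs):
        for seed in range(100):
            ps = draw_parameter_set(specs, seed)
            for r in ROUTES:
                out = perioperative_outcome_distribution(r, ps)
                assert sum(out.values()) == pytest.approx(1.0)
                assert all(p >= 0 for p in out.values())
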