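"""CEA engine: ICER arithmetic, PSA reproducibility, CEAC, influence."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hystcea.cea import (
    PsaIteration,
    ceac,
    icer,
    influence_analysis,
    psa_to_frame,
    run_base_case,
    run_psa,
    scale_to_national,
)
from hystcea.decision import counterfactual_scenario, postwarning_scenario


@pytest.fixture(scope="module")
def psa_small(specs, age_dist, lifetable):
    return run_psa(specs, n_iter=120, seed=11, age_distribution=age_dist,
                   lifetable=lifetable)


class TestIcer:
    def test_published_increment_reproduces_published_ratio(self):
        # difference in costs / difference in QALYs
        r = icer(19_542_869, 867.15)
        assert r.flag == "ratio"
        assert round(r.value) == 22_537

    @pytest.mark.parametrize(
        "dc, dq, flag",
        [(-1, 1, "dominant"), (0, 1, "dominant"), (1, -1, "dominated"),
         (1, 0, "undefined"), (-1, -1, "ratio")],
    )
    def test_dominance_flags(self, dc, dq, flag):
        assert icer(dc, dq).flag == flag

    def test_nonfinite_inputs_rejected(self):
        with pytest.raises(ValueError):
            icer(float("nan"), 1.0)

    @given(dc=st.floats(-1e9, 1e9), dq=st.floats(0.01, 1e4))
    @settings(max_examples=50, deadline=None)
    def test_ratio_consistency(self, dc, dq):
        r = icer(dc, dq)
        if r.flag == "ratio":
            assert r.value == pytest.approx(dc / dq)
        else:
            assert dc <= 0  # more effective and not costlier -> dominant


class TestNationalScaling:
    def test_study_count_scales_by_population_share(self):
        assert scale_to_national(105_698, 0.2989) == pytest.approx(353_623.28,
                                                                   abs=0.01)

    @pytest.mark.parametrize("count, share, expected",
                             [(10, 0.5, 20), (7, 1.0, 7)])
    def test_simple_ratios(self, count, share, expected):
        assert scale_to_national(count, share) == expected

    def test_invalid_share_rejected(self):
        with pytest.raises(ValueError):
            scale_to_national(10, 0.0)


class TestBaseCase:
    def test_differences_are_post_minus_counterfactual(
            self, base_params, age_dist, lifetable):
        rep = run_base_case(base_params, age_dist, lifetable)
        d = rep.differences
        assert d["majors"] == pytest.approx(
            rep.postwarning.majors - rep.counterfactual.majors)
        assert d["total_cost"] == pytest.approx(
            rep.postwarning.total_cost - rep.counterfactual.total_cost)

    def test_identical_scenarios_give_zero_differences(
            self, base_params, age_dist, lifetable):
        sc = postwarning_scenario(base_params)
        rep = run_base_case(base_params, age_dist, lifetable,
                            scenario_post=sc, scenario_cf=sc)
        assert rep.differences["total_cost"] == pytest.approx(0.0, abs=1e-6)
        assert rep.icer.flag == "undefined"

    def test_swapping_scenarios_negates_increments(
            self, base_params, age_dist, lifetable):
        rep = run_base_case(base_params, age_dist, lifetable)
        post, cf = (postwarning_scenario(base_params),
                    counterfactual_scenario(base_params))
        swapped = run_base_case(base_params, age_dist, lifetable,
                                scenario_post=cf, scenario_cf=post)
        assert swapped.differences["total_cost"] == pytest.approx(
            -rep.differences["total_cost"])
        assert swapped.differences["total_qaly"] == pytest.approx(
            -rep.differences["total_qaly"])


class TestPsa:
    def test_reproducible_under_seed(self, specs, age_dist, lifetable):
        a = run_psa(specs, n_iter=5, seed=4, age_distribution=age_dist,
                    lifetable=lifetable)
        b = run_psa(specs, n_iter=5, seed=4, age_distribution=age_dist,
                    lifetable=lifetable)
        pd.testing.assert_frame_equal(psa_to_frame(a), psa_to_frame(b))

    def test_degenerate_psa_equals_base_case(self, specs, base_params,
                                             age_dist, lifetable):
        # every distribution collapsed to its base value
        point_specs = [
            s if s.family in ("point", "derived")
            else dataclasses.replace(s, family="point", low=None, high=None)
            for s in specs
        ]
        its = run_psa(point_specs, n_iter=3, seed=9,
                      age_distribution=age_dist, lifetable=lifetable)
        rep = run_base_case(base_params, age_dist, lifetable)
        for it in its:
            assert it.delta_cost == pytest.approx(
                rep.differences["total_cost"], rel=1e-9)
            assert it.delta_qaly == pytest.approx(
                rep.differences["total_qaly"], rel=1e-9)

    def test_iteration_table_columns(self, psa_small):
        df = psa_to_frame(psa_small)
        assert len(df) == 120
        assert {"iteration", "seed", "delta_cost", "delta_qaly",
                "morc_prop_cf_lsh"} <= set(df.columns)
        assert df[["delta_cost", "delta_qaly"]].notna().all().all()


class TestCeac:
    def test_dominant_iteration_is_always_cost_effective(self):
        it = PsaIteration(0, 0, delta_cost=-1.0, delta_qaly=1.0, values={})
        assert all(p.proportion == 1.0 for p in ceac([it], [0, 5e4, 2e5]))

    def test_limits_match_sign_fractions(self, psa_small):
        dc = np.array([i.delta_cost for i in psa_small])
        dq = np.array([i.delta_qaly for i in psa_small])
        low, high = ceac(psa_small, [0.0, 1e9])
        assert low.proportion == pytest.approx(np.mean(dc <= 0))
        assert high.proportion == pytest.approx(np.mean(dq > 0))

    def test_proportions_bounded(self, psa_small):
        for p in ceac(psa_small):
            assert 0.0 <= p.proportion <= 1.0


class TestInfluence:
    @staticmethod
    def _planted_iterations(n=200, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.random(n)
        noise = rng.random(n)
        return [
            PsaIteration(i, i, delta_cost=1_000.0 * x[i] + noise[i],
                         delta_qaly=1.0,
                         values={"planted": x[i], "noise": noise[i],
                                 "constant": 0.5})
            for i in range(n)
        ]

    @pytest.mark.parametrize("method", ["spearman", "prcc"])
    def test_planted_linear_signal_ranks_first(self, method):
        ranking = influence_analysis(self._planted_iterations(), method=method)
        assert ranking.iloc[0]["parameter"] == "planted"
        assert "constant" not in set(ranking["parameter"])

    def test_too_few_iterations_rejected(self):
        with pytest.raises(ValueError):
            influence_analysis(self._planted_iterations(n=50))

    def test_morcellation_survival_inputs_rank_high(self, psa_small):
        # qualitative check: drivers of the cancer subtree appear near the top
        ranking = influence_analysis(psa_small)
        top = set(ranking.head(10)["parameter"])
        expected_any = {
            "weibull_endometrial_scale_morc", "weibull_endometrial_inc_total",
            "weibull_sarcoma_inc_total", "morc_prop_cf_lsh",
            "utility_abdominal", "recovery_weeks_abdominal",
            "weekly_earnings",
        }
        assert top & expected_any
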