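import dataclasses

import numpy as np
import pandas as pd
import pytest

from qalytree.distributions import ParameterSpec
from qalytree.model import DecisionModel
from qalytree.sensitivity import (
    PSASample,
    SensitivityError,
    ceac,
    one_way_dsa,
    quadrant_summary,
    run_psa,
    tornado,
)
from qalytree.evaluation import StrategyOutcome


def with_extra_param(model, spec):
    params = dict(model.parameters)
    params[spec.name] = spec
    return dataclasses.replace(model, parameters=params)


def all_fixed(model):
    params = {
        name: ParameterSpec(name, s.base_value, "fixed", 0.0, kind=s.kind)
        for name, s in model.parameters.items()
    }
    return dataclasses.replace(model, parameters=params)


class TestOneWayDSA:
    def test_c_drug_spread_is_exactly_linear(self, om85_model):
        entry = one_way_dsa(om85_model, "c_drug", 0.25)
        assert entry.low_input == pytest.approx(55.5)
        assert entry.high_input == pytest.approx(92.5)
        # INMB is linear in the drug cost with slope -1
        assert entry.spread == pytest.approx(2 * 0.25 * 74.0, rel=1e-9)

    def test_c_rti_spread(self, om85_model):
        entry = one_way_dsa(om85_model, "c_rti", 0.25)
        # INMB linear in c_rti with coefficient dp = 0.2 * 0.65
        assert entry.spread == pytest.approx(2 * 0.25 * 2022.0 * 0.13, rel=1e-9)

    def test_inert_parameter_has_zero_spread(self, om85_model):
        model = with_extra_param(
            om85_model, ParameterSpec("c_unused", 100.0, "gamma", 10.0, kind="cost")
        )
        entry = one_way_dsa(model, "c_unused", 0.25)
        assert entry.spread == 0.0

    def test_inputs_bracket_base(self, om85_model):
        for name, spec in om85_model.parameters.items():
            if spec.family == "fixed":
                continue
            entry = one_way_dsa(om85_model, name)
            assert entry.low_input <= spec.base_value <= entry.high_input

    def test_utility_high_clipped_at_one(self, om85_model):
        entry = one_way_dsa(om85_model, "u_base", 0.25)
        assert entry.high_input == 1.0
        assert entry.clipped

    def test_lognormal_effect_uses_distribution_interval(self, om85_model):
        entry = one_way_dsa(om85_model, "reduction", 0.25)
        # central 95% interval of LogN fitted to (0.65, 0.07)
        assert entry.low_input == pytest.approx(0.5236, abs=5e-4)
        assert entry.high_input == pytest.approx(0.7977, abs=5e-4)

    def test_explicit_dsa_bounds_win(self, om85_model):
        model = with_extra_param(
            om85_model,
            ParameterSpec("c_x", 100.0, "gamma", 10.0, kind="cost", dsa_low=90.0, dsa_high=130.0),
        )
        entry = one_way_dsa(model, "c_x", 0.25)
        assert (entry.low_input, entry.high_input) == (90.0, 130.0)

    def test_unknown_parameter(self, om85_model):
        with pytest.raises(SensitivityError, match="p_typo"):
            one_way_dsa(om85_model, "p_typo")


class TestTornado:
    def test_sorted_by_spread_descending(self, om85_model):
        entries = tornado(om85_model)
        spreads = [e.spread for e in entries]
        assert spreads == sorted(spreads, reverse=True)
        assert len(entries) == 7  # all non-fixed parameters

    def test_single_varying_parameter(self, om85_model):
        model = all_fixed(om85_model)
        model = dataclasses.replace(
            model,
            parameters={
                **model.parameters,
                "c_drug": ParameterSpec("c_drug", 74.0, "gamma", 18.5, kind="cost"),
            },
        )
        entries = tornado(model)
        assert [e.parameter for e in entries] == ["c_drug"]

    def test_no_varying_parameter_rejected(self, om85_model):
        with pytest.raises(SensitivityError):
            tornado(all_fixed(om85_model))

    def test_equal_spreads_break_ties_alphabetically(self, om85_model):
        model = with_extra_param(
            om85_model, ParameterSpec("a_inert", 1.0, "gamma", 0.1, kind="cost")
        )
        model = with_extra_param(
            model, ParameterSpec("b_inert", 1.0, "gamma", 0.1, kind="cost")
        )
        entries = tornado(model)
        inert = [e.parameter for e in entries if e.spread == 0.0]
        assert inert == ["a_inert", "b_inert"]

    def test_verdict_never_flips_across_scenarios(self, om85_model):
        # every low/high scenario keeps INMB > 0 (dominance direction holds)
        for entry in tornado(om85_model):
            assert entry.outcome_at_low > 0
            assert entry.outcome_at_high > 0


class TestRunPSA:
    def test_all_fixed_equals_base_case(self, om85_model):
        model = all_fixed(om85_model)
        psa = run_psa(model, n=1, seed=0)
        base = om85_model.base_case()
        assert psa.delta_cost[0] == pytest.approx(base.delta_cost, rel=1e-12)
        assert psa.delta_qaly[0] == pytest.approx(base.delta_qaly, rel=1e-12)

    def test_determinism_bitwise(self, om85_model):
        a = run_psa(om85_model, n=500, seed=77)
        b = run_psa(om85_model, n=500, seed=77)
        pd.testing.assert_frame_equal(a.table(), b.table())

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")  # rare reduction clamps
    def test_means_match_base_case_within_3_se(self, om85_model):
        # parameters enter multiplicatively and independently, so the PSA
        # mean of each delta is the deterministic base-case delta
        psa = run_psa(om85_model, n=10_000, seed=5)
        base = om85_model.base_case()
        se_c = psa.delta_cost.std(ddof=1) / np.sqrt(psa.n)
        se_q = psa.delta_qaly.std(ddof=1) / np.sqrt(psa.n)
        assert abs(psa.delta_cost.mean() - base.delta_cost) < 3 * se_c
        assert abs(psa.delta_qaly.mean() - base.delta_qaly) < 3 * se_q

    def test_inmb_identity_per_iteration(self, om85_model):
        psa = run_psa(om85_model, n=200, seed=3)
        np.testing.assert_allclose(
            psa.inmb, psa.delta_qaly * om85_model.wtp - psa.delta_cost, atol=1e-9
        )
        s = psa[17]
        assert s.inmb == pytest.approx(s.delta_qaly * om85_model.wtp - s.delta_cost)

    def test_shared_binding_across_strategies(self, om85_model):
        psa = run_psa(om85_model, n=50, seed=1)
        for s in psa[:5]:
            # recompute both arms from the recorded binding
            outs = om85_model.outcomes(s.binding)
            assert outs["placebo"].expected_cost == pytest.approx(s.reference.expected_cost)
            assert outs["om85"].expected_cost == pytest.approx(s.intervention.expected_cost)

    def test_n_below_one_rejected(self, om85_model):
        with pytest.raises(SensitivityError):
            run_psa(om85_model, n=0, seed=0)

    def test_table_columns(self, om85_model):
        frame = run_psa(om85_model, n=10, seed=0).table()
        for col in ("iteration", "p_repeat", "delta_cost", "delta_qaly", "inmb"):
            assert col in frame.columns
        assert len(frame) == 10


def _sample(dq, dc, wtp=5180.0):
    return PSASample(
        iteration=0,
        binding={},
        reference=StrategyOutcome("r", 0.0, 0.0),
        intervention=StrategyOutcome("i", dc, dq),
        delta_cost=dc,
        delta_qaly=dq,
        inmb=dq * wtp - dc,
    )


class TestQuadrantSummary:
    def test_dominant_base_case_all_in_gain_save(self, om85_model):
        model = all_fixed(om85_model)
        q = quadrant_summary(run_psa(model, n=10, seed=0))
        assert q.gain_save == 1.0
        assert q.cost_effective == 1.0

    def test_proportions_sum_to_one_exactly(self, om85_model):
        q = quadrant_summary(run_psa(om85_model, n=2000, seed=9))
        assert q.gain_save + q.gain_cost + q.loss_save + q.loss_cost == 1.0

    def test_one_point_per_quadrant(self):
        samples = [_sample(0.1, -10), _sample(0.1, 10), _sample(-0.1, -10), _sample(-0.1, 10)]
        q = quadrant_summary(samples)
        assert (q.gain_save, q.gain_cost, q.loss_save, q.loss_cost) == (0.25,) * 4

    def test_zero_deltas_count_to_favourable_side(self):
        q = quadrant_summary([_sample(0.0, 0.0)])
        assert q.gain_cost == 1.0  # dQ=0 -> gain half; dC=0 -> costly half of dc>=0
        assert q.cost_effective == 0.0  # INMB == 0 is not > 0

    def test_om85_cost_saving_proportion_near_99pct(self, om85_model):
        q = quadrant_summary(run_psa(om85_model, n=10_000, seed=2))
        assert q.gain_save + q.loss_save == pytest.approx(0.99, abs=0.02)

    def test_empty_samples_rejected(self):
        with pytest.raises(SensitivityError):
            quadrant_summary([])


class TestCEAC:
    def test_at_zero_wtp_equals_cost_saving_fraction(self, om85_model):
        psa = run_psa(om85_model, n=2000, seed=4)
        (pt,) = ceac(psa, [0.0])
        assert pt.probability == float(np.mean(psa.delta_cost < 0))

    def test_large_wtp_limit_equals_qaly_gain_fraction(self, om85_model):
        psa = run_psa(om85_model, n=2000, seed=4)
        (pt,) = ceac(psa, [1e12])
        assert pt.probability == pytest.approx(float(np.mean(psa.delta_qaly > 0)), abs=1e-3)

    def test_degenerate_grid_matches_quadrant_fraction(self, om85_model):
        psa = run_psa(om85_model, n=2000, seed=4)
        (pt,) = ceac(psa, [om85_model.wtp])
        assert pt.probability == quadrant_summary(psa).cost_effective

    def test_grid_validation(self, om85_model):
        psa = run_psa(om85_model, n=10, seed=0)
        with pytest.raises(SensitivityError):
            ceac(psa, [])
        with pytest.raises(SensitivityError):
            ceac(psa, [-1.0, 5.0])
        with pytest.raises(SensitivityError):
            ceac(psa, [10.0, 5.0])

    def test_works_on_sample_lists(self):
        samples = [_sample(0.01, -100), _sample(-0.01, 200)]
        pts = ceac(samples, [0.0, 5180.0])
        assert pts[0].probability == 0.5
        assert pts[1].probability == 0.5
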