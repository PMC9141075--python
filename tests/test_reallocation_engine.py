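import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coherent_staffing.care_system_model import SkillMatrix
from coherent_staffing.markov_prediction import StaffingState
from coherent_staffing.reallocation_engine import (
    FloatPool,
    build_float_pool,
    deploy_float,
    flex_rate,
    inherent_pooling_matrix,
    pairwise_reallocate,
    run_model,
)


def make_state(e: dict, shift_type: str = "day") -> StaffingState:
    units = list(e)
    a = pd.Series({u: max(v, 0) + 4 for u, v in e.items()})
    d = a - pd.Series(e)
    return StaffingState(0, shift_type, a, d)


def make_skill(units, ones) -> SkillMatrix:
    Z = pd.DataFrame(
        np.eye(len(units), dtype=int), index=list(units), columns=list(units)
    )
    for j, i in ones:
        Z.loc[j, i] = 1
    Z.index.name = "from"
    return SkillMatrix(Z)


def brute_force_optimal_coverage(e, z):
    """Max shortage covered, enumerating all feasible integer move sets."""
    n = len(e)
    donors = [j for j in range(n) if e[j] > 0]
    best = 0

    def rec(di, need, covered):
        nonlocal best
        if di == len(donors):
            best = max(best, covered)
            return
        j = donors[di]
        targets = [i for i in range(n) if need[i] > 0 and z[j][i] and i != j]

        def alloc(ti, left, need, covered):
            if ti == len(targets):
                rec(di + 1, need, covered)
                return
            i = targets[ti]
            for q in range(0, min(left, need[i]) + 1):
                nd = list(need)
                nd[i] -= q
                alloc(ti + 1, left - q, nd, covered + q)

        alloc(0, e[j], list(need), covered)

    rec(0, [-x if x < 0 else 0 for x in e], 0)
    return best


class TestPairwiseReallocate:
    def test_simple_transfer(self):
        # brute force over feasible move sets gives the same residuals
        state = make_state({"A": -2, "B": 3})
        plan = pairwise_reallocate(state, make_skill("AB", [("B", "A")]))
        assert plan.moves == {("B", "A"): 2}
        assert plan.residual_e.to_dict() == {"A": 0, "B": 1}
        assert plan.total_moved == 2

    def test_no_shortage_empty_plan(self):
        state = make_state({"A": 1, "B": 0})
        plan = pairwise_reallocate(state, make_skill("AB", [("B", "A")]))
        assert plan.moves == {}
        assert plan.total_moved == 0

    def test_skill_matrix_forbids(self):
        state = make_state({"A": -2, "B": 3})
        plan = pairwise_reallocate(state, make_skill("AB", []))
        assert plan.moves == {}
        pd.testing.assert_series_equal(plan.residual_e, state.e)

    def test_donor_never_overcommitted(self):
        state = make_state({"A": -3, "B": -3, "C": 2})
        plan = pairwise_reallocate(
            state, make_skill("ABC", [("C", "A"), ("C", "B")])
        )
        outgoing = sum(q for (j, _), q in plan.moves.items() if j == "C")
        assert outgoing <= 2

    def test_least_flexible_donor_preserved(self):
        # D can serve both shortages; C only B.  Moving D first would
        # strand C's surplus.
        state = make_state({"A": -1, "B": -2, "C": 1, "D": 2})
        plan = pairwise_reallocate(
            state,
            make_skill("ABCD", [("C", "B"), ("D", "A"), ("D", "B")]),
        )
        assert (plan.residual_e >= 0).all()

    @settings(max_examples=60, deadline=None)
    @given(
        e=st.lists(st.integers(-3, 3), min_size=2, max_size=5),
        bits=st.integers(0, 2**20 - 1),
    )
    def test_feasibility_invariants(self, e, bits):
        n = len(e)
        units = [f"u{k}" for k in range(n)]
        z = np.eye(n, dtype=int)
        flat = [(j, i) for j in range(n) for i in range(n) if i != j]
        for idx, (j, i) in enumerate(flat):
            z[j, i] = (bits >> idx) & 1
        Z = pd.DataFrame(z, index=units, columns=units)
        Z.index.name = "from"
        state = make_state(dict(zip(units, e)))
        plan = pairwise_reallocate(state, SkillMatrix(Z))
        sent = {u: 0 for u in units}
        received = {u: 0 for u in units}
        for (j, i), q in plan.moves.items():
            assert q > 0 and j != i
            assert Z.loc[j, i] == 1
            sent[j] += q
            received[i] += q
        for k, u in enumerate(units):
            assert sent[u] <= max(e[k], 0)
            assert received[u] <= max(-e[k], 0)
            assert plan.residual_e[u] == e[k] - sent[u] + received[u]
        assert plan.total_moved == sum(sent.values())

    @settings(max_examples=40, deadline=None)
    @given(
        e=st.lists(st.integers(-3, 3), min_size=2, max_size=4),
        bits=st.integers(0, 2**12 - 1),
    )
    def test_matches_bruteforce_on_random_small_systems(self, e, bits):
        n = len(e)
        units = [f"u{k}" for k in range(n)]
        z = np.eye(n, dtype=int)
        flat = [(j, i) for j in range(n) for i in range(n) if i != j]
        for idx, (j, i) in enumerate(flat):
            z[j, i] = (bits >> idx) & 1
        Z = pd.DataFrame(z, index=units, columns=units)
        Z.index.name = "from"
        plan = pairwise_reallocate(make_state(dict(zip(units, e))), SkillMatrix(Z))
        residual_short = int(-plan.residual_e[plan.residual_e < 0].sum())
        total_short = -sum(x for x in e if x < 0)
        optimal = total_short - brute_force_optimal_coverage(e, z.tolist())
        assert residual_short == optimal


class TestFlexRate:
    def test_worked_example(self):
        assert flex_rate(4, 38).percent == 11

    def test_zero_moves(self):
        assert flex_rate(0, 38).percent == 0

    def test_rounding(self):
        # 100 * 7 / 66 = 10.61 -> 11
        assert flex_rate(7, 66).percent == 11

    def test_sequences(self):
        fr = flex_rate([2, 2], [20, 18])
        assert fr.fraction == pytest.approx(4 / 38)
        assert fr.percent == 11

    def test_zero_scheduled_errors(self):
        with pytest.raises(ValueError, match="scheduled"):
            flex_rate(1, 0)


class TestFloatPool:
    def test_day_pool_size(self, reference_config):
        pool, _ = build_float_pool(reference_config.roster, 0.07)
        assert pool.size == {"day": 2, "evening": 1, "night": 1}

    def test_zero_rate_unchanged(self, reference_config):
        pool, reduced = build_float_pool(reference_config.roster, 0.0)
        assert all(v == 0 for v in pool.size.values())
        pd.testing.assert_frame_equal(
            reduced.scheduled, reference_config.roster.scheduled
        )

    def test_headcount_conserved(self, reference_config):
        for rate in (0.07, 0.20, 0.40):
            pool, reduced = build_float_pool(reference_config.roster, rate)
            for s in ("day", "evening", "night"):
                assert (
                    reduced.total(s) + pool.size[s]
                    == reference_config.roster.total(s)
                )
                assert pool.withdrawn.loc[s].sum() == pool.size[s]
                assert (reduced.row(s) >= 0).all()

    def test_twenty_percent_training_crosscheck(self, reference_config):
        # 20% of the 176 registered nurses -> 35 to train, EUR 700k
        from coherent_staffing.care_system_model import nurses_to_train
        from coherent_staffing.evaluation import training_cost

        n = nurses_to_train("model2", reference_config.registry, 0.20)
        assert n == 35
        assert training_cost(n) == 700_000

    def test_invalid_rates(self, reference_config):
        for r in (-0.1, 1.0, 1.5):
            with pytest.raises(ValueError):
                build_float_pool(reference_config.roster, r)


class TestDeployFloat:
    def test_largest_shortage_first(self):
        e = pd.Series({"A": -3, "B": -1})
        deployed = deploy_float(e, 2)
        assert deployed.to_dict() == {"A": 2, "B": 0}

    def test_leftover_returns_home(self):
        e = pd.Series({"A": -1, "B": 0})
        home = pd.Series({"A": 1, "B": 2})
        deployed = deploy_float(e, 3, home=home)
        assert deployed["A"] >= 1
        assert deployed.sum() == 3

    def test_no_home_keeps_idle(self):
        e = pd.Series({"A": -1, "B": 0})
        assert deploy_float(e, 3).sum() == 1


class TestRunModel:
    def test_model0_keeps_gaps(self, reference_config):
        state = make_state({u: v for u, v in zip(
            reference_config.unit_ids, [-1, 2, 0, -1, 1, 0, 0])})
        plan = run_model(0, state, reference_config)
        pd.testing.assert_series_equal(plan.residual_e, state.e)
        assert plan.total_moved == 0

    def test_model3_with_empty_pool_equals_model1(self, reference_config):
        pool = FloatPool(
            rate=0.0,
            size={s: 0 for s in ("day", "evening", "night")},
            withdrawn=reference_config.roster.scheduled * 0,
        )
        state = make_state({u: v for u, v in zip(
            reference_config.unit_ids, [2, -1, -2, 1, -1, 0, 3])})
        p3 = run_model(3, state, reference_config, float_pool=pool)
        p1 = run_model(1, state, reference_config)
        assert p3.moves == p1.moves
        pd.testing.assert_series_equal(p3.residual_e, p1.residual_e)

    def test_model2_deployment_example(self, reference_config):
        # shortages {-3, -1} with 2 pool nurses -> {2, 0}, both left -1
        units = reference_config.unit_ids
        e = {u: 0 for u in units}
        e["N1"], e["N2"] = -3, -1
        pool = FloatPool(
            rate=0.07,
            size={s: 2 for s in ("day", "evening", "night")},
            withdrawn=reference_config.roster.scheduled * 0,
        )
        state = make_state(e)
        plan = run_model(2, state, reference_config, float_pool=pool)
        assert plan.float_deployed["N1"] == 2
        assert plan.float_deployed["N2"] == 0
        assert plan.residual_e["N1"] == -1
        assert plan.residual_e["N2"] == -1

    def test_unknown_model_errors(self, reference_config):
        with pytest.raises(ValueError, match="unknown model"):
            run_model(5, make_state({"N1": 0}), reference_config)

    def test_pool_required_for_models_2_3(self, reference_config):
        state = make_state({u: 0 for u in reference_config.unit_ids})
        for model_id in (2, 3):
            with pytest.raises(ValueError, match="float pool"):
                run_model(model_id, state, reference_config)

    def test_conservation(self, reference_config):
        state = make_state({u: v for u, v in zip(
            reference_config.unit_ids, [3, -2, -1, 1, -1, 2, 0])})
        plan = run_model(1, state, reference_config)
        assert plan.net_delta().sum() == 0

    def test_model1_no_worse_than_model0_pointwise(self, reference_config):
        rng = np.random.default_rng(5)
        for _ in range(30):
            e = dict(zip(reference_config.unit_ids, rng.integers(-3, 4, 7)))
            state = make_state(e)
            r0 = run_model(0, state, reference_config).residual_e
            r1 = run_model(1, state, reference_config).residual_e
            assert (r1[r1 < 0] >= r0[r1[r1 < 0].index]).all()

    def test_model3_no_worse_than_model2_same_pool(self, reference_config):
        pool, _ = build_float_pool(reference_config.roster, 0.07)
        rng = np.random.default_rng(6)
        for _ in range(30):
            e = dict(zip(reference_config.unit_ids, rng.integers(-3, 4, 7)))
            state = make_state(e)
            r2 = run_model(
                2, state, reference_config, float_pool=pool, shift_type="day"
            ).residual_e
            r3 = run_model(
                3, state, reference_config, float_pool=pool, shift_type="day"
            ).residual_e
            assert -r3[r3 < 0].sum() <= -r2[r2 < 0].sum()


class TestInherentPooling:
    def test_current_layout_is_identity(self, reference_config):
        Z = inherent_pooling_matrix(reference_config).Z
        assert (Z.values == np.eye(len(reference_config.unit_ids))).all()

    def test_pooled_layout_uses_config_matrix(self, all_configs):
        from coherent_staffing.care_system_model import CONFIG2

        Z = inherent_pooling_matrix(all_configs[CONFIG2]).Z
        assert (Z.values == 1).all()
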