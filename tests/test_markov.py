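"""Markov engine: matrix construction, mortality composition, propagation.

The matrix-power oracle recomputes occupancy independently with repeated
matrix multiplication; worked mortality compositions were evaluated by hand
from the competing-risk formula before the engine was built.
"""

import math

import numpy as np
import pytest

from strokecea.decision_tree import Arm, run_decision_tree
from strokecea.markov import (
    DEAD,
    ND,
    STATES,
    accrue_cycle,
    apply_background_mortality,
    build_transition_matrix,
    run_markov,
)
from strokecea.parameters import Param, update_path
from strokecea.synthetic import GeneratorConfig, generate_parameter_set


class TestTransitionMatrix:
    def test_after_first_year_rows_without_background_mortality(self, fixtures):
        ps = fixtures["zero_background_mortality"]
        m = build_transition_matrix("after_first_year", 70.0, ps)
        np.testing.assert_allclose(m[0], [0.979, 0.0, 0.013, 0.0, 0.008], atol=1e-12)
        np.testing.assert_allclose(m[2], [0.834, 0.137, 0.0, 0.0, 0.029], atol=1e-12)
        np.testing.assert_allclose(m[3], [0.0, 0.971, 0.0, 0.0, 0.029], atol=1e-12)

    def test_recurrent_after_disabling_cannot_improve(self, ps):
        for era in ("first_year", "after_first_year"):
            m = build_transition_matrix(era, 64.5, ps)
            assert m[3, 0] == 0.0

    @pytest.mark.parametrize("era", ["first_year", "after_first_year"])
    @pytest.mark.parametrize("age", [60.25, 64.5, 79.75, 92.0])
    def test_rows_stochastic(self, ps, era, age):
        m = build_transition_matrix(era, age, ps)
        np.testing.assert_allclose(m.sum(axis=1), np.ones(5), atol=1e-9)
        assert (m >= 0).all()
        np.testing.assert_allclose(m[DEAD], [0, 0, 0, 0, 1], atol=0)

    def test_unknown_era_rejected(self, ps):
        with pytest.raises(ValueError):
            build_transition_matrix("year_zero", 64.5, ps)

    def test_age_below_table_rejected(self, ps):
        with pytest.raises(ValueError):
            build_transition_matrix("first_year", 40.0, ps)


class TestBackgroundMortality:
    ROW = np.array([0.979, 0.0, 0.013, 0.0, 0.008])

    def test_zero_background_is_identity(self):
        np.testing.assert_allclose(
            apply_background_mortality(self.ROW, 0.0, 1.68), self.ROW, atol=0)

    def test_worked_composition(self):
        # hand evaluation: death = 1 - (1 - 0.008)(1 - 0.0018400725732370393)
        p_bg = 0.0018400725732370393
        out = apply_background_mortality(self.ROW, p_bg, 1.0)
        expected_death = 1.0 - (1.0 - 0.008) * (1.0 - p_bg)
        assert math.isclose(out[DEAD], expected_death, rel_tol=1e-12)
        assert math.isclose(out[DEAD], 0.009825, abs_tol=5e-7)
        np.testing.assert_allclose(
            out[:DEAD], self.ROW[:DEAD] * (1.0 - expected_death) / 0.992, rtol=1e-12)
        assert math.isclose(out.sum(), 1.0, abs_tol=1e-12)

    @pytest.mark.parametrize("p_bg,rr", [(0.002, 1.0), (0.01, 1.68), (0.05, 1.92)])
    def test_composed_death_dominates_both_risks(self, p_bg, rr):
        out = apply_background_mortality(self.ROW, p_bg, rr)
        assert out[DEAD] >= max(self.ROW[DEAD], min(1.0, p_bg * rr)) - 1e-15
        assert math.isclose(out.sum(), 1.0, abs_tol=1e-12)

    def test_replace_if_larger_takes_maximum(self):
        out = apply_background_mortality(self.ROW, 0.05, 1.0, mode="replace_if_larger")
        assert math.isclose(out[DEAD], 0.05, rel_tol=1e-12)
        out = apply_background_mortality(self.ROW, 0.001, 1.0, mode="replace_if_larger")
        assert math.isclose(out[DEAD], self.ROW[DEAD], rel_tol=1e-12)

    def test_ignore_mode_identity(self):
        np.testing.assert_allclose(
            apply_background_mortality(self.ROW, 0.5, 1.68, mode="ignore"), self.ROW)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            apply_background_mortality(self.ROW, 0.01, 1.0, mode="bogus")


class TestPropagation:
    def test_single_step_equals_hand_multiplication(self, fixtures):
        ps = fixtures["zero_background_mortality"]
        entry = ps.efficacy.dist_bmm
        trace = run_markov(entry, ps, n_cycles=2)
        m = build_transition_matrix("first_year", 64.25, ps)
        sv0 = np.array([entry.nondisabling.point, entry.disabling.point, 0, 0,
                        entry.dead.point])
        np.testing.assert_allclose(trace.occupancy[0], sv0, atol=1e-15)
        np.testing.assert_allclose(trace.occupancy[1], sv0 @ m, atol=1e-14)

    def test_matrix_power_oracle_on_frozen_chain(self, fixtures):
        # freeze era and age band so the chain is homogeneous, then compare
        # against an independent entry @ M^k computation
        ps = fixtures["zero_background_mortality"]
        ps = update_path(ps, "transitions.first_year",
                         dict(ps.transitions.after_first_year))
        entry = ps.efficacy.dist_sr
        n = 40
        trace = run_markov(entry, ps, n_cycles=n)
        m = build_transition_matrix("after_first_year", 64.25, ps)
        sv = np.array([entry.nondisabling.point, entry.disabling.point, 0, 0,
                       entry.dead.point])
        for k in range(n):
            np.testing.assert_allclose(
                trace.occupancy[k], sv @ np.linalg.matrix_power(m, k), atol=1e-12)

    @pytest.mark.parametrize("seed", [3, 11, 42])
    def test_mass_conservation_and_dead_monotonicity(self, seed):
        ps = generate_parameter_set(GeneratorConfig(seed=seed))
        entry = ps.efficacy.dist_bmm
        trace = run_markov(entry, ps, n_cycles=79, start_age=64.0)
        np.testing.assert_allclose(trace.occupancy.sum(axis=1), np.ones(79), atol=1e-9)
        dead = trace.occupancy[:, DEAD]
        assert (np.diff(dead) >= -1e-15).all()

    def test_dead_strictly_increases_with_positive_background_mortality(self, ps):
        trace = run_markov(ps.efficacy.dist_bmm, ps, n_cycles=79)
        dead = trace.occupancy[:, DEAD]
        assert (np.diff(dead) > 0).all()

    def test_all_dead_entry_accrues_nothing(self, fixtures):
        ps = fixtures["all_dead_entry"]
        trace = run_markov(ps.efficacy.dist_bmm, ps, n_cycles=20)
        assert trace.total_cost == 0.0
        assert trace.total_qaly == 0.0
        assert trace.total_ly == 0.0
        np.testing.assert_allclose(trace.occupancy[:, DEAD], np.ones(20), atol=0)

    def test_unit_utilities_make_qaly_equal_ly(self, fixtures):
        ps = fixtures["utilities_one"]
        trace = run_markov(ps.efficacy.dist_bmm, ps, n_cycles=79)
        np.testing.assert_allclose(trace.qaly, trace.ly, rtol=1e-12)

    def test_cumulative_qaly_bounded_by_ly(self, ps):
        trace = run_markov(ps.efficacy.dist_sr, ps, n_cycles=79)
        assert trace.total_qaly <= trace.total_ly

    def test_invalid_entry_rejected(self, ps):
        with pytest.raises(ValueError):
            run_markov(np.array([0.5, 0.2, 0.0, 0.0, 0.2]), ps, n_cycles=5)

    def test_trace_dataframe_layout(self, ps):
        trace = run_markov(ps.efficacy.dist_bmm, ps, n_cycles=8)
        df = trace.to_dataframe()
        assert list(df.columns[:2]) == ["cycle", "age"]
        assert set(STATES) <= set(df.columns)
        assert len(df) == 8


class TestAccrual:
    def test_empty_living_states_accrue_zero(self, ps):
        assert accrue_cycle([0, 0, 0, 0, 1.0], ps, 3.0) == (0.0, 0.0, 0.0)

    def test_full_nondisabling_undiscounted(self, fixtures):
        ps = fixtures["zero_discount"]
        cost, qaly, ly = accrue_cycle([1.0, 0, 0, 0, 0], ps, 5.0)
        assert math.isclose(cost, 355.0, rel_tol=1e-12)   # 0.25 * 1420
        assert math.isclose(qaly, 0.19, rel_tol=1e-12)    # 0.25 * 0.76
        assert math.isclose(ly, 0.25, rel_tol=1e-12)

    def test_discounting_at_one_year(self, ps):
        c1, q1, l1 = accrue_cycle([1.0, 0, 0, 0, 0], ps, 0.0)
        c2, q2, l2 = accrue_cycle([1.0, 0, 0, 0, 0], ps, 1.0)
        for a, b in ((c1, c2), (q1, q2), (l1, l2)):
            assert math.isclose(b, a / 1.05, rel_tol=1e-12)

    def test_recurrent_event_charged_per_entry_not_maintenance(self, ps):
        cost, qaly, _ = accrue_cycle([0, 0, 1.0, 0, 0], ps, 0.0)
        assert math.isclose(cost, ps.costs.recurrent_event.point, rel_tol=1e-12)
        assert math.isclose(qaly, 0.25 * ps.utilities.u_recurrent.point, rel_tol=1e-12)

    def test_discounted_cost_monotone_in_rate(self, ps):
        entry = ps.efficacy.dist_bmm
        totals = []
        for r in (0.0, 0.02, 0.05, 0.08, 0.12):
            mod = update_path(ps, "settings.discount_rate_cost", Param(r, 0.0, 0.2))
            totals.append(run_markov(entry, mod, n_cycles=79).total_cost)
        assert all(b < a for a, b in zip(totals, totals[1:]))


class TestArmTotalsAgainstEngine:
    def test_half_cycle_correction_reduces_accruals(self, ps):
        entry = run_decision_tree(Arm.BMM_ALONE, ps).exit_distribution
        hcc = run_markov(entry, ps, n_cycles=79, half_cycle_correction=True)
        no = run_markov(entry, ps, n_cycles=79, half_cycle_correction=False)
        # occupancy declines over time, so mid-cycle valuation is smaller
        assert hcc.total_ly < no.total_ly
        assert hcc.total_qaly < no.total_qaly

    def test_zero_cycles_allowed(self, ps):
        trace = run_markov(ps.efficacy.dist_bmm, ps, n_cycles=0)
        assert trace.total_cost == 0.0 and len(trace.cycles) == 0
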