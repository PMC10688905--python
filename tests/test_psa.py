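"""PSA: distribution fitting, sampling determinism, CEAC behaviour."""

import math

import numpy as np
import pytest
from scipy import stats

from strokecea.outcomes import run_base_case
from strokecea.parameters import Param, update_path
from strokecea.psa import (
    DistributionAssignment,
    FittedDistribution,
    acceptance_probability,
    assign_distributions,
    ceac,
    ceac_crossing,
    run_psa,
    sample_parameters,
)


@pytest.fixture(scope="module")
def assignment(ps):
    return assign_distributions(ps)


class TestFitting:
    def test_family_rules(self, assignment):
        fam = {e.path: e.family for e in assignment.entries}
        assert fam["efficacy.dist_sr"] == "dirichlet"
        assert fam["acute.p_sich_bmm"] == "beta"
        assert fam["utilities.u_nondisabling"] == "beta"
        assert fam["costs.sr_additional"] == "gamma"
        assert fam["mortality.rr_nonstroke_disabled"] == "gamma"
        assert fam["utilities.u_dead"] == "fixed"  # no range printed

    def test_beta_matches_mean_and_interval(self, assignment):
        e = assignment.by_path()["utilities.u_nondisabling"]
        dist = stats.beta(*e.shape)
        assert math.isclose(dist.mean(), 0.76, rel_tol=1e-9)
        lo, hi = dist.ppf([0.025, 0.975])
        assert abs(lo - 0.69) < 0.01 and abs(hi - 0.82) < 0.01

    def test_gamma_matches_mean(self, assignment):
        e = assignment.by_path()["costs.sr_additional"]
        k, theta = e.shape
        assert math.isclose(k * theta, 11695.0, rel_tol=1e-9)

    def test_dirichlet_marginals_track_printed_ranges(self, assignment):
        e = assignment.by_path()["efficacy.dist_sr"]
        alphas = np.asarray(e.shape)
        s = alphas.sum()
        sd = np.sqrt(alphas / s * (1 - alphas / s) / (s + 1))
        printed_sd = (np.asarray(e.high) - np.asarray(e.low)) / (2 * 1.959963984540054)
        # a single concentration compromises across the three components
        assert np.all(sd > 0.5 * printed_sd) and np.all(sd < 2.0 * printed_sd)

    def test_point_outside_range_rejected(self, ps):
        bad = update_path(ps, "costs.sr_additional", Param(11695.0, 12000.0, 13520.0))
        with pytest.raises(ValueError, match="sr_additional"):
            assign_distributions(bad)


class TestSampling:
    def test_same_seed_identical_parameter_set(self, assignment, ps):
        a, _ = sample_parameters(assignment, 123, ps)
        b, _ = sample_parameters(assignment, 123, ps)
        assert a.to_dict() == b.to_dict()

    def test_zero_variance_assignment_returns_points(self, assignment, ps):
        frozen = DistributionAssignment(
            assignment.range_mode,
            [FittedDistribution(e.path, "fixed", e.point, e.point, e.low, e.high)
             for e in assignment.entries],
        )
        out, rejected = sample_parameters(frozen, 5, ps)
        assert rejected == 0
        assert out.to_dict() == ps.to_dict()

    def test_sampled_sets_are_valid(self, assignment, ps):
        rng = np.random.default_rng(7)
        for _ in range(50):
            psi, _ = sample_parameters(assignment, rng, ps)
            assert psi.check() == []
            assert math.isclose(float(psi.efficacy.dist_sr.points().sum()), 1.0,
                                abs_tol=1e-9)

    def test_empirical_means_match_points(self, assignment, ps):
        # direct draws from the fitted marginals, 2 MC standard errors
        n = 20000
        rng = np.random.default_rng(11)
        for path in ("costs.sr_additional", "utilities.u_disabling", "acute.p_ivt_sr"):
            e = assignment.by_path()[path]
            if e.family == "beta":
                draws = rng.beta(*e.shape, size=n)
            else:
                draws = rng.gamma(e.shape[0], e.shape[1], size=n)
            mcse = draws.std() / math.sqrt(n)
            assert abs(draws.mean() - e.point[0]) < 2.5 * mcse


@pytest.fixture(scope="module")
def small_run(ps):
    return run_psa(ps, 200, seed=42)


class TestRunPSA:
    def test_seed_reproducibility_bit_identical(self, ps, small_run):
        again = run_psa(ps, 200, seed=42)
        assert np.array_equal(small_run.d_cost, again.d_cost)
        assert np.array_equal(small_run.d_qaly, again.d_qaly)
        assert small_run.sampled.equals(again.sampled)

    def test_record_count_and_provenance(self, small_run):
        assert small_run.n_iter == 200
        assert len(small_run.d_cost) == 200
        assert small_run.seed == 42

    def test_ce_plane_upper_right_quadrant(self, small_run):
        frac_ne = np.mean((small_run.d_cost > 0) & (small_run.d_qaly > 0))
        assert frac_ne > 0.95

    def test_ceac_monotone_when_effect_positive(self, small_run):
        assert (small_run.d_qaly > 0).all()
        curve = ceac(small_run, np.arange(0, 50001, 1000))
        probs = [p for _, p in curve]
        assert all(b >= a for a, b in zip(probs, probs[1:]))

    def test_ceac_at_zero_wtp_counts_cost_saving(self, small_run):
        p0 = acceptance_probability(small_run, 0.0)
        assert math.isclose(p0, float(np.mean(small_run.d_cost < 0)), abs_tol=1e-12)
        assert p0 < 0.05

    def test_single_iteration_zero_variance_equals_base(self, ps):
        frozen = ps
        for path, p in ps.iter_params():
            frozen = update_path(frozen, path, Param.fixed(p.point))
        rs = run_psa(frozen, 1, seed=3)
        base = run_base_case(ps)
        assert math.isclose(rs.d_cost[0], base.incr_cost, rel_tol=1e-12)
        assert math.isclose(rs.d_qaly[0], base.incr_qaly, rel_tol=1e-12)

    def test_variance_shrinkage_converges_to_base_case(self, ps):
        base = run_base_case(ps)
        spreads = []
        for shrink in (1.0, 0.3, 0.05):
            shrunk = ps
            for path, p in ps.iter_params():
                if p.is_fixed:
                    continue
                shrunk = update_path(shrunk, path, Param(
                    p.point,
                    p.point - shrink * (p.point - p.low),
                    p.point + shrink * (p.high - p.point)))
            rs = run_psa(shrunk, 60, seed=9)
            spreads.append(float(np.hypot(
                (rs.d_cost - base.incr_cost).std(),
                ((rs.d_qaly - base.incr_qaly) * 10000).std())))
        assert spreads[0] > spreads[1] > spreads[2]
        assert abs(np.mean(run_psa(shrunk, 60, seed=9).d_qaly) - base.incr_qaly) < 0.01

    def test_crossing_bisection_matches_curve(self, small_run):
        w = ceac_crossing(small_run)
        assert acceptance_probability(small_run, w + 50) >= 0.5
        assert acceptance_probability(small_run, max(w - 50, 0.0)) <= 0.5

    def test_invalid_iteration_count(self, ps):
        with pytest.raises(ValueError):
            run_psa(ps, 0, seed=1)
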