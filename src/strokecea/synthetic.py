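"""Random but valid parameter sets, plus canonical degenerate fixtures.

The generator produces structurally valid inputs over a realistic dynamic
range — acute-stroke outcome triples, diagonally dominant quarterly
transition rows, age-increasing background mortality, USD-scale costs,
ordered utilities — without reproducing any particular published table, so
property tests of the engines stay independent of the shipped defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .parameters import (
    AcuteEventInputs,
    AnalysisSettings,
    CostInputs,
    EfficacyInputs,
    MortalityInputs,
    OutcomeDistribution,
    Param,
    ParameterSet,
    TransitionInputs,
    UtilityInputs,
    default_parameters,
    update_path,
)

__all__ = ["GeneratorConfig", "generate_parameter_set", "degenerate_fixtures"]


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    cost_low: float = 500.0
    cost_high: float = 20000.0
    range_width: float = 0.2  # half-width of generated ranges, relative to the point
    mortality_floor: float = 0.002  # annual probability in the youngest band
    horizon_years: float = 20.0

    def __post_init__(self):
        if not (0.0 < self.cost_low < self.cost_high):
            raise ValueError("need 0 < cost_low < cost_high")
        if not (0.0 <= self.range_width < 1.0):
            raise ValueError("range_width must be in [0, 1)")


def _ranged(rng: np.random.Generator, point: float, width: float,
            lo: float = 0.0, hi: float = np.inf) -> Param:
    half = width * point
    return Param(point, max(lo, point - half), min(hi, point + half))


def _triple(rng: np.random.Generator, width: float) -> OutcomeDistribution:
    p = rng.dirichlet((4.0, 3.0, 3.0))
    comps = []
    for x in p:
        half = width * x
        comps.append(Param(x, max(0.0, x - half), min(1.0, x + half)))
    return OutcomeDistribution(*comps)


def _stochastic_row(rng: np.random.Generator, alphas) -> np.ndarray:
    return rng.dirichlet(np.asarray(alphas, dtype=float))


def generate_parameter_set(gc: GeneratorConfig) -> ParameterSet:
    """A random parameter set that passes full validation."""
    rng = np.random.default_rng(gc.seed)
    w = gc.range_width

    efficacy = EfficacyInputs(
        dist_sr=_triple(rng, w),
        dist_bmm=_triple(rng, w),
        rr_mrs02=_ranged(rng, rng.uniform(1.2, 3.5), w),
        rr_mrs35=_ranged(rng, rng.uniform(0.4, 1.0), w),
        rr_mrs6=_ranged(rng, rng.uniform(0.4, 1.0), w),
    )
    acute = AcuteEventInputs(
        *(_ranged(rng, rng.uniform(0.01, 0.3), w, hi=1.0) for _ in range(4))
    )

    # diagonally dominant quarterly rows; recurrence-from-disabling cannot improve
    fy_nd = _stochastic_row(rng, (90, 3, 2, 2))
    fy_dis = _stochastic_row(rng, (3, 88, 2, 4))
    ay_nd = _stochastic_row(rng, (95, 1, 2, 2))
    ay_dis = _stochastic_row(rng, (1, 92, 2, 4))
    rec_nd = _stochastic_row(rng, (15, 3, 1))
    rec_dis = _stochastic_row(rng, (18, 1))
    transitions = TransitionInputs(
        first_year={
            "nondisabling": dict(zip(("nondisabling", "disabling", "recurrent", "dead"), fy_nd)),
            "disabling": dict(zip(("nondisabling", "disabling", "recurrent", "dead"), fy_dis)),
        },
        after_first_year={
            "nondisabling": dict(zip(("nondisabling", "disabling", "recurrent", "dead"), ay_nd)),
            "disabling": dict(zip(("nondisabling", "disabling", "recurrent", "dead"), ay_dis)),
        },
        recurrent_from_nondisabling=dict(zip(("nondisabling", "disabling", "dead"), rec_nd)),
        recurrent_from_disabling=dict(zip(("disabling", "dead"), rec_dis)),
    )

    growth = rng.uniform(1.5, 2.2)
    probs = np.minimum(gc.mortality_floor * growth ** np.arange(6), 0.95)
    probs = np.maximum.accumulate(probs + np.arange(6) * 1e-9)  # strictly increasing
    mortality = MortalityInputs(
        annual={60 + 5 * i: float(p) for i, p in enumerate(probs)},
        rr_nonstroke_disabled=_ranged(rng, rng.uniform(1.0, 2.5), w, lo=1.0),
    )

    def cost() -> Param:
        point = float(np.exp(rng.uniform(np.log(gc.cost_low), np.log(gc.cost_high))))
        return _ranged(rng, point, w)

    costs = CostInputs(*(cost() for _ in range(9)))

    u = np.sort(rng.uniform(0.05, 0.95, size=3))
    utilities = UtilityInputs(
        u_nondisabling=_ranged(rng, float(u[2]), w, hi=1.0),
        u_disabling=_ranged(rng, float(u[0]), w, hi=1.0),
        u_recurrent=_ranged(rng, float(u[1]), w, hi=1.0),
        u_dead=Param.fixed(0.0),
    )
    settings = AnalysisSettings(
        discount_rate_cost=Param(float(rng.uniform(0.0, 0.08)), 0.0, 0.08),
        discount_rate_utility=Param(float(rng.uniform(0.0, 0.08)), 0.0, 0.08),
        horizon_years=gc.horizon_years,
        cycle_years=0.25,
        start_age=float(rng.uniform(60.0, 80.0)),
        wtp_low=float(rng.uniform(5000, 20000)),
        wtp_high=float(rng.uniform(25000, 60000)),
    )
    ps = ParameterSet(efficacy, acute, transitions, mortality, costs, utilities, settings)
    violations = ps.check()
    if violations:  # pragma: no cover - generator guarantees validity
        raise AssertionError(f"generator produced invalid set: {violations}")
    return ps


def degenerate_fixtures() -> dict[str, ParameterSet]:
    """Canonical edge-case parameter sets for engine verification.

    Built by modifying the shipped defaults; some deliberately bypass the
    plausibility checks of file validation (e.g. all utilities equal to 1)
    to pin down exact engine identities.
    """
    base = default_parameters()
    fixtures: dict[str, ParameterSet] = {}

    dead = OutcomeDistribution.from_points((0.0, 0.0, 1.0))
    ps = update_path(base, "efficacy.dist_sr", dead)
    fixtures["all_dead_entry"] = update_path(ps, "efficacy.dist_bmm", dead)

    zero = Param.fixed(0.0)
    ps = update_path(base, "settings.discount_rate_cost", zero)
    fixtures["zero_discount"] = update_path(ps, "settings.discount_rate_utility", zero)

    one = Param.fixed(1.0)
    ps = base
    for name in ("u_nondisabling", "u_disabling", "u_recurrent"):
        ps = update_path(ps, f"utilities.{name}", one)
    fixtures["utilities_one"] = ps

    # background mortality negligible but still strictly increasing
    tiny = {60 + 5 * i: i * 1e-15 for i in range(6)}
    fixtures["zero_background_mortality"] = update_path(base, "mortality.annual", tiny)

    fixtures["zero_sr_cost"] = update_path(base, "costs.sr_additional", zero)

    ps = update_path(base, "costs.sr_additional", zero)
    ps = update_path(ps, "efficacy.dist_sr", base.efficacy.dist_bmm)
    ps = update_path(ps, "acute.p_ivt_sr", base.acute.p_ivt_bmm)
    fixtures["identical_arms"] = update_path(ps, "acute.p_sich_sr", base.acute.p_sich_bmm)

    # closed-form life-years: no death anywhere, no discounting
    alive = update_path(fixtures["zero_discount"], "mortality.annual", tiny)
    tr = alive.transitions
    def no_death(row, keys):
        row = {k: row.get(k, 0.0) for k in keys}
        mass = row.pop("dead")
        live_keys = [k for k in row]
        total = sum(row.values())
        return {**{k: row[k] + mass * row[k] / total for k in live_keys}, "dead": 0.0}
    keys4 = ("nondisabling", "disabling", "recurrent", "dead")
    new_tr = replace(
        tr,
        first_year={s: no_death(tr.first_year[s], keys4) for s in ("nondisabling", "disabling")},
        after_first_year={s: no_death(tr.after_first_year[s], keys4)
                          for s in ("nondisabling", "disabling")},
        recurrent_from_nondisabling=no_death(
            tr.recurrent_from_nondisabling, ("nondisabling", "disabling", "dead")),
        recurrent_from_disabling=no_death(tr.recurrent_from_disabling, ("disabling", "dead")),
    )
    fixtures["immortal_undiscounted"] = replace(alive, transitions=new_tr)
    return fixtures
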