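"""First-cycle (0-90 day) decision tree.

Both strategies are expanded as expected values over the trial's 90-day
outcome distribution, plus expected costs for the co-intervention (IVT),
the adverse event (sICH), and — for the thrombectomy arm — the additional
device/procedure cost. Event proportions enter as cost weights only: the
90-day outcome distributions already include every trial event, so pricing
sICH/IVT separately must not move outcome mass.

Timing convention: the tree occupies the model's first 0.25-year cycle at
t = 0, undiscounted. Patients dying within 90 days accrue the acute death
cost and zero QALY/LY for the whole cycle; survivors accrue the full
0.25-year state utility.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .parameters import OutcomeDistribution, Param, ParameterSet

__all__ = ["Arm", "DecisionTreeResult", "run_decision_tree", "apply_rr_to_distribution"]


class Arm(str, Enum):
    SR_PLUS_BMM = "SR+BMM"
    BMM_ALONE = "BMM"


@dataclass(frozen=True)
class DecisionTreeResult:
    arm: Arm
    cost_90d: float
    qaly_90d: float
    ly_90d: float
    exit_distribution: OutcomeDistribution


def run_decision_tree(arm: Arm, ps: ParameterSet) -> DecisionTreeResult:
    """Expected 90-day cost/QALY/LY for one strategy and the outcome
    distribution handed to the Markov model."""
    arm = Arm(arm)
    if arm is Arm.SR_PLUS_BMM:
        dist = ps.efficacy.dist_sr
        p_ivt = ps.acute.p_ivt_sr.point
        p_sich = ps.acute.p_sich_sr.point
        device_cost = ps.costs.sr_additional.point
    else:
        dist = ps.efficacy.dist_bmm
        p_ivt = ps.acute.p_ivt_bmm.point
        p_sich = ps.acute.p_sich_bmm.point
        device_cost = 0.0

    c = ps.costs
    cost = (
        device_cost
        + p_ivt * c.ivt_additional.point
        + p_sich * c.sich_event.point
        + dist.nondisabling.point * c.acute_bmm_nondisabling.point
        + dist.disabling.point * c.acute_bmm_disabling.point
        + dist.dead.point * c.acute_bmm_death.point
    )
    u = ps.utilities
    cycle = ps.settings.cycle_years
    qaly = cycle * (
        dist.nondisabling.point * u.u_nondisabling.point
        + dist.disabling.point * u.u_disabling.point
    )
    ly = cycle * (1.0 - dist.dead.point)
    return DecisionTreeResult(arm, cost, qaly, ly, dist)


def apply_rr_to_distribution(
    base: OutcomeDistribution, rr02: float, rr35: float, rr6: float
) -> OutcomeDistribution:
    """Derive an outcome triple by applying per-category relative risks to a
    base triple and renormalising (used when effectiveness comes from pooled
    trial relative risks instead of a single trial's distribution)."""
    if min(rr02, rr35, rr6) <= 0:
        raise ValueError("relative risks must be > 0")
    raw = (
        base.nondisabling.point * rr02,
        base.disabling.point * rr35,
        base.dead.point * rr6,
    )
    if max(raw) > 1.0 + 0.05:
        import warnings

        warnings.warn(
            f"RR x base produces component {max(raw):.3f} > 1 before "
            "renormalisation; implausible RR/base combination",
            stacklevel=2,
        )
    s = sum(raw)
    return OutcomeDistribution(
        Param.fixed(raw[0] / s), Param.fixed(raw[1] / s), Param.fixed(raw[2] / s)
    )
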