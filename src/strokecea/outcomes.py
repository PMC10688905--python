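"""Arm totals, incremental cost-effectiveness, and threshold classification."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .decision_tree import Arm, run_decision_tree
from .markov import run_markov
from .parameters import ParameterSet

__all__ = [
    "ArmResult",
    "CEAResult",
    "total_arm",
    "icer",
    "classify_ce",
    "net_monetary_benefit",
    "run_base_case",
    "results_table",
]


@dataclass(frozen=True)
class ArmResult:
    arm: Arm
    total_cost: float
    total_qaly: float
    total_ly: float


@dataclass(frozen=True)
class CEAResult:
    reference: ArmResult
    comparator: ArmResult
    incr_cost: float
    incr_qaly: float
    incr_ly: float
    icer_qaly: Optional[float]  # None when dominance applies
    icer_ly: Optional[float]
    classification: str


def total_arm(
    arm: Arm,
    ps: ParameterSet,
    background_mortality_mode: str = "compose",
    n_cycles: int | None = None,
    start_age: float | None = None,
    half_cycle_correction: bool = True,
) -> ArmResult:
    """Decision-tree plus Markov totals (discounted) for one strategy."""
    dt = run_decision_tree(arm, ps)
    if n_cycles is None:
        n_cycles = ps.settings.n_markov_cycles
    if n_cycles == 0:
        return ArmResult(Arm(arm), dt.cost_90d, dt.qaly_90d, dt.ly_90d)
    trace = run_markov(
        dt.exit_distribution, ps, n_cycles=n_cycles, start_age=start_age,
        background_mortality_mode=background_mortality_mode,
        half_cycle_correction=half_cycle_correction,
    )
    return ArmResult(
        Arm(arm),
        dt.cost_90d + trace.total_cost,
        dt.qaly_90d + trace.total_qaly,
        dt.ly_90d + trace.total_ly,
    )


def icer(reference: ArmResult, comparator: ArmResult,
         wtp_low: float = 12551.0, wtp_high: float = 37654.0) -> CEAResult:
    """Incremental results of ``comparator`` versus ``reference``.

    The ratio is only formed when both incremental cost and effect are
    positive; otherwise a dominance (or equivalence) flag replaces it.
    """
    d_cost = comparator.total_cost - reference.total_cost
    d_qaly = comparator.total_qaly - reference.total_qaly
    d_ly = comparator.total_ly - reference.total_ly

    icer_q = icer_l = None
    if d_cost == 0.0 and d_qaly == 0.0:
        cls = "equivalent"
    elif d_cost <= 0.0 and d_qaly >= 0.0:
        cls = "dominant"
    elif d_cost >= 0.0 and d_qaly <= 0.0:
        cls = "dominated"
    else:
        if d_qaly > 0 and d_cost > 0:
            icer_q = d_cost / d_qaly
            cls = classify_ce(icer_q, wtp_low, wtp_high)
        else:  # cheaper and worse: ratio is a savings-per-QALY-lost trade-off
            icer_q = d_cost / d_qaly
            cls = "cost_effective" if icer_q > wtp_high else "not_cost_effective"
        if d_ly != 0.0:
            icer_l = d_cost / d_ly
    return CEAResult(reference, comparator, d_cost, d_qaly, d_ly, icer_q, icer_l, cls)


def classify_ce(icer_qaly: float, wtp_low: float, wtp_high: float) -> str:
    """Classify an ICER against the 1x / 3x per-capita-GDP thresholds."""
    if icer_qaly < wtp_low:
        return "highly_cost_effective"
    if icer_qaly <= wtp_high:
        return "cost_effective"
    return "not_cost_effective"


def net_monetary_benefit(arm: ArmResult, wtp: float) -> float:
    """NMB = WTP x QALYs - cost; differences in NMB order strategies."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * arm.total_qaly - arm.total_cost


def run_base_case(
    ps: ParameterSet,
    background_mortality_mode: str = "compose",
    n_cycles: int | None = None,
    start_age: float | None = None,
    half_cycle_correction: bool = True,
) -> CEAResult:
    """Full pipeline: both arms, incremental results, classification."""
    bmm = total_arm(Arm.BMM_ALONE, ps, background_mortality_mode, n_cycles, start_age,
                    half_cycle_correction)
    sr = total_arm(Arm.SR_PLUS_BMM, ps, background_mortality_mode, n_cycles, start_age,
                   half_cycle_correction)
    return icer(bmm, sr, ps.settings.wtp_low, ps.settings.wtp_high)


def results_table(results: dict[str, CEAResult]) -> pd.DataFrame:
    """Arrange labelled CEA results as a report table (one row per arm,
    reference arm first, incremental columns on the comparator row)."""
    rows = []
    for label, res in results.items():
        rows.append({
            "analysis": label, "strategy": res.reference.arm.value,
            "total_cost": res.reference.total_cost,
            "incr_cost": None,
            "total_qaly": res.reference.total_qaly, "incr_qaly": None,
            "icer_qaly": None,
            "total_ly": res.reference.total_ly, "incr_ly": None, "icer_ly": None,
            "classification": None,
        })
        rows.append({
            "analysis": label, "strategy": res.comparator.arm.value,
            "total_cost": res.comparator.total_cost,
            "incr_cost": res.incr_cost,
            "total_qaly": res.comparator.total_qaly, "incr_qaly": res.incr_qaly,
            "icer_qaly": res.icer_qaly,
            "total_ly": res.comparator.total_ly, "incr_ly": res.incr_ly,
            "icer_ly": res.icer_ly,
            "classification": res.classification,
        })
    return pd.DataFrame(rows)
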