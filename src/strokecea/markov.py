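"""Markov cohort engine for the post-90-day period.

Five states: non-disabling, disabling, two one-cycle recurrent-stroke
tunnel states keyed by origin (a recurrence after a disabling stroke cannot
exit to the non-disabling state), and absorbing death. Quarterly cycles;
transition rows switch era after the first post-acute year; age-dependent
background mortality is layered on top of the stroke-specific death
probabilities as an independent competing risk.

The engine exposes three compositions of background and stroke mortality
(``background_mortality_mode``), because printed transition rows already
carry death mass and the interaction with a life table is a structural
choice:

* ``compose`` (default): multiplicative competing risks,
  p_die = 1 - (1 - p_row_death) * (1 - p_background);
* ``ignore``: life table not applied (row death only);
* ``replace_if_larger``: p_die = max(p_row_death, p_background).

Cycle k spans [0.25 k, 0.25 (k+1)) years from model start and is
discounted by (1 + r)^(-0.25 k). By default state membership is valued
with a half-cycle (trapezoid) correction — the mean of the cycle's start
and end occupancy — the standard correction for a discrete-time cohort
approximating continuous residence; ``half_cycle_correction=False`` values
membership at cycle start instead. The recurrent-stroke event cost is
always charged on cycle-start tunnel occupancy (entries into the tunnel),
since it prices an event rather than residence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .parameters import OutcomeDistribution, ParameterSet

__all__ = [
    "STATES",
    "CohortTrace",
    "apply_background_mortality",
    "build_transition_matrix",
    "run_markov",
    "accrue_cycle",
]

STATES = ("nondisabling", "disabling", "recurrent_nd", "recurrent_dis", "dead")
ND, DIS, REC_ND, REC_DIS, DEAD = range(5)

_MODES = ("compose", "ignore", "replace_if_larger")


def apply_background_mortality(
    row: np.ndarray, p_bg_cycle: float, rr: float = 1.0, mode: str = "compose"
) -> np.ndarray:
    """Composite a per-cycle background mortality probability into one
    5-entry transition row, removing the added death mass proportionally
    from the non-death entries."""
    if mode not in _MODES:
        raise ValueError(f"unknown background_mortality_mode {mode!r}")
    row = np.asarray(row, dtype=float)
    p_bg = min(1.0, p_bg_cycle * rr)
    if mode == "ignore" or p_bg == 0.0:
        return row.copy()
    p_row = row[DEAD]
    if mode == "compose":
        p_die = 1.0 - (1.0 - p_row) * (1.0 - p_bg)
    else:  # replace_if_larger
        p_die = max(p_row, p_bg)
    p_die = min(p_die, 1.0)
    out = row.copy()
    live = 1.0 - p_row
    if live > 0.0:
        out[:DEAD] *= (1.0 - p_die) / live
    out[DEAD] = p_die
    return out


def build_transition_matrix(
    era: str,
    age: float,
    ps: ParameterSet,
    background_mortality_mode: str = "compose",
) -> np.ndarray:
    """One-cycle row-stochastic matrix for a given era ('first_year' or
    'after_first_year') and cohort age. Recurrent-stroke mass from each
    living state is routed into the origin-matched tunnel state."""
    tr = ps.transitions
    if era not in ("first_year", "after_first_year"):
        raise ValueError(f"unknown era {era!r}")
    block = getattr(tr, era)

    m = np.zeros((5, 5))
    nd_row = block["nondisabling"]
    m[ND] = [nd_row["nondisabling"], nd_row["disabling"], nd_row["recurrent"], 0.0,
             nd_row["dead"]]
    dis_row = block["disabling"]
    m[DIS] = [dis_row["nondisabling"], dis_row["disabling"], 0.0, dis_row["recurrent"],
              dis_row["dead"]]
    rnd = tr.recurrent_from_nondisabling
    m[REC_ND] = [rnd["nondisabling"], rnd["disabling"], 0.0, 0.0, rnd["dead"]]
    rdis = tr.recurrent_from_disabling
    m[REC_DIS] = [rdis.get("nondisabling", 0.0), rdis["disabling"], 0.0, 0.0, rdis["dead"]]
    m[DEAD, DEAD] = 1.0

    p_bg = ps.mortality.cycle_probability(age, ps.settings.cycle_years)
    rr = ps.mortality.rr_nonstroke_disabled.point
    # excess non-stroke mortality applies to disabled occupants only
    rr_by_state = {ND: 1.0, DIS: rr, REC_ND: 1.0, REC_DIS: rr}
    for s, rr_s in rr_by_state.items():
        m[s] = apply_background_mortality(m[s], p_bg, rr_s, background_mortality_mode)
    return m


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle record of state occupancy and discounted accruals.

    ``occupancy[k]`` is the state vector at the start of cycle ``cycles[k]``;
    accrual increments value that membership for the whole cycle.
    """

    cycles: np.ndarray  # 1..n (cycle index from model start)
    ages: np.ndarray
    occupancy: np.ndarray  # (n, 5)
    cost_undiscounted: np.ndarray
    cost: np.ndarray  # discounted
    qaly: np.ndarray  # discounted
    ly: np.ndarray  # discounted

    @property
    def total_cost(self) -> float:
        return float(self.cost.sum())

    @property
    def total_qaly(self) -> float:
        return float(self.qaly.sum())

    @property
    def total_ly(self) -> float:
        return float(self.ly.sum())

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(STATES))
        df.insert(0, "cycle", self.cycles)
        df.insert(1, "age", self.ages)
        df["cost_undiscounted"] = self.cost_undiscounted
        df["cost_discounted"] = self.cost
        df["qaly_discounted"] = self.qaly
        df["ly_discounted"] = self.ly
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def accrue_cycle(
    sv: Sequence[float], ps: ParameterSet, t_years: float
) -> tuple[float, float, float]:
    """Discounted (cost, QALY, LY) increments for one cycle of occupancy.

    Chronic annual costs/utilities are scaled to the quarterly cycle; the
    recurrent-stroke event cost is charged per entry into a tunnel state
    (tunnel occupancy equals that cycle's entries), with tunnel occupants
    contributing the recurrent-state utility and no maintenance cost.
    """
    sv = np.asarray(sv, dtype=float)
    cyc = ps.settings.cycle_years
    c, u = ps.costs, ps.utilities
    rec = sv[REC_ND] + sv[REC_DIS]
    cost = (
        cyc * (sv[ND] * c.annual_nondisabling.point + sv[DIS] * c.annual_disabling.point)
        + rec * c.recurrent_event.point
    )
    qaly = cyc * (
        sv[ND] * u.u_nondisabling.point + sv[DIS] * u.u_disabling.point
        + rec * u.u_recurrent.point
    )
    ly = cyc * (1.0 - sv[DEAD])
    df_c = (1.0 + ps.settings.discount_rate_cost.point) ** (-t_years)
    df_u = (1.0 + ps.settings.discount_rate_utility.point) ** (-t_years)
    return cost * df_c, qaly * df_u, ly * df_u


def run_markov(
    entry: OutcomeDistribution | np.ndarray,
    ps: ParameterSet,
    n_cycles: int | None = None,
    start_age: float | None = None,
    background_mortality_mode: str = "compose",
    half_cycle_correction: bool = True,
) -> CohortTrace:
    """Propagate a cohort from the end of the decision tree to the horizon.

    ``entry`` is the 90-day outcome distribution (or a full 5-state vector);
    cycle k (k = 1..n) starts at t = 0.25 k years from model start at cohort
    age ``start_age + 0.25 k``. Cycles 1-3 use the first-year transition
    era, later cycles the after-first-year era.
    """
    settings = ps.settings
    if n_cycles is None:
        n_cycles = settings.n_markov_cycles
    if n_cycles < 0:
        raise ValueError("n_cycles must be >= 0")
    if start_age is None:
        start_age = settings.start_age
    cyc = settings.cycle_years

    if isinstance(entry, OutcomeDistribution):
        sv = np.array([entry.nondisabling.point, entry.disabling.point, 0.0, 0.0,
                       entry.dead.point])
    else:
        sv = np.asarray(entry, dtype=float).copy()
    if abs(sv.sum() - 1.0) > 1e-9 or (sv < -1e-12).any():
        raise ValueError("entry state vector must be a probability distribution")

    cycles = np.arange(1, n_cycles + 1)
    ages = start_age + cyc * cycles
    occ = np.empty((n_cycles + 1, 5))  # last row: occupancy after the final cycle

    # matrices repeat within (era, age band); cache them
    cache: dict[tuple[str, float], np.ndarray] = {}
    first_year_cycles = int(round(1.0 / cyc)) - 1  # cycles 1..3 on the quarterly grid
    for i, k in enumerate(cycles):
        occ[i] = sv
        era = "first_year" if k <= first_year_cycles else "after_first_year"
        age = ages[i]
        band = ps.mortality.annual_probability(age)
        key = (era, band)
        m = cache.get(key)
        if m is None:
            m = cache[key] = build_transition_matrix(era, age, ps, background_mortality_mode)
        sv = sv @ m
    occ[n_cycles] = sv

    entries = occ[:-1]  # cycle-start occupancy (= entries into tunnel states)
    state = 0.5 * (occ[:-1] + occ[1:]) if half_cycle_correction else entries

    # vectorised accrual: residence-based rewards on (possibly corrected)
    # membership, the recurrent event cost on tunnel entries
    c, u = ps.costs, ps.utilities
    rec_entries = entries[:, REC_ND] + entries[:, REC_DIS]
    rec_state = state[:, REC_ND] + state[:, REC_DIS]
    cost_u = (
        cyc * (state[:, ND] * c.annual_nondisabling.point
               + state[:, DIS] * c.annual_disabling.point)
        + rec_entries * c.recurrent_event.point
    )
    qaly_u = cyc * (
        state[:, ND] * u.u_nondisabling.point + state[:, DIS] * u.u_disabling.point
        + rec_state * u.u_recurrent.point
    )
    ly_u = cyc * (1.0 - state[:, DEAD])
    t = cyc * cycles
    df_c = (1.0 + settings.discount_rate_cost.point) ** (-t)
    df_u = (1.0 + settings.discount_rate_utility.point) ** (-t)
    return CohortTrace(
        cycles=cycles,
        ages=ages,
        occupancy=entries,
        cost_undiscounted=cost_u,
        cost=cost_u * df_c,
        qaly=qaly_u * df_u,
        ly=ly_u * df_u,
    )
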