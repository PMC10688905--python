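"""Deterministic sensitivity analyses: one-way (tornado), scenarios,
start-age subgroups, and the ICER-by-time-horizon sweep.

One-way analysis recomputes the full pipeline with one ranged input at its
low and then its high bound, all others at their point estimates. Inputs
come in three behaviours:

* plain scalars (costs, utilities, event proportions, discount rate) are
  simply replaced;
* a 90-day outcome-triple component is set to its bound and the remaining
  two components are rescaled proportionally so the triple still sums to 1;
* the pooled relative risks act through the thrombectomy-arm distribution:
  varying one RR rebuilds that arm's 90-day triple as RR x control-arm
  triple (renormalised), with the other two RRs at their point values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .decision_tree import apply_rr_to_distribution
from .outcomes import CEAResult, run_base_case
from .parameters import (
    OutcomeDistribution,
    Param,
    ParameterSet,
    set_point,
    update_path,
)

__all__ = [
    "TornadoEntry",
    "ScenarioSpec",
    "one_way_sensitivity",
    "run_scenario",
    "default_scenarios",
    "run_subgroup",
    "icer_by_horizon",
    "HorizonResult",
    "tornado_table",
]


def _raw_icer(res: CEAResult) -> float:
    if res.incr_qaly == 0.0:
        raise ZeroDivisionError("zero incremental QALYs; ICER undefined")
    return res.incr_cost / res.incr_qaly


def _vary_triple(dist: OutcomeDistribution, comp: str, value: float) -> OutcomeDistribution:
    """Set one component of an outcome triple to ``value`` and rescale the
    other two proportionally so the triple still sums to one."""
    comps = {c: getattr(dist, c).point for c in ("nondisabling", "disabling", "dead")}
    rest = 1.0 - comps[comp]
    if rest <= 0.0:
        raise ValueError(f"cannot rescale around degenerate component {comp}")
    scale = (1.0 - value) / rest
    out = {}
    for c, p in comps.items():
        out[c] = Param.fixed(value if c == comp else p * scale)
    return OutcomeDistribution(**out)


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low_input: float
    high_input: float
    icer_low: float  # ICER with the parameter at its low bound
    icer_high: float

    @property
    def span(self) -> float:
        return abs(self.icer_high - self.icer_low)


_TRIPLE_LABELS = {
    ("dist_sr", "nondisabling"): "SR: non-disabling stroke at day 90",
    ("dist_sr", "disabling"): "SR: disabling stroke at day 90",
    ("dist_sr", "dead"): "SR: death at day 90",
    ("dist_bmm", "nondisabling"): "BMM: non-disabling stroke at day 90",
    ("dist_bmm", "disabling"): "BMM: disabling stroke at day 90",
    ("dist_bmm", "dead"): "BMM: death at day 90",
}

_RR_LABELS = {
    "rr_mrs02": "RR of non-disabling stroke (mRS 0-2)",
    "rr_mrs35": "RR of disabling stroke (mRS 3-5)",
    "rr_mrs6": "RR of death (mRS 6)",
}


def one_way_sensitivity(
    ps: ParameterSet,
    background_mortality_mode: str = "compose",
    half_cycle_correction: bool = True,
) -> list[TornadoEntry]:
    """Tornado entries for every input with a printed range, sorted by
    descending ICER span. Fixed inputs (low == high) are skipped."""

    def icer_for(ps_mod: ParameterSet) -> float:
        return _raw_icer(run_base_case(
            ps_mod, background_mortality_mode,
            half_cycle_correction=half_cycle_correction))

    entries: list[TornadoEntry] = []

    # scalar parameters; the discount rate moves cost and utility rates together
    for path, p in ps.iter_params():
        if p.is_fixed or path.startswith("efficacy.dist") or path.startswith("efficacy.rr"):
            continue
        if path == "settings.discount_rate_utility":
            continue  # folded into the single discount-rate entry below
        if path == "settings.discount_rate_cost":
            def at(v):
                mod = set_point(ps, "settings.discount_rate_cost", v)
                return set_point(mod, "settings.discount_rate_utility", v)
            label = "Discount rate"
        else:
            def at(v, _path=path):
                return set_point(ps, _path, v)
            label = path
        entries.append(
            TornadoEntry(label, p.low, p.high, icer_for(at(p.low)), icer_for(at(p.high)))
        )

    # outcome-triple components with proportional renormalisation
    for dist_name in ("dist_sr", "dist_bmm"):
        dist: OutcomeDistribution = getattr(ps.efficacy, dist_name)
        for comp in ("nondisabling", "disabling", "dead"):
            p: Param = getattr(dist, comp)
            if p.is_fixed:
                continue
            def at(v, _d=dist, _c=comp, _n=dist_name):
                return update_path(ps, f"efficacy.{_n}", _vary_triple(_d, _c, v))
            entries.append(
                TornadoEntry(
                    _TRIPLE_LABELS[(dist_name, comp)], p.low, p.high,
                    icer_for(at(p.low)), icer_for(at(p.high)),
                )
            )

    # pooled relative risks act through the SR-arm distribution
    rr_points = {name: getattr(ps.efficacy, name).point
                 for name in ("rr_mrs02", "rr_mrs35", "rr_mrs6")}
    for name in ("rr_mrs02", "rr_mrs35", "rr_mrs6"):
        p: Param = getattr(ps.efficacy, name)
        if p.is_fixed:
            continue
        def at(v, _name=name):
            rrs = dict(rr_points)
            rrs[_name] = v
            dist = apply_rr_to_distribution(
                ps.efficacy.dist_bmm, rrs["rr_mrs02"], rrs["rr_mrs35"], rrs["rr_mrs6"]
            )
            return update_path(ps, "efficacy.dist_sr", dist)
        entries.append(
            TornadoEntry(_RR_LABELS[name], p.low, p.high,
                         icer_for(at(p.low)), icer_for(at(p.high)))
        )

    entries.sort(key=lambda e: e.span, reverse=True)
    return entries


def tornado_table(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "low_input": e.low_input,
                "high_input": e.high_input,
                "icer_at_low": e.icer_low,
                "icer_at_high": e.icer_high,
                "span": e.span,
            }
            for e in entries
        ]
    )


@dataclass(frozen=True)
class ScenarioSpec:
    """A named set of overrides on the base-case parameter set.

    ``scale`` multiplies a Param (point and range) by a factor;
    ``set_points`` replaces a Param's point estimate;
    ``sr_dist_from_rr`` replaces the thrombectomy arm's 90-day distribution
    with RR x control-arm distribution (pooled-efficacy scenario).
    """

    name: str
    scale: Mapping[str, float] = field(default_factory=dict)
    set_points: Mapping[str, float] = field(default_factory=dict)
    sr_dist_from_rr: bool = False

    def apply(self, ps: ParameterSet) -> ParameterSet:
        out = ps
        for path, factor in self.scale.items():
            p = _get_param(out, path)
            out = update_path(out, path, Param(p.point * factor, p.low * factor, p.high * factor))
        for path, value in self.set_points.items():
            out = set_point(out, path, value)
        if self.sr_dist_from_rr:
            eff = out.efficacy
            dist = apply_rr_to_distribution(
                eff.dist_bmm, eff.rr_mrs02.point, eff.rr_mrs35.point, eff.rr_mrs6.point
            )
            out = update_path(out, "efficacy.dist_sr", dist)
        return out


def _get_param(ps: ParameterSet, path: str) -> Param:
    obj = ps
    for part in path.split("."):
        try:
            obj = obj[part] if isinstance(obj, Mapping) else getattr(obj, part)
        except AttributeError:
            raise KeyError(f"unknown parameter {path!r}") from None
    if not isinstance(obj, Param):
        raise KeyError(f"{path} does not name a scalar parameter")
    return obj


def default_scenarios() -> list[ScenarioSpec]:
    """The four published alternative scenarios."""
    return [
        ScenarioSpec("Scenario 1: SR cost reduced by 50%",
                     scale={"costs.sr_additional": 0.5}),
        ScenarioSpec("Scenario 2: SR cost increased by 50%",
                     scale={"costs.sr_additional": 1.5}),
        ScenarioSpec("Scenario 3: utility not discounted",
                     set_points={"settings.discount_rate_utility": 0.0}),
        ScenarioSpec("Scenario 4: efficacy from pooled relative risks",
                     sr_dist_from_rr=True),
    ]


def run_scenario(
    spec: ScenarioSpec,
    ps: ParameterSet,
    background_mortality_mode: str = "compose",
    half_cycle_correction: bool = True,
) -> CEAResult:
    return run_base_case(spec.apply(ps), background_mortality_mode,
                         half_cycle_correction=half_cycle_correction)


def run_subgroup(
    start_age: float,
    ps: ParameterSet,
    overrides: ScenarioSpec | None = None,
    background_mortality_mode: str = "compose",
    half_cycle_correction: bool = True,
) -> CEAResult:
    """Rerun the pipeline for a cohort entering at a different age; the
    background-mortality age-band lookup shifts accordingly."""
    if overrides is not None:
        ps = overrides.apply(ps)
    return run_base_case(ps, background_mortality_mode, start_age=start_age,
                         half_cycle_correction=half_cycle_correction)


@dataclass(frozen=True)
class HorizonResult:
    horizons: list[float]
    icers: list[float]
    first_cost_effective: float | None  # smallest horizon with ICER <= wtp_high
    first_highly_cost_effective: float | None  # ... <= wtp_low

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"horizon_years": self.horizons, "icer_qaly": self.icers})


def icer_by_horizon(
    ps: ParameterSet,
    horizons: Sequence[float],
    background_mortality_mode: str = "compose",
    half_cycle_correction: bool = True,
) -> HorizonResult:
    """ICER of the truncated model at each time horizon (multiples of the
    cycle length; the first cycle is the decision tree)."""
    cyc = ps.settings.cycle_years
    icers = []
    for h in horizons:
        n_total = h / cyc
        if abs(n_total - round(n_total)) > 1e-9 or h < cyc:
            raise ValueError(f"horizon {h} is not a multiple of the cycle length >= {cyc}")
        n_cycles = int(round(n_total)) - 1
        res = run_base_case(ps, background_mortality_mode, n_cycles=n_cycles,
                            half_cycle_correction=half_cycle_correction)
        icers.append(_raw_icer(res))
    first_ce = next(
        (h for h, i in zip(horizons, icers) if i <= ps.settings.wtp_high), None)
    first_hce = next(
        (h for h, i in zip(horizons, icers) if i <= ps.settings.wtp_low), None)
    return HorizonResult(list(horizons), icers, first_ce, first_hce)
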