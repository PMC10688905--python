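"""Model inputs: typed parameter blocks, validation, persistence, conversions.

The model is driven by a single structured parameter file holding every
clinical, cost, utility and analysis input with a point estimate and an
uncertainty range (``low == high == point`` marks a parameter that is held
fixed in sensitivity analyses; the shipped default file prints those as a
degenerate range).

Probability inputs come in three shapes:

* scalar probabilities (IVT / sICH proportions) and utilities, each a
  :class:`Param` constrained to [0, 1];
* 90-day outcome triples over {non-disabling, disabling, dead}
  (:class:`OutcomeDistribution`), renormalised at construction when the
  printed points sum to within 1% of one;
* long-term quarterly transition rows, stored as plain mappings whose rows
  must sum to one.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, fields, is_dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Any, Iterator, Mapping

import numpy as np
import yaml

__all__ = [
    "Param",
    "OutcomeDistribution",
    "EfficacyInputs",
    "AcuteEventInputs",
    "TransitionInputs",
    "MortalityInputs",
    "CostInputs",
    "UtilityInputs",
    "AnalysisSettings",
    "ParameterSet",
    "ParameterValidationError",
    "validate_parameters",
    "default_parameters",
    "read_parameters",
    "write_parameters",
    "rate_to_probability",
    "annual_prob_to_cycle_prob",
    "update_path",
    "set_point",
]

SUM_TOL = 1e-9
RENORM_BAND = (0.99, 1.01)


class ParameterValidationError(ValueError):
    """Raised when a raw parameter mapping violates the model's invariants.

    Carries the full list of violations so a hand-edited file can be fixed
    in one pass.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__(
            "invalid parameter set:\n" + "\n".join(f"  - {v}" for v in violations)
        )


@dataclass(frozen=True)
class Param:
    """A scalar input with point estimate and (low, high) uncertainty range."""

    point: float
    low: float
    high: float

    @property
    def is_fixed(self) -> bool:
        """True when no range is available; such inputs stay fixed in SA/PSA."""
        return self.low == self.high

    @staticmethod
    def fixed(value: float) -> "Param":
        return Param(value, value, value)

    def check(self, name: str, lo: float = -math.inf, hi: float = math.inf) -> list[str]:
        out = []
        if not (self.low <= self.point <= self.high):
            out.append(f"{name}: point {self.point} outside range [{self.low}, {self.high}]")
        for label, v in (("point", self.point), ("low", self.low), ("high", self.high)):
            if not (lo <= v <= hi):
                out.append(f"{name}.{label} = {v} outside allowed [{lo}, {hi}]")
        return out


def _param_from(raw: Any, name: str, errs: list[str]) -> Param:
    if isinstance(raw, (int, float)):
        return Param.fixed(float(raw))
    if isinstance(raw, Mapping):
        try:
            point = float(raw["point"])
        except (KeyError, TypeError, ValueError):
            errs.append(f"{name}: missing or non-numeric 'point'")
            return Param.fixed(0.0)
        low = float(raw.get("low", point))
        high = float(raw.get("high", point))
        return Param(point, low, high)
    errs.append(f"{name}: expected number or mapping with point/low/high, got {type(raw).__name__}")
    return Param.fixed(0.0)


@dataclass(frozen=True)
class OutcomeDistribution:
    """90-day functional-outcome triple: P(mRS 0-2), P(mRS 3-5), P(mRS 6).

    Construction renormalises the points (and scales the ranges by the same
    factor) when the raw sum lies within [0.99, 1.01] — printed tables round
    components independently — and rejects anything further from one.
    """

    nondisabling: Param
    disabling: Param
    dead: Param

    def __post_init__(self):
        s = self.nondisabling.point + self.disabling.point + self.dead.point
        if not (RENORM_BAND[0] <= s <= RENORM_BAND[1]):
            raise ValueError(f"outcome triple sums to {s}, outside {RENORM_BAND}")
        if abs(s - 1.0) > SUM_TOL:
            for name in ("nondisabling", "disabling", "dead"):
                p: Param = getattr(self, name)
                object.__setattr__(
                    self, name, Param(p.point / s, p.low / s, p.high / s)
                )

    def points(self) -> np.ndarray:
        return np.array([self.nondisabling.point, self.disabling.point, self.dead.point])

    @staticmethod
    def from_points(p: "np.ndarray | tuple[float, float, float]") -> "OutcomeDistribution":
        a, b, c = (float(x) for x in p)
        return OutcomeDistribution(Param.fixed(a), Param.fixed(b), Param.fixed(c))

    def check(self, name: str) -> list[str]:
        errs = []
        for comp in ("nondisabling", "disabling", "dead"):
            errs += getattr(self, comp).check(f"{name}.{comp}", 0.0, 1.0)
        return errs


def _dist_from(raw: Any, name: str, errs: list[str]) -> OutcomeDistribution:
    if not isinstance(raw, Mapping):
        errs.append(f"{name}: expected mapping with nondisabling/disabling/dead")
        return OutcomeDistribution.from_points((1 / 3, 1 / 3, 1 / 3))
    comps = {}
    for comp in ("nondisabling", "disabling", "dead"):
        if comp not in raw:
            errs.append(f"{name}.{comp}: missing")
            comps[comp] = Param.fixed(1 / 3)
        else:
            comps[comp] = _param_from(raw[comp], f"{name}.{comp}", errs)
    try:
        return OutcomeDistribution(**comps)
    except ValueError as e:
        errs.append(f"{name}: {e}")
        return OutcomeDistribution.from_points((1 / 3, 1 / 3, 1 / 3))


@dataclass(frozen=True)
class EfficacyInputs:
    dist_sr: OutcomeDistribution
    dist_bmm: OutcomeDistribution
    rr_mrs02: Param
    rr_mrs35: Param
    rr_mrs6: Param

    def check(self) -> list[str]:
        errs = self.dist_sr.check("efficacy.dist_sr") + self.dist_bmm.check("efficacy.dist_bmm")
        for name in ("rr_mrs02", "rr_mrs35", "rr_mrs6"):
            p: Param = getattr(self, name)
            errs += p.check(f"efficacy.{name}")
            if p.low <= 0:
                errs.append(f"efficacy.{name}: relative risks must be > 0")
        return errs


@dataclass(frozen=True)
class AcuteEventInputs:
    p_ivt_sr: Param
    p_ivt_bmm: Param
    p_sich_sr: Param
    p_sich_bmm: Param

    def check(self) -> list[str]:
        errs = []
        for f in fields(self):
            errs += getattr(self, f.name).check(f"acute.{f.name}", 0.0, 1.0)
        return errs


# transition rows are mappings destination -> quarterly probability
Row = Mapping[str, float]


@dataclass(frozen=True)
class TransitionInputs:
    """Quarterly transition probabilities for the two post-acute eras plus
    the one-cycle recurrent-stroke tunnel exits, keyed by origin state."""

    first_year: Mapping[str, Row]
    after_first_year: Mapping[str, Row]
    recurrent_from_nondisabling: Row
    recurrent_from_disabling: Row

    def check(self) -> list[str]:
        errs = []
        for era in ("first_year", "after_first_year"):
            block = getattr(self, era)
            for src in ("nondisabling", "disabling"):
                row = block.get(src) if isinstance(block, Mapping) else None
                if row is None:
                    errs.append(f"transitions.{era}.{src}: missing")
                    continue
                errs += _check_row(f"transitions.{era}.{src}", row,
                                   ("nondisabling", "disabling", "recurrent", "dead"))
        errs += _check_row("transitions.recurrent_from_nondisabling",
                           self.recurrent_from_nondisabling,
                           ("nondisabling", "disabling", "dead"))
        errs += _check_row("transitions.recurrent_from_disabling",
                           self.recurrent_from_disabling, ("disabling", "dead"))
        # recurrence after a disabling stroke cannot improve the functional state
        if self.recurrent_from_disabling.get("nondisabling", 0.0) != 0.0:
            errs.append("transitions.recurrent_from_disabling: exit to nondisabling must be 0")
        return errs


def _check_row(name: str, row: Row, keys: tuple[str, ...]) -> list[str]:
    errs = []
    unknown = set(row) - set(keys)
    if unknown:
        errs.append(f"{name}: unknown destinations {sorted(unknown)}")
    vals = [float(row.get(k, 0.0)) for k in keys]
    if any(not (0.0 <= v <= 1.0) for v in vals):
        errs.append(f"{name}: entries outside [0, 1]: {vals}")
    s = sum(vals)
    if abs(s - 1.0) > SUM_TOL:
        errs.append(f"{name}: row sums to {s!r}, not 1")
    return errs


@dataclass(frozen=True)
class MortalityInputs:
    """Annual all-cause background mortality by 5-year age band (band lower
    edges as keys; the last band is open-ended) and the relative risk of
    non-stroke death while disabled (mRS 3-5)."""

    annual: Mapping[int, float]
    rr_nonstroke_disabled: Param

    def band_edges(self) -> list[int]:
        return sorted(int(k) for k in self.annual)

    def annual_probability(self, age: float) -> float:
        """Annual background mortality for a cohort aged ``age`` years."""
        edges = self.band_edges()
        if age < edges[0]:
            raise ValueError(f"age {age} below first mortality band ({edges[0]})")
        band = max(e for e in edges if e <= age)
        return float(self.annual[band])

    def cycle_probability(self, age: float, cycle_years: float) -> float:
        return annual_prob_to_cycle_prob(self.annual_probability(age), cycle_years)

    def check(self) -> list[str]:
        errs = []
        edges = self.band_edges()
        probs = [float(self.annual[e]) for e in edges]
        if any(not (0.0 <= p < 1.0) for p in probs):
            errs.append(f"mortality.annual: probabilities outside [0, 1): {probs}")
        if any(b <= a for a, b in zip(probs, probs[1:])):
            errs.append("mortality.annual: probabilities must increase strictly with age")
        errs += self.rr_nonstroke_disabled.check("mortality.rr_nonstroke_disabled")
        if self.rr_nonstroke_disabled.low < 1.0:
            errs.append("mortality.rr_nonstroke_disabled: RR must be >= 1")
        return errs


@dataclass(frozen=True)
class CostInputs:
    """Direct medical costs, 2021 USD."""

    sr_additional: Param
    ivt_additional: Param
    annual_nondisabling: Param
    annual_disabling: Param
    acute_bmm_nondisabling: Param
    acute_bmm_disabling: Param
    acute_bmm_death: Param
    recurrent_event: Param
    sich_event: Param

    def check(self) -> list[str]:
        errs = []
        for f in fields(self):
            errs += getattr(self, f.name).check(f"costs.{f.name}", 0.0)
        return errs


@dataclass(frozen=True)
class UtilityInputs:
    """Annual health-state utility weights (EQ-5D, Chinese value set)."""

    u_nondisabling: Param
    u_disabling: Param
    u_recurrent: Param
    u_dead: Param

    def check(self) -> list[str]:
        errs = []
        for f in fields(self):
            errs += getattr(self, f.name).check(f"utilities.{f.name}", 0.0, 1.0)
        if self.u_dead.point != 0.0 or not self.u_dead.is_fixed:
            errs.append("utilities.u_dead: must be fixed at 0")
        if not (self.u_nondisabling.point > self.u_recurrent.point > self.u_disabling.point):
            errs.append("utilities: expected ordering u_nondisabling > u_recurrent > u_disabling")
        return errs


@dataclass(frozen=True)
class AnalysisSettings:
    discount_rate_cost: Param
    discount_rate_utility: Param
    horizon_years: float = 20.0
    cycle_years: float = 0.25
    start_age: float = 64.0
    wtp_low: float = 12551.0
    wtp_high: float = 37654.0

    @property
    def n_markov_cycles(self) -> int:
        """Cycles after the decision tree: the first cycle (0-90 d) belongs
        to the tree, the Markov chain runs the remainder of the horizon."""
        total = self.horizon_years / self.cycle_years
        return int(round(total)) - 1

    def check(self) -> list[str]:
        errs = []
        for name in ("discount_rate_cost", "discount_rate_utility"):
            errs += getattr(self, name).check(f"settings.{name}", 0.0, 1.0)
        total = self.horizon_years / self.cycle_years
        if abs(total - round(total)) > 1e-9 or round(total) < 1:
            errs.append(
                f"settings: horizon_years {self.horizon_years} is not a positive "
                f"multiple of cycle_years {self.cycle_years}"
            )
        if self.wtp_low < 0 or self.wtp_high < self.wtp_low:
            errs.append("settings: require 0 <= wtp_low <= wtp_high")
        return errs


@dataclass(frozen=True)
class ParameterSet:
    efficacy: EfficacyInputs
    acute: AcuteEventInputs
    transitions: TransitionInputs
    mortality: MortalityInputs
    costs: CostInputs
    utilities: UtilityInputs
    settings: AnalysisSettings

    def check(self) -> list[str]:
        return (
            self.efficacy.check() + self.acute.check() + self.transitions.check()
            + self.mortality.check() + self.costs.check() + self.utilities.check()
            + self.settings.check()
        )

    def to_dict(self) -> dict:
        return _to_plain(self)

    def iter_params(self) -> Iterator[tuple[str, Param]]:
        """Yield (dotted path, Param) for every scalar ranged-or-fixed input."""
        for block in ("acute", "costs", "utilities"):
            obj = getattr(self, block)
            for f in fields(obj):
                yield f"{block}.{f.name}", getattr(obj, f.name)
        for name in ("rr_mrs02", "rr_mrs35", "rr_mrs6"):
            yield f"efficacy.{name}", getattr(self.efficacy, name)
        for dist in ("dist_sr", "dist_bmm"):
            d = getattr(self.efficacy, dist)
            for comp in ("nondisabling", "disabling", "dead"):
                yield f"efficacy.{dist}.{comp}", getattr(d, comp)
        yield "mortality.rr_nonstroke_disabled", self.mortality.rr_nonstroke_disabled
        yield "settings.discount_rate_cost", self.settings.discount_rate_cost
        yield "settings.discount_rate_utility", self.settings.discount_rate_utility


_KNOWN_TOP = ("efficacy", "acute", "transitions", "mortality", "costs", "utilities", "settings")


def validate_parameters(raw: Mapping) -> ParameterSet:
    """Build a validated :class:`ParameterSet` from a parsed mapping.

    Raises :class:`ParameterValidationError` listing *all* violations.
    Unknown keys produce a warning (they are ignored), so files can carry
    provenance notes alongside the data.
    """
    errs: list[str] = []
    unknown = [k for k in raw if k not in _KNOWN_TOP and not k.startswith("_")]
    if unknown:
        warnings.warn(f"ignoring unknown parameter-file keys: {sorted(unknown)}", stacklevel=2)

    def block(name: str) -> Mapping:
        b = raw.get(name)
        if not isinstance(b, Mapping):
            errs.append(f"{name}: missing or not a mapping")
            return {}
        return b

    eff = block("efficacy")
    efficacy = EfficacyInputs(
        dist_sr=_dist_from(eff.get("dist_sr"), "efficacy.dist_sr", errs),
        dist_bmm=_dist_from(eff.get("dist_bmm"), "efficacy.dist_bmm", errs),
        rr_mrs02=_param_from(eff.get("rr_mrs02", 1.0), "efficacy.rr_mrs02", errs),
        rr_mrs35=_param_from(eff.get("rr_mrs35", 1.0), "efficacy.rr_mrs35", errs),
        rr_mrs6=_param_from(eff.get("rr_mrs6", 1.0), "efficacy.rr_mrs6", errs),
    )
    ac = block("acute")
    acute = AcuteEventInputs(
        **{f.name: _param_from(ac.get(f.name, 0.0), f"acute.{f.name}", errs)
           for f in fields(AcuteEventInputs)}
    )
    tr = block("transitions")
    transitions = TransitionInputs(
        first_year={k: dict(v) for k, v in (tr.get("first_year") or {}).items()},
        after_first_year={k: dict(v) for k, v in (tr.get("after_first_year") or {}).items()},
        recurrent_from_nondisabling=dict(tr.get("recurrent_from_nondisabling") or {}),
        recurrent_from_disabling=dict(tr.get("recurrent_from_disabling") or {}),
    )
    mo = block("mortality")
    annual_raw = mo.get("annual") or {}
    try:
        annual = {int(k): float(v) for k, v in annual_raw.items()}
    except (TypeError, ValueError):
        errs.append("mortality.annual: keys must be integer band edges, values numeric")
        annual = {60: 0.01}
    if not annual:
        errs.append("mortality.annual: missing")
        annual = {60: 0.01}
    mortality = MortalityInputs(
        annual=annual,
        rr_nonstroke_disabled=_param_from(
            mo.get("rr_nonstroke_disabled", 1.0), "mortality.rr_nonstroke_disabled", errs),
    )
    co = block("costs")
    costs = CostInputs(
        **{f.name: _param_from(co.get(f.name, 0.0), f"costs.{f.name}", errs)
           for f in fields(CostInputs)}
    )
    ut = block("utilities")
    utilities = UtilityInputs(
        **{f.name: _param_from(ut.get(f.name, 0.0), f"utilities.{f.name}", errs)
           for f in fields(UtilityInputs)}
    )
    se = block("settings")
    settings = AnalysisSettings(
        discount_rate_cost=_param_from(se.get("discount_rate_cost", 0.05),
                                       "settings.discount_rate_cost", errs),
        discount_rate_utility=_param_from(se.get("discount_rate_utility", 0.05),
                                          "settings.discount_rate_utility", errs),
        horizon_years=float(se.get("horizon_years", 20)),
        cycle_years=float(se.get("cycle_years", 0.25)),
        start_age=float(se.get("start_age", 64)),
        wtp_low=float(se.get("wtp_low", 12551)),
        wtp_high=float(se.get("wtp_high", 37654)),
    )
    ps = ParameterSet(efficacy, acute, transitions, mortality, costs, utilities, settings)
    errs += ps.check()
    if errs:
        raise ParameterValidationError(errs)
    return ps


def default_parameters() -> ParameterSet:
    """The shipped default inputs (trial outcomes, Chinese costs/utilities)."""
    with resources.files("strokecea.data").joinpath("baoche_2021_usd.json").open() as fh:
        return validate_parameters(json.load(fh))


def read_parameters(path: str | Path) -> ParameterSet:
    """Read and validate a JSON (.json) or YAML (.yml/.yaml) parameter file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yml", ".yaml"):
        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    if not isinstance(raw, Mapping):
        raise ParameterValidationError([f"{path}: top level must be a mapping"])
    return validate_parameters(raw)


def write_parameters(ps: ParameterSet, path: str | Path) -> None:
    """Write a parameter set; format chosen from the file extension."""
    path = Path(path)
    data = ps.to_dict()
    if path.suffix.lower() in (".yml", ".yaml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2) + "\n")


def _to_plain(obj: Any) -> Any:
    if isinstance(obj, Param):
        return {"point": obj.point, "low": obj.low, "high": obj.high}
    if is_dataclass(obj):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, Mapping):
        return {str(k): _to_plain(v) for k, v in obj.items()}
    return obj


# ---------------------------------------------------------------------------
# conversions

def rate_to_probability(rate: float) -> float:
    """Convert a per-period incidence rate to a probability: 1 - exp(-rate)."""
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    return 1.0 - math.exp(-rate)


def annual_prob_to_cycle_prob(p_annual: float, cycle_years: float) -> float:
    """Compound an annual probability down to a shorter cycle:
    1 - (1 - p)^cycle_years."""
    if not (0.0 <= p_annual <= 1.0):
        raise ValueError(f"annual probability must be in [0, 1], got {p_annual}")
    if cycle_years <= 0:
        raise ValueError("cycle_years must be positive")
    return 1.0 - (1.0 - p_annual) ** cycle_years


# ---------------------------------------------------------------------------
# functional updates (used by scenario / tornado / PSA machinery)

def update_path(obj, path: str, value):
    """Return a copy of a (possibly nested) frozen dataclass with the value
    at dotted ``path`` replaced. Mappings along the path are shallow-copied."""
    return _update(obj, path.split("."), value)


def _update(obj, parts: list[str], value):
    if not parts:
        return value
    head, rest = parts[0], parts[1:]
    if is_dataclass(obj):
        if not any(f.name == head for f in fields(obj)):
            raise KeyError(f"unknown parameter field {head!r} on {type(obj).__name__}")
        return replace(obj, **{head: _update(getattr(obj, head), rest, value)})
    if isinstance(obj, Mapping):
        if head not in obj:
            raise KeyError(f"unknown key {head!r}")
        new = dict(obj)
        new[head] = _update(obj[head], rest, value)
        return new
    raise KeyError(f"cannot descend into {type(obj).__name__} at {head!r}")


def set_point(ps: ParameterSet, path: str, point: float) -> ParameterSet:
    """Replace the point estimate of the :class:`Param` at ``path``, widening
    the range if the new point falls outside it."""
    cur = _get(ps, path)
    if not isinstance(cur, Param):
        raise TypeError(f"{path} is not a scalar Param")
    return update_path(ps, path, Param(point, min(cur.low, point), max(cur.high, point)))


def _get(obj, path: str):
    for part in path.split("."):
        obj = obj[part] if isinstance(obj, Mapping) else getattr(obj, part)
    return obj
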