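"""Probabilistic sensitivity analysis.

Parameter uncertainty is propagated by Monte Carlo: each ranged input is
assigned a standard second-order distribution — beta for probabilities and
utilities, gamma for costs and relative risks, Dirichlet for the 90-day
outcome triples (drawn jointly so they sum to one by construction) — fitted
by moment matching so the mean equals the point estimate and the printed
range maps to the distribution's central 95% interval (``range_mode="ci95"``,
the default) or to a uniform-width support with clipping
(``range_mode="minmax"``). Inputs without a printed range stay fixed, as do
the long-term transition rows. Blocks are sampled independently.

Each iteration runs the full decision-tree + Markov pipeline and records the
incremental cost and effect; acceptability at a willingness-to-pay threshold
is the fraction of iterations with positive incremental net monetary
benefit, which handles non-positive incremental effects without division.

By default the PSA samples the second-order uncertain inputs — costs,
utilities, acute event proportions, and the non-stroke-mortality relative
risk — while the trial's 90-day efficacy distributions and the analysis
discount rates stay at their point estimates (they are explored in the
scenario and one-way analyses instead, and the published acceptability
statistics correspond to this configuration). ``sample_efficacy_distributions``
and ``sample_discount_rates`` switch on the fully probabilistic variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .outcomes import run_base_case
from .parameters import (
    OutcomeDistribution,
    Param,
    ParameterSet,
    update_path,
)

__all__ = [
    "FittedDistribution",
    "DistributionAssignment",
    "PSAResultSet",
    "assign_distributions",
    "sample_parameters",
    "run_psa",
    "ceac",
    "ceac_crossing",
    "acceptance_probability",
]

_Z95 = 1.959963984540054  # central 95% normal quantile


@dataclass(frozen=True)
class FittedDistribution:
    """One parameter's sampling distribution with fitting provenance."""

    path: str
    family: str  # beta | gamma | dirichlet | fixed
    shape: tuple[float, ...]  # (a, b) beta; (k, theta) gamma; alphas dirichlet
    point: tuple[float, ...]
    low: tuple[float, ...]
    high: tuple[float, ...]


@dataclass(frozen=True)
class DistributionAssignment:
    range_mode: str
    entries: list[FittedDistribution]

    def by_path(self) -> dict[str, FittedDistribution]:
        return {e.path: e for e in self.entries}


def _interval_sd(low: float, high: float, range_mode: str) -> float:
    if range_mode == "ci95":
        return (high - low) / (2.0 * _Z95)
    if range_mode == "minmax":
        return (high - low) / math.sqrt(12.0)  # uniform-equivalent spread
    raise ValueError(f"unknown range_mode {range_mode!r}")


def _fit_beta(p: Param, sd: float) -> tuple[float, float]:
    m, v = p.point, sd * sd
    cap = m * (1.0 - m)
    if v >= cap:  # spread wider than a beta supports at this mean
        v = 0.95 * cap
    k = cap / v - 1.0
    return m * k, (1.0 - m) * k


def _fit_gamma(p: Param, sd: float) -> tuple[float, float]:
    m, v = p.point, sd * sd
    return m * m / v, v / m  # shape, scale


def _fit_dirichlet(dist: OutcomeDistribution, range_mode: str) -> np.ndarray:
    """Concentration s minimising squared error between the Dirichlet
    marginal variances p_i(1-p_i)/(s+1) and the variances implied by the
    printed component ranges."""
    pts = dist.points()
    target_v = np.array([
        _interval_sd(getattr(dist, c).low, getattr(dist, c).high, range_mode) ** 2
        for c in ("nondisabling", "disabling", "dead")
    ])
    cap = pts * (1.0 - pts)

    def err(log_s: float) -> float:
        s = math.exp(log_s)
        return float(((cap / (s + 1.0) - target_v) ** 2).sum())

    res = optimize.minimize_scalar(err, bounds=(0.0, 20.0), method="bounded")
    s = math.exp(res.x)
    return s * pts


_BETA_PREFIXES = ("acute.", "utilities.", "settings.discount_rate")
_GAMMA_PREFIXES = ("costs.", "efficacy.rr_", "mortality.rr_")


def assign_distributions(ps: ParameterSet, range_mode: str = "ci95") -> DistributionAssignment:
    """Fit a sampling distribution to every input of the parameter set."""
    entries: list[FittedDistribution] = []
    for dist_name in ("dist_sr", "dist_bmm"):
        dist: OutcomeDistribution = getattr(ps.efficacy, dist_name)
        comps = [getattr(dist, c) for c in ("nondisabling", "disabling", "dead")]
        pts = tuple(c.point for c in comps)
        lows = tuple(c.low for c in comps)
        highs = tuple(c.high for c in comps)
        if all(c.is_fixed for c in comps):
            fam, shape = "fixed", pts
        else:
            fam, shape = "dirichlet", tuple(_fit_dirichlet(dist, range_mode))
        entries.append(FittedDistribution(
            f"efficacy.{dist_name}", fam, shape, pts, lows, highs))

    for path, p in ps.iter_params():
        if path.startswith("efficacy.dist_"):
            continue  # triple components are covered by the joint Dirichlet
        if p.point < 0:
            raise ValueError(f"{path}: cannot fit a sampling distribution to a negative point")
        if p.is_fixed or p.point == 0.0:
            entries.append(FittedDistribution(
                path, "fixed", (p.point,), (p.point,), (p.low,), (p.high,)))
            continue
        if not (p.low <= p.point <= p.high):
            raise ValueError(f"{path}: point outside printed range; cannot fit")
        sd = _interval_sd(p.low, p.high, range_mode)
        if path.startswith(_BETA_PREFIXES):
            a, b = _fit_beta(p, sd)
            fam, shape = "beta", (a, b)
        elif path.startswith(_GAMMA_PREFIXES):
            k, theta = _fit_gamma(p, sd)
            fam, shape = "gamma", (k, theta)
        else:
            raise ValueError(f"{path}: no distribution family rule")
        entries.append(FittedDistribution(path, fam, shape, (p.point,), (p.low,), (p.high,)))
    return DistributionAssignment(range_mode, entries)


def _draw(e: FittedDistribution, rng: np.random.Generator) -> np.ndarray:
    if e.family == "fixed":
        return np.asarray(e.point)
    if e.family == "beta":
        x = rng.beta(*e.shape)
    elif e.family == "gamma":
        x = rng.gamma(e.shape[0], e.shape[1])
    elif e.family == "dirichlet":
        return rng.dirichlet(np.asarray(e.shape))
    else:  # pragma: no cover
        raise ValueError(e.family)
    return np.asarray(x)


def sample_parameters(
    da: DistributionAssignment,
    rng: np.random.Generator | int,
    base: ParameterSet,
    max_rejects: int = 1000,
) -> tuple[ParameterSet, int]:
    """One random, *valid* parameter set (plus the number of whole-set
    rejections). Draws violating the parameter-model invariants — in
    practice a recurrent-stroke utility sampled outside the
    non-disabling/disabling ordering — are rejected and redrawn."""
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    for attempt in range(max_rejects + 1):
        ps = base
        for e in da.entries:
            if e.family == "fixed":
                continue
            x = _draw(e, rng)
            if da.range_mode == "minmax":
                x = np.clip(x, np.asarray(e.low), np.asarray(e.high))
            if e.family == "dirichlet":
                ps = update_path(ps, e.path, OutcomeDistribution.from_points(x))
            else:
                v = float(np.clip(x, 0.0, 1.0)) if e.family == "beta" else float(x)
                cur: Param = _get_param(ps, e.path)
                ps = update_path(
                    ps, e.path, Param(v, min(cur.low, v), max(cur.high, v)))
        if not ps.check():
            return ps, attempt
    raise RuntimeError(f"rejection sampling failed after {max_rejects} attempts")


def _get_param(ps: ParameterSet, path: str) -> Param:
    obj = ps
    for part in path.split("."):
        obj = getattr(obj, part)
    return obj


@dataclass(frozen=True)
class PSAResultSet:
    """Per-iteration incremental (cost, QALY) pairs with run provenance."""

    seed: int
    n_iter: int
    d_cost: np.ndarray
    d_qaly: np.ndarray
    n_rejected: int
    sampled: pd.DataFrame = field(repr=False)  # per-iteration sampled scalars

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "iteration": np.arange(self.n_iter),
            "incr_cost": self.d_cost,
            "incr_qaly": self.d_qaly,
        })


def run_psa(
    ps: ParameterSet,
    n_iter: int,
    seed: int,
    range_mode: str = "ci95",
    background_mortality_mode: str = "compose",
    half_cycle_correction: bool = True,
    sample_efficacy_distributions: bool = False,
    sample_discount_rates: bool = False,
) -> PSAResultSet:
    """Monte Carlo PSA: sample, run the full pipeline, record (dC, dE).

    Deterministic given ``seed``: the same seed yields a bit-identical
    result set.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    da = assign_distributions(ps, range_mode)
    skip = []
    if not sample_efficacy_distributions:
        skip.append("efficacy.dist_")
    if not sample_discount_rates:
        skip.append("settings.discount_rate")
    if skip:
        da = DistributionAssignment(da.range_mode, [
            e if not any(e.path.startswith(s) for s in skip)
            else FittedDistribution(e.path, "fixed", e.point, e.point, e.low, e.high)
            for e in da.entries
        ])
    rng = np.random.default_rng(seed)
    d_cost = np.empty(n_iter)
    d_qaly = np.empty(n_iter)
    scalar_paths = [e.path for e in da.entries if e.family in ("beta", "gamma")]
    triple_paths = [e.path for e in da.entries if e.family == "dirichlet"]
    cols = scalar_paths + [f"{p}.{c}" for p in triple_paths
                           for c in ("nondisabling", "disabling", "dead")]
    sampled = np.empty((n_iter, len(cols)))
    rejected = 0
    for i in range(n_iter):
        ps_i, rej = sample_parameters(da, rng, ps)
        rejected += rej
        res = run_base_case(
            ps_i, background_mortality_mode,
            half_cycle_correction=half_cycle_correction,
        )
        d_cost[i] = res.incr_cost
        d_qaly[i] = res.incr_qaly
        row = [ _get_param(ps_i, p).point for p in scalar_paths ]
        for p in triple_paths:
            row.extend(_get_dist(ps_i, p).points())
        sampled[i] = row
    return PSAResultSet(
        seed=seed, n_iter=n_iter, d_cost=d_cost, d_qaly=d_qaly,
        n_rejected=rejected, sampled=pd.DataFrame(sampled, columns=cols),
    )


def _get_dist(ps: ParameterSet, path: str) -> OutcomeDistribution:
    obj = ps
    for part in path.split("."):
        obj = getattr(obj, part)
    return obj


def acceptance_probability(rs: PSAResultSet, wtp: float) -> float:
    """Fraction of iterations where the intervention's incremental net
    monetary benefit at ``wtp`` is positive."""
    return float(np.mean(rs.d_qaly * wtp - rs.d_cost > 0.0))


def ceac(rs: PSAResultSet, wtp_grid: Sequence[float]) -> list[tuple[float, float]]:
    """Cost-effectiveness acceptability curve over a willingness-to-pay grid."""
    if rs.n_iter == 0:
        raise ValueError("empty PSA result set")
    return [(float(w), acceptance_probability(rs, w)) for w in wtp_grid]


def ceac_crossing(rs: PSAResultSet, prob: float = 0.5,
                  lo: float = 0.0, hi: float = 60000.0) -> float:
    """Willingness-to-pay at which acceptability first reaches ``prob``
    (bisection on the monotone empirical curve)."""
    f = lambda w: acceptance_probability(rs, w) - prob
    if f(hi) < 0:
        raise ValueError("acceptability never reaches the requested probability")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
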