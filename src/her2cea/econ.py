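"""Incremental cost-effectiveness analysis and sensitivity analysis.

Strategies are compared on the efficiency frontier: strictly dominated
strategies (more costly, no more effective) are removed, then extendedly
dominated ones (a strategy whose incremental cost-effectiveness ratio
exceeds that of the next, more effective frontier segment), and pairwise
ICERs Δcost/ΔQALY are reported along the surviving frontier.

One-way deterministic SA re-runs every strategy with a single parameter at
its low and high bound.  Probabilistic SA draws each parameter from its
declared distribution — gamma for costs (moment-matched shape/rate), beta
for utilities and probabilities (moment-matched), uniform(low, high) for
disutilities and the discount rate — propagates every draw through all
strategies, and summarises uncertainty as cost-effectiveness acceptability
curves from the net monetary benefit NMB = w·QALY − cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .markov import StrategyResult
from .params import ConfigurationError, ParameterSet


def icer_frontier(results: Sequence[StrategyResult]) -> pd.DataFrame:
    """Dominance-adjusted ICER table.

    Returns one row per strategy (sorted by cost) with ``dominated``,
    ``extended_dominated`` flags and the ICER versus the previous
    non-dominated strategy.  A zero-ΔQALY tie on the frontier is reported
    as dominance of the costlier strategy, never as a division.
    """
    if len(results) < 2:
        raise ValueError("need at least two strategies")
    names = [r.strategy for r in results]
    if len(set(names)) != len(names):
        raise ValueError("duplicate strategy identifiers")

    rows = sorted(results, key=lambda r: (r.cost, -r.qaly))
    dominated: set[str] = set()
    # strict dominance: some other strategy has cost <= and qaly >= (one
    # strict); outcome-identical strategies keep only the first by sort order
    for i, r in enumerate(rows):
        for j, s in enumerate(rows):
            if s is r:
                continue
            tie = s.cost == r.cost and s.qaly == r.qaly and j < i
            if tie or (
                s.cost <= r.cost and s.qaly >= r.qaly
                and (s.cost < r.cost or s.qaly > r.qaly)
            ):
                dominated.add(r.strategy)
                break
    extended: set[str] = set()
    while True:
        frontier = [
            r for r in rows
            if r.strategy not in dominated and r.strategy not in extended
        ]
        changed = False
        for j in range(1, len(frontier) - 1):
            a, b, c = frontier[j - 1], frontier[j], frontier[j + 1]
            dq_ab = b.qaly - a.qaly
            dq_bc = c.qaly - b.qaly
            if dq_ab <= 0:
                continue
            icer_ab = (b.cost - a.cost) / dq_ab
            icer_bc = (c.cost - b.cost) / dq_bc if dq_bc > 0 else math.inf
            if icer_ab > icer_bc:
                extended.add(b.strategy)
                changed = True
                break
        if not changed:
            break

    out = []
    prev = None
    for r in rows:
        flag_d = r.strategy in dominated
        flag_e = r.strategy in extended
        icer = math.nan
        if not flag_d and not flag_e:
            if prev is not None:
                icer = (r.cost - prev.cost) / (r.qaly - prev.qaly)
            prev = r
        out.append(
            {
                "strategy": r.strategy,
                "cost": r.cost,
                "qaly": r.qaly,
                "ly": r.ly,
                "dominated": flag_d,
                "extended_dominated": flag_e,
                "icer": icer,
            }
        )
    return pd.DataFrame(out)


def one_way_dsa(
    builder: Callable[[ParameterSet], list[StrategyResult]],
    paramset: ParameterSet,
    name: str,
) -> tuple[list[StrategyResult], list[StrategyResult]]:
    """Re-run all strategies with one parameter at its low then high bound."""
    p = paramset[name]
    if not p.has_bounds:
        raise ValueError(f"parameter {name!r} has no DSA bounds")
    low = builder(paramset.with_value(name, p.low))
    high = builder(paramset.with_value(name, p.high))
    return low, high


def tornado(
    builder: Callable[[ParameterSet], list[StrategyResult]],
    paramset: ParameterSet,
    names: Sequence[str],
    outcome: Callable[[list[StrategyResult]], float],
) -> pd.DataFrame:
    """One-way DSA over many parameters, ordered by outcome range.

    ``outcome`` maps the list of strategy results to the scalar plotted on
    the tornado axis (e.g. an ICER between two named strategies).
    """
    rows = []
    for name in names:
        lo_res, hi_res = one_way_dsa(builder, paramset, name)
        lo, hi = outcome(lo_res), outcome(hi_res)
        rows.append(
            {
                "parameter": name,
                "outcome_low": lo,
                "outcome_high": hi,
                "range": abs(hi - lo),
            }
        )
    df = pd.DataFrame(rows).sort_values("range", ascending=False, kind="stable")
    return df.reset_index(drop=True)


def pairwise_icer(results: Sequence[StrategyResult], a: str, b: str) -> float:
    """ICER of strategy ``b`` versus ``a`` (Δcost/ΔQALY)."""
    by = {r.strategy: r for r in results}
    ra, rb = by[a], by[b]
    dq = rb.qaly - ra.qaly
    if dq == 0:
        return math.inf
    return (rb.cost - ra.cost) / dq


def gamma_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """(shape, rate) of the gamma distribution with the given moments."""
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be positive")
    shape = (mean / sd) ** 2
    rate = mean / sd**2
    return shape, rate


def beta_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """(alpha, beta) of the beta distribution with the given moments."""
    if not 0 < mean < 1:
        raise ValueError("mean must lie in (0, 1)")
    if sd <= 0:
        raise ValueError("sd must be positive")
    if sd**2 >= mean * (1 - mean):
        raise ValueError(
            f"variance {sd**2:.3g} too large for a beta with mean {mean:.3g}"
        )
    nu = mean * (1 - mean) / sd**2 - 1.0
    return mean * nu, (1 - mean) * nu


def sample_paramset(
    paramset: ParameterSet, seed: int | np.random.Generator
) -> ParameterSet:
    """One probabilistic-SA draw of every distribution-bearing parameter.

    Gamma and beta parameters are moment-matched to (baseline, sd);
    uniform parameters draw from (low, high).  Parameters with no
    distribution, or a degenerate (zero/absent) SD where one is required,
    stay fixed at baseline.  Draws are independent across parameters.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    values: dict[str, float] = {}
    for p in paramset:
        if p.dist == "none":
            continue
        if p.dist == "uniform":
            if not p.has_bounds:
                raise ConfigurationError(f"{p.name}: uniform without bounds")
            lo, hi = min(p.low, p.high), max(p.low, p.high)
            values[p.name] = float(rng.uniform(lo, hi))
        elif p.dist == "gamma":
            if not (math.isfinite(p.sd) and p.sd > 0):
                continue
            shape, rate = gamma_from_moments(abs(p.baseline), p.sd)
            draw = float(rng.gamma(shape, 1.0 / rate))
            values[p.name] = math.copysign(draw, p.baseline)
        elif p.dist == "beta":
            if not (math.isfinite(p.sd) and p.sd > 0):
                continue
            a, b = beta_from_moments(p.baseline, p.sd)
            values[p.name] = float(rng.beta(a, b))
    return paramset.with_values(values)


def run_psa(
    builder: Callable[[ParameterSet], list[StrategyResult]],
    paramset: ParameterSet,
    n_draws: int,
    seed: int,
) -> pd.DataFrame:
    """Monte-Carlo PSA: all strategies evaluated on each sampled set.

    Returns a long DataFrame (draw, strategy, cost, qaly, ly).
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for d in range(n_draws):
        sampled = sample_paramset(paramset, rng)
        for r in builder(sampled):
            rows.append(
                {
                    "draw": d,
                    "strategy": r.strategy,
                    "cost": r.cost,
                    "qaly": r.qaly,
                    "ly": r.ly,
                }
            )
    return pd.DataFrame(rows)


def nmb(result: StrategyResult, wtp: float) -> float:
    """Net monetary benefit w·QALY − cost."""
    return wtp * result.qaly - result.cost


def default_wtp_grid() -> np.ndarray:
    return np.linspace(0.0, 200_000.0, 2001)


def ceac(samples: pd.DataFrame, wtp_grid=None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves.

    For each willingness-to-pay value, the fraction of draws in which each
    strategy has the highest net monetary benefit (ties split evenly, so
    curves sum to one at every w).
    """
    if wtp_grid is None:
        wtp_grid = default_wtp_grid()
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    wide_q = samples.pivot(index="draw", columns="strategy", values="qaly")
    wide_c = samples.pivot(index="draw", columns="strategy", values="cost")
    strategies = list(wide_q.columns)
    q = wide_q.to_numpy()  # (draws, strategies)
    c = wide_c.to_numpy()
    n = q.shape[0]
    rows = []
    for w in wtp_grid:
        nb = w * q - c
        best = nb.max(axis=1, keepdims=True)
        winners = np.isclose(nb, best)
        share = winners / winners.sum(axis=1, keepdims=True)
        probs = share.sum(axis=0) / n
        for s, p in zip(strategies, probs):
            rows.append({"wtp": w, "strategy": s, "probability": p})
    return pd.DataFrame(rows)
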