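"""Synthetic right-censored individual patient data (IPD).

The published survival inputs are curve parameters, not patient records,
so testing the fitting stage needs simulated cohorts: event times are
drawn from the log-logistic distribution by inverse-CDF sampling,

    t = (1/λ) · (u / (1 − u))^(1/γ),   u ~ Uniform(0, 1),

and censoring times are uniform on (0, t_max) with t_max solved so the
expected censored fraction equals the requested rate.  This emulates the
administrative right-censoring of trial follow-up; it does not emulate
informative censoring or curve-digitisation error in real reconstructed
data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import integrate, optimize

from .params import ParameterSet
from .survival import LogLogisticParams, survival_at


@dataclass(frozen=True)
class SyntheticCohortConfig:
    n: int
    params: LogLogisticParams
    censor_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must lie in [0, 1)")


def loglogistic_inverse_cdf(params: LogLogisticParams, u) -> np.ndarray:
    """Quantile function of the event-time distribution: F⁻¹(u)."""
    u = np.asarray(u, dtype=float)
    return (1.0 / params.scale) * (u / (1.0 - u)) ** (1.0 / params.shape)


def _censor_horizon(params: LogLogisticParams, censor_rate: float) -> float:
    """Solve for t_max of Uniform(0, t_max) censoring such that
    P(censored) = E[S(C)] = (1/t_max)∫₀^{t_max} S(t) dt = censor_rate."""

    def expected_censored(tmax: float) -> float:
        val, _ = integrate.quad(
            lambda t: survival_at(params, t), 0.0, tmax, limit=200
        )
        return val / tmax

    med = params.median
    lo, hi = med * 1e-3, med * 1e3
    # expected_censored decreases from ~1 (tmax→0) towards the tail mass
    f = lambda tm: expected_censored(tm) - censor_rate
    while f(hi) > 0 and hi < med * 1e9:
        hi *= 10
    return optimize.brentq(f, lo, hi, xtol=1e-10 * med)


def gen_loglogistic_ipd(config: SyntheticCohortConfig) -> pd.DataFrame:
    """Simulate a right-censored cohort; columns ``time`` and ``event``."""
    rng = np.random.default_rng(config.seed)
    u = rng.uniform(size=config.n)
    t_event = loglogistic_inverse_cdf(config.params, u)
    if config.censor_rate > 0:
        tmax = _censor_horizon(config.params, config.censor_rate)
        t_cens = rng.uniform(0.0, tmax, size=config.n)
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)
    else:
        event = np.ones(config.n, dtype=int)
        time = t_event
    return pd.DataFrame({"time": time, "event": event})


def km_estimate(data: pd.DataFrame) -> pd.DataFrame:
    """Kaplan–Meier product-limit estimate; columns time/survival/at_risk."""
    if len(data) == 0:
        raise ValueError("no records")
    kmf = KaplanMeierFitter()
    kmf.fit(data["time"], event_observed=data["event"])
    surv = kmf.survival_function_
    out = pd.DataFrame(
        {
            "time": surv.index.to_numpy(float),
            "survival": surv.iloc[:, 0].to_numpy(float),
            "at_risk": kmf.event_table["at_risk"].reindex(surv.index).to_numpy(float),
        }
    )
    return out.reset_index(drop=True)


def km_survival_at(km: pd.DataFrame, t: float) -> float:
    """Step-function lookup S(t) from a :func:`km_estimate` table."""
    mask = km["time"] <= t
    if not mask.any():
        return 1.0
    return float(km.loc[mask, "survival"].iloc[-1])


def make_fixture(
    paramset: ParameterSet, perturbation: float, seed: int
) -> ParameterSet:
    """Multiplicatively jittered copy of a parameter set for smoke tests.

    Baseline, bounds and SD of each parameter scale by the same factor
    1 + perturbation·u with u ~ Uniform(−1, 1), preserving orderings and
    sign; probability/utility parameters are clipped to (0, 1) supports.
    """
    if not 0 <= perturbation < 1:
        raise ValueError("perturbation must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    new = {}
    for p in paramset:
        factor = 1.0 + perturbation * rng.uniform(-1.0, 1.0)
        scaled = {
            k: getattr(p, k) * factor
            for k in ("baseline", "low", "high", "sd")
            if math.isfinite(getattr(p, k))
        }
        if p.dist == "beta" or p.units == "probability":
            clipped = False
            for k in ("baseline", "low", "high"):
                if k in scaled:
                    v = min(max(scaled[k], 1e-9), 1.0 - 1e-9)
                    clipped = clipped or v != scaled[k]
                    scaled[k] = v
            lo = scaled.get("low")
            hi = scaled.get("high")
            if lo is not None and hi is not None and lo > hi:
                scaled["low"], scaled["high"] = hi, lo
                clipped = True
            if clipped and "sd" in scaled and "low" in scaled and "high" in scaled:
                # keep the bounds-to-SD convention intact after clipping
                scaled["sd"] = (scaled["high"] - scaled["low"]) / 4.0
        new[p.name] = dc_replace(p, **scaled)
    return ParameterSet(paramset.scenario, new, paramset.patient)
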