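"""Parametric survival machinery for the transition-probability engine.

The progression-free and overall survival of each treatment line follows a
log-logistic distribution parameterised as

    S(t) = 1 / (1 + (λ t)^γ),      γ, λ > 0,

so the median survival time is 1/λ and the hazard
h(t) = γ λ (λ t)^(γ−1) / (1 + (λ t)^γ) is unimodal for γ > 1 and
monotonically decreasing for γ ≤ 1.  Per-cycle transition probabilities
derive from conditional survival over one cycle:
tp(k) = 1 − S((k+1)Δ)/S(kΔ).

Right-censored maximum-likelihood fitting is provided for five standard
families (exponential, Weibull, Gompertz, lognormal, log-logistic) with
AIC/BIC model selection, so synthetic individual-patient data generated
from the packaged shape/scale values can be refit and the family choice
audited.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

FAMILIES = ("exponential", "weibull", "gompertz", "lognormal", "loglogistic")


@dataclass(frozen=True)
class LogLogisticParams:
    """Shape γ and scale λ (per ``time_unit``) of a log-logistic curve."""

    shape: float
    scale: float
    time_unit: str = "week"

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("shape and scale must be positive")

    @property
    def median(self) -> float:
        return 1.0 / self.scale

    def rescaled(self, unit_ratio: float) -> "LogLogisticParams":
        """Convert the time unit: t' = t/ratio ⇒ λ' = λ·ratio."""
        return LogLogisticParams(self.shape, self.scale * unit_ratio, "week")


def survival_at(params: LogLogisticParams, t) -> np.ndarray | float:
    """S(t) = 1/(1 + (λt)^γ); vectorised over ``t``."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    out = 1.0 / (1.0 + (params.scale * t) ** params.shape)
    return out if out.ndim else float(out)


def hazard_at(params: LogLogisticParams, t) -> np.ndarray | float:
    """h(t) = γλ(λt)^(γ−1) / (1 + (λt)^γ) = −d/dt ln S(t).

    For γ < 1 the hazard diverges as t → 0⁺; t must be strictly positive.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("t must be strictly positive")
    g, lam = params.shape, params.scale
    x = (lam * t) ** g
    out = g * lam * (lam * t) ** (g - 1.0) / (1.0 + x)
    return out if out.ndim else float(out)


def cycle_transition_prob(
    params: LogLogisticParams, cycle_index, cycle_length: float = 1.0
):
    """Probability of the event during cycle k given survival to its start:
    tp(k) = 1 − S((k+1)Δ)/S(kΔ)."""
    if cycle_length <= 0:
        raise ValueError("cycle_length must be positive")
    k = np.asarray(cycle_index, dtype=float)
    if np.any(k < 0):
        raise ValueError("cycle_index must be non-negative")
    s0 = survival_at(params, k * cycle_length)
    s1 = survival_at(params, (k + 1) * cycle_length)
    out = 1.0 - np.asarray(s1) / np.asarray(s0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class FitResult:
    """A converged maximum-likelihood fit of one parametric family."""

    family: str
    params: dict[str, float]
    loglik: float
    aic: float
    bic: float
    n: int
    n_params: int
    converged: bool = True


class FittingError(RuntimeError):
    pass


def _as_arrays(data) -> tuple[np.ndarray, np.ndarray]:
    """Accept a DataFrame with time/event columns, a sequence of (time,
    event) records, or a pair of arrays."""
    if isinstance(data, pd.DataFrame):
        return data["time"].to_numpy(float), data["event"].to_numpy(int)
    if isinstance(data, tuple) and len(data) == 2:
        return np.asarray(data[0], float), np.asarray(data[1], int)
    arr = np.asarray([(r[0], r[1]) for r in data], dtype=float)
    if arr.size == 0:
        return np.empty(0), np.empty(0, int)
    return arr[:, 0], arr[:, 1].astype(int)


# Each family maps an unconstrained parameter vector x to a log-density /
# log-survival pair; k is the family's parameter count.

def _loglik(family: str, x: np.ndarray, t: np.ndarray, e: np.ndarray) -> float:
    with np.errstate(over="ignore", invalid="ignore"):
        if family == "exponential":
            lam = math.exp(x[0])
            logf = math.log(lam) - lam * t
            logS = -lam * t
        elif family == "weibull":
            k, lam = math.exp(x[0]), math.exp(x[1])
            z = lam * t
            logf = math.log(k) + math.log(lam) + (k - 1) * np.log(z) - z**k
            logS = -(z**k)
        elif family == "gompertz":
            a, b = x[0], math.exp(x[1])  # shape a unconstrained
            if abs(a) < 1e-12:
                logf = math.log(b) - b * t
                logS = -b * t
            else:
                logS = -(b / a) * (np.exp(a * t) - 1.0)
                logf = math.log(b) + a * t + logS
        elif family == "lognormal":
            mu, sigma = x[0], math.exp(x[1])
            z = (np.log(t) - mu) / sigma
            logf = -np.log(t * sigma * math.sqrt(2 * math.pi)) - 0.5 * z**2
            logS = special.log_ndtr(-z)
        elif family == "loglogistic":
            g, lam = math.exp(x[0]), math.exp(x[1])
            z = np.log(lam * t) * g
            # S = 1/(1+e^z); f = g/t * e^z / (1+e^z)^2
            logS = -np.logaddexp(0.0, z)
            logf = math.log(g) - np.log(t) + z + 2.0 * logS
        else:
            raise ValueError(f"unknown family {family!r}")
    ll = np.sum(np.where(e == 1, logf, logS))
    # large finite penalty keeps simplex arithmetic warning-free
    return float(ll) if np.isfinite(ll) else -1e300


_N_PARAMS = {
    "exponential": 1, "weibull": 2, "gompertz": 2,
    "lognormal": 2, "loglogistic": 2,
}


def _initial_guess(family: str, t: np.ndarray) -> np.ndarray:
    med = float(np.median(t))
    med = med if med > 0 else 1.0
    if family == "exponential":
        return np.array([-math.log(np.mean(t))])
    if family == "gompertz":
        return np.array([0.01, -math.log(np.mean(t))])
    if family == "lognormal":
        lt = np.log(t[t > 0])
        return np.array([float(np.mean(lt)), math.log(float(np.std(lt)) + 0.1)])
    # weibull / loglogistic: shape 1, scale 1/median
    return np.array([0.0, -math.log(med)])


def fit_mle(
    data,
    family: str,
    n_restarts: int = 5,
    seed: int = 0,
    xtol: float = 1e-8,
) -> FitResult:
    """Right-censored maximum-likelihood fit of one parametric family.

    Maximises Σ_events log f(t) + Σ_censored log S(t) by Nelder–Mead in a
    transformed (unconstrained) parameter space, restarting from jittered
    initial values and keeping the best converged optimum.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    t, e = _as_arrays(data)
    if len(t) == 0:
        raise FittingError("no data")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if int(e.sum()) < 2:
        raise FittingError("need at least 2 events to fit")
    t = np.clip(t, 1e-12, None)  # guard exact zeros in log terms

    rng = np.random.default_rng(seed)
    x0 = _initial_guess(family, t)
    best = None
    for i in range(max(1, n_restarts)):
        start = x0 if i == 0 else x0 + rng.normal(scale=0.5, size=x0.shape)
        res = optimize.minimize(
            lambda x: -_loglik(family, x, t, e),
            start,
            method="Nelder-Mead",
            options={"xatol": xtol, "fatol": xtol, "maxiter": 4000},
        )
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise FittingError(f"{family}: optimisation failed to converge")

    x = best.x
    if family == "exponential":
        params = {"rate": math.exp(x[0])}
    elif family == "weibull":
        params = {"shape": math.exp(x[0]), "scale": math.exp(x[1])}
    elif family == "gompertz":
        params = {"shape": x[0], "rate": math.exp(x[1])}
    elif family == "lognormal":
        params = {"mu": x[0], "sigma": math.exp(x[1])}
    else:
        params = {"shape": math.exp(x[0]), "scale": math.exp(x[1])}
    ll = -float(best.fun)
    k = _N_PARAMS[family]
    n = len(t)
    return FitResult(
        family=family,
        params=params,
        loglik=ll,
        aic=2 * k - 2 * ll,
        bic=k * math.log(n) - 2 * ll,
        n=n,
        n_params=k,
        converged=bool(best.success),
    )


def fit_all(data, families: Sequence[str] = FAMILIES, seed: int = 0) -> list[FitResult]:
    return [fit_mle(data, fam, seed=seed) for fam in families]


def select_model(fits: Sequence[FitResult]) -> FitResult:
    """Best fit by smallest AIC; ties by smaller BIC, then fewer parameters."""
    if not fits:
        raise ValueError("no fits to select from")
    return min(fits, key=lambda f: (f.aic, f.bic, f.n_params))


def curve_from_params(
    paramset, regimen: str, endpoint: str, time_unit_ratio: float = 1.0
) -> LogLogisticParams:
    """Bind a regimen's ``pfs``/``os`` curve from a parameter set."""
    if endpoint not in ("pfs", "os"):
        raise ValueError("endpoint must be 'pfs' or 'os'")
    p = LogLogisticParams(
        shape=paramset.value(f"{endpoint}_shape_{regimen}"),
        scale=paramset.value(f"{endpoint}_scale_{regimen}"),
    )
    return p.rescaled(time_unit_ratio) if time_unit_ratio != 1.0 else p


def calibration_table(paramset, regimens: Sequence[str]) -> pd.DataFrame:
    """Implied median survival times (1/λ, in the curves' time unit) for
    user inspection of the time-unit assumption."""
    rows = []
    for r in regimens:
        for ep in ("pfs", "os"):
            c = curve_from_params(paramset, r, ep)
            rows.append(
                {
                    "regimen": r,
                    "endpoint": ep,
                    "shape": c.shape,
                    "scale": c.scale,
                    "implied_median": c.median,
                }
            )
    return pd.DataFrame(rows)


def read_ipd(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"time", "event"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns time,event")
    return df


def write_ipd(df: pd.DataFrame, path: str | Path) -> None:
    df[["time", "event"]].to_csv(path, index=False)
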