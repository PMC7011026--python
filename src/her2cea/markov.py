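"""Weekly-cycle Markov cohort engine for sequential treatment lines.

State space for an L-line sequence: PF_line1 … PF_lineL (progression-free
on each line), PD (progressed after the final line), Dead.  Each line's
progression and mortality follow that line's PFS and OS log-logistic
curves *on the line's own clock*: curves describe time since the line
started, so a patient progressing to the next line restarts that line's
clock at zero.  The cohort in a line is therefore age-structured — the
engine tracks, for every cycle, how much mass has spent k cycles in the
line — which makes the per-cycle transition probabilities exact rather
than an average over entry times.

Competing risks within a cycle: death is applied first from the line's OS
curve, and progression applies to survivors
(tp_prog = tp_prog_raw × (1 − tp_death)); an independent-complement
convention is available via ``overlap="independent"``.

Costs and QALYs accumulate per cycle, discounted at 1/(1+r_w)^week:
regimen and monitoring cost streams are indexed by line age, grade ≥3
adverse events and the progression disutility are one-time amounts on the
expected transition mass, and a palliative/end-of-life cost is charged
once on the mass entering Dead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .costing import (
    AEProfile,
    WeeklyCostStream,
    background_cost_stream,
    load_ae_profiles,
    load_regimens,
    weekly_cost_stream,
)
from .params import ConfigurationError, ParameterSet
from .survival import LogLogisticParams, curve_from_params, survival_at

WEEKS_PER_YEAR = 52.18


@dataclass(frozen=True)
class TreatmentSequence:
    """An ordered list of treatment-line regimen identifiers."""

    name: str
    lines: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.lines) < 1:
            raise ValueError("a sequence needs at least one line")


@dataclass
class ModelConfig:
    """Run options for the cohort engine.

    horizon: model horizon in weeks (default 10 years).
    cycle_length: cycle length Δ in weeks; transition probabilities,
        discounting and cost spreading all scale with Δ.
    overlap: per-cycle competing-risk convention, "death_first" or
        "independent".
    responder_fraction: share of the progression-free cohort receiving the
        additive treatment-response utility increment.
    half_cycle: trapezoidal (half-cycle) correction for state membership.
    """

    horizon: float = 520.0
    cycle_length: float = 1.0
    overlap: str = "death_first"
    responder_fraction: float = 1.0
    half_cycle: bool = False

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1 week")
        if self.cycle_length <= 0:
            raise ValueError("cycle_length must be positive")
        if self.overlap not in ("death_first", "independent"):
            raise ValueError(f"unknown overlap convention {self.overlap!r}")
        if not 0 <= self.responder_fraction <= 1:
            raise ValueError("responder_fraction must lie in [0, 1]")

    @property
    def n_cycles(self) -> int:
        return int(round(self.horizon / self.cycle_length))


@dataclass
class LineBinding:
    """One treatment line with its curves, costs and AE profile bound."""

    regimen: str
    pfs: LogLogisticParams
    os: LogLogisticParams
    drug_stream: WeeklyCostStream
    background_stream: WeeklyCostStream
    ae: AEProfile


@dataclass
class ModelSpec:
    """A fully bound model: sequence, curves, streams, utilities."""

    sequence: TreatmentSequence
    lines: list[LineBinding]
    paramset: ParameterSet
    config: ModelConfig
    pd_background: WeeklyCostStream

    @property
    def state_names(self) -> list[str]:
        return [f"PF_line{i+1}" for i in range(len(self.lines))] + ["PD", "Dead"]

    @property
    def n_states(self) -> int:
        return len(self.lines) + 2

    @property
    def utilities(self) -> dict[str, float]:
        ps = self.paramset
        return {
            "u_pf": ps.value("u_progression_free"),
            "u_response": ps.value("u_response"),
            "u_pd": ps.value("u_progressed"),
            "d_progression": ps.value("du_progression"),
        }


def build_model(
    sequence: TreatmentSequence | list[str],
    paramset: ParameterSet,
    config: ModelConfig | None = None,
    source=None,
) -> ModelSpec:
    """Bind a treatment sequence to curves, cost streams and AE profiles."""
    if not isinstance(sequence, TreatmentSequence):
        sequence = TreatmentSequence(name="+".join(sequence), lines=tuple(sequence))
    config = config or ModelConfig()
    regimens = load_regimens(source)
    ae_profiles = load_ae_profiles(paramset, source)
    n_weeks = int(math.ceil(config.horizon))
    lines = []
    for rid in sequence.lines:
        if rid not in regimens:
            raise ConfigurationError(
                f"sequence {sequence.name!r} references unknown regimen {rid!r}"
            )
        for prefix in ("pfs_shape", "pfs_scale", "os_shape", "os_scale"):
            if f"{prefix}_{rid}" not in paramset:
                raise ConfigurationError(
                    f"regimen {rid!r}: missing curve parameter {prefix}_{rid}"
                )
        if rid not in ae_profiles:
            raise ConfigurationError(f"regimen {rid!r}: no adverse-event profile")
        reg = regimens[rid]
        lines.append(
            LineBinding(
                regimen=rid,
                pfs=curve_from_params(paramset, rid, "pfs"),
                os=curve_from_params(paramset, rid, "os"),
                drug_stream=weekly_cost_stream(reg, paramset, n_weeks, source),
                background_stream=background_cost_stream(
                    reg.her2_targeted, n_weeks, paramset
                ),
                ae=ae_profiles[rid],
            )
        )
    pd_background = background_cost_stream(False, n_weeks, paramset)
    return ModelSpec(
        sequence=sequence,
        lines=lines,
        paramset=paramset,
        config=config,
        pd_background=pd_background,
    )


@dataclass
class Trace:
    """Cycle-by-cycle cohort occupancy and transition flows.

    ``occupancy[c]`` is the distribution at the *start* of cycle c
    (c = 0 … n_cycles, so the final row is the end-of-horizon state).
    ``pf_age[i][c, k]`` is the mass that starts cycle c having spent k
    cycles on line i; ``pd_age`` is analogous on the final line's clock.
    """

    state_names: list[str]
    occupancy: np.ndarray                  # (n_cycles+1, n_states)
    pf_age: list[np.ndarray]               # per line: (n_cycles+1, n_cycles+1)
    pd_age: np.ndarray                     # (n_cycles+1, n_cycles+2)
    progression_inflow: np.ndarray         # (n_cycles,) mass entering any progression
    death_inflow: np.ndarray               # (n_cycles,) mass entering Dead
    cycle_length: float

    @property
    def n_cycles(self) -> int:
        return len(self.progression_inflow)


def _conditional_tp(curve: LogLogisticParams, n_cycles: int, dt: float) -> np.ndarray:
    """tp[k] = 1 − S((k+1)Δ)/S(kΔ) for k = 0 … n_cycles−1."""
    grid = np.arange(n_cycles + 1) * dt
    s = survival_at(curve, grid)
    return 1.0 - s[1:] / s[:-1]


def run_trace(spec: ModelSpec) -> Trace:
    """Run the cohort trace: 100% of the cohort starts progression-free on
    line 1 at line-time zero."""
    cfg = spec.config
    n = cfg.n_cycles
    dt = cfg.cycle_length
    L = len(spec.lines)

    tp_death = [_conditional_tp(line.os, n, dt) for line in spec.lines]
    tp_prog = [_conditional_tp(line.pfs, n, dt) for line in spec.lines]

    pf = [np.zeros(n + 2) for _ in range(L)]  # index = cycles spent in line
    pd_ages = np.zeros(n + 2)
    dead = 0.0

    occupancy = np.zeros((n + 1, L + 2))
    pf_age = [np.zeros((n + 1, n + 1)) for _ in range(L)]
    pd_age = np.zeros((n + 1, n + 2))
    prog_inflow = np.zeros(n)
    death_inflow = np.zeros(n)

    pf[0][0] = 1.0

    for c in range(n + 1):
        for i in range(L):
            occupancy[c, i] = pf[i].sum()
            pf_age[i][c] = pf[i][: n + 1]
        occupancy[c, L] = pd_ages.sum()
        occupancy[c, L + 1] = dead
        pd_age[c] = pd_ages
        if c == n:
            break

        new_pf = [np.zeros(n + 2) for _ in range(L)]
        new_pd = np.zeros(n + 2)
        deaths_c = 0.0
        prog_c = 0.0

        for i in range(L):
            ages = np.arange(n + 1)
            m = pf[i][: n + 1]
            tpd = tp_death[i][np.minimum(ages, n - 1)]
            tpp_raw = tp_prog[i][np.minimum(ages, n - 1)]
            if cfg.overlap == "death_first":
                deaths = m * tpd
                prog = m * (1.0 - tpd) * tpp_raw
            else:  # independent application of both raw probabilities
                total = tpd + tpp_raw
                if np.any(m[total > 1.0] > 1e-12):
                    bad = int(np.argmax((total > 1.0) & (m > 1e-12)))
                    raise RuntimeError(
                        f"cycle {c}, line {i+1}: tp_prog + tp_death = "
                        f"{total[bad]:.4f} > 1 at line age {bad}"
                    )
                deaths = m * tpd
                prog = m * tpp_raw
            stay = m - deaths - prog
            deaths_c += deaths.sum()
            prog_c += prog.sum()
            new_pf[i][1 : n + 2] += stay
            if i + 1 < L:
                new_pf[i + 1][0] += prog.sum()
            else:
                # progression from the final line: enter PD carrying the
                # final line's clock (its OS curve keeps governing death)
                new_pd[1 : n + 2] += prog

        # PD occupants: death per the final line's OS curve at their age
        ages = np.arange(n + 1)
        mpd = pd_ages[: n + 1]
        tpd = tp_death[L - 1][np.minimum(ages, n - 1)]
        pd_deaths = mpd * tpd
        deaths_c += pd_deaths.sum()
        new_pd[1 : n + 2] += mpd - pd_deaths

        dead += deaths_c
        prog_inflow[c] = prog_c
        death_inflow[c] = deaths_c
        pf = new_pf
        pd_ages = new_pd

        total = sum(v.sum() for v in pf) + pd_ages.sum() + dead
        if abs(total - 1.0) > 1e-9:
            raise RuntimeError(
                f"cycle {c}: occupancy not conserved (sum = {total!r})"
            )

    return Trace(
        state_names=spec.state_names,
        occupancy=occupancy,
        pf_age=pf_age,
        pd_age=pd_age,
        progression_inflow=prog_inflow,
        death_inflow=death_inflow,
        cycle_length=dt,
    )


def discount_factor(week, rate_weekly: float):
    """(1 + r_w)^(−week); vectorised over ``week``."""
    if rate_weekly < 0:
        raise ValueError("discount rate must be non-negative")
    week = np.asarray(week, dtype=float)
    if np.any(week < 0):
        raise ValueError("week must be non-negative")
    out = (1.0 + rate_weekly) ** (-week)
    return out if out.ndim else float(out)


def _stream_per_cycle(stream: WeeklyCostStream, n_cycles: int, dt: float) -> np.ndarray:
    """Cost attributed to each cycle of line age, spreading each week's
    charge uniformly over the cycles that fall inside it."""
    idx = np.floor(np.arange(n_cycles + 1) * dt).astype(int)
    idx = np.clip(idx, 0, len(stream.costs) - 1)
    return stream.costs[idx] * dt


@dataclass
class StrategyResult:
    """Discounted totals for one strategy."""

    strategy: str
    cost: float
    qaly: float
    ly: float
    breakdown: dict[str, float] = field(default_factory=dict)


def accumulate(trace: Trace, spec: ModelSpec) -> StrategyResult:
    """Discounted cost, discounted QALY and (undiscounted) life-years."""
    cfg = spec.config
    n = trace.n_cycles
    dt = trace.cycle_length
    if any(len(line.drug_stream) < math.ceil(cfg.horizon) for line in spec.lines):
        raise ValueError("cost stream shorter than the model horizon")
    r = spec.paramset.discount_weekly
    disc = discount_factor(np.arange(n + 1) * dt, r)
    util = spec.utilities

    L = len(spec.lines)
    occ = trace.occupancy
    if cfg.half_cycle:
        state_time = 0.5 * (occ[:-1] + occ[1:])  # (n, n_states)
        w_disc = disc[:-1]
    else:
        state_time = occ[:-1]
        w_disc = disc[:-1]

    drug_cost = 0.0
    background_cost = 0.0
    ae_cost = 0.0
    ae_qaly = 0.0
    for i, line in enumerate(spec.lines):
        per_cycle_drug = _stream_per_cycle(line.drug_stream, n, dt)
        per_cycle_bg = _stream_per_cycle(line.background_stream, n, dt)
        pf = trace.pf_age[i][:-1]  # (n, n+1)
        drug_cost += float(w_disc @ (pf @ per_cycle_drug))
        background_cost += float(w_disc @ (pf @ per_cycle_bg))
        # adverse events: expected event mass per cycle on treatment
        p_cycle = 1.0 - (1.0 - line.ae.weekly_prob) ** dt
        mass = pf.sum(axis=1) * p_cycle
        ae_cost += float(w_disc @ mass) * line.ae.event_cost
        ae_qaly += float(w_disc @ mass) * line.ae.event_disutility
    per_cycle_pd_bg = _stream_per_cycle(spec.pd_background, n, dt)
    background_cost += float(w_disc @ (trace.pd_age[:-1, : n + 1] @ per_cycle_pd_bg))

    palliative = spec.paramset.value("palliative_care")
    palliative_cost = float(w_disc @ trace.death_inflow) * palliative
    progression_qaly = (
        float(w_disc @ trace.progression_inflow) * util["d_progression"]
    )

    u_pf = util["u_pf"] + cfg.responder_fraction * util["u_response"]
    u_state = np.array([u_pf] * L + [util["u_pd"], 0.0])
    year_frac = dt / WEEKS_PER_YEAR
    state_qaly = float(w_disc @ (state_time @ u_state)) * year_frac

    alive = state_time[:, : L + 1].sum(axis=1)
    ly = float(alive.sum()) * year_frac

    cost = drug_cost + background_cost + ae_cost + palliative_cost
    qaly = state_qaly + ae_qaly + progression_qaly
    return StrategyResult(
        strategy=spec.sequence.name,
        cost=cost,
        qaly=qaly,
        ly=ly,
        breakdown={
            "drug": drug_cost,
            "background": background_cost,
            "adverse_events": ae_cost,
            "palliative": palliative_cost,
            "state_qaly": state_qaly,
            "ae_disutility": ae_qaly,
            "progression_disutility": progression_qaly,
        },
    )


def run_strategy(
    sequence: TreatmentSequence | list[str],
    paramset: ParameterSet,
    config: ModelConfig | None = None,
    source=None,
) -> StrategyResult:
    """Build, trace and accumulate one strategy."""
    spec = build_model(sequence, paramset, config, source)
    trace = run_trace(spec)
    return accumulate(trace, spec)
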