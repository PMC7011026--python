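"""Drug acquisition costing and weekly cost streams.

Parenteral drugs are dosed per kg, per m² of body surface area, or flat,
and purchased as whole vials.  Two charging conventions are supported:

* **wastage** — every opened vial is charged in full; the cost of an
  administration is the cheapest multiset of whole vials covering the dose
  (:func:`vial_cost_wastage`).
* **no wastage** — the same vial combination is opened, but the
  smallest-strength vial in it is charged pro rata for the remaining dose
  (:func:`vial_cost_fractional`).  This convention, rather than a global
  cost minimisation over fractional vials, reproduces the published
  per-administration figures for every drug in the catalog.

Oral drugs are charged per day with tablet counts rounded up to whole
tablets.  Regimen schedules expand to week-indexed cost vectors
(:func:`weekly_cost_stream`); recurring monitoring (physician visits, blood
work, CT, echocardiogram) expands analogously
(:func:`background_cost_stream`), and grade ≥3 adverse-event management is
a one-time per-event cost (:func:`ae_event_cost`).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .params import ParameterSet, PatientProfile, load_yaml, ConfigurationError

DOSING_BASES = ("per_kg", "per_m2", "flat", "oral_daily_per_m2", "oral_daily_flat")


@dataclass(frozen=True)
class VialOption:
    strength: float  # mg
    price: float     # USD per vial

    def __post_init__(self) -> None:
        if self.strength <= 0:
            raise ValueError("vial strength must be positive")
        if self.price < 0:
            raise ValueError("vial price must be non-negative")


@dataclass(frozen=True)
class TabletOption:
    strength: float  # mg
    price: float     # USD per tablet (or per daily pack)


@dataclass(frozen=True)
class DrugSpec:
    """Dosing rule plus purchasable presentations for one drug."""

    name: str
    dosing_basis: str
    dose_amount: float                    # mg/kg, mg/m2, mg, or mg/day
    loading_amount: float | None = None   # where loading differs
    vials: tuple[VialOption, ...] = ()
    tablet: TabletOption | None = None

    def __post_init__(self) -> None:
        if self.dosing_basis not in DOSING_BASES:
            raise ValueError(f"unknown dosing basis {self.dosing_basis!r}")
        if self.dose_amount <= 0:
            raise ValueError("dose_amount must be positive")
        if not self.vials and self.tablet is None:
            raise ValueError(f"{self.name}: no vial or tablet option")


@dataclass(frozen=True)
class VialCombination:
    """A whole-vial cover of a dose with its cost."""

    counts: tuple[tuple[float, int], ...]  # (strength, n) pairs, sorted
    cost: float

    @property
    def n_vials(self) -> int:
        return sum(n for _, n in self.counts)

    @property
    def total_strength(self) -> float:
        return sum(s * n for s, n in self.counts)


def compute_dose(
    spec: DrugSpec, patient: PatientProfile, phase: str = "maintenance"
) -> float:
    """Administered dose in mg for one patient (daily dose for orals)."""
    if phase not in ("loading", "maintenance"):
        raise ValueError(f"unknown phase {phase!r}")
    amount = spec.dose_amount
    if phase == "loading" and spec.loading_amount is not None:
        amount = spec.loading_amount
    basis = spec.dosing_basis
    if basis == "per_kg":
        return amount * patient.weight
    if basis in ("per_m2", "oral_daily_per_m2"):
        return amount * patient.bsa
    return amount  # flat / oral_daily_flat


def _iter_covers(dose: float, vials: list[VialOption]):
    """All whole-vial count vectors whose strength covers the dose."""
    # enough of any single option alone always covers, so per-option counts
    # beyond ceil(dose/strength) can never improve a cover
    upper = [math.ceil(dose / v.strength) if dose > 0 else 0 for v in vials]
    for counts in itertools.product(*(range(u + 1) for u in upper)):
        if sum(c * v.strength for c, v in zip(counts, vials)) >= dose:
            yield counts


def vial_cost_wastage(
    dose: float, vials: list[VialOption] | tuple[VialOption, ...]
) -> VialCombination:
    """Cheapest multiset of whole vials whose total strength covers ``dose``.

    Ties are broken by fewer vials, then by larger total strength.
    """
    if dose < 0:
        raise ValueError("dose must be non-negative")
    vials = [v if isinstance(v, VialOption) else VialOption(**v) for v in vials]
    if not vials:
        raise ValueError("vial catalog is empty")
    if dose == 0:
        return VialCombination(counts=(), cost=0.0)
    best = None
    best_key = None
    for counts in _iter_covers(dose, vials):
        cost = sum(c * v.price for c, v in zip(counts, vials))
        n = sum(counts)
        strength = sum(c * v.strength for c, v in zip(counts, vials))
        key = (round(cost, 9), n, -strength)
        if best_key is None or key < best_key:
            best_key = key
            best = counts
    pairs = tuple(
        sorted((v.strength, c) for c, v in zip(best, vials) if c > 0)
    )
    cost = sum(c * v.price for c, v in zip(best, vials))
    return VialCombination(counts=pairs, cost=round(cost, 10))


def vial_cost_fractional(
    dose: float,
    vials: list[VialOption] | tuple[VialOption, ...],
    fractions: dict[float, float] | None = None,
) -> float:
    """No-wastage cost: whole vials plus a pro-rata fraction of the last one.

    The vial combination is the wastage-optimal cover; the smallest-strength
    vial in it is charged by ``remainder / strength`` instead of in full.
    ``fractions`` optionally overrides the charged vial counts as a mapping
    ``strength -> (possibly fractional) number of vials``, used to reproduce
    published figures that round the fraction before pricing.
    """
    if dose < 0:
        raise ValueError("dose must be non-negative")
    vials = [v if isinstance(v, VialOption) else VialOption(**v) for v in vials]
    # a rational buyer ignores any option dominated at the same strength
    price_of: dict[float, float] = {}
    for v in vials:
        price_of[v.strength] = min(price_of.get(v.strength, math.inf), v.price)
    if fractions is not None:
        total = 0.0
        for strength, n in fractions.items():
            if n < 0:
                raise ValueError("vial count must be non-negative")
            frac = n - math.floor(n)
            if not 0 <= frac <= 1:
                raise ValueError("fraction outside [0, 1]")
            total += n * price_of[strength]
        return total
    if dose == 0:
        return 0.0
    combo = vial_cost_wastage(dose, vials)
    # charge the smallest-strength vial of the combination pro rata
    small_strength, _ = combo.counts[0]
    whole = sum(
        n * price_of[s] for s, n in combo.counts
    ) - price_of[small_strength]
    covered = combo.total_strength - small_strength
    remainder = max(dose - covered, 0.0)
    return whole + remainder / small_strength * price_of[small_strength]


@dataclass(frozen=True)
class WeeklyCostStream:
    """Week-indexed cost vector; ``costs[0]`` is treatment week 1."""

    regimen: str
    scenario: str
    costs: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.costs < 0):
            raise ValueError("weekly costs must be non-negative")

    def __getitem__(self, week: int) -> float:
        """Cost of 1-indexed treatment week ``week``."""
        if week < 1:
            raise IndexError("weeks are 1-indexed")
        return float(self.costs[week - 1])

    def __len__(self) -> int:
        return len(self.costs)


def _pattern_weeks(pattern: dict, n_weeks: int):
    start = int(pattern["start"])
    period = pattern.get("period")
    until = int(pattern.get("until", n_weeks))
    if start < 1:
        raise ValueError("patterns reference weeks >= 1")
    if period is None:
        return [start] if start <= n_weeks else []
    period = int(period)
    if period < 1:
        raise ValueError("period must be >= 1")
    return list(range(start, min(until, n_weeks) + 1, period))


@dataclass(frozen=True)
class RegimenSchedule:
    """A regimen's component parameters and their administration weeks."""

    name: str
    label: str
    components: tuple[tuple[str, tuple[dict, ...]], ...]  # (param, patterns)
    her2_targeted: bool = True

    def component_weeks(self, n_weeks: int) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for param, patterns in self.components:
            weeks: list[int] = []
            for pat in patterns:
                weeks.extend(_pattern_weeks(pat, n_weeks))
            out.setdefault(param, []).extend(sorted(weeks))
        return out


def load_regimens(source: str | Path | None = None) -> dict[str, RegimenSchedule]:
    raw = load_yaml("regimens.yaml", source)["regimens"]
    out = {}
    for name, cfg in raw.items():
        comps = tuple(
            (c["param"], tuple(c["weeks"])) for c in cfg["components"]
        )
        out[name] = RegimenSchedule(
            name=name,
            label=cfg.get("label", name),
            components=comps,
            her2_targeted=bool(cfg.get("her2_targeted", True)),
        )
    return out


def load_drugs(source: str | Path | None = None) -> dict[str, DrugSpec]:
    raw = load_yaml("drugs.yaml", source)["drugs"]
    out = {}
    for name, cfg in raw.items():
        vials = tuple(
            VialOption(strength=v["strength"], price=v["price"])
            for v in cfg.get("vials", [])
        )
        tab = cfg.get("tablet")
        out[name] = DrugSpec(
            name=name,
            dosing_basis=cfg["dosing_basis"],
            dose_amount=float(cfg["dose_amount"]),
            loading_amount=(
                float(cfg["loading_amount"]) if "loading_amount" in cfg else None
            ),
            vials=vials,
            tablet=TabletOption(tab["strength"], tab["price"]) if tab else None,
        )
    return out


def oral_daily_cost(spec: DrugSpec, patient: PatientProfile) -> float:
    """Daily tablet cost, rounding up to whole tablets."""
    if spec.tablet is None:
        raise ValueError(f"{spec.name} has no tablet option")
    dose = compute_dose(spec, patient)
    n_tablets = math.ceil(dose / spec.tablet.strength - 1e-9)
    return n_tablets * spec.tablet.price


def weekly_cost_stream(
    regimen: RegimenSchedule | str,
    scenario_params: ParameterSet,
    n_weeks: int,
    source: str | Path | None = None,
) -> WeeklyCostStream:
    """Expand a regimen into its per-week acquisition cost vector.

    Component per-administration prices come from the scenario's parameter
    set, so deterministic/probabilistic SA on an acquisition cost flows
    straight into the stream.
    """
    if n_weeks < 1:
        raise ValueError("n_weeks must be >= 1")
    if isinstance(regimen, str):
        regimens = load_regimens(source)
        if regimen not in regimens:
            raise ConfigurationError(f"unknown regimen {regimen!r}")
        regimen = regimens[regimen]
    costs = np.zeros(n_weeks)
    for param, weeks in regimen.component_weeks(n_weeks).items():
        price = scenario_params.value(param)
        for w in weeks:
            costs[w - 1] += price
    return WeeklyCostStream(
        regimen=regimen.name, scenario=scenario_params.scenario, costs=costs
    )


@dataclass(frozen=True)
class AEProfile:
    """Grade ≥3 adverse-event burden of one regimen.

    ``event_cost`` and ``event_disutility`` are one-time amounts applied to
    the expected event mass; ``weekly_prob`` is the probability of an event
    per week on treatment.
    """

    regimen: str
    weekly_prob: float
    event_cost: float
    event_disutility: float
    components: tuple[tuple[str, float, float], ...] = ()  # (event, incidence, unit cost)

    def __post_init__(self) -> None:
        if not 0 <= self.weekly_prob <= 1:
            raise ValueError("weekly_prob must lie in [0, 1]")
        if self.event_disutility > 0:
            raise ValueError("disutility must be <= 0")


def ae_event_cost(components) -> float:
    """Σ incidence × unit management cost over a regimen's event profile."""
    total = 0.0
    for incidence, unit_cost in components:
        if not 0 <= incidence <= 1:
            raise ValueError(f"incidence {incidence} outside [0, 1]")
        total += incidence * unit_cost
    return total


def load_ae_profiles(
    paramset: ParameterSet, source: str | Path | None = None
) -> dict[str, AEProfile]:
    raw = load_yaml("adverse_events.yaml", source)
    unit = raw["unit_costs"]
    out = {}
    for name, cfg in raw["profiles"].items():
        comps = tuple(
            (c["event"], float(c["incidence"]), float(unit[c["event"]]))
            for c in cfg["components"]
        )
        out[name] = AEProfile(
            regimen=name,
            weekly_prob=paramset.value(f"ae_weekly_prob_{name}"),
            event_cost=paramset.value(f"ae_cost_{name}"),
            event_disutility=paramset.value(f"du_ae_{name}"),
            components=comps,
        )
    return out


def background_cost_stream(
    on_her2: bool, n_weeks: int, paramset: ParameterSet
) -> WeeklyCostStream:
    """Recurring monitoring costs: each charge falls on the first week of
    its interval (physician fee and blood work every 3 weeks, CT every 9,
    echocardiogram every 13 — the latter only on HER2-targeted therapy)."""
    if n_weeks < 1:
        raise ValueError("n_weeks must be >= 1")
    costs = np.zeros(n_weeks)
    items = [("physician_fee", 3), ("blood_work", 3), ("ct_scan", 9)]
    if on_her2:
        items.append(("echocardiogram", 13))
    for name, interval in items:
        price = paramset.value(name)
        costs[::interval] += price
    return WeeklyCostStream(
        regimen="background", scenario=paramset.scenario, costs=costs
    )
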