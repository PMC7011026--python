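"""Scenario-keyed model parameter registry.

Every model input — unit prices, adverse-event costs, utilities,
disutilities, log-logistic survival shape/scale pairs, adverse-event
probabilities and the weekly discount rate — is a named :class:`ParamValue`
carrying its baseline, deterministic-SA bounds, probabilistic-SA standard
deviation and sampling distribution.  Two scenarios are packaged:

``base_case``
    Parenteral drugs costed by whole vials (opened vials fully charged).
``no_wastage``
    The final partially-used vial of the combination charged pro rata;
    scenarios differ only in the four affected acquisition-cost entries.

Bound/SD conventions: parameters without an empirical interval use a
symmetric ±25% or ±50% band around the baseline (:func:`dsa_bounds`), and
the PSA standard deviation is (high − low)/4 (:func:`psa_sd`), i.e. the
bounds are read as a ±2 SD interval.  Survival-curve rows carry regression
standard errors instead, so the SD rule is not applied to them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterator

import pandas as pd
import yaml

SCENARIOS = ("base_case", "no_wastage")

#: Distributions a parameter may declare for probabilistic SA.
DISTRIBUTIONS = ("gamma", "beta", "uniform", "none")

_COLUMNS = [
    "name", "baseline", "low", "high", "sd", "dist", "schedule",
    "units", "assumption", "provenance", "note",
]


class ConfigurationError(ValueError):
    """Unknown scenario or malformed configuration."""


class SchemaError(ValueError):
    """A required parameter or column is missing."""


@dataclass(frozen=True)
class PatientProfile:
    """Reference patient used for weight- and BSA-based dosing."""

    weight: float = 58.1   # kg
    bsa: float = 1.59      # m^2

    def __post_init__(self) -> None:
        if self.weight <= 0 or self.bsa <= 0:
            raise ValueError("weight and bsa must be positive")


@dataclass(frozen=True)
class ParamValue:
    """One named model input with its sensitivity-analysis metadata."""

    name: str
    baseline: float
    low: float = math.nan
    high: float = math.nan
    sd: float = math.nan
    dist: str = "none"
    schedule: str = ""
    units: str = ""
    assumption: str = ""
    provenance: str = "published"
    note: str = ""

    def __post_init__(self) -> None:
        if self.dist not in DISTRIBUTIONS:
            raise ConfigurationError(
                f"parameter {self.name!r}: unknown distribution {self.dist!r}"
            )

    @property
    def has_bounds(self) -> bool:
        return math.isfinite(self.low) and math.isfinite(self.high)


@dataclass
class ParameterSet:
    """All parameters for one costing scenario, keyed by name."""

    scenario: str
    params: dict[str, ParamValue] = field(default_factory=dict)
    patient: PatientProfile = field(default_factory=PatientProfile)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ConfigurationError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}"
            )

    def __getitem__(self, name: str) -> ParamValue:
        try:
            return self.params[name]
        except KeyError:
            raise SchemaError(f"parameter {name!r} not in set") from None

    def __contains__(self, name: str) -> bool:
        return name in self.params

    def __iter__(self) -> Iterator[ParamValue]:
        return iter(self.params.values())

    def __len__(self) -> int:
        return len(self.params)

    def value(self, name: str) -> float:
        return self[name].baseline

    @property
    def discount_weekly(self) -> float:
        return self.value("discount_weekly")

    def with_value(self, name: str, baseline: float) -> "ParameterSet":
        """Copy of the set with one baseline replaced (used by DSA/PSA)."""
        p = self[name]
        new = dict(self.params)
        new[name] = replace(p, baseline=baseline)
        return ParameterSet(self.scenario, new, self.patient)

    def with_values(self, values: dict[str, float]) -> "ParameterSet":
        new = dict(self.params)
        for name, baseline in values.items():
            new[name] = replace(self[name], baseline=baseline)
        return ParameterSet(self.scenario, new, self.patient)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {c: getattr(p, c) for c in _COLUMNS} for p in self.params.values()
        ]
        return pd.DataFrame(rows, columns=_COLUMNS)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def data_path(filename: str = "") -> Path:
    """Path to a packaged data file."""
    root = resources.files("her2cea").joinpath("data")
    return Path(str(root.joinpath(filename) if filename else root))


def _read_param_csv(path: Path) -> dict[str, ParamValue]:
    df = pd.read_csv(path, dtype={"note": str})
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, ParamValue] = {}
    for row in df.itertuples(index=False):
        d = row._asdict()
        for key in ("schedule", "units", "assumption", "provenance", "note"):
            if not isinstance(d[key], str):
                d[key] = ""
        for key in ("low", "high", "sd"):
            d[key] = float(d[key]) if pd.notna(d[key]) else math.nan
        if not isinstance(d["dist"], str) or not d["dist"]:
            d["dist"] = "none"
        out[d["name"]] = ParamValue(**d)
    return out


# Parameter names every scenario must provide (spot checks; the regimens in
# regimens.yaml reference acquisition-cost names directly and fail loudly).
_REQUIRED = (
    "physician_fee", "trastuzumab_loading", "trastuzumab_maintenance",
    "docetaxel", "tdm1", "palliative_care", "u_progression_free",
    "u_response", "u_progressed", "du_progression", "discount_weekly",
)


def load_parameters(
    source: str | Path | None = None, scenario: str = "base_case"
) -> ParameterSet:
    """Load a validated :class:`ParameterSet` for one scenario.

    Parameters
    ----------
    source
        Directory holding a ``manifest.yaml`` plus the parameter CSVs it
        names.  ``None`` loads the packaged tables.
    scenario
        ``"base_case"`` or ``"no_wastage"``.
    """
    root = Path(source) if source is not None else data_path()
    manifest_file = root / "manifest.yaml"
    if not manifest_file.exists():
        raise ConfigurationError(f"no manifest.yaml under {root}")
    manifest = yaml.safe_load(manifest_file.read_text())
    scenarios = manifest.get("scenarios", {})
    if scenario not in scenarios:
        raise ConfigurationError(
            f"unknown scenario {scenario!r}; manifest defines {sorted(scenarios)}"
        )
    params: dict[str, ParamValue] = {}
    for fname in scenarios[scenario]:
        params.update(_read_param_csv(root / fname))
    missing = [n for n in _REQUIRED if n not in params]
    if missing:
        raise SchemaError(f"scenario {scenario!r} lacks parameters: {missing}")
    patient_cfg = manifest.get("patient", {})
    patient = PatientProfile(
        weight=float(patient_cfg.get("weight_kg", 58.1)),
        bsa=float(patient_cfg.get("bsa_m2", 1.59)),
    )
    return ParameterSet(scenario=scenario, params=params, patient=patient)


def dsa_bounds(baseline: float, rule: float) -> tuple[float, float]:
    """Symmetric deterministic-SA bounds baseline × (1 ∓ rule).

    ``rule`` is the fractional half-width, e.g. 0.25 for a ±25% band.
    """
    if not math.isfinite(baseline):
        raise ValueError("baseline must be finite")
    if not 0 < rule < 1:
        raise ValueError(f"rule must lie in (0, 1), got {rule}")
    return baseline * (1 - rule), baseline * (1 + rule)


def psa_sd(low: float, high: float) -> float:
    """PSA standard deviation (high − low)/4, reading the bounds as ±2 SD."""
    if high < low:
        raise ValueError(f"high ({high}) < low ({low})")
    return (high - low) / 4.0


_RULES = {"rule25": 0.25, "rule50": 0.50}


@dataclass
class ValidationReport:
    """Outcome of :func:`validate`: hard violations plus provenance notes."""

    violations: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [f"violation: {v}" for v in self.violations]
        lines += [f"note: {n}" for n in self.notes]
        return "\n".join(lines) or "ok"


def validate(paramset: ParameterSet, sd_rtol: float = 1e-3) -> ValidationReport:
    """Check ordering, sign and SD-rule invariants; report, never raise.

    The SD rule is checked against ``baseline × rule/2`` for ±rule rows
    (their printed bounds are display-rounded) and against
    ``(high − low)/4`` for "calculated" rows; regression-derived survival
    rows carry standard errors and are exempt.
    """
    report = ValidationReport()
    if len(paramset) == 0:
        report.violations.append("parameter set is empty")
        return report
    for p in paramset:
        if p.note:
            report.notes.append(f"{p.name}: {p.note}")
        if p.has_bounds and not (p.low <= p.baseline <= p.high):
            report.violations.append(
                f"{p.name}: bounds not ordered (low={p.low}, "
                f"baseline={p.baseline}, high={p.high})"
            )
        if math.isfinite(p.sd) and p.sd < 0:
            report.violations.append(f"{p.name}: sd {p.sd} < 0")
        expected_sd = None
        if p.assumption in _RULES:
            expected_sd = abs(p.baseline) * _RULES[p.assumption] / 2.0
        elif p.assumption == "calculated" and p.has_bounds:
            expected_sd = psa_sd(p.low, p.high)
        if (
            expected_sd is not None
            and math.isfinite(p.sd)
            and expected_sd > 0
            and abs(p.sd - expected_sd) / expected_sd > sd_rtol
        ):
            report.violations.append(
                f"{p.name}: sd {p.sd} deviates from rule value "
                f"{expected_sd:.6g} by more than {sd_rtol:.1%}"
            )
    return report


def load_yaml(filename: str, source: str | Path | None = None) -> dict:
    """Read one of the packaged YAML configuration files."""
    root = Path(source) if source is not None else data_path()
    return yaml.safe_load((root / filename).read_text())
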