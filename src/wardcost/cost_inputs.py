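"""Priced model inputs: unit costs, inflation, and configuration ingestion.

All currency amounts are GBP and are carried at full floating precision;
rounding to whole pounds is a report-time concern only.  Fiscal-year labels
("2021/22") are opaque strings — no date arithmetic is attempted.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .staffing import ActivityProfile, StaffRole

__all__ = [
    "UnitCost",
    "InflationIndex",
    "ModelInputs",
    "ConfigError",
    "load_config",
    "inflate_cost",
    "default_config_path",
]

DEFAULT_HORIZON_DAYS = 30
DEFAULT_DSA_FRACTION = 0.15


class ConfigError(ValueError):
    """Raised when a configuration file is missing keys or fails validation."""


@dataclass(frozen=True)
class UnitCost:
    """A priced resource with currency-year provenance.

    ``amount`` is always non-negative: savings are a sign applied at costing
    time, never stored on the price itself.
    """

    label: str
    amount: float
    currency_year: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ConfigError(
                f"unit cost {self.label!r} has negative amount {self.amount}"
            )


@dataclass(frozen=True)
class InflationIndex:
    """Map of fiscal-year label -> positive index value."""

    values: Mapping[str, float]

    def __post_init__(self) -> None:
        for year, value in self.values.items():
            if value <= 0:
                raise ConfigError(f"inflation index for {year!r} must be > 0, got {value}")

    def __contains__(self, year: str) -> bool:
        return year in self.values

    def __getitem__(self, year: str) -> float:
        try:
            return self.values[year]
        except KeyError:
            raise KeyError(f"fiscal year {year!r} not present in inflation index") from None


def inflate_cost(amount: float, from_year: str, to_year: str, index: InflationIndex) -> float:
    """Re-price ``amount`` from one fiscal year to another.

    Returns ``amount * index[to_year] / index[from_year]``.  Identity when the
    two years are equal, even if absent from the index.
    """
    if from_year == to_year:
        return amount
    return amount * index[to_year] / index[from_year]


@dataclass
class ModelInputs:
    """Fully validated bundle of everything the costing model consumes."""

    unit_costs: dict[str, UnitCost]
    staff_roles: dict[str, StaffRole]
    activities: dict[str, ActivityProfile]
    cohort_size: int
    observed_months: float
    fixed_costs: dict[str, float] = field(default_factory=dict)
    setup_costs: dict[str, float] = field(default_factory=dict)
    horizon_days: int = DEFAULT_HORIZON_DAYS
    dsa_fraction: float = DEFAULT_DSA_FRACTION
    inflation_index: InflationIndex | None = None
    calibration_targets: dict[str, dict[str, float]] = field(default_factory=dict)
    synthetic: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.cohort_size <= 0:
            raise ConfigError(f"cohort size must be > 0, got {self.cohort_size}")
        if not (0 < self.observed_months <= 12):
            raise ConfigError(
                f"observation window must be in (0, 12] months, got {self.observed_months}"
            )
        if self.horizon_days <= 0:
            raise ConfigError(f"horizon must be > 0 days, got {self.horizon_days}")
        if not (0 <= self.dsa_fraction < 1):
            raise ConfigError(f"DSA fraction must be in [0, 1), got {self.dsa_fraction}")
        for bucket_name, bucket in (("fixed", self.fixed_costs), ("setup", self.setup_costs)):
            for category, amount in bucket.items():
                if amount < 0:
                    raise ConfigError(
                        f"{bucket_name} cost {category!r} is negative ({amount})"
                    )
        overlap = set(self.fixed_costs) & set(self.setup_costs)
        if overlap:
            raise ConfigError(
                "cost categories must appear in exactly one of fixed/setup buckets; "
                f"duplicated: {sorted(overlap)}"
            )

    @property
    def fixed_total(self) -> float:
        return float(sum(self.fixed_costs.values()))

    @property
    def setup_total(self) -> float:
        return float(sum(self.setup_costs.values()))

    def unit_cost(self, label: str) -> float:
        try:
            return self.unit_costs[label].amount
        except KeyError:
            raise KeyError(f"no unit cost configured for {label!r}") from None

    def to_dict(self) -> dict:
        """Serialize to the same nested structure the config file uses."""
        out: dict = {
            "unit_costs": {
                label: {
                    "amount": uc.amount,
                    "currency_year": uc.currency_year,
                    "source": uc.source,
                }
                for label, uc in self.unit_costs.items()
            },
            "staff_roles": {
                label: {"annual_cost": r.annual_cost, "annual_hours": r.annual_hours}
                for label, r in self.staff_roles.items()
            },
            "activities": {
                label: _activity_to_dict(a) for label, a in self.activities.items()
            },
            "fixed_costs": dict(self.fixed_costs),
            "setup_costs": dict(self.setup_costs),
            "cohort": {"size": self.cohort_size, "observed_months": self.observed_months},
            "horizon_days": self.horizon_days,
            "dsa_fraction": self.dsa_fraction,
        }
        if self.inflation_index is not None:
            out["inflation_index"] = dict(self.inflation_index.values)
        if self.calibration_targets:
            out["calibration_targets"] = {
                arm: dict(targets) for arm, targets in self.calibration_targets.items()
            }
        if self.synthetic:
            out["synthetic"] = dict(self.synthetic)
        return out

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _activity_to_dict(activity: ActivityProfile) -> dict:
    d: dict = {"duration_min": activity.duration_min}
    if activity.staff_mix:
        d["staff_mix"] = dict(activity.staff_mix)
    if activity.cost_per_minute is not None:
        d["cost_per_minute"] = activity.cost_per_minute
    return d


def default_config_path() -> Path:
    """Path of the configuration shipped with the package."""
    return Path(importlib.resources.files("wardcost") / "data" / "default_config.yaml")


def _require(section: Mapping, key: str, where: str):
    if key not in section:
        raise ConfigError(f"missing required key {key!r} in {where}")
    return section[key]


def load_config(path: str | Path | None = None) -> ModelInputs:
    """Load and validate a model configuration file (YAML).

    With ``path=None`` the packaged default configuration is loaded.  Raises
    :class:`ConfigError` naming the offending key on schema or validation
    failure.
    """
    path = default_config_path() if path is None else Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"configuration root must be a mapping, got {type(raw).__name__}")

    unit_costs: dict[str, UnitCost] = {}
    for label, entry in _require(raw, "unit_costs", "configuration").items():
        if isinstance(entry, (int, float)):
            entry = {"amount": entry}
        unit_costs[label] = UnitCost(
            label=label,
            amount=float(_require(entry, "amount", f"unit_costs.{label}")),
            currency_year=str(entry.get("currency_year", "")),
            source=str(entry.get("source", "")),
        )

    staff_roles: dict[str, StaffRole] = {}
    for label, entry in raw.get("staff_roles", {}).items():
        staff_roles[label] = StaffRole(
            label=label,
            annual_cost=float(_require(entry, "annual_cost", f"staff_roles.{label}")),
            annual_hours=float(_require(entry, "annual_hours", f"staff_roles.{label}")),
        )

    activities: dict[str, ActivityProfile] = {}
    for label, entry in raw.get("activities", {}).items():
        activities[label] = ActivityProfile(
            label=label,
            duration_min=float(_require(entry, "duration_min", f"activities.{label}")),
            staff_mix=dict(entry.get("staff_mix", {})),
            cost_per_minute=(
                float(entry["cost_per_minute"]) if "cost_per_minute" in entry else None
            ),
        )

    cohort = _require(raw, "cohort", "configuration")
    known_keys = {
        "unit_costs", "staff_roles", "activities", "fixed_costs", "setup_costs",
        "cohort", "horizon_days", "dsa_fraction", "inflation_index",
        "calibration_targets", "synthetic",
    }
    unknown = set(raw) - known_keys
    if unknown:
        raise ConfigError(f"unknown configuration section(s): {sorted(unknown)}")

    for bucket in ("fixed_costs", "setup_costs"):
        for category, amount in raw.get(bucket, {}).items():
            if not isinstance(amount, (int, float)):
                raise ConfigError(f"{bucket}.{category} must be a number, got {amount!r}")

    index = None
    if "inflation_index" in raw:
        index = InflationIndex({str(k): float(v) for k, v in raw["inflation_index"].items()})

    return ModelInputs(
        unit_costs=unit_costs,
        staff_roles=staff_roles,
        activities=activities,
        cohort_size=int(_require(cohort, "size", "cohort")),
        observed_months=float(_require(cohort, "observed_months", "cohort")),
        fixed_costs={k: float(v) for k, v in raw.get("fixed_costs", {}).items()},
        setup_costs={k: float(v) for k, v in raw.get("setup_costs", {}).items()},
        horizon_days=int(raw.get("horizon_days", DEFAULT_HORIZON_DAYS)),
        dsa_fraction=float(raw.get("dsa_fraction", DEFAULT_DSA_FRACTION)),
        inflation_index=index,
        calibration_targets={
            arm: {k: float(v) for k, v in targets.items()}
            for arm, targets in raw.get("calibration_targets", {}).items()
        },
        synthetic=dict(raw.get("synthetic", {})),
    )
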