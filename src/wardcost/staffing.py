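"""Staff cost-per-minute derivation and timed-activity costing.

A staff role's per-minute rate comes from its total annual employment cost
(wages, on-costs, qualifications, training, overheads) divided by annual
working minutes.  An activity is costed as duration times a blended per-minute
rate — either an explicit override or a staff-mix weighted average.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

__all__ = ["StaffRole", "ActivityProfile", "cost_per_minute", "activity_cost"]

_MIX_TOL = 1e-9


@dataclass(frozen=True)
class StaffRole:
    label: str
    annual_cost: float
    annual_hours: float

    def __post_init__(self) -> None:
        if self.annual_hours <= 0:
            raise ValueError(
                f"staff role {self.label!r}: annual working hours must be > 0"
            )
        if self.annual_cost < 0:
            raise ValueError(f"staff role {self.label!r}: annual cost must be >= 0")


@dataclass(frozen=True)
class ActivityProfile:
    """A timed activity performed by a mix of staff roles.

    ``staff_mix`` maps role label -> proportion (summing to 1).  When the
    blended rate is known directly (e.g. a published per-minute figure),
    ``cost_per_minute`` overrides the mix.
    """

    label: str
    duration_min: float
    staff_mix: Mapping[str, float] = field(default_factory=dict)
    cost_per_minute: float | None = None

    def __post_init__(self) -> None:
        if self.duration_min <= 0:
            raise ValueError(f"activity {self.label!r}: duration must be > 0 minutes")
        if self.staff_mix:
            if any(p < 0 for p in self.staff_mix.values()):
                raise ValueError(f"activity {self.label!r}: negative mix proportion")
            total = sum(self.staff_mix.values())
            if abs(total - 1.0) > _MIX_TOL:
                raise ValueError(
                    f"activity {self.label!r}: staff mix sums to {total}, expected 1"
                )
        elif self.cost_per_minute is None:
            raise ValueError(
                f"activity {self.label!r}: needs a staff mix or an override rate"
            )
        if self.cost_per_minute is not None and self.cost_per_minute < 0:
            raise ValueError(f"activity {self.label!r}: negative per-minute rate")


def cost_per_minute(role: StaffRole) -> float:
    """GBP per working minute: annual cost / (annual hours x 60)."""
    return role.annual_cost / (role.annual_hours * 60.0)


def activity_cost(profile: ActivityProfile, roles: Mapping[str, StaffRole]) -> float:
    """Cost of one occurrence of an activity.

    Uses the override per-minute rate when set; otherwise blends the
    per-minute rates of the staff mix.  Raises ``KeyError`` if a mix role is
    missing from ``roles`` and no override exists.
    """
    if profile.cost_per_minute is not None:
        rate = profile.cost_per_minute
    else:
        rate = 0.0
        for role_label, proportion in profile.staff_mix.items():
            if role_label not in roles:
                raise KeyError(
                    f"activity {profile.label!r} references unknown staff role "
                    f"{role_label!r} and has no override rate"
                )
            rate += proportion * cost_per_minute(roles[role_label])
    return profile.duration_min * rate
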