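"""One-way deterministic sensitivity analysis and break-even threshold analysis.

Both operate on the deterministic expected-value form of the model: per
patient, every event count is replaced by its mean, which makes the
incremental cost an exact function of the inputs and the calibrated rates —
no Monte Carlo noise in the tornado.

Parameter labels address scalars in the model state:

- ``unit_cost.<label>``       one priced resource (e.g. ``unit_cost.admission``)
- ``rate.<field>``            one EventRates field (e.g. ``rate.vw_home_visits``)
- ``fixed_costs``             all annual fixed categories, scaled together
- ``setup_costs``             all one-off set-up categories, scaled together
- ``activity.<label>.duration``  one activity's duration in minutes
"""

from __future__ import annotations

import copy
import dataclasses
import math
from dataclasses import dataclass

from .cost_inputs import ModelInputs
from .staffing import activity_cost
from .synthetic_cohort import EventRates

__all__ = [
    "DsaResult",
    "BreakevenResult",
    "expected_vw_per_patient",
    "expected_sc_per_patient",
    "expected_incremental_per_patient",
    "one_way_dsa",
    "breakeven",
    "breakeven_threshold",
]


def expected_vw_per_patient(inputs: ModelInputs, rates: EventRates) -> float:
    """Expected virtual-ward cost per annualized patient (shares included)."""
    shared = (inputs.fixed_total + inputs.setup_total) / inputs.cohort_size
    return shared + _expected_vw_variable(inputs, rates)


def _expected_vw_variable(inputs: ModelInputs, rates: EventRates) -> float:
    visit_cost = activity_cost(inputs.activities["home_visit"], inputs.staff_roles)
    call_cost = activity_cost(inputs.activities["virtual_call"], inputs.staff_roles)
    return (
        inputs.unit_cost("home_monitoring")
        + inputs.unit_cost("home_setup")
        + rates.vw_home_visits * visit_cost
        + rates.vw_calls * call_cost
        + rates.vw_poc_tests * inputs.unit_cost("poc_test")
        + rates.vw_ed_probability * inputs.unit_cost("ed_attendance")
        + rates.vw_readmission_probability * inputs.unit_cost("admission")
        + rates.vw_nhs111_rate * inputs.unit_cost("nhs111_contact")
        - rates.bed_days_saved_mean * inputs.unit_cost("excess_bed_day")
    )


def expected_sc_per_patient(inputs: ModelInputs, rates: EventRates) -> float:
    """Expected standard-care cost per patient."""
    return (
        rates.sc_outpatient_rate * inputs.unit_cost("outpatient_appointment")
        + rates.sc_ed_probability * inputs.unit_cost("ed_attendance")
        + rates.step_up_proportion * inputs.unit_cost("admission")
        + rates.sc_readmission_probability * inputs.unit_cost("admission")
        + rates.sc_nhs111_rate * inputs.unit_cost("nhs111_contact")
    )


def expected_incremental_per_patient(inputs: ModelInputs, rates: EventRates) -> float:
    return expected_vw_per_patient(inputs, rates) - expected_sc_per_patient(inputs, rates)


@dataclass(frozen=True)
class DsaResult:
    parameter: str
    base: float
    low: float
    high: float
    incremental_low: float
    incremental_high: float

    @property
    def spread(self) -> float:
        return abs(self.incremental_high - self.incremental_low)

    @property
    def sign_flip(self) -> bool:
        lo = min(self.incremental_low, self.incremental_high)
        hi = max(self.incremental_low, self.incremental_high)
        return lo < 0 < hi


@dataclass(frozen=True)
class BreakevenResult:
    """Smallest annual patient volume at which the ward stops costing extra."""

    threshold: int | None
    per_patient_saving: float
    burden: float  # one-off set-up plus annual fixed costs

    @property
    def reachable(self) -> bool:
        return self.threshold is not None


@dataclass
class _Scenario:
    inputs: ModelInputs
    rates: EventRates

    def incremental(self) -> float:
        return expected_incremental_per_patient(self.inputs, self.rates)


def _get_set(scenario: _Scenario, label: str):
    """Resolve a parameter label to (current value, setter)."""
    if label.startswith("unit_cost."):
        name = label[len("unit_cost."):]
        if name not in scenario.inputs.unit_costs:
            raise KeyError(f"unknown unit cost {name!r} in DSA parameter {label!r}")

        def set_unit(v: float) -> None:
            uc = scenario.inputs.unit_costs[name]
            scenario.inputs.unit_costs[name] = dataclasses.replace(uc, amount=v)

        return scenario.inputs.unit_costs[name].amount, set_unit

    if label.startswith("rate."):
        name = label[len("rate."):]
        if not hasattr(scenario.rates, name):
            raise KeyError(f"unknown rate {name!r} in DSA parameter {label!r}")

        def set_rate(v: float) -> None:
            scenario.rates = scenario.rates.replace(**{name: v})

        return getattr(scenario.rates, name), set_rate

    if label in ("fixed_costs", "setup_costs"):
        bucket = getattr(scenario.inputs, label)
        base = float(sum(bucket.values()))

        def set_bucket(v: float) -> None:
            scale = v / base if base else 0.0
            for key in bucket:
                bucket[key] *= scale

        return base, set_bucket

    if label.startswith("activity.") and label.endswith(".duration"):
        name = label[len("activity."):-len(".duration")]
        if name not in scenario.inputs.activities:
            raise KeyError(f"unknown activity {name!r} in DSA parameter {label!r}")

        def set_duration(v: float) -> None:
            act = scenario.inputs.activities[name]
            scenario.inputs.activities[name] = dataclasses.replace(act, duration_min=v)

        return scenario.inputs.activities[name].duration_min, set_duration

    raise KeyError(f"unresolvable DSA parameter label {label!r}")


def one_way_dsa(
    inputs: ModelInputs,
    rates: EventRates,
    parameters: list[str],
    fraction: float | None = None,
) -> list[DsaResult]:
    """Vary each parameter alone by ±fraction and record the incremental cost.

    Results come back in tornado order: spread descending, ties broken by
    parameter label.  ``fraction`` defaults to the configured DSA fraction and
    must lie strictly in (0, 1).
    """
    if fraction is None:
        fraction = inputs.dsa_fraction
    if not (0 < fraction < 1):
        raise ValueError(f"DSA fraction must be in (0, 1), got {fraction}")

    results: list[DsaResult] = []
    for label in parameters:
        base, _ = _get_set(_Scenario(copy.deepcopy(inputs), rates), label)
        row = {}
        for bound, factor in (("low", 1.0 - fraction), ("high", 1.0 + fraction)):
            scenario = _Scenario(copy.deepcopy(inputs), rates)
            _, setter = _get_set(scenario, label)
            setter(base * factor)
            row[bound] = scenario.incremental()
        results.append(
            DsaResult(
                parameter=label,
                base=base,
                low=base * (1.0 - fraction),
                high=base * (1.0 + fraction),
                incremental_low=row["low"],
                incremental_high=row["high"],
            )
        )
    return sorted(results, key=lambda r: (-r.spread, r.parameter))


def breakeven_threshold(burden: float, per_patient_saving: float) -> int | None:
    """Smallest integer n >= 1 with burden - n * saving <= 0, or None.

    Closed form (ceiling of burden / saving) with a boundary correction so
    the result agrees exactly with a brute-force scan under floating-point
    arithmetic.
    """
    if per_patient_saving <= 0:
        return None
    n = max(1, math.ceil(burden / per_patient_saving))
    while n > 1 and burden - (n - 1) * per_patient_saving <= 0:
        n -= 1
    while burden - n * per_patient_saving > 0:
        n += 1
    return n


def breakeven(inputs: ModelInputs, rates: EventRates) -> BreakevenResult:
    """Annual patient volume at which ward and standard-care costs are equal.

    The fixed-plus-set-up burden is recouped at the per-patient net variable
    saving (standard-care cost minus the ward's variable cost per patient).
    Flagged unreachable when that saving is non-positive.
    """
    burden = inputs.setup_total + inputs.fixed_total
    saving = expected_sc_per_patient(inputs, rates) - _expected_vw_variable(inputs, rates)
    return BreakevenResult(
        threshold=breakeven_threshold(burden, saving),
        per_patient_saving=saving,
        burden=burden,
    )
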