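"""Arm-level aggregation, incremental costs, and component decomposition.

Produces the three result surfaces of the model: the headline summary
(population and per-patient totals per arm with the incremental column),
the cost-type breakdown (set-up / fixed / variable), and the per-patient
component decomposition.  Aggregation is at full precision; whole-pound
rounding (half away from zero) is applied only by the report writers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .cost_inputs import ModelInputs
from .pathway_costing import CostBreakdown, DIRECT_COMPONENTS, INDIRECT_COMPONENTS

__all__ = [
    "ArmSummary",
    "IncrementalResult",
    "summarize_arm",
    "incremental",
    "decompose",
    "round_pounds",
    "format_pounds",
]


def round_pounds(x: float) -> int:
    """Round to whole pounds, half away from zero."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def format_pounds(x: float) -> str:
    """Report formatting: whole pounds, thousands separator, leading minus."""
    r = round_pounds(x)
    return f"-£{abs(r):,}" if r < 0 else f"£{r:,}"


@dataclass(frozen=True)
class ArmSummary:
    """Cost-type totals for one arm of the model.

    ``population_total`` and ``per_patient_total`` are derived, preserving the
    identities population = setup + fixed + variable and per-patient =
    population / cohort size at full precision.
    """

    setup_total: float
    fixed_total: float
    variable_total: float
    cohort_size: int

    def __post_init__(self) -> None:
        if self.cohort_size <= 0:
            raise ValueError(f"cohort size must be > 0, got {self.cohort_size}")

    @property
    def population_total(self) -> float:
        return self.setup_total + self.fixed_total + self.variable_total

    @property
    def per_patient_total(self) -> float:
        return self.population_total / self.cohort_size


@dataclass(frozen=True)
class IncrementalResult:
    """VW-minus-SC cost differences; negative values mean the ward saves money."""

    vw: ArmSummary
    sc: ArmSummary

    @property
    def population(self) -> float:
        return self.vw.population_total - self.sc.population_total

    @property
    def per_patient(self) -> float:
        return self.population / self.vw.cohort_size


def summarize_arm(
    breakdowns: Sequence[CostBreakdown],
    inputs: ModelInputs,
    arm: str,
    annualization_factor: float = 1.0,
    n_annual: int | None = None,
) -> ArmSummary:
    """Aggregate per-patient breakdowns into cost-type totals for one arm.

    Variable cost is the sum of per-patient event-driven costs, scaled by the
    annualization factor; annual fixed and one-off set-up totals come from the
    model inputs for the virtual-ward arm and are zero for standard care.
    """
    if arm not in ("vw", "sc"):
        raise ValueError(f"arm must be 'vw' or 'sc', got {arm!r}")
    if not breakdowns:
        raise ValueError("cannot summarize an empty arm")
    if annualization_factor <= 0:
        raise ValueError("annualization factor must be > 0")
    variable = annualization_factor * sum(b.variable_total for b in breakdowns)
    if n_annual is None:
        n_annual = int(round(annualization_factor * len(breakdowns)))
    if arm == "vw":
        return ArmSummary(
            setup_total=inputs.setup_total,
            fixed_total=inputs.fixed_total,
            variable_total=variable,
            cohort_size=n_annual,
        )
    return ArmSummary(
        setup_total=0.0, fixed_total=0.0, variable_total=variable, cohort_size=n_annual
    )


def incremental(vw: ArmSummary, sc: ArmSummary) -> IncrementalResult:
    """Incremental result; the two arms must describe equally sized cohorts."""
    if vw.cohort_size != sc.cohort_size:
        raise ValueError(
            f"cohort-size mismatch: vw={vw.cohort_size}, sc={sc.cohort_size}"
        )
    return IncrementalResult(vw=vw, sc=sc)


_TOTAL_ROWS = ("total_direct", "total_indirect", "total")


def decompose(
    vw_breakdowns: Sequence[CostBreakdown],
    sc_breakdowns: Sequence[CostBreakdown],
) -> pd.DataFrame:
    """Mean per-patient cost of every component in each arm, plus deltas.

    Returns a frame indexed by component (direct components, ``total_direct``,
    indirect components, ``total_indirect``, ``total``) with columns
    ``vw``, ``sc``, ``incremental``.  Component deltas sum to the total delta
    at full precision.
    """
    if not vw_breakdowns or not sc_breakdowns:
        raise ValueError("both arms must contain at least one costed patient")

    def arm_means(breakdowns: Sequence[CostBreakdown]) -> dict[str, float]:
        n = len(breakdowns)
        means: dict[str, float] = {}
        for comp in DIRECT_COMPONENTS:
            means[comp] = sum(b.direct[comp] for b in breakdowns) / n
        means["total_direct"] = sum(means[c] for c in DIRECT_COMPONENTS)
        for comp in INDIRECT_COMPONENTS:
            means[comp] = sum(b.indirect[comp] for b in breakdowns) / n
        means["total_indirect"] = sum(means[c] for c in INDIRECT_COMPONENTS)
        means["total"] = means["total_direct"] + means["total_indirect"]
        return means

    vw = arm_means(vw_breakdowns)
    sc = arm_means(sc_breakdowns)
    rows = (
        list(DIRECT_COMPONENTS)
        + ["total_direct"]
        + list(INDIRECT_COMPONENTS)
        + ["total_indirect", "total"]
    )
    frame = pd.DataFrame(
        {
            "vw": [vw[r] for r in rows],
            "sc": [sc[r] for r in rows],
        },
        index=pd.Index(rows, name="component"),
    )
    frame["incremental"] = frame["vw"] - frame["sc"]
    return frame
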