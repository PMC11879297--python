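"""Patient-level pathway costing for the virtual-ward and standard-care arms.

The unit of analysis is a :class:`PatientEpisode`: one ward admission plus the
resource-use events observed in a post-discharge window.  Costing follows a
fixed component chart:

direct (virtual-ward arm only)
    platform share, set-up share, home monitoring, POC testing, home visits,
    home set-up, phone/virtual calls
indirect
    outpatient appointments, ED attendances, initial hospital admission
    (step-up counterfactual), readmissions, excess-bed-day savings
    (step-down, negative in the VW arm), NHS 111 contacts

Accounting conventions: the avoided inpatient stay of step-down patients
appears as a *negative* VW-arm component, never as a positive standard-care
cost; step-up counterfactuals carry the full non-elective admission cost.
Day 0 is the day of discharge and the horizon test is inclusive
(offset <= horizon).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import pandas as pd

from .cost_inputs import ModelInputs
from .staffing import activity_cost

__all__ = [
    "EVENT_KINDS",
    "DIRECT_COMPONENTS",
    "INDIRECT_COMPONENTS",
    "Event",
    "PatientEpisode",
    "CostBreakdown",
    "apply_horizon",
    "annualize",
    "cost_vw_patient",
    "cost_sc_patient",
    "episodes_to_frames",
    "frames_to_episodes",
]

EVENT_KINDS = frozenset(
    {
        "home_visit_routine",
        "home_visit_rapid",
        "virtual_call",
        "poc_test",
        "ed_attendance",
        "readmission",
        "nhs111_contact",
        "outpatient_appointment",
    }
)

DIRECT_COMPONENTS = (
    "vw_platform_share",
    "setup_share",
    "home_monitoring",
    "poc_testing",
    "home_visits",
    "home_setup",
    "calls",
)

INDIRECT_COMPONENTS = (
    "outpatient",
    "ed_visits",
    "initial_admission",
    "readmission",
    "excess_bed_day_savings",
    "nhs111",
)


@dataclass(frozen=True)
class Event:
    kind: str
    day: int  # offset from discharge; day 0 = day of discharge

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.day < 0:
            raise ValueError(f"event day offset must be >= 0, got {self.day}")


@dataclass(frozen=True)
class PatientEpisode:
    id: str
    pathway: str  # "step_up" | "step_down"
    age: float
    gender: str  # "F" | "M"
    diagnosis: str  # ICD-10 code
    vw_length_of_stay: float = 0.0
    bed_days_saved: float = 0.0
    events: tuple[Event, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.pathway not in ("step_up", "step_down"):
            raise ValueError(f"pathway must be step_up or step_down, got {self.pathway!r}")
        if self.bed_days_saved < 0:
            raise ValueError("bed_days_saved must be >= 0")
        if self.pathway == "step_up" and self.bed_days_saved != 0:
            raise ValueError("step_up episodes cannot save bed days")
        if self.vw_length_of_stay < 0:
            raise ValueError("vw_length_of_stay must be >= 0")
        object.__setattr__(self, "events", tuple(self.events))

    def count(self, *kinds: str) -> int:
        return sum(1 for e in self.events if e.kind in kinds)


@dataclass(frozen=True)
class CostBreakdown:
    """Per-patient cost decomposition; totals are exact component sums."""

    direct: dict[str, float]
    indirect: dict[str, float]

    def __post_init__(self) -> None:
        for name, chart, given in (
            ("direct", DIRECT_COMPONENTS, self.direct),
            ("indirect", INDIRECT_COMPONENTS, self.indirect),
        ):
            unknown = set(given) - set(chart)
            if unknown:
                raise ValueError(f"unknown {name} component(s): {sorted(unknown)}")
        object.__setattr__(
            self, "direct", {c: float(self.direct.get(c, 0.0)) for c in DIRECT_COMPONENTS}
        )
        object.__setattr__(
            self,
            "indirect",
            {c: float(self.indirect.get(c, 0.0)) for c in INDIRECT_COMPONENTS},
        )

    @property
    def direct_total(self) -> float:
        return sum(self.direct.values())

    @property
    def indirect_total(self) -> float:
        return sum(self.indirect.values())

    @property
    def overall(self) -> float:
        return self.direct_total + self.indirect_total

    @property
    def shared_total(self) -> float:
        """Fixed + set-up shares — the non-variable part of the direct bucket."""
        return self.direct["vw_platform_share"] + self.direct["setup_share"]

    @property
    def variable_total(self) -> float:
        """Event-driven cost: everything except the fixed/set-up shares."""
        return self.overall - self.shared_total


def apply_horizon(episode: PatientEpisode, horizon: int) -> PatientEpisode:
    """Drop events beyond the post-discharge horizon (inclusive at the bound).

    Idempotent; all non-event fields are unchanged.
    """
    if horizon <= 0:
        raise ValueError(f"horizon must be > 0 days, got {horizon}")
    kept = tuple(e for e in episode.events if e.day <= horizon)
    if len(kept) == len(episode.events):
        return episode
    return replace(episode, events=kept)


def annualize(
    cohort: Sequence[PatientEpisode], observed_months: float
) -> tuple[float, int]:
    """Scale factor and extrapolated cohort size for a partial observation year.

    Returns ``(12 / observed_months, round(n * factor))``.  The factor applies
    to cohort-level totals (costs, counts, patient numbers); patient-level
    records are never duplicated.
    """
    if observed_months <= 0:
        raise ValueError(f"observed_months must be > 0, got {observed_months}")
    if observed_months > 12:
        raise ValueError(f"observed_months must be <= 12, got {observed_months}")
    factor = 12.0 / observed_months
    return factor, int(round(len(cohort) * factor))


def _event_counts(episode: PatientEpisode) -> dict[str, int]:
    counts = {kind: 0 for kind in EVENT_KINDS}
    for event in episode.events:
        counts[event.kind] += 1  # Event validates kind at construction
    return counts


def cost_vw_patient(
    episode: PatientEpisode, inputs: ModelInputs, n_annual: int
) -> CostBreakdown:
    """Cost one horizon-filtered virtual-ward episode.

    Shared annual fixed and one-off set-up costs are allocated equally across
    the ``n_annual`` annualized patients.  Monitoring-equipment and home
    set-up costs apply once per onboarded admission (length of stay > 0).
    Home visits and calls are microcosted via the staffing module; the
    outpatient and initial-admission components are zero in this arm by
    convention, and avoided bed days enter as a negative component for
    step-down patients.
    """
    if n_annual <= 0:
        raise ValueError(f"n_annual must be > 0, got {n_annual}")
    counts = _event_counts(episode)
    onboarded = episode.vw_length_of_stay > 0

    visit_cost = activity_cost(inputs.activities["home_visit"], inputs.staff_roles)
    call_cost = activity_cost(inputs.activities["virtual_call"], inputs.staff_roles)

    direct = {
        "vw_platform_share": inputs.fixed_total / n_annual,
        "setup_share": inputs.setup_total / n_annual,
        "home_monitoring": inputs.unit_cost("home_monitoring") if onboarded else 0.0,
        "poc_testing": counts["poc_test"] * inputs.unit_cost("poc_test"),
        "home_visits": (counts["home_visit_routine"] + counts["home_visit_rapid"])
        * visit_cost,
        "home_setup": inputs.unit_cost("home_setup") if onboarded else 0.0,
        "calls": counts["virtual_call"] * call_cost,
    }
    indirect = {
        "outpatient": 0.0,
        "ed_visits": counts["ed_attendance"] * inputs.unit_cost("ed_attendance"),
        "initial_admission": 0.0,
        "readmission": counts["readmission"] * inputs.unit_cost("admission"),
        "excess_bed_day_savings": -episode.bed_days_saved
        * inputs.unit_cost("excess_bed_day"),
        "nhs111": counts["nhs111_contact"] * inputs.unit_cost("nhs111_contact"),
    }
    return CostBreakdown(direct=direct, indirect=indirect)


def cost_sc_patient(episode: PatientEpisode, inputs: ModelInputs) -> CostBreakdown:
    """Cost one horizon-filtered standard-care counterfactual episode.

    The standard-care arm carries no direct ward costs.  Step-up
    counterfactuals incur the full non-elective admission they would have had;
    a step-down counterfactual's longer inpatient stay is accounted for as the
    VW arm's negative excess-bed-day component, so it is zero here.
    """
    counts = _event_counts(episode)
    indirect = {
        "outpatient": counts["outpatient_appointment"]
        * inputs.unit_cost("outpatient_appointment"),
        "ed_visits": counts["ed_attendance"] * inputs.unit_cost("ed_attendance"),
        "initial_admission": (
            inputs.unit_cost("admission") if episode.pathway == "step_up" else 0.0
        ),
        "readmission": counts["readmission"] * inputs.unit_cost("admission"),
        "excess_bed_day_savings": 0.0,
        "nhs111": counts["nhs111_contact"] * inputs.unit_cost("nhs111_contact"),
    }
    return CostBreakdown(direct={}, indirect=indirect)


def episodes_to_frames(
    episodes: Sequence[PatientEpisode],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Patient table (one row per patient) and long-format event table."""
    patients = pd.DataFrame(
        {
            "id": [e.id for e in episodes],
            "pathway": [e.pathway for e in episodes],
            "age": [e.age for e in episodes],
            "gender": [e.gender for e in episodes],
            "icd10": [e.diagnosis for e in episodes],
            "vw_length_of_stay": [e.vw_length_of_stay for e in episodes],
            "bed_days_saved": [e.bed_days_saved for e in episodes],
        }
    )
    events = pd.DataFrame(
        [
            {"id": e.id, "event_kind": ev.kind, "day": ev.day}
            for e in episodes
            for ev in e.events
        ],
        columns=["id", "event_kind", "day"],
    )
    return patients, events


def frames_to_episodes(
    patients: pd.DataFrame, events: pd.DataFrame
) -> list[PatientEpisode]:
    """Inverse of :func:`episodes_to_frames` (event order within patient kept)."""
    by_patient: dict[str, list[Event]] = {}
    for row in events.itertuples(index=False):
        by_patient.setdefault(str(row.id), []).append(
            Event(kind=str(row.event_kind), day=int(row.day))
        )
    out = []
    for row in patients.itertuples(index=False):
        out.append(
            PatientEpisode(
                id=str(row.id),
                pathway=str(row.pathway),
                age=float(row.age),
                gender=str(row.gender),
                diagnosis=str(row.icd10),
                vw_length_of_stay=float(row.vw_length_of_stay),
                bed_days_saved=float(row.bed_days_saved),
                events=tuple(by_patient.get(str(row.id), ())),
            )
        )
    return out
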