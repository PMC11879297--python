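"""Synthetic virtual-ward cohorts and control pools.

No patient-level data accompanies the model, so this module generates
cohorts with the statistical structure the analysis assumes: a step-up /
step-down mix, post-discharge events with day offsets, bed-days saved for
step-down patients, and an oversized control pool whose covariates overlap
the treated cohort (with a configurable shift, so matching has signal to
remove).

Rates are *within-horizon* per-patient means.  Event days are drawn from a
discrete uniform on ``0..event_day_max`` which deliberately extends past the
horizon; generation inflates each rate by the inverse probability of landing
inside the horizon, so that after horizon filtering the expected counts equal
the configured rates exactly (Poisson/Bernoulli thinning).

``calibrate_rates`` back-derives rates from target per-patient component
costs (rate = target cost / unit cost per event), which makes the full
pipeline reproduce a given per-patient cost decomposition in expectation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cost_inputs import ModelInputs
from .pathway_costing import Event, PatientEpisode
from .staffing import activity_cost

__all__ = ["EventRates", "CohortConfig", "calibrate_rates", "generate_cohort", "covariates_frame"]


@dataclass(frozen=True)
class EventRates:
    """Per-patient within-horizon resource-use means for both arms.

    ``*_probability`` fields are Bernoulli probabilities (at most one event
    per patient); the others are Poisson means.  ``bed_days_saved_mean`` is a
    cohort-wide mean — only step-down patients save bed days, so the
    conditional mean is this value divided by the step-down proportion.
    """

    vw_home_visits: float
    vw_calls: float
    vw_poc_tests: float
    vw_ed_probability: float
    vw_readmission_probability: float
    vw_nhs111_rate: float
    bed_days_saved_mean: float
    step_up_proportion: float
    sc_outpatient_rate: float
    sc_ed_probability: float
    sc_readmission_probability: float
    sc_nhs111_rate: float

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if value < 0:
                raise ValueError(f"rate {f.name} must be >= 0, got {value}")
        for f in (
            "vw_ed_probability",
            "vw_readmission_probability",
            "sc_ed_probability",
            "sc_readmission_probability",
            "step_up_proportion",
        ):
            value = getattr(self, f)
            if value > 1:
                raise ValueError(f"{f} is a probability, got {value}")

    def replace(self, **changes: float) -> "EventRates":
        return dataclasses.replace(self, **changes)


def calibrate_rates(
    targets: dict[str, dict[str, float]], inputs: ModelInputs
) -> EventRates:
    """Event rates implied by target per-patient component costs.

    ``targets`` has ``vw`` and ``sc`` sub-maps keyed by component label (the
    same labels the cost decomposition uses).  Each rate is the target cost
    divided by the per-event cost of that component; the step-up proportion
    falls out of the standard-care initial-admission component the same way.
    Raises ``ValueError`` on a zero per-event cost.
    """
    vw = targets.get("vw", {})
    sc = targets.get("sc", {})

    visit_cost = activity_cost(inputs.activities["home_visit"], inputs.staff_roles)
    call_cost = activity_cost(inputs.activities["virtual_call"], inputs.staff_roles)

    def ratio(target: float, unit: float, what: str) -> float:
        if unit <= 0:
            raise ValueError(f"cannot calibrate {what}: per-event cost is {unit}")
        return target / unit

    return EventRates(
        vw_home_visits=ratio(vw.get("home_visits", 0.0), visit_cost, "home visits"),
        vw_calls=ratio(vw.get("calls", 0.0), call_cost, "calls"),
        vw_poc_tests=ratio(vw.get("poc_testing", 0.0), inputs.unit_cost("poc_test"), "POC tests"),
        vw_ed_probability=ratio(
            vw.get("ed_visits", 0.0), inputs.unit_cost("ed_attendance"), "VW ED attendance"
        ),
        vw_readmission_probability=ratio(
            vw.get("readmission", 0.0), inputs.unit_cost("admission"), "VW readmission"
        ),
        vw_nhs111_rate=ratio(
            vw.get("nhs111", 0.0), inputs.unit_cost("nhs111_contact"), "VW NHS 111"
        ),
        bed_days_saved_mean=ratio(
            vw.get("excess_bed_day_savings", 0.0),
            inputs.unit_cost("excess_bed_day"),
            "bed days saved",
        ),
        step_up_proportion=ratio(
            sc.get("initial_admission", 0.0), inputs.unit_cost("admission"), "step-up proportion"
        ),
        sc_outpatient_rate=ratio(
            sc.get("outpatient", 0.0), inputs.unit_cost("outpatient_appointment"), "SC outpatient"
        ),
        sc_ed_probability=ratio(
            sc.get("ed_visits", 0.0), inputs.unit_cost("ed_attendance"), "SC ED attendance"
        ),
        sc_readmission_probability=ratio(
            sc.get("readmission", 0.0), inputs.unit_cost("admission"), "SC readmission"
        ),
        sc_nhs111_rate=ratio(
            sc.get("nhs111", 0.0), inputs.unit_cost("nhs111_contact"), "SC NHS 111"
        ),
    )


@dataclass
class CohortConfig:
    """Everything the generator needs, including the seed."""

    n_patients: int
    rates: EventRates
    seed: int
    observed_months: float = 6.0
    age_mean: float = 76.0
    age_sd: float = 11.0
    age_min: float = 40.0
    age_max: float = 99.0
    female_probability: float = 0.47
    diagnoses: dict[str, float] = field(
        default_factory=lambda: {"I50.0": 0.35, "I50.1": 0.25, "I50.9": 0.40}
    )
    control_pool_ratio: float = 2.0
    control_age_shift: float = 2.0
    event_day_max: int = 45
    horizon_days: int = 30
    mean_vw_length_of_stay: float = 7.0
    rapid_visit_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be > 0")
        for name in ("female_probability", "rapid_visit_fraction"):
            p = getattr(self, name)
            if not (0 <= p <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.event_day_max < self.horizon_days:
            raise ValueError("event_day_max must be >= horizon_days")
        if abs(sum(self.diagnoses.values()) - 1.0) > 1e-9:
            raise ValueError("diagnosis weights must sum to 1")

    @classmethod
    def from_inputs(
        cls, inputs: ModelInputs, seed: int, n_patients: int | None = None
    ) -> "CohortConfig":
        """Build the generator configuration from loaded model inputs.

        ``n_patients`` defaults to the observed fraction of the annual cohort
        (annual size scaled down by observed months / 12).
        """
        if n_patients is None:
            n_patients = int(round(inputs.cohort_size * inputs.observed_months / 12.0))
        rates = calibrate_rates(inputs.calibration_targets, inputs)
        syn = dict(inputs.synthetic)
        kwargs = {
            k: syn[k]
            for k in (
                "age_mean", "age_sd", "age_min", "age_max", "female_probability",
                "diagnoses", "control_pool_ratio", "control_age_shift",
                "event_day_max", "mean_vw_length_of_stay", "rapid_visit_fraction",
            )
            if k in syn
        }
        return cls(
            n_patients=n_patients,
            rates=rates,
            seed=seed,
            observed_months=inputs.observed_months,
            horizon_days=inputs.horizon_days,
            **kwargs,
        )

    @property
    def within_horizon_probability(self) -> float:
        """P(event day <= horizon) under the uniform day distribution."""
        return (self.horizon_days + 1) / (self.event_day_max + 1)


def _truncated_ages(
    rng: np.random.Generator, n: int, mean: float, sd: float, lo: float, hi: float
) -> np.ndarray:
    ages = rng.normal(mean, sd, size=n)
    return np.clip(ages, lo, hi).round(1)


def _draw_days(rng: np.random.Generator, n: int, day_max: int) -> np.ndarray:
    return rng.integers(0, day_max + 1, size=n)


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[PatientEpisode], list[PatientEpisode]]:
    """Generate ``(vw_cohort, control_pool)`` reproducibly from the seed.

    Returned episodes keep all generated events, including those past the
    horizon; horizon filtering is the pipeline's job.  The control pool is
    ``control_pool_ratio`` times larger than the cohort and carries
    standard-care resource use (outpatient, ED, readmission, NHS 111 events).
    """
    rng = np.random.default_rng(config.seed)
    r = config.rates
    p_in = config.within_horizon_probability

    def inflated_probability(p: float, what: str) -> float:
        p_gen = p / p_in
        if p_gen > 1:
            raise ValueError(
                f"{what}: probability {p} cannot be realised with only "
                f"{p_in:.3f} of event days inside the horizon"
            )
        return p_gen

    vw_cohort: list[PatientEpisode] = []
    step_down_prop = 1.0 - r.step_up_proportion
    bed_days_cond_mean = (
        r.bed_days_saved_mean / step_down_prop if step_down_prop > 0 else 0.0
    )
    ages = _truncated_ages(
        rng, config.n_patients, config.age_mean, config.age_sd,
        config.age_min, config.age_max,
    )
    for i in range(config.n_patients):
        step_up = rng.random() < r.step_up_proportion
        gender = "F" if rng.random() < config.female_probability else "M"
        diagnosis = str(
            rng.choice(list(config.diagnoses), p=list(config.diagnoses.values()))
        )
        los = 1.0 + float(rng.poisson(max(config.mean_vw_length_of_stay - 1.0, 0.0)))
        bed_days = 0.0 if step_up else float(rng.poisson(bed_days_cond_mean))

        events: list[Event] = []

        def add_count_events(kind: str, rate: float) -> None:
            n = rng.poisson(rate / p_in)
            for day in _draw_days(rng, n, config.event_day_max):
                events.append(Event(kind=kind, day=int(day)))

        n_visits = rng.poisson(r.vw_home_visits / p_in)
        for day in _draw_days(rng, n_visits, config.event_day_max):
            kind = (
                "home_visit_rapid"
                if rng.random() < config.rapid_visit_fraction
                else "home_visit_routine"
            )
            events.append(Event(kind=kind, day=int(day)))
        add_count_events("virtual_call", r.vw_calls)
        add_count_events("poc_test", r.vw_poc_tests)
        add_count_events("nhs111_contact", r.vw_nhs111_rate)
        if rng.random() < inflated_probability(r.vw_ed_probability, "VW ED attendance"):
            events.append(
                Event("ed_attendance", int(_draw_days(rng, 1, config.event_day_max)[0]))
            )
        if rng.random() < inflated_probability(
            r.vw_readmission_probability, "VW readmission"
        ):
            events.append(
                Event("readmission", int(_draw_days(rng, 1, config.event_day_max)[0]))
            )

        vw_cohort.append(
            PatientEpisode(
                id=f"vw{i:05d}",
                pathway="step_up" if step_up else "step_down",
                age=float(ages[i]),
                gender=gender,
                diagnosis=diagnosis,
                vw_length_of_stay=los,
                bed_days_saved=bed_days,
                events=tuple(events),
            )
        )

    n_controls = int(round(config.control_pool_ratio * config.n_patients))
    control_ages = _truncated_ages(
        rng, n_controls, config.age_mean + config.control_age_shift, config.age_sd,
        config.age_min, config.age_max,
    )
    control_pool: list[PatientEpisode] = []
    for i in range(n_controls):
        step_up = rng.random() < r.step_up_proportion
        gender = "F" if rng.random() < config.female_probability else "M"
        diagnosis = str(
            rng.choice(list(config.diagnoses), p=list(config.diagnoses.values()))
        )
        events = []

        def add_sc_events(kind: str, rate: float) -> None:
            n = rng.poisson(rate / p_in)
            for day in _draw_days(rng, n, config.event_day_max):
                events.append(Event(kind=kind, day=int(day)))

        add_sc_events("outpatient_appointment", r.sc_outpatient_rate)
        add_sc_events("nhs111_contact", r.sc_nhs111_rate)
        if rng.random() < inflated_probability(r.sc_ed_probability, "SC ED attendance"):
            events.append(
                Event("ed_attendance", int(_draw_days(rng, 1, config.event_day_max)[0]))
            )
        if rng.random() < inflated_probability(
            r.sc_readmission_probability, "SC readmission"
        ):
            events.append(
                Event("readmission", int(_draw_days(rng, 1, config.event_day_max)[0]))
            )
        control_pool.append(
            PatientEpisode(
                id=f"sc{i:05d}",
                pathway="step_up" if step_up else "step_down",
                age=float(control_ages[i]),
                gender=gender,
                diagnosis=diagnosis,
                vw_length_of_stay=0.0,
                bed_days_saved=0.0,
                events=tuple(events),
            )
        )

    return vw_cohort, control_pool


def covariates_frame(episodes: list[PatientEpisode]) -> pd.DataFrame:
    """Covariate table (id, age, gender, icd10) for the matching stage."""
    return pd.DataFrame(
        {
            "id": [e.id for e in episodes],
            "age": [e.age for e in episodes],
            "gender": [e.gender for e in episodes],
            "icd10": [e.diagnosis for e in episodes],
        }
    )
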