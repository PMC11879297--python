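import pytest

from wardcost import load_config
from wardcost.synthetic_cohort import calibrate_rates


@pytest.fixture(scope="session")
def default_inputs():
    return load_config()


@pytest.fixture(scope="session")
def default_rates(default_inputs):
    return calibrate_rates(default_inputs.calibration_targets, default_inputs)


@pytest.fixture
def tiny_config(tmp_path):
    """Write a minimal but complete config file and return its path."""

    def _write(**overrides):
        import yaml

        base = {
            "unit_costs": {
                "home_visit": {"amount": 102.0},
                "ed_attendance": {"amount": 158.0},
                "nhs111_contact": {"amount": 11.0},
                "outpatient_appointment": {"amount": 213.0},
                "admission": {"amount": 2587.0},
                "excess_bed_day": {"amount": 338.0},
                "poc_test": {"amount": 49.0},
                "home_monitoring": {"amount": 34.0},
                "home_setup": {"amount": 30.0},
            },
            "staff_roles": {
                "nurse": {"annual_cost": 93180.0, "annual_hours": 1553},
            },
            "activities": {
                "home_visit": {"duration_min": 45, "cost_per_minute": 1.02},
                "virtual_call": {"duration_min": 10, "cost_per_minute": 1.79},
            },
            "fixed_costs": {"platform": 400.0},
            "setup_costs": {"comms": 82.0},
            "cohort": {"size": 10, "observed_months": 6},
        }
        base.update(overrides)
        path = tmp_path / "config.yaml"
        path.write_text(yaml.safe_dump(base))
        return path

    return _write
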