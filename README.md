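# wardcost

A cost-comparison model for virtual wards ("hospital at home") versus
standard inpatient care. The package costs a virtual-ward cohort and a
propensity-matched standard-care counterfactual at the patient level,
decomposes costs into set-up / fixed / variable and direct / indirect
components, reports incremental results, and runs one-way deterministic
sensitivity (tornado) and break-even threshold analyses. A synthetic cohort
generator — calibrated so expected per-patient component costs match a given
target decomposition — makes the entire pipeline runnable and testable
without any patient-level data.

## Modules

| module | role |
| --- | --- |
| `wardcost.cost_inputs` | unit costs, inflation index, configuration loading/validation |
| `wardcost.staffing` | staff cost-per-minute derivation, timed-activity costing |
| `wardcost.pathway_costing` | patient episodes, horizon filtering, per-patient cost breakdowns for both arms |
| `wardcost.incremental_analysis` | arm summaries, incremental costs, component decomposition |
| `wardcost.sensitivity` | one-way deterministic sensitivity analysis, break-even threshold |
| `wardcost.control_matching` | logistic propensity scores, greedy 1:1 matching without replacement, balance tables |
| `wardcost.synthetic_cohort` | rate calibration and reproducible cohort / control-pool generation |
| `wardcost.cli_report` | CLI, pipeline orchestration, CSV/text reports, run manifest |

## CLI

A default configuration (unit costs, staff rates, fixed/set-up costs,
cohort parameters, calibration targets) ships with the package; pass
`--config my.yaml` to override it.

```sh
# everything: generate -> match -> cost -> DSA -> break-even
wardcost run-all --out results/run --seed 1

# or stage by stage (stages communicate through files in --out)
wardcost generate  --out results/run --seed 1
wardcost match     --out results/run --seed 1
wardcost cost      --out results/run --seed 1
wardcost dsa       --out results/run --seed 1 --dsa-fraction 0.15
wardcost breakeven --out results/run --seed 1
```

Outputs include `table3_summary.csv` (arm and incremental totals),
`table4_cost_types.csv` (set-up / fixed / variable), `table5_components.csv`
(per-patient component decomposition), `tornado.csv`, `pairs.csv` /
`balance.csv` from matching, a plain-text `summary.txt`, and a
`manifest.json` recording config hash, seed, stages, and outputs. Runs are
byte-identical for identical config + seed.

## Python API

```python
import wardcost as w

inputs = w.load_config()                                  # packaged defaults
rates = w.calibrate_rates(inputs.calibration_targets, inputs)
cfg = w.CohortConfig.from_inputs(inputs, seed=1)
cohort, pool = w.generate_cohort(cfg)

episode = w.apply_horizon(cohort[0], inputs.horizon_days)
breakdown = w.cost_vw_patient(episode, inputs, n_annual=inputs.cohort_size)

w.breakeven(inputs, rates)     # smallest annual volume at which the ward breaks even
w.one_way_dsa(inputs, rates, ["unit_cost.admission"], fraction=0.15)
```

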