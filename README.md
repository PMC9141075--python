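# coherent-staffing

Shift-level nurse flexibility and reallocation analysis for multi-unit
care systems, built around a 70-bed, two-department perinatology
reference system (neonatology and obstetrics, seven locations, three
8 h shifts per day).

The package answers capacity questions of the form *"given this care
system layout and this demand stream, which nurse-flexibility strategy
minimizes under- and overstaffing, and what does it cost?"* by
combining:

- **`care_system_model`** — units, beds, rosters, nurse-to-patient
  ratios, qualification (skill) matrices and the registered-nurse
  headcount for three strategic layouts: six independent units
  (`current`), two pooled departments (`config1_two_departments`) and
  one pooled department (`config2_one_department`).  The reference
  system ships as editable YAML/CSV data files.
- **`synthetic_demand`** — a seeded patient-flow generator: per-group
  Markov transitions over units with an absorbing exit, Poisson
  admissions with a day-level gamma multiplier, and a calibration
  routine that tunes the multiplier dispersion until the per-shift
  total nurse-demand series hits a target coefficient of variation
  (e.g. 31% or 49%).
- **`markov_prediction`** — shift-ahead (8 h) expected census per unit
  from the current census and the transition matrices, converted to
  required nurses via ceiling on the shift's nurse-to-patient ratio,
  and the resulting per-unit staffing gaps.
- **`reallocation_engine`** — centralized single-shift reallocation:
  skill-constrained pairwise moves (strategy model 1), a centrally held
  float pool deployed to the largest shortages (model 2), their
  combination (model 3), float-pool sizing/withdrawal, and flex-rate
  accounting.
- **`shift_simulator`** — the what-if experiments R0–R8: drive a
  demand trace through predict → reallocate each shift, score residual
  gaps against realized demand, and summarize under-/overstaffing and
  empirical flexibility-rate distributions.
- **`evaluation`** — practical rounding, best-strategy selection,
  decision regret across demand conditions, training costs
  (EUR 20,000/nurse), minimum sufficient flex rate, and flexible
  nurse/bed sizing by largest-remainder apportionment on bed shares.
- **`cli_io`** — manifest-driven orchestration with deterministic
  CSV/JSON outputs and the `coherent-staffing` CLI.

## Quick start

```python
import numpy as np
import coherent_staffing as cs

config = cs.load_reference_system()            # 70-bed reference system
matrices = cs.default_transition_matrices()
rates = cs.default_arrival_rates(config, matrices)

demand = cs.DemandScenario(
    horizon_shifts=1095, arrival_rates=rates, dispersion=0.375, seed=1
)
spec = cs.ScenarioSpec.for_response("R1", demand)   # model 1, current layout
result = cs.run_scenario(spec)
print(result.summary())    # mean under-/overstaffed nurses per shift
```

## Command line

```sh
coherent-staffing fixture --layout current          # dump the reference system
coherent-staffing predict --census census.csv --shift-type evening
coherent-staffing reallocate --state state.csv --model 1
coherent-staffing simulate --response R2 --horizon 1095 --seed 1 --cv 0.31
coherent-staffing run-all --out results/ --seed 1   # full R0-R8 grid, both CVs
coherent-staffing evaluate --results results/results.csv --out results/
```

`run-all` writes `results.csv` (raw and rounded gap averages plus
training costs per response and demand condition), per-shift logs,
flexibility-rate distributions and a `decision.json` with the best
strategy sets, regret and the cost-aware optimum.  Outputs are
byte-reproducible for a fixed manifest and seed.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes unit tests per module, hypothesis property tests
(conservation, feasibility, monotonicity), and `tests/test_acceptance.py`
with the acceptance criteria: worked examples, ordering properties of
the strategy comparison on a common seeded 1095-shift trace, exhaustive
oracle equivalence of the greedy reallocation on small systems, and
demand-CV calibration recovery.  The full run takes a few minutes; the
long items are the exhaustive enumeration and the common-trace grid.

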