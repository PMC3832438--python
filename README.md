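# thrombolyzer

Simulation and quantitative analysis of preclinical thrombolysis
experiments:

* **`thrombolyzer.synthetic`** — synthetic-data generators: a one-compartment
  bolus+infusion pharmacokinetic model driving a latent thrombus-burden
  lysis/regrowth ODE (carotid flow traces with baseline, FeCl3-style
  occlusion, dose-dependent recanalization and concentration-gated
  reocclusion), plus impedance-aggregometry kinetics, one-site Langmuir
  titrations, and mono-exponential decay curves. All randomness is driven by
  explicit seeds.
* **`thrombolyzer.flow`** — flow-trace analysis: baseline estimation,
  sustained zero-flow (complete occlusion) detection, minimum-flow
  standardization, per-minute binning, the thrombolysis score
  (100 × mean monitored flow / baseline, trapezoidal), effective
  recanalization (≥50% of baseline sustained >30 min) and reocclusion
  detection, dose-group summaries, and routine group comparison
  (one-way ANOVA + Tukey HSD; Mann-Whitney for two groups).
* **`thrombolyzer.aggregometry`** — impedance aggregometry statistics:
  maximal above-baseline aggregation, percent inhibition
  (100 × (1 − a/a₀)), and percent disaggregation (restoration toward the
  pre-agonist baseline at a fixed readout after agent addition).
* **`thrombolyzer.binding`** — estimators: Kd via the 1/(1−i) vs [L]/i
  linearization (slope = 1/Kd), and elimination half-life via log-linear
  least squares.
* **`thrombolyzer.study` / CLI** — end-to-end simulate → analyze →
  summarize studies from a YAML/JSON config, with deterministic per-animal
  seeding, full provenance (config hash, seeds, version), TSV/JSON reports
  and figures.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes unit tests per module, hypothesis property tests for the
documented invariants (scale invariance of the score, burden bounds,
algebraic identities, offset invariance), and `tests/test_acceptance.py`
with one test per acceptance criterion (exact inhibition anchors,
disaggregation anchor, Kd/half-life parameter recovery, dose-response
monotonicity, regimen-dependent reocclusion ordering, and brute-force /
fine-grid oracle equivalences).

## CLI

```sh
# simulate one trace and analyze it
thrombolyzer simulate --dose 5 --regimen ten_pct_bolus_infusion --seed 3 --out trace.csv
thrombolyzer analyze-flow --trace trace.csv --monitor-min 120 --frac 0.5 --sustain-min 30

# materialize a full synthetic dose-response study (7 groups x n animals)
thrombolyzer fixtures --out fixtures/ --seed 1 --n-per-group 5

# aggregometry statistics
thrombolyzer analyze-agg --trace treated.csv --mode inhibition --control-trace control.csv
thrombolyzer analyze-agg --trace disagg.csv --mode disaggregation --readout-s 300

# curve fitting
thrombolyzer fit-kd --input titration.csv --amax-mode plateau
thrombolyzer fit-halflife --input decay.csv

# full study from a config file
thrombolyzer run-study --config study.yaml --out run/ --plot
```

Example `study.yaml`:

```yaml
groups:
  - {label: saline, dose: 0.0, n_animals: 5}
  - {label: d5, dose: 5.0, regimen: ten_pct_bolus_infusion, n_animals: 5}
  - {label: bolus5, dose: 5.0, regimen: total_bolus, n_animals: 5}
pk: {half_life_min: 4.1}
analysis: {frac: 0.5, sustain_min: 30, monitor_min: 120}
seed_base: 0
```

Flow traces are `time_s,flow` CSVs with a `<name>.csv.markers.json` sidecar
holding experiment-phase times (`fecl3_on`, `drug_start`, ...); aggregometry
traces are `time_s,impedance_ohm` CSVs with a `.meta.json` sidecar;
titrations are `conc_M,absorbance`; decays are `time_min,fluorescence`.

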