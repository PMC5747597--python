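# bpval

Statistical pipeline for validating an automated blood-pressure / heart-rate
monitor against a previously validated criterion device, using the
alternating seven-reading measurement protocol (criterion at positions
1, 3, 5, 7; test device at 2, 4, 6) and the two-phase pass/fail counting
rules of the ESH International Protocol family, extended to heart rate.

Stages:

* **Study model & I/O** — long-format CSV (`participant_id,session,position,
  device,variable,value`) with structural validation (device/position
  alternation, complete seven-reading series, plausibility bounds); a wide
  seven-column dialect and participant-profile CSVs are also read.
* **Validation protocol** — selected differences (per test reading, the
  smaller absolute difference against its flanking criterion readings),
  inclusive cumulative banding (≤5/≤10/≤15 mm Hg for BP, ≤3/≤5/≤8 bpm for
  HR), requirement scaling from the 33-subject base (k = round(n/33)), and
  pair-level ("two of" / "all of") plus subject-level phase evaluations with
  an overall verdict.
* **Reliability** — single-measures ICC (two-way random, absolute agreement
  by default; consistency model by flag) with F-based 95% CIs, SEM =
  SD·√(1−ICC), session-change paired t-tests, and an optional Monte-Carlo
  Lilliefors normality check.
* **Agreement** — participant-level device means, independent or paired
  t-tests, Pearson correlation, Bland–Altman bias and 1.96·SD limits with
  exportable point sets.
* **Design power** — paired-difference sample size with attrition inflation
  (z-based, noncentral-t option) and achieved-power inversion.
* **Synthetic studies** — a seeded generator (subject truth → session shift →
  per-position latent → device noise/bias) with packaged scenarios
  (`paper_like`, `biased_device`, `noisy_device`) and a pass-probability
  estimator, so the full pipeline runs with no external data.

## CLI

```bash
bpval simulate --config paper_like --seed 42 --out study.csv
bpval validate --input study.csv --variables SBP,DBP,HR --report verdict.json
bpval reliability --input study.csv --report reliability.json
bpval agreement --input study.csv --ba-points ba_points.csv
bpval power --delta 0.9 --sigma 3.2 --alpha 0.05 --power 0.8 --attrition 0.2
bpval run --scenario paper_like --seed 42 --out-dir out/   # all stages
```

`validate` and `run` exit 0 when the device passes, 2 when it fails, and 3
on usage or data errors. `--config` / `--scenario` accept a packaged
scenario name or a YAML file with `SimulationConfig` fields.

## Library use

```python
from bpval import (SimulationConfig, generate_study, validate_device,
                   load_scenario)

dataset = generate_study(load_scenario("paper_like"))
verdict = validate_device(dataset)
print(verdict.overall, verdict.results[(1, "SBP")].phase1.counts)
```
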