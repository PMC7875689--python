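# surveyiv

Instrumental-variable causal inference for ordinal survey outcomes:
direction testing on a causal diagram plus compliance-weighted effect
estimation, built for encouragement-design questions in cross-sectional
health surveys (the motivating case: does patient-portal usage improve
self-efficacy in seeking health information, studied with HINTS 5 Cycle 1
variables).

## The problem and the method

A survey records provider **encouragement** Z ∈ {0,1}, ordinal **portal
usage** D ∈ {0..4} (0 / 1–2 / 3–5 / 6–9 / 10+ times a year), 5-point Likert
**self-efficacy** outcomes Y, and categorical confounders X (age, gender,
race, education, income, ...). Association between D and Y is uninformative
about causality: X confounds everything observable, unmeasured traits U may
confound (D, Y), and Y → D is as plausible a priori as D → Y.

`surveyiv` treats Z as an instrument and works on the diagram
Z → D → Y (against the alternative Z → D ← Y), with X observed and U latent:

* **Direction testing** — two conditional-independence tests of the
  instrument against the outcome:
  Test A (Z ⫫ Y | X, D) rejects when Y drives D, because conditioning on
  the collider D opens Z → D ← Y; Test B (Z ⫫ Y | X) rejects when D drives
  Y through the open chain. The rejection pattern at α = .05 yields a
  four-way verdict (treatment→outcome / outcome→treatment / inconclusive /
  both-rejected). Tests are 1-df likelihood-ratio tests in a
  proportional-odds model (a stratified-permutation variant is provided).
* **Effect estimation** — two-stage least squares for the Angrist–Imbens
  estimand with a multi-valued treatment: a weighted average of per-unit
  effects E[Y(j) − Y(j−1)] over compliers at each step j, with weights
  ω_j ∝ P(D ≥ j | Z=1) − P(D ≥ j | Z=0), valid under instrument
  independence and monotone compliance D(1) ≥ D(0).

Supporting machinery: the survey missing-data policy, chained-equation
imputation of categorical confounders, Pearson chi-square descriptives, and
a structural-causal-model generator with stored potential outcomes whose
defaults are calibrated to the published HINTS margins — so every claim the
package makes is testable without the survey file. See `docs/methods.md`.

## Worked example

```python
import surveyiv as siv

# a survey-scale draw where usage truly improves confidence (tau = 0.30)
cfg = siv.scenario_presets()["forward_strong"]
table, truth = siv.generate(cfg, seed=11)

report = siv.run_pipeline(table, seed=11)
entry = report["outcomes"]["confidence"]
print(entry["verdict"]["verdict"])
print(entry["ci_tests"]["test_A"]["p"], entry["ci_tests"]["test_B"]["p"])
late = entry["late"]
print(f'{late["estimate"]:.3f} ({late["ci_low"]:.3f}, {late["ci_high"]:.3f})')
```

prints

```
treatment_causes_outcome
0.823382312 0.0
0.308 (0.268, 0.348)
```

Test A retains (p = .82), Test B rejects (p < 1e-10), so the verdict is
that usage causes the outcome, and the pipeline then reports the TSLS
effect: 0.31 Likert points per additional usage level, with the 95% CI
covering the generating τ = 0.30. On a real export the entry point is the
same: `siv.run_pipeline("survey.csv", schema=...)`, with the schema mapping
columns to roles and levels (see `surveyiv.cli` for the YAML form). The CLI
mirrors the library:

```bash
surveyiv simulate --preset forward_strong --seed 11 --out survey.csv
surveyiv experiment --preset reverse --reps 200 --seed 0
```

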