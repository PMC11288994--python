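# sepsiscreen

A simulation and evaluation pipeline for prehospital sepsis screening.
Because real EMS (emergency medical services) records with linked inpatient
outcomes cannot be shared, the package generates synthetic cohorts with the
documentation structure such analyses face, and evaluates four
prehospital-adapted screening tools against an inpatient sepsis label.

Components:

- **`synthetic`** — cohort generator: condition prevalences, vital-sign
  distributions shifted in septic cases, per-variable documentation rates by
  staff type (paramedics vs. emergency physicians), implausible-value
  contamination, 30-day mortality follow-up. Deterministic under a seed.
- **`preprocess`** — plausibility filtering, two-slot assessment resolution
  (a variable counts as documented if either slot is filled), GCS→ACVPU
  derivation, and four missing-data strategies: `complete_case`,
  `missing_as_normal`, `hotdeck` (seeded, stratified), `missing_as_worst`.
- **`scores`** — qSOFA, prehospital SIRS (no leukocytes/paCO₂), prehospital
  MEWS (no urine output) and NEWS2, driven by versioned JSON score tables;
  positivity at qSOFA/SIRS ≥ 2, MEWS ≥ 4, NEWS2 ≥ 5.
- **`accuracy`** — confusion matrices, Se/Sp/PPV/NPV with Wilson 95% CIs,
  likelihood ratios, dichotomous AUROC = (Se+Sp)/2, McNemar, Pearson χ² with
  Cramér's V, Bonferroni.
- **`intersections`** — 16-way partition of cases by tool-positivity
  combination, unique-to-tool shares, combined any/all rules.
- **`cohort_stats`** — incidence, hospital/30-day case fatality,
  documentation-completeness tables, suspicion rates.
- **`cli` / `reporting`** — orchestration, CSV/markdown reports, manifest.

## CLI

```sh
sepsiscreen simulate --seed 1 --out-dir sim            # cases.csv, outcomes.csv
sepsiscreen preprocess --cases sim/cases.csv --missing-strategy hotdeck \
    --seed 1 --out resolved.csv
sepsiscreen score --resolved resolved.csv --strategy hotdeck --out panel.csv
sepsiscreen evaluate --panel panel.csv --outcomes sim/outcomes.csv --out accuracy.csv
sepsiscreen intersect --panel panel.csv --outcomes sim/outcomes.csv --out intersections.csv
sepsiscreen cohort-stats --cases sim/cases.csv --outcomes sim/outcomes.csv --out-dir stats
```

Or everything at once from a JSON config (schema = `sepsiscreen.cli.PipelineConfig`):

```sh
echo '{"cohort": {"n_cases": 4503, "seed": 1}, "strategies": ["hotdeck", "normal"]}' > cfg.json
sepsiscreen run --config cfg.json --out-dir bundle
```

The bundle contains the cohort CSVs, per-strategy score panels and accuracy
tables, the intersection partition, cohort statistics, a markdown report and
a manifest (config hash, seed, versions) sufficient to reproduce it.

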