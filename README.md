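# radformal

Formal-methods radiomic classification of mild acute pancreatitis from
per-slice CT feature tables.

The pipeline takes a per-(patient, slice) radiomic feature table (22 canonical
features in 6 families: FIRST, GLCM, GLDM, GLSZM, SHAPE, GLRLM), excludes
patients with incomplete panel coverage, discretizes every feature into five
equal-width ordinal levels (*very_low* … *very_high*), encodes each patient's
slice series as a linear labeled transition system serialized in a minimal CCS
dialect, and classifies patients by model-checking a modal mu-calculus Property
against each chain. The Property itself is synthesized from radiologist-chosen
exemplar patients: per feature class, a conjunction over features of
disjunctions of `presence(feature__level)` atoms built from the exemplars'
modal levels, OR-composed across classes. Diagnostic performance is reported as
confusion matrices and accuracy / precision / sensitivity / specificity, with
an optional (explicitly idealized) adjudication combining model and radiologist
calls. A seeded synthetic-cohort generator reproduces the study cohort's
statistical structure so the whole pipeline runs without any imaging data.

## CLI

All stages are exposed as `radformal` subcommands: `simulate`, `filter`,
`discretize`, `build-models`, `synthesize-rule`, `check`, `classify`,
`evaluate`, `run`. A full run:

```bash
cat > config.yaml <<'EOF'
synthetic:
  n_healthy: 40
  n_map: 40
  effect_size: 3.0
rule:
  auto: {classes: [FIRST, SHAPE], n_exemplars: 3}
EOF
radformal run --config config.yaml --seed 1 --out out/
```

This writes `out/report.json` (config echo, exclusions, rule provenance,
per-patient calls with action-trace witnesses, matrices and metrics),
`out/scheme.json`, `out/rule.json`, `out/metrics.csv`, and one `.ccs` model
per patient under `out/models/`. Real data instead of `synthetic:` is given as
`features:` (wide CSV `patient_id,slice_index,<feature>...` or tidy long form)
and `labels:` (`patient_id,status[,ctsi][,radiologist_call]`) paths.

Check a single formula against a serialized model:

```bash
radformal check --model out/models/P001.ccs --formula 'presence(mean__very_high)'
```

The formula grammar is `tt | ff | X | and | or | not | <a>phi | [a]phi |
min X . phi | max X . phi | presence(a) | absence(a)` with the wildcard
action `-`.

## Layout

| module | contents |
| --- | --- |
| `radformal.feature_io` | canonical panel, CSV readers, completeness filter |
| `radformal.discretization` | equal-width five-level schemes |
| `radformal.formal_model` | patient chains, CCS serialization/parsing |
| `radformal.logic` | formula AST, parser, fixpoint model checker |
| `radformal.rule_synthesis` | exemplar-derived Properties, rule ranking |
| `radformal.evaluation` | confusion matrices, metrics, combination policies |
| `radformal.synthetic_data` | seeded cohort generator, missingness injection |
| `radformal.cli_pipeline` | orchestration, run reports, information-gain ranking, CLI |
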