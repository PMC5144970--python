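# plastinorm

Reaction-norm analysis of fungal race-tube growth assays: growth-rate
estimation, natural-spline environmental optima, mixed-model G×E ANOVA, and
hierarchical Bayesian mutant-vs-control contrasts — plus a synthetic-data
generator that emulates the factorial design (26 genotypes × 4 environmental
parameters × 6 settings × 5 replicates) so every stage is testable without
external data.

## Modules

| module | what it does |
| --- | --- |
| `plastinorm.synthetic_data` | factorial design enumeration, growth-rate and race-tube simulation, backcross background expectation |
| `plastinorm.growth_rates` | OLS slope (mm/hr) per race tube with visibility trimming and zero-growth rules; R² quality summaries |
| `plastinorm.reaction_norms` | per-genotype norms, natural cubic spline fits (no extrapolation), grid-search optima, elevation/shape decomposition |
| `plastinorm.mixed_anova` | REML variance-components models; Type III F-tests with Satterthwaite denominator df; χ² LRTs for random terms; Holm-corrected pairwise interaction tests |
| `plastinorm.bayes_contrasts` | heterogeneous-variance hierarchical model sampled by Metropolis-within-Gibbs; 95 % HPD contrasts; R-hat/ESS diagnostics |
| `plastinorm.io_utils` | CSV schemas and validation, YAML pipeline config, end-to-end orchestration |

## CLI

```sh
plastinorm simulate --out out/ --seed 1              # synthetic factorial table
plastinorm rates --in tubes.csv --design design.csv --out rates.csv
plastinorm norms --in rates.csv --df 4 --out norms/
plastinorm anova --in rates.csv --model eq2 --param temperature --out anova/
plastinorm contrasts --in rates.csv --param salt --setting 0.8 \
    --control 4200 --seed 1 --out contrasts/
plastinorm run --config config.yaml --out out/ --seed 1   # whole pipeline
```

Exit codes: 0 success, 2 validation failure, 3 convergence/QC failure.

Growth-rate CSVs are long format with columns
`genotype, mechanism, env_param, setting, replicate, rate_mm_per_hr,
missing_flag`; race-tube CSVs use `assay_id, time_hr, position_mm`.
A `column_map` block in the YAML config adapts external layouts.

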