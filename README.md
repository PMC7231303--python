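# movecomp

Analysis toolkit for accelerometer-assessed 24-h movement behaviours
(sleep, sedentary time, light and moderate-to-vigorous physical activity)
in relation to hippocampal gray-matter volume, built around four analysis
families:

- **accel** — epoch-level accelerometry reduction: intensity classification
  (SED < 35 m*g*, LPA 35–200 m*g*, MVPA > 200 m*g*), a 33-band × 25-m*g*
  awake-time intensity spectrum, non-wear imputation from the same
  clock-time slot on other days, weekday/weekend 5:2 weighting, and the
  valid-day filter (≥ 16 h wear on ≥ 4 days incl. ≥ 1 weekend day).
- **stdmodels** — covariate-adjusted OLS of GMV on each behaviour's absolute
  minutes, a weight-status moderation screen (joint interaction F-test at
  α = 0.15) and stratified fits.
- **coda** — compositional analysis: isometric log-ratio pivot coordinates
  of the 4-part daily composition (closed to 1440 min), γ coefficients for
  each behaviour relative to the rest, and isotemporal-substitution curves
  with delta-method confidence bands.
- **plsmv** — multivariate pattern analysis: PLS1 regression of the
  (covariate-residualized) outcome on the collinear intensity spectrum,
  Monte-Carlo cross-validation (repeated 50/50 splits) for component
  selection, target projection to a single predictive component, and
  per-band selectivity ratios in [−1, 1] with resampling CIs.
- **synthdata** — a synthetic cohort generator (logistic-normal
  compositions around group means, correlated behaviours, configurable
  planted effects, epoch-series simulation) so the whole chain is testable
  end-to-end without access to participant data.
- **pipeline** — orchestration of all of the above into a configured,
  reproducible run with tidy CSV outputs and figure analogues.

## Command-line usage

```sh
# generate a synthetic cohort (participant table, optionally epoch series)
movecomp generate --n 93 --seed 7 --out participants.csv \
    --epochs-out epochs.csv --epoch-seconds 60

# reduce an epoch CSV to weighted behaviour summaries
movecomp accel summarize --epochs epochs.csv --out summary.csv

# analyses on a participant table
movecomp models absolute --table participants.csv --behavior mvpa --stratify
movecomp models coda --table participants.csv --outcome right_hippocampus
movecomp models reallocate --table participants.csv --donor sed --receiver mvpa
movecomp models pls --table participants.csv --group "obesity II-III" \
    --reps 1000 --holdout 0.5 --seed 7

# full pipeline (demo configuration bundled in the repo)
movecomp run --config configs/demo.yaml
```

The pipeline writes `participants.csv`, `table1.csv`, `correlations.csv`,
`absolute_models.csv`, `moderation.csv`, `coda_models.csv`,
`reallocation_curves.csv`, `pls_model_selection.csv`, `sr_profiles.csv`,
figure PNGs, `manifest.json` and `run.log` to the configured output
directory; runs are byte-reproducible under a fixed seed.

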