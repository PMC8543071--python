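# wmtempo

Analysis pipeline for a dual-item continuous-report working-memory task with
temporally predictable or unpredictable interference (distractors vs.
interrupters) during the retention delay. The package bundles:

- **`wmtempo.circular`** — arithmetic on the 180°-periodic orientation space
  (wrapping into (−90, +90], signed/absolute deviations, doubling transform).
- **`wmtempo.cohort`** — synthetic cohorts: a factorial trial-schedule
  generator (12 blocks × 32 trials, 75% interference, onsets 500/1250/2000 ms,
  fixed vs. variable onset blocks, distraction vs. interruption blocks) and a
  generative response model (von Mises target noise, swaps to the interfering
  item, uniform guesses, sinusoidal attraction bias, shifted-lognormal RTs,
  configurable contaminant trials). CSV round-trip via `write_cohort` /
  `read_cohort`.
- **`wmtempo.preprocess`** — trial-removal rules (probe RT > 5000 ms, RT >
  mean + 2.5 SD, dial timeout > 4000 ms, distractor keypress, interrupter
  miss / wrong key / RT > 1000 ms) with single-reason attribution, and
  participant exclusion at > 10% rejected trials.
- **`wmtempo.metrics`** — reproduction error, 0–100 feedback score, condition
  means, paired contrasts, Cousineau/Morey within-subject SEM.
- **`wmtempo.mixture`** — EM fit of the target / non-target / uniform report
  mixture on the doubled circle (shared κ, dispersed restarts); per
  participant × condition swap table.
- **`wmtempo.bias`** — moving-window response-bias curve (step 5°, window
  45°, circular wrap), signed AUC integration, sign-equated bias, one-sample
  attraction test.
- **`wmtempo.inference`** — fully within-subjects rm-ANOVA (1–3 factors, no
  sphericity correction) with generalized eta squared, paired t with Cohen's
  d(z), Bonferroni adjustment, exact noncentral-t power / sample size.
- **`wmtempo.pipeline` / `wmtempo.cli`** — reproducible simulate → analyze →
  recover orchestration with YAML config, seed policy and hashed manifests.

## CLI

```sh
# simulate a cohort (defaults: 54 participants x 384 trials)
wmtempo simulate --seed 1 --out out/

# run the full analysis on a trial CSV
wmtempo analyze --input out/trials.csv --out out/analysis/

# parameter-recovery study
wmtempo recover --seed 1 --n-seeds 10 --out out/
```

All commands accept `--config cfg.yaml` with sections `design`,
`generation`, `preprocessing`, `analysis` and a `seed` key; every field has
a default, so all flags are optional except `analyze --input`. Analysis
outputs are tidy CSVs plus `results.json` (ANOVA tables, t tests, swap
table, bias curves) and `manifest.json` with SHA-256 hashes of all outputs.

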