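# sleepsca

Specification curve analysis (SCA) of adolescent digital-screen engagement
and sleep, packaged as a tested, reusable pipeline:

1. **`sleepsca.synthetic`** — a calibrated synthetic cohort generator
   producing retrospective questionnaire items, covariate blocks, and
   144-slot (4 AM–4 AM, 10-minute) time-use diaries for a configurable diary
   subsample, with configurable standardized true effects linking technology
   pathways to sleep outcomes.
2. **`sleepsca.measures`** — derived measures: midpoint bedtime/wake
   recodings, total retrospective sleep, the four-item screen composite,
   diary sleep onset (last non-sleep→sleep transition, 1–144 score, 4 AM
   fallback), diary participation / time-spent / before-bed use, and the
   nested covariate sets.
3. **`sleepsca.grid`** — declarative enumeration of the 120 analytical
   specifications (2 day types × 3 sleep measures × 4 technology measures ×
   5 control sets).
4. **`sleepsca.engine`** — standardized OLS per specification with listwise
   deletion, ranked curve assembly, percentile bootstrap over participants,
   median-β summaries, paired weekday/weekend comparison, preliminary
   correlation/difficulty analyses, and coefficient→minutes translation.
5. **`sleepsca.plots` / `sleepsca.cli`** — the two-panel curve dashboard,
   participants-per-specification figure, and the end-to-end CLI with a
   reproducibility manifest.

## CLI

```sh
sleepsca simulate --n 10000 --seed 1 --out out/          # cohort.csv + diaries.csv
sleepsca derive --cohort out/cohort.csv --diaries out/diaries.csv --out out/derived.csv
sleepsca grid --out out/grid.csv
sleepsca run --data out/derived.csv --out out/
sleepsca bootstrap --data out/derived.csv --reps 500 --seed 1 --out out/
sleepsca summarize --results out/results.csv --by day_type
sleepsca plot --results out/results.csv --out out/
sleepsca all --n 10000 --seed 1 --reps 500 --out out/    # everything + manifest.json
```

A TOML configuration file can replace `--n`; every key under `[generator]`
overrides the calibrated default:

```toml
[generator]
n_participants = 10000
diary_fraction = 0.3333
seed = 1

[generator.true_effects.weekday]
time_spent_diary = -0.18
time_spent_retro = -0.23
```

Missingness keys accept block names (`demographics`, `family`, `mother`,
`child`, `sleep_items`, `screen_items`, `difficulties`) or individual column
names. Cohort CSVs use empty fields for missing values; diaries are written
long (`person_id, day_type, slot, code`) with codes `SLEEP`, `DIG_MSG`,
`DIG_SOCIAL`, `DIG_BROWSE`, `DIG_GAMES`, `DIG_TV`, `OTHER`.

## Calibration notes

Ordinal items are produced by thresholding standard-normal latents at
cutpoints solved in closed form so the expected binned mean equals the
published target exactly; the diary time-spent distribution is log-normal
with a selection correction so the mean *among participants* hits its target.
Injected effects are standardized against the realised technology measures,
so a single injected pathway equals the implied standardized regression
coefficient of its matching specification.
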