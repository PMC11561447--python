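# kdscreen

Keystroke-dynamics screening pipeline for mild cognitive impairment (MCI):
extract hold/flight-time features from raw smartphone keyboard event logs,
evaluate their discriminant power against neuropsychological scores, and
simulate full synthetic cohorts so every stage is testable end to end.

## What it does

- **`kdscreen.keystroke_features`** — parse time-stamped press/release event
  logs (JSON array or NDJSON), pair presses with same-key releases, compute
  hold time (HT: release − press) and flight time (FT: next press − current
  release), drop implausible values (HT > 700 ms, FT > 3000 ms; boundaries
  retained), keep only sessions with more than 40 key presses, and aggregate
  per participant (pooled keystroke mean by default, session-mean optional).
- **`kdscreen.diagnostics`** — empirical ROC over the exhaustive midpoint
  threshold set, trapezoidal AUC (≡ all-pairs concordance with ties ½),
  DeLong or bootstrap confidence intervals, Youden-index-optimal cutoffs,
  and logistic predicted-probability fusion of marker pairs. The MCI group
  is the positive class; cognitive screening scores are evaluated with
  lower-is-positive orientation.
- **`kdscreen.stats`** — pooled (Student) two-sample t test from raw data or
  printed summaries, uncorrected Pearson chi-square for 2×2 tables, Spearman
  correlation with average-rank tie handling, and group-comparison /
  correlation-matrix reports.
- **`kdscreen.synthetic_data`** — Gaussian-copula cohort generator with
  group-specific normal marginals and pooled-scale Spearman calibration
  (per-pair bisection against a Monte-Carlo mixture), plus a raw event-stream
  simulator (gamma within-participant noise, negative-binomial session/press
  counts, configurable outlier contamination). Deterministic per seed.
- **`kdscreen.cli`** — `kdscreen simulate | extract | evaluate | report`
  subcommands tying the stages together with manifests for reproducibility.

## CLI usage

```sh
# generate a synthetic cohort (event log + participant metadata)
kdscreen simulate --seed 1 --out-dir run/

# extract per-participant HT/FT features
kdscreen extract --events run/events.json --out run/features.csv \
    --report run/extract.json

# group comparisons, marker panel (ROC/AUC/cutoffs), correlations
kdscreen evaluate --features run/features.csv --metadata run/metadata.csv \
    --out run/eval.json

# render the evaluation as a text report
kdscreen report --evaluation run/eval.json
```

Exit codes: 0 success, 2 validation error, 3 degenerate data.

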