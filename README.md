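# tapjid

Analysis pipeline for smartphone touchscreen event streams: builds
joint-interval distributions (JIDs) of consecutive inter-touch intervals,
regresses every JID bin on age or cognitive scores with robust
(bisquare IRLS) regression and 2-D cluster-corrected inference, and
classifies pairwise couplings of age-adjusted residuals across bins
("consistent" vs "inconsistent" behavioral aging). A synthetic cohort
generator makes the whole pipeline testable without any external data.

## What it does

1. **event_store** — reads touch-event / screen-episode CSVs, segments
   screen-on usage sessions, extracts inter-touch-interval (ITI)
   sequences, applies the cohort filter (≥ 7 days of recording and
   ≥ 100 interactions) and the ± 10-day window around a cognitive test.
2. **jid_core** — 2-D Gaussian KDE (bandwidth 0.1 in log10 units) of
   consecutive (k, k+1) ITI pairs, discretized on a 50 × 50 grid over
   10^0.5–10^5 ms into a probability-mass grid (2500 features); Full,
   Social and Transition variants; JID entropy; daily-usage summary.
3. **cog_scores** — median simple/choice reaction times, global/local
   task-switch costs, Corsi span, 2-back d′, with the minimum-trial
   validity rules (12/24/12/2/30) and the two 0–1 finger-preference
   scales.
4. **binwise_glm** — mass univariate robust regression (Tukey bisquare
   IRLS) of each bin on the design, 2-D cluster correction of the t maps
   against a max-cluster-mass null (Freedman–Lane permutation by
   default; participant bootstrap available), scalar robust regressions
   and Benjamini–Hochberg FDR.
5. **aging_residuals** — two-step (gender, then age) residualization of
   significant bins and consistency labeling of residual correlations
   across bin pairs more than 5 bins apart (R² > 0.1, FDR α = 0.001).
6. **synthetic_cohort** — deterministic cohort generator with an
   age-dependent fast (~100 ms) / slow (~4 s) ITI mixture, app-label
   Markov chains, trial-level cognitive records and a latent pace factor
   planting known residual couplings, plus the analytic ground truth
   (`PlantedTruth`) derived from the generating model.
7. **pipeline / cli** — orchestration of the three analyses (age maps,
   cognitive maps, residual pairs) with manifests, audits and a click
   CLI.

## CLI

```bash
tapjid simulate --seed 7 --n 150 --out data/          # synthetic cohort
tapjid sessions --events data/events.csv --episodes data/episodes.csv \
    --out sessions.csv
tapjid jid --events data/events.csv --episodes data/episodes.csv \
    --participant P0000 --variant full --out jid.csv
tapjid run --config config.yaml --tasks crt           # all three analyses
```

`config.yaml` keys mirror `tapjid.pipeline.RunConfig` (data_dir, out_dir,
variant, n_boot, cluster_alpha, fdr_alpha, seed, social_apps, ...).
Outputs land under `out_dir/` as 50 × 50 CSV maps (beta/t/p/R² per
predictor), `clusters_<model>.json`, `residual_pairs.csv` and a
`manifest.json` embedding the config hash and seed.

## Notes

- Timestamps are integer epoch milliseconds; duplicate timestamps per
  participant are collapsed (zero intervals are undefined on a log
  scale).
- Every JID sums to 1 and is bit-identical under duplication of its
  pair multiset (usage-amount invariance).
- All stochastic stages take an explicit seed; reruns with the same
  config and seed are reproducible.
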