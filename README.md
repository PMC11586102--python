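# batnight

Nightly activity budgets of colonially roosting bats from PIT-tag
detections at roost entrances.

## The problem

Colonies of cave-roosting bats (the motivating system is the nectar-feeding
bat *Leptonycteris yerbabuenae* on the Baja California Peninsula) can be
monitored passively by RFID transceivers with cord antennae at the roost
entrance: every time a PIT-tagged bat passes the entrance the antenna logs
a burst of reads. A single cord antenna cannot sense direction, but because
bats roost by day and forage by night, passage direction can be inferred by
alternation — the first detection after sunset is the emergence **exit**,
the next a return **entry**, and so on. From the coded event sequence of
each *bat-night* (one individual between a sunset and the following
sunrise) four activity metrics follow:

* **time of emergence** — first exit, in minutes after local sunset
  (computed with the NOAA solar method from site coordinates),
* **returns to the roost** — number of entries after the first exit,
* **hours inside the roost** — `Σ (exit_{i+1} − entry_i)` over consecutive
  entry→exit pairs,
* **hours of activity** — `Σ (entry_i − exit_i)` over exit→entry pairs.

These metrics are then compared across reproductive condition
(nonreproductive / pregnant / lactating females), sex, and
food-availability season with GLMs and mixed models:
Poisson or negative-binomial for return counts, gamma (inverse or log
link) for durations, Gaussian for sunset-relative emergence;
likelihood-ratio tests against the null, Tukey-style pairwise contrasts,
and a 16-model a priori candidate set ranked by AIC with crossed random
intercepts for bat identity and year.

The package is aimed at movement/behavioral ecologists running PIT-tag
roost monitoring who want a tested, reproducible path from raw antenna
reads to fitted effect sizes — plus a synthetic colony generator so the
entire chain can be verified without any field data.

## Worked example

Simulate a three-group maternity colony (lactating-like bats make fewer,
longer foraging bouts; pregnant-like bats more, shorter ones), then run the
reproductive-condition analysis:

```bash
batnight simulate --config examples/sim_config.yaml --out-dir data --seed 42
batnight all --config examples/run.yaml
```

with `run.yaml`:

```yaml
detections: data/detections.csv
deployments: data/deployments.csv
sites: data/sites.yaml
site_id: synthetic_complex
mode: repro_condition
window_days: 14
out_dir: artifacts
seed: 42
```

The run writes `coded_events.csv`, `metrics.csv`, `analysis_table.csv`,
`lrt.json`, `contrasts.csv`, per-metric effect tables, `fits.json`,
`cleaning_report.json` and a `run_log.json` naming the config hash and
seed. For a 60-bat, 600-bat-night colony the metrics table begins

```
tag_id,night_date,emergence_min_after_sunset,emergence_clock,n_returns,hours_inside,hours_active,n_events,censored_open_end
lact-0000,2017-04-01,33.65,2017-04-01 19:10:56,3,1.189,7.983,6,False
lact-0000,2017-04-02,27.78,2017-04-02 19:05:28,0,0.0,0.0,1,True
```

(the second night is a lone exit with no observed return — an open-ended,
censored night), the likelihood-ratio tests give

```
n_returns      chi2 31.75, df 2, p = 1.3e-07
hours_inside   chi2 16.65, df 2, p = 2.4e-04
hours_active   chi2  3.76, df 2, p = 0.15
emergence      chi2  0.24, df 2, p = 0.89
```

and the Tukey-adjusted contrast of nightly returns, lactating vs pregnant,
is 0.63 (95% CI 0.51–0.76, p ≈ 7e-08) — i.e. pregnant-like bats returned
about 1.6× more per night, close to the generator's true rate ratio of
about 1.5. Total hours of activity do not separate here even though bout
lengths differ, because fewer-but-longer and more-but-shorter bouts add up
to similar nightly totals — exactly the kind of trade-off the four metrics
are designed to distinguish.

The library API mirrors the pipeline stages: `detections_io` (readers,
sunset/sunrise), `event_coding` (cleaning filters, burst deduplication,
night assignment, exit/entry coding), `metrics`, `covariates` (season
mapping, analysis-table assembly), `stats` (GLM/GLMM, LRT, contrasts, AIC
set) and `synthetic` (colony generator and recovery experiments).

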