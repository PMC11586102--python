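# Methods

## Detection model and event coding

Raw input is a stream of timestamped antenna reads `{tag_id, timestamp,
site_id, roost_id}` in local civil time. Timestamps carry no timezone
suffix and are interpreted against the site's fixed `utc_offset`; no
daylight-saving inference is attempted, because sunset-relative arithmetic
must be unambiguous and the study region does not observe DST uniformly.
CSV with a header row is the only accepted dialect — readers reject rather
than sniff, so two runs of the same files are bit-identical.

Cleaning proceeds in a fixed order:

1. **Post-tagging exclusion** (`exclusion_days`, default 3): all
   detections earlier than `tagged_at + 3 days` are dropped, removing the
   window in which handling stress can distort behavior.
2. **Condition window** (`window_days`, default 14 for the
   reproductive-condition analysis, unlimited otherwise): reproductive
   condition is recorded once at tagging, so only the following two weeks
   of detections can be attributed to that condition with confidence.
3. **Burst deduplication** (`burst_gap_s`, default 60 s): a cord antenna
   re-reads a passing tag many times; maximal runs of same-tag reads with
   successive gaps ≤ the threshold collapse into one passage stamped with
   the run's first read. The operation is idempotent and monotone (a
   larger threshold never yields more passages). The threshold is
   exposed as configuration because no universally correct value exists;
   60 s is conservative for a bat transiting an entrance.
4. **Roost-complex merging**: two entrances < 1 km apart between which
   bats switch within a night are coded as one logical entrance
   (`merge_roosts`); the original roost is retained on each passage for
   reporting. A between-roost transfer therefore counts as time outside.
5. **Night assignment**: the night window is `[sunset − 30 min, sunrise]`.
   The 30-min pre-sunset tolerance admits occasional early emergence
   (small negative emergence times are real); passages outside every
   window are daytime reads and are dropped with a count.
6. **Direction coding**: within each bat-night, passages alternate
   EXIT, ENTRY, EXIT, … starting from EXIT (emergence-first). A single
   antenna cannot observe direction, so alternation is the identifying
   assumption. A missed passage flips every subsequent inferred direction
   for that night; this is **not** corrected or imputed — the synthetic
   module quantifies the resulting error instead (mean absolute error of
   nightly activity hours of roughly 1.6 h at a 30% per-passage miss
   rate under default generator settings, measured by
   `scripts/acceptance.py`). No probabilistic or HMM repair is attempted.

Sunset and sunrise come from the NOAA solar-calculator method
(Julian-century series for declination and the equation of time, zenith
90.833°). Supported latitudes are |lat| < 60°; polar conditions raise.
The implementation is cross-checked in the test suite against an
independently coded PSA (Blanco-Muriel) ephemeris with bisection on solar
elevation −0.8333°; the two methods agree within 15 s at the study
latitude, and the test tolerance is ±2 min.

## Metrics

For a coded bat-night with events `a1, b1, a2, b2, …` (a = exit,
b = entry):

* emergence = `a1 − sunset` in minutes (also reported as clock time);
* returns = number of entries;
* hours inside = `Σ (a_{i+1} − b_i)`;
* hours active = `Σ (b_i − a_i)`.

For uncensored nights (last event an entry) the two duration metrics
telescope to `last event − first event`; `compute_all` enforces this
conservation identity to 1 s and refuses to emit a violating row. A night
ending in an exit is open-ended: the final outside interval is excluded
from the sums and the row flagged `censored_open_end`, rather than
truncated at sunrise, which would fabricate a datum. Time between sunset
and first emergence is not counted as time inside: the inside metric is
defined from return→exit pairs only. Nights with no return→exit pair have
`hours_inside = 0`; whether such zeros enter a model is decided at the
statistics layer (gamma families require positive responses, and
`drop_nonpositive` excludes them with a logged count).

## Covariates

Food-availability season follows columnar-cactus phenology in the study
region: Nov–Jan low, Feb–Apr nectar, May–Jul nectar–fruit, Aug–Oct fruit.
Season and year are assigned from the night date (covariates are nightly
properties, not tagging-time properties). Daily mean temperature (°C) and
precipitation (mm) join by night date, complete-case: bat-nights without
an environmental record are dropped with a logged count. The
reproductive-condition analysis keeps females whose condition is
nonreproductive, pregnant or lactating; postlactating females are excluded
as an input-level decision.

## Statistical layer

Family/link pairs are fixed per response type: poisson+log or
negative-binomial+log (NB2, dispersion estimated by full ML) for return
counts; gamma with inverse link (single-factor condition models) or log
link (seasonal mixed models) for durations; gaussian+identity for
sunset-relative emergence. AIC is computed as `2k − 2ℓ` with `k` counting
mean-structure parameters plus one dispersion/scale parameter where the
family estimates one.

The condition analysis compares each single-fixed-effect GLM to its null
by likelihood ratio (χ² with df = parameter difference) and follows with
all pairwise condition contrasts. Contrasts are estimated-marginal-means
contrasts: the design matrix is rebuilt with the factor forced to each
level, averaged over the observed covariate distribution, and differenced
on the link scale. The family-wise adjustment is the multivariate-normal
max-|z| method over the contrast set — the large-sample analogue of the
Tukey adjustment in emmeans; the exact multivariate-t refinement is
deliberately out of scope, and adjusted p-values are floored at the
unadjusted ones. Effects are reported on the response scale: exponentiated
coefficients for log links, plain differences for the identity link, and
ratios of predicted means (delta-method CIs on the log-ratio) for the
inverse link, where a coefficient by itself has no ratio interpretation.

The sex/season analysis uses a deterministic 16-model candidate set per
metric over {sex, season, temperature, precipitation} with a sex×season
interaction: the null; the four single-term models; sex+season and its
interactive twin; those two plus temperature, plus precipitation, plus
both; temperature+precipitation; and sex or season with both environmental
covariates. The original supplementary model list is not archived with the
data, so this menu is the package's own documented reconstruction. Models
within 2 AIC units of the minimum form the best set; ties are all
reported, no single winner is forced. Ranking requires identical row
counts across fits, which the pipeline guarantees by filtering once before
fitting the whole set.

Crossed random intercepts for bat identity and year are fit by maximum
likelihood (not REML, so AICs are comparable) through a linear mixed model
with one variance component per grouping factor when the response is
gaussian. For the poisson, negative-binomial and gamma families no
Laplace-approximate crossed-random-intercept GLMM is available in the
Python stack this package builds on; those models fall back to the GLM
point fit with cluster-robust standard errors grouped on bat identity, and
the fit metadata records `fallback="glm_cluster_robust"`. Fixed-effect
point estimates are unchanged by the fallback; what changes is the
uncertainty accounting, which the robust clustering addresses to first
order. The gaussian mixed path is cross-checked in the test suite against
an independent glmmTMB fit.

## Synthetic colony generator

Per bat-night the generator draws an emergence offset
`Normal(μ_g, σ_g)` minutes after sunset (redrawn if outside the
night window; default 30 ± 12 min), a Poisson number `k ~ Poisson(λ_g)` of
return/exit cycles, gamma bout (outside) and gap (inside) durations, and a
terminal return before dawn with probability `final_return_prob`
(default 0.85 — most bats are home by sunrise, and without a terminal
return every simulated night would be censored and the conservation
identity untestable). Cycles that would cross sunrise are dropped whole.
Gamma distributions are the generator's modeling choice for positive,
right-skewed durations; the normal emergence offset likewise. Bout/gap
draws are floored at `min_interval_h` (default 0.1 h): a real passage
takes time, and intervals below the burst-dedup threshold would be
indistinguishable from read bursts by construction. Event times are
rounded to whole seconds so that written CSVs round-trip exactly.

The detection process misses each passage independently with
`detection_miss_prob` and expands surviving passages into bursts of
`1 + Poisson(burst_reads_mean)` reads spaced 1–10 s apart. Ground-truth
metrics are bookkept analytically during generation — never by calling
the metrics module — so they are an independent oracle: with miss
probability 0 the full chain reproduces them exactly (verified at
10,000 bat-nights).

What the generator does **not** emulate: clock drift, reader outages,
tag loss and tag collisions, multi-antenna geometry, migration arrivals
and departures mid-season, and any dependence of behavior on weather.
Passing tests therefore demonstrate correctness of the processing and
inference chain under the stated detection model, not robustness to every
failure mode of field hardware.

## Problem sizes and numerical choices

Default verification sizes are chosen to make Monte-Carlo noise small
relative to the quantities checked: 10,000 bat-nights for the lossless
chain, 1,000 replicates for LRT type-I calibration (binomial SE ≈ 0.7
percentage points at the nominal 5%), 200 replicates for CI coverage,
100 replicates for AIC selection power. The LRT statistic is clamped at 0
(optimizer jitter can make the null fractionally "better"), contrast
variance floors avoid division by zero for aliased contrasts, and the
Tukey critical value is found by root-finding on the rectangle probability
of the contrast correlation matrix. Every stochastic routine takes an
explicit seed; sub-seeds are drawn from a master generator so one integer
reproduces a whole experiment.

## Known limitations

* Direction inference is purely positional; a missed passage corrupts the
  remainder of that bat-night's coding (quantified, not corrected).
* Non-gaussian mixed models use the cluster-robust fallback described
  above rather than true random intercepts.
* The inverse-link gamma mean ratio uses a delta-method CI, adequate at
  the sample sizes here but first-order only.
* The 16-model menu is a reconstruction and is flagged as such in its
  docstring.
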