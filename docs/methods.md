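# Methods

## Problem setting

A mass gathering that is about to turn dangerous produces three
correlated anomalies in a geotagged microblog stream: posting volume near
the site rises far above routine levels, the posts cluster spatially, and
their content shifts toward crowd complaints and negative emotion.
crowdwatch computes one hourly series per phenomenon and combines them
into a per-hour alert. The package works entirely on the generic record
`(id, timestamp, lon, lat, tokens)`; nothing is specific to any one
platform.

## Spatial model

**Grid.** The study area (a lon/lat bounding box) is divided into square
cells of 2 arc-minutes (the analysis resolution used in the motivating
case study; configurable). Cells are half-open in both axes except the
global max edge, indexed (row, col) from the southwest origin; the grid
is the ceiling cover of the bbox, so boundary records are never lost.
Cells with zero counts enter the statistic — the literal reading of
"divide the study area" — which matters: empty-ring structure around a
buffered disc contributes real spatial autocorrelation.

**Moran's I.** For cell values x₁…xₙ and weights w,

I = n Σᵢⱼ wᵢⱼ(xᵢ−x̄)(xⱼ−x̄) / (Σᵢⱼ wᵢⱼ Σᵢ(xᵢ−x̄)²).

Weights are binary queen contiguity by default and **not**
row-standardized — the formula already normalizes by Σw. Rook contiguity
(used by the exact checkerboard test) and row standardization (used to
cross-check against R's `ape::Moran.I`, which standardizes internally)
are available switches. Degenerate inputs (constant surface, no positive
weights) return a flagged undefined result rather than raising, because
all-zero night-hour surfaces are routine; undefined bins propagate as NaN
through every series and are excluded from detection baselines.

**Geodesy.** Distances are haversine great-circle with mean Earth radius
6371.0088 km; the site buffer is a closed geodesic disc (default radius
10 km). Timestamps carry a fixed UTC offset (+08:00 default) and bins are
aligned to local clock hours, half-open [t, t+1h).

## Topic model

The text model is standard LDA: θ_d ~ Dir(α) per document,
φ_k ~ Dir(β) per topic, word topics and words multinomial. Inference is
**collapsed Gibbs sampling** — φ and θ integrated out, per-word
assignments resampled from
p(z=k | rest) ∝ (n_dk+α)(n_kw+β)/(n_k+Vβ) — rather than online
variational inference: the two target the same model, and a Gibbs chain
driven by an internal xorshift64* generator is bit-reproducible for a
given (corpus, seed) on any platform. The variational route (scikit-learn)
serves as an independent cross-check in the test suite, where the two
inferences must agree on the dominant-topic partition (ARI ≥ 0.8).
Point estimates use the final chain state with prior smoothing
(φ_kv ∝ n_kv+β, θ_dk ∝ n_dk+α); no burn-in averaging by default.

Defaults: α = 50/N_T, β = 0.01 (common symmetric-prior heuristics; the
case study states none), `n_iterations` = 1000 for standalone fits. The
pipeline uses 300 sweeps — ample for mixing at its corpus sizes
(~3,000 documents of ~10 tokens), and the topic stage does not feed the
alert rule.

**Preprocessing** drops exact duplicates (same tokens, timestamp,
coordinates), deletes stop/removal tokens (the analogue of stripping the
dominant holiday-greeting vocabulary before fitting), and excludes — but
counts — records left empty; tokens are atomic strings with no
segmentation or case folding.

**Classification.** Each topic's top-K words (K = 10; ties to the lower
word id) are intersected with per-class keyword sets in precedence order
crowd_complaint > relief > blessing; no hit means unrelated. Keyword sets
must be pairwise disjoint. Each record takes the class of its dominant
topic (argmax θ_d, ties to the lower index); per-class hourly proportions
sum to 1 in every non-empty bin.

## Sentiment model

The original analysis used a proprietary scoring API; crowdwatch
substitutes a transparent scorer with the same contract (score ∈ [0,1],
high = positive): score = logistic(g·m̄) with gain g = 3 and m̄ the mean
polarity of lexicon-covered tokens. Unknown tokens are excluded from the
mean entirely, so lexicon coverage does not dilute polarity; a document
with no covered tokens is neutral (0.5). Replication of any real-data
score values is explicitly not claimed — only the contract and the
group-level dynamics.

Groups: [0,.2) [.2,.4) [.4,.6) [.6,.8) [.8,1] → 1…5. Boundary scores
(exactly 0.2, 0.4, …) go to the upper group; the comparison uses the
literal boundary floats so binning is deterministic at representable
boundaries. Negative proportion = share of Groups 1–2 per bin. With the
default short polarity-token budget the achievable scores are discrete
(mostly Groups 1/3/5); the negative proportion, the tracked statistic, is
unaffected.

## Detection rule

Per bin: **count anomaly** iff count ≥ count_ratio × median of all other
bins (inclusive; median is robust to the event bins themselves; an
all-zero baseline flags any positive bin with a warning). **Moran peak**
iff the bin is the series maximum and ≥ mean + moran_z·sd over defined
bins (sd must be > 0; fewer than 3 defined values → no flags).
**Sentiment shift** iff negative proportion − baseline mean ≥
negative_shift (inclusive with 1e−12 slack for float representation);
inside the pipeline the baseline excludes the count-anomaly bins.
**Alert = count_anomaly AND (moran_peak OR sentiment_shift).** Defaults:
count_ratio 2.0 (gathering nights roughly double the background),
moran_z 1.0, negative_shift 0.10. The combined rule is this package's
operationalization of an analysis that originally identified the event
post hoc by inspection; every threshold is exposed in config.

## Synthetic scenario generator

The generator's defaults are the study conditions. Over a 48-hour span
and a ~27-km box of central Shanghai: a homogeneous Poisson background of
120 records/hour (uniform over the box); during the four event hours, an
additional inhomogeneous component around the Bund with expected hourly
counts 56 × (1, 4/3, 2, 31/12) — the 120k:160k:240k:310k reported crowd
ramp normalized to its first hour — so the peak-hour city-wide count is
≈ 2.2× the background median, matching the reported "roughly double";
the 10-km buffer subset shows proportionally stronger contrast. Event
points are isotropic Gaussian with σ = 2.5 km: a spread below one grid
cell (~3.7 km) would register as a single-cell spike, which global
Moran's I correctly does not read as aggregation, so the hotspot must
span several cells for the spatial signal to exist at the 2′ resolution.

Text: θ_d ~ Dir(0.3) over six topics (crowd, blessing, relief, three
neutral), document length 1 + Poisson-truncated around mean 8, words from
a fixed row-stochastic φ (90% of a topic's mass uniform on its own ten
words). Event records mix θ_d toward the crowd topic with weight 0.7.
Two polarity tokens are appended per document, each positive with
probability 0.5 at background and 0.5 − 0.35 during the event, giving a
background negative-post proportion ≈ 25% and an event-hour mix ≈ 45% —
the qualitative pattern reported for the real event (27.83% before,
40.95% during). Polarity tokens carry zero mass in the topical φ rows and
their true mean polarity is recorded per record.

Randomness is one seed split into documented substreams (spatial,
temporal, textual); identical (config, seed) reproduces byte-identical
records. Ground truth (true φ, per-record θ, event flags, polarities) is
returned alongside for recovery tests.

**What the generator does not emulate:** population-density structure
(background is spatially uniform), human-mobility or social-graph
dynamics, user-level posting heterogeneity, natural-language text
(tokens are synthetic atoms), and platform artifacts (bots, geocoding
error). Passing tests therefore demonstrate that the statistics recover
structure they are designed for under the stated generative assumptions —
not that the thresholds transfer to any particular real platform, where
baselines are burstier and lexicon coverage far lower.

## Numerical and design choices

- Moran's I is computed from sparse (i, j, w) triples; agreement with a
  brute-force dense double loop is required to 1e−12, with an external
  reference (ape) to 1e−9.
- `assign_cell` and the inclusive detection comparisons carry ~1e−9/1e−12
  relative slack so edge points and exact-threshold cases are stable
  under float subtraction error.
- Scenario calibration tests run 20 event and 20 matched null seeds with
  default thresholds; the problem size (48 h × ~6,000 records per run)
  keeps a full calibration under a minute per 40 runs on one CPU and is
  the package's chosen desk-scale study condition.
- Tie-breaks are always toward the lower index (dominant topic, top
  words) so reports are deterministic.

## Known limitations

- The alert rule needs a count baseline: an event spanning most of the
  analysis window would contaminate the median and mute the ratio signal.
- Global Moran's I detects area-wide clustering, not hotspot location;
  local indicators (LISA, G*) are out of scope.
- The sentiment scorer handles no negation, intensifiers, or emoji, and
  keyword classification is exact-match on atomic tokens.
- Topic-number selection is out of scope; N_T is a config input.
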