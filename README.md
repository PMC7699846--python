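# crowdwatch

Detection of dangerous crowd aggregations from geotagged microblog
check-ins. The package targets the surveillance problem posed by mass
gatherings — events such as the 2014 Shanghai New Year's Eve stampede at
the Bund, where roughly 120,000 people at 20:00 grew to 310,000 by 23:00
before the crush — and asks whether the spatial, topical and emotional
footprint of a gathering is visible in a stream of geotagged posts early
enough to matter. It is a library for epidemiologists, public-safety
analysts and computational social scientists, used from Python (a thin
`crowdwatch` CLI is included for batch runs).

## Method

Three hourly signals are computed from check-in records
(`id, timestamp, lon, lat, tokens`):

1. **Spatial aggregation.** Check-ins within a 10-km geodesic buffer of
   the focal site are counted on a regular 2′ × 2′ lon/lat grid, and each
   hourly count surface x₁…xₙ is summarized by global Moran's I,

   I = n Σᵢⱼ wᵢⱼ(xᵢ−x̄)(xⱼ−x̄) / (Σᵢⱼ wᵢⱼ · Σᵢ(xᵢ−x̄)²),

   with binary queen-contiguity weights wᵢⱼ (not row-standardized; rook
   and row-standardized variants are switches). E[I] = −1/(n−1) under the
   permutation null; a crowd shows up as a joint peak of the count and
   Moran series.

2. **Topics.** Post text (pre-tokenized; tokens are atomic strings) is
   modeled with latent Dirichlet allocation — topic mixtures
   θ_d ~ Dir(α), word distributions φ_k ~ Dir(β), word topics
   z ~ Mult(θ_d), words w ~ Mult(φ_z) — fit by collapsed Gibbs sampling.
   Each topic is classified crowd_complaint / relief / blessing /
   unrelated by intersecting its top-10 words with keyword sets, and each
   post inherits the class of its dominant topic (argmax θ_d).

3. **Sentiment.** Each post scores 1/(1+e^(−3·m̄)) ∈ [0,1], m̄ the mean
   lexicon polarity of its tokens; scores bin into five groups of width
   0.2, and the hourly proportion of negative posts (Groups 1–2) is
   tracked.

A bin raises an **alert** iff its count is ≥ 2× the median of the other
bins AND (it is the Moran's I peak at ≥ mean + 1 sd, OR its negative
proportion exceeds baseline by ≥ 0.10). All thresholds are configurable.

Because the original Weibo corpus cannot be redistributed, a first-class
synthetic generator (`crowdwatch.simulate`) reproduces the scenario's
structure: Poisson background over central Shanghai, a Bund hotspot whose
hourly intensity ramps as 120:160:240:310, LDA-generated text shifted
toward crowd topics during the event, and polarity tokens shifted
negative. Ground truth (true φ, θ, event flags, polarities) is returned
for recovery testing.

## Worked example

```bash
python examples/05_detection_pipeline.py
```

prints (seed 42):

```
records=6289  in-buffer=3077  valid-docs=3077

bins with any flag:
  31 Dec 14:00  count_x1.18 count_anomaly=False moran_peak=False sentiment_shift=True ALERT=False
  31 Dec 20:00  count_x2.07 count_anomaly=True moran_peak=True sentiment_shift=True ALERT=True
  31 Dec 21:00  count_x2.22 count_anomaly=True moran_peak=False sentiment_shift=True ALERT=True
  31 Dec 22:00  count_x2.95 count_anomaly=True moran_peak=False sentiment_shift=True ALERT=True
  31 Dec 23:00  count_x4.00 count_anomaly=True moran_peak=False sentiment_shift=True ALERT=True

alert bins: ['31 Dec 20:00', '31 Dec 21:00', '31 Dec 22:00', '31 Dec 23:00']
event window: 31 Dec 20:00 - 01 Jan 00:00
```

Every alert falls inside the simulated event window: the evening count
ramp crosses the 2× baseline rule at 20:00 and the sentiment shift (and,
at 20:00, the Moran peak) corroborates it. Isolated sentiment flags
outside the window never alert on their own. The other examples
(`examples/01`–`04`) walk through the generator, the count/Moran series,
topic extraction — including the ten-topic case-study classification
(7/10 stampede-related) — and sentiment binning (event-window negative
proportion ≈ 46% vs ≈ 21% pre-event at this seed).

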