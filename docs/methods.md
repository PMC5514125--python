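# Methods

This note documents the models, parameter choices and numerical
decisions behind `softcalls`, and what the synthetic-data studies do
and do not demonstrate.

## Synthetic data

**Waveforms.** A call is a harmonic stack: harmonic *h* of the
bird-and-type-specific fundamental has amplitude `rolloff**(h-1)`
(default rolloff 0.5) and a random phase; the fundamental may sweep
linearly across the call (`fm_glide`, as in the downsweeping distance
call); white noise is added at `noise_floor` relative amplitude; 2.5 ms
raised-cosine fades remove edge clicks and the peak is scaled to 0.9.
This is deliberately simple — spectral features have closed-form
expectations (the fundamental estimator must return the planted f0 to
within one FFT bin) — and is not a model of real syllable production
(no amplitude modulation, no nonlinear phenomena, no reverberation).
Default per-type fundamentals (500–900 Hz) and durations (0.06–0.30 s)
sit in the species-typical range; each simulated bird carries one
individual fundamental offset shared across its call types, offsets
evenly spaced over ±60 Hz so they are distinct by construction.

**Exchanges.** Each bird calls spontaneously as a homogeneous Poisson
process per call type (default 0.02 events/s per type, ≈ 290 calls per
type over a 4 h session — unrealistically regular but sufficient for
validating the scoring, which is rate-agnostic).  After each
spontaneous call the partner answers with a configurable probability at
a truncated-normal lag; answers do not trigger further answers, so the
planted answer probability is identifiable from the streams.

**Latencies.** Truncated normal on (0, 1.5] s — the latency analysis
window — parameterized by its *realized* mean: the location is solved
by bisection so the mean of the truncated distribution equals
`answer_latency_mean` exactly.  Without this, truncation would shift
the planted 0.55/0.67 s means by several ms and bias every recovery
check.  Defaults: mate 0.55 s, familiar/unfamiliar 0.67 s (a 0.12 s
mate advantage, the size of effect reported for distance-type calls in
this paradigm), SD 0.25 s, answer probabilities 0.60 (mate) vs 0.45,
and a per-subject latency offset with SD 0.03 s giving the subject
random intercept something to estimate.  `answer_latency_sd = 0`
degenerates to a fixed lag, used by construction-forced tests.

**Randomness.** Every operation draws from `split_rng(seed, *tags)` —
a `numpy` `SeedSequence` whose spawn key is the CRC-32 of the tag
tuple — so each stage can be regenerated independently and identical
configurations are byte-identical.

## Acoustics

Short-time analysis uses a 512-sample Hann window with 50% overlap at
44.1 kHz (≈ 86 Hz resolution, 5.8 ms hop); the exact settings of the
legacy sorting software are not documented anywhere, so these are
package choices, configurable via `FFTParams`.  Content below 85 Hz
(the stimulus high-pass edge) is always excluded.  Windows carrying
less than 10% of the loudest window's power are skipped: per-window
statistics on fade tails are numerically meaningless and inflate the
across-window SD features with quantization noise.

*Wiener entropy* is the geometric/arithmetic mean ratio of power bins,
reported on the linear [0, 1] scale (1 = white, 0 = pure line); a log
variant is a trivial wrapper if needed.  *Fundamental frequency* is
the lowest spectral peak above 85 Hz with prominence ≥ 5% of the
spectrum maximum ("first peak"), falling back to the argmax bin; a
cepstral estimator was considered and rejected as unnecessary for
harmonic-stack material.  The 14-feature set computes its moment
statistics (mean, SD, median, skew, kurtosis, mode) on the mean
normalized power spectrum treated as a distribution over frequency;
flatness and normalized Shannon entropy summarize its shape;
dominant-frequency statistics track the per-window argmax; the
frequency precision is the bin width (constant given the settings, and
therefore ignored by downstream discriminant analysis).

*Clustering* z-scores the sorting features per dimension and runs
k-means with 10 restarts; k is user-supplied (the repertoire is known).
Segments whose distance to their centroid exceeds the 99th percentile
are flagged NOISE — a reproducible stand-in for manual noise
elimination; curator overrides are applied via `apply_manual_edits`.
Clustering quality is always judged by partition agreement (adjusted
Rand), never raw labels.

## Playback design

Blocks, familiarity order and within-series emission order are
unconstrained uniform permutations from the seed (the original
"semi-random" constraint, if any, is undocumented; none is imposed).
Timing: in-series gaps U(1.5, 2.5) s, series gaps U(60, 80) s, block
gaps U(120, 140) s.  Counts (3 exemplars × 100, 300 per series; 15/18
series) are the full design and the defaults; they are parameters so
simulation studies can run reduced designs.  Stimulus preprocessing is
a zero-phase 4th-order Butterworth high-pass at 85 Hz, 5 ms
raised-cosine fades and peak normalization to −0.1 dBFS ("normalized
to 0.1 dB (maximal sample value)" read as a peak ceiling).  Fades are
applied before *and* after filtering: an abrupt onset splatters energy
across the band and the filter's edge transients would otherwise
overshoot the interior and capture the normalization peak.  Sound
level calibration is hardware; the schedule only carries an
informational per-call-type gain field.

## Answer scoring

All timing is onset-to-onset.  A responder event answers its nearest
preceding trigger if the lag is in (0, 0.5] s (exclusive at 0,
inclusive at the window; the original boundary convention is not
stated); each responder event answers at most one trigger, each trigger
may receive several.  First-answer latency uses the (0, 1.5] window.
Because the minimum inter-emission gap equals the latency window
(1.5 s), an answer can never be mis-attributed to the following
emission.  Habituation bins are half-open `[k·500, (k+1)·500)` s.
Repeatability is reported primarily as the intraclass form
`r = (MSA − MSW)/(MSA + (n₀−1)·MSW)` clamped to [0, 1] (with n₀ the
unequal-group-size correction), with the raw F ratio `MSA/MSW`
alongside: the bounded index is what printed values like 0.995 can
only be, while the F ratio is what the text of the classic description
says.  Emissions unanswered within the window are missing latencies,
not zeros; zero answer counts are valid data.

## Inference

"Bayesian" here means the flat-prior asymptotic posterior of the fixed
effects: ML fit, then multivariate-normal draws centred on the
estimates with the estimated covariance (the `sim` approach) — not
MCMC, and random-effect uncertainty is not propagated.  The fixed part
is the full familiarity × call-type × trial interaction; factors with
one observed level drop out so the same machinery serves reduced
designs.  Random intercepts for subject, audience and playback order
are design-based and kept even when a component estimates to zero;
with several random factors they enter as variance components on a
single grouping.  Significance is two-step: non-overlapping 95% CrIs,
else the exceedance probability with the 5% rule; ties in paired draws
count 0.5, and draws equal to within 1e−9 relative are ties (exact
comparisons on degenerate fits would otherwise resolve by rounding
noise).  No multiple-testing correction is applied anywhere, matching
the procedure the pipeline reimplements.

Optimization: `MixedLM.fit` uses a Powell → Nelder-Mead → BFGS
cascade.  With a subject variance near zero the gradient optimizers
either stall at a grossly inflated variance (inflating every cell CrI)
or collapse the component with an unusable Hessian; Powell lands on
the boundary cleanly.  Non-finite entries in a degenerate coefficient
covariance are treated as exactly-known directions.  Singular-fit and
convergence warnings are recorded in the fit's `diagnostics`, along
with residual skewness/kurtosis for the normality check.

The baseline-vs-playback correlation is OLS of playback answer
proportion on baseline proportion (per trial) with posterior-simulated
slope CrIs — with ≤ 6 subjects per sex a mixed model has nothing to
estimate.  Subset robustness re-scores the first/last *n* emissions of
each series (series shorter than *n* are kept whole with a warning)
and tabulates sign agreement of the familiarity contrasts against the
full analysis.

## Distinctiveness

Per (focal bird, call type): features standardized, PCA to 2
components (correlation-based, since units mix Hz, s and unitless),
LDA on caller identity, resubstitution prediction; the reported index
is the proportion misassigned.  "Familiarity level as a predictor" is
read as a proxy for caller identity — one opposite-sex individual per
familiarity level per focal bird.  Resubstitution is the documented
default (leave-one-out behind a flag); with 9 stimuli per bird/type it
is optimistic, which the study-level checks account for by using many
stimuli per identity where chance-level behaviour is asserted.
Constant feature columns (e.g. the fixed spectral resolution) are
dropped rather than erroring: they carry no identity information, and
erroring would make the standard 14-feature set unusable.  Chance
misassignment for k balanced indistinguishable callers is (k−1)/k.

## Simulation studies and their scope

All studies run the full chain (schedule → synthetic bird → scoring →
model → posterior), not isolated formulas.  Problem sizes are chosen
to finish in minutes on one CPU:

- *Null calibration*: 500 replicates, 6 subjects, one call-type block,
  60 emissions per series, equal latency means; counts how often the
  directional exceedance rule at 5% rejects mate-vs-familiar.  The
  expected rate is the nominal 5%.
- *Effect recovery*: 200 replicates at full series length (3 × 100
  emissions), 6 subjects, planted 0.12 s effect.  Significance is the
  sqrt-scale exceedance rule; the effect size is re-estimated as the
  within-subject difference of mean latencies (exactly unbiased for
  the planted value — a back-transformed sqrt-scale contrast estimates
  a slightly different functional and would show a spurious few-ms
  offset).
- *Cluster recovery*: 20 replicates × 3 planted types × 40 renditions
  with within-type f0 (3%) and duration (5%) jitter.  The planted
  types differ in fundamental, duration, harmonic richness and FM
  glide, as real tet/distance/hat calls do; with types that differ in
  only one or two of the nine sorting dimensions the k-means objective
  can legitimately prefer merging them, so this study validates the
  pipeline, not k-means' behaviour on arbitrarily similar types.
- *Distinctiveness limits*: 3 identities × 60 stimuli; identical voice
  distributions must sit at chance 2/3 within binomial error, voices
  separated by ≫ within-voice SD near 0.

Passing these shows the pipeline recovers what it is supposed to
recover under its own generative assumptions (Poisson calling,
truncated-normal latencies, harmonic-stack calls).  It does not show
robustness to bursty calling, overlapping vocalizations, noisy
recordings or non-normal latency distributions beyond truncation —
none of which the generator emulates.
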