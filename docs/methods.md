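# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limits of what the test suite demonstrates.

## Task and behavior generator

Sessions follow the head-fixed Pavlovian structure: a 1-s auditory cue,
reward delivered exactly 2 s after cue onset, 100 trials by default, and
inter-trial intervals (reward → next cue) drawn from a shifted exponential
with flat hazard, rejected above 10 s, so the support is [4, 10] s. The rate
constant is not a free dial: it is found by root-finding so the truncated
distribution's median equals 5.4 s (λ ≈ 0.448 s⁻¹; the closed-form median
condition `F(1.4)/F(6) = 1/2` is satisfied to 1e-9). Cue onsets are
quantized to a dyadic ~1-µs grid so that `reward − cue` equals the
configured delay bit-for-bit.

Licking is generated directly as bouts (no video emulation): an
anticipatory bout starting 0.5 s after each cue (1.4 s long by default) and
a consummatory bout starting 0.1 s after each reward (2.0 s). A
consummatory bout whose onset falls inside the preceding anticipatory bout
is clipped to start at that bout's offset, keeping same-kind bouts disjoint.
Movement bouts are a Poisson process (0.08 s⁻¹, 0.8 s long) confined to
ITIs and kept clear of the first 3 s after reward.

## Spike trains and population templates

Units are inhomogeneous Poisson processes simulated by thinning a
piecewise-constant intensity at 1-ms resolution: tonic rate times the
product of active multiplicative event gains (gain 1 = no modulation,
gain < 1 = firing decrease; overlapping modulations multiply). An optional
absolute refractory period exists but is off by default, because the
downstream GLM assumes Poisson counts.

The four population templates encode the qualitative phenotypes of the
projection-defined populations; the underlying study reports patterns, not
effect sizes, so the gains below are package defaults chosen once to
reproduce those patterns, and are fully configurable:

| population | tonic (Hz) | cue | reward | lick | movement | pauses |
|---|---|---|---|---|---|---|
| DMS | 5.0 | 2.2× (20 ms, 250 ms) | — | — | 0.6× | — |
| DLS | 5.5 | 2.0× | 2.4× (40 ms, 200 ms) | 1.5× | 0.6× | — |
| VLS | 5.5 | — | 3.2× (40 ms, 200 ms) | — | — | — |
| NAc core | 3.0 | 1.7× (350 ms) | 1.8× (350 ms) | 1.6× | — | 4/min, 2 s |

DMS encodes the cue but not reward; DLS multiplexes cue, reward and
licking; VLS has the strongest, reward-only response; NAc core responds
with a few-hundred-millisecond delay, locked to licking, fires tonically
slower and exhibits long pauses (modelled as rate-zero gaps). Only the NAc
core template injects pauses: unmodelled rate-zero gaps overdisperse the
Poisson GLM, and the pause fields exist specifically to emulate that
population's long pauses. Per-unit variability is lognormal jitter on the
tonic rate (SD 0.12 in log units) and on every non-unit gain (SD 0.08);
unit gains stay exactly 1 so ground-truth encoding labels are preserved.

## Encoding model

PSTHs use 40-ms bins over −1 to +4 s around cue onset. Per-trial rates are
z-scored against the mean and SD of the pooled 1-s pre-cue baseline bins of
all trials, then smoothed with a 5-tap Gaussian kernel renormalized to unit
sum. The kernel's half-width of 70 ms is read as FWHM (σ ≈ 29.7 ms ≈ 0.74
bins) — the only reading consistent with a 5-tap kernel at 40-ms bins. The
stored per-trial z matrix is unsmoothed (its pooled baseline mean is zero
by construction); the across-trial mean trace is smoothed.

The GLM tiles each trial with 200-ms count bins from 1 s before its cue to
the next trial's start (session end for the last trial), dropping a trailing
partial bin, so cue and reward onsets land exactly on bin edges. Binary
regressors: cue and reward are 1 for the two bins covering 0–400 ms from
the respective onset; lick and movement are 1 where the bin overlaps a bout
by at least 75 % of the bin. Several regressors may be active in one bin.
The model is a maximum-likelihood Poisson regression with intercept and log
link (statsmodels); no multiple-testing correction is applied across the
four coefficients (raw p < 0.05), the dominant parameter is the largest
|coefficient| among significant ones. Goodness of fit is the upper-tail
chi-square probability of the residual deviance; note this approximation is
only calibrated when bin means are not small — with ~1 count per bin the
deviance is biased above its degrees of freedom and long sessions reject
well-specified units far above the nominal rate, so the calibration test
runs at high bin means.

Event-window firing (cue: 0–240 ms; reward: 40–240 ms) is compared to a
shuffled baseline: 1000 windows of equal length placed uniformly at random
within ITIs (excluding the first second after reward), with a two-sided
percentile p using the (k+1)/(n+1) convention.

## Tonic firing statistics

All tonic statistics use only ITI spikes "outside of engagement": the
interval from 3 s after reward to 1 s before the next cue, with ISIs counted
only when both spikes fall in the same segment. CV2 is the mean over
adjacent interval pairs of 2|Iₙ₊₁−Iₙ|/(Iₙ₊₁+Iₙ).

The RGS detector centers log ISIs on the mean of the inter-quartile subset
and scales by the normalized median absolute deviation (1.4826·MAD).
Candidate intervals beyond the α-quantile (default 0.05) of the fitted
central normal seed strings; within the surrounding run of same-direction
deviations, the substring containing the seed with maximal joint Gaussian
surprise is selected (search capped at 200 intervals per side). A string is
kept when its surprise exceeds a string-level significance `string_alpha`.
Bursts require ≥ 3 spikes and use `string_alpha = 0.001`; pauses require
≥ 2 spikes (one interval) and use `string_alpha = 0.05`. The asymmetry is
deliberate: log ISIs of Poisson-like firing are left-skewed, so the
Gaussian model understates short-ISI tail probabilities (a stricter string
threshold restores the α-level false-positive rate on Poisson nulls) while
the light right tail already makes the pause test conservative. With these
defaults the detector keeps Poisson-null false positives at or below 5 % of
spikes while recovering ≥ 90 % of injected 5-spike bursts at 10× the tonic
rate.

## Clustering

PSTH matrices are column-mean-centered (not variance-scaled — rows are
already on a common z scale) and decomposed by SVD; each leading component's
sign is fixed so its largest-magnitude loading is positive. The first two
component scores feed average-linkage agglomerative clustering on Euclidean
distances (scipy). The cut level k is a configuration parameter, default 4
to match the four populations. Enrichment tables report, per cluster, the
population mix, and per population, the fraction captured by its modal
cluster.

## Photometry

Processing order is exactly: 5-sample median filter → 20-Hz second-order
Butterworth low-pass → 0.001-Hz second-order high-pass (photobleaching) →
motion correction → dF/F baseline → divide → sweep normalization. All
filters are zero-phase (forward–backward, second-order sections), so event
latencies are preserved; the quoted cutoffs therefore apply with their
magnitude response squared. Motion correction subtracts the
ordinary-least-squares fit (slope plus intercept) of the conditioned
reference channel from the conditioned activity channel; a constant
reference degenerates to mean-centering. Because the high-pass removes the
DC level, the dF/F baseline is the 0.001-Hz low-pass of the corrected
signal *after restoring the pre-high-pass mean offset*, keeping the
denominator strictly positive. Sweeps are cue-aligned windows (−1 to +4 s)
with the mean of the pre-cue second subtracted per sweep; the peak reward
response is the across-trial mean of the per-trial dF/F maximum in 0–1 s
after reward (window configurable; the source chain does not state it).

The photometry generator convolves the population's relative rate
modulation with a fast-rise (50 ms), slow-decay (500 ms) indicator kernel,
adds a shared low-pass-filtered (1 Hz) motion artifact with channel gains
0.8/1.0, white noise, and an optional exponential bleaching trend common to
both channels.

## Distributional TD model

The environment is a 5-state chain traversed deterministically, reward only
at the terminal state, episode restart afterwards; γ defaults to 0.9 (the
source does not state chain length or γ; a short chain is the minimal
environment with deterministic transitions, and both are configurable).
Training rewards are Gaussian with mean 5 and SD 5 — "N(5, 5)" is read as
(mean, SD), which makes the 0–20 test range span ±3 SD; a variance reading
is available through configuration. The reward is indexed per neuron
(r_{t,i}): each simulated neuron draws independently from the training
distribution, so across-neuron summaries average over reward noise. Values
start at 0; training runs 10,000 episodes; δ = 0 applies no update.

A fixed-learning-rate agent does not converge pointwise — it fluctuates
around its stationary point — so the "converged" value is the time average
of V over the final half of training. At that stationary point the
reward-state value equals the τ-expectile of the training distribution with
τ = α⁺/(α⁺+α⁻), up to an O(α) bias that vanishes for small rates; the
closed-form Gaussian expectile (bracketing root-finder on exact partial
expectations) serves as the independent oracle in tests.

Learning-rate fitting maps data to the model as follows: per-unit
reward-window (40–240 ms) firing rates are baseline-subtracted and divided
by the pooled across-population SD, giving dimensionless targets that
preserve each population's width and skew; a Gaussian KDE
(Silverman-bandwidth, support ±4 bandwidths past the sample range) is built
per population; one target per neuron is drawn from it (the
distribution-matching alternative was considered and rejected as
under-determined — one draw per neuron is what "a sample drawn from
activity distributions" implements most directly). The grid is
α ∈ {0.01, …, 1.00} on both axes; each pair's stationary expected
reward-state TD error is computed analytically as μ − expectile_τ(μ, σ)
rather than by re-simulation, the squared difference to the target is
minimized, and exact ties break toward the smaller α⁺+α⁻ (grid pairs are
pre-sorted by rate sum, making the first minimum the smallest-sum pair).

Evaluation freezes values (no learning during test), draws test rewards
uniformly over the configured range, and scores each neuron by the MSE
between the test rewards and its converged reward-state value. Agents are
built per population plus a "unified" agent fit to the pooled sample; all
have 50 neurons.

## Pipeline, sizes, and determinism

The default run simulates 10 units per population (40 GLM fits), one
photometry session per population, and five 50-neuron agents at 10,000
episodes — well under a minute on one CPU; all sizes are configuration
fields.
Randomness flows from one master seed through hierarchical
`numpy.random.SeedSequence` substreams per stage and unit, so the whole run
(and the report checksum, which excludes wall-clock timings) is a pure
function of (config, seed).

## What the synthetic data does and does not show

The generator reproduces the task timing, the qualitative population
phenotypes, Poisson count statistics, and a photometry forward model with a
shared artifact. It does not emulate spike-sorting artifacts, bursty
non-Poisson tonic firing (real dopamine neurons are partly pacemaker-like;
CV2 here is ≈1 by construction), EMG/video-derived bout noise,
session-to-session drift, or hemodynamic/optical nonlinearities. Passing
tests therefore demonstrate correctness of the analysis chain and internal
consistency of the model — not that the templates' effect sizes match any
particular recorded population. Pause detection on Poisson-like tonic
firing is intrinsically weak (a detectable gap must be several log-SDs
long), which is why the NAc-core template's pauses are long (2 s) and why
regular-firing neurons would show far better pause sensitivity than these
synthetic units.
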