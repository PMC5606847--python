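# Methods

This note documents the analysis conventions, the synthetic-data model
behind the validation suite, and the design choices made where the
underlying experimental conventions were genuinely open.

## Conventions

All times are seconds, floating point, zero-based from recording start.
Alignment and binning windows are half-open `[a, b)`, so a spike at
exactly a bin edge belongs to the right-hand bin and binning is
unambiguous. Duplicate spike timestamps are invalid input (an
extracellular single unit cannot fire twice at one instant at
millisecond resolution) and are rejected rather than deduplicated.

## Spike metrics

**CV.** The coefficient of variation uses the sample (n−1) standard
deviation of the ISIs over their mean, and requires at least two ISIs.
CV is invariant under time rescaling, which the suite property-tests.

**Burst segmentation.** A single left-to-right scan over the ISI
sequence: a burst is initiated by an ISI strictly below the 10 ms start
threshold, accrues spikes while ISIs stay at or below the 20 ms end
threshold, and ends before the first ISI that exceeds it. The spike
that follows a terminating ISI is *not* part of the burst (the standard
onset/offset reading of the two-threshold rule), a spike belongs to at
most one burst, and scanning resumes at the spike after the burst's
last spike. The implementation is checked for exact agreement with an
independently coded claimed-spike sweep on 1,000 random trains.

**Autocorrelogram.** All ordered spike pairs with lag in
`(0, max_lag]` contribute (not only adjacent spikes); zero-lag self
pairs are excluded; default 10 ms bins to 2 s. The bin width must
divide the maximum lag exactly.

**Firing-mode classification.** The classical labels are assigned by
eye from the autocorrelogram shape; this package pins the judgement
down so it is deterministic and testable. Counts are smoothed with a
3-bin moving average; the steady-state level is the mean over the last
quartile of lags with Poisson SD `sqrt(steady)`; peaks must exceed the
steady state by 2 of those SDs. The checks run in this order:

1. *bursting* — the mean over the first 100 ms significantly exceeds
   the steady state **and** the histogram's global maximum lies inside
   that window (an initial peak decaying to a steady state). The
   initial-peak shape, not peak counting, is the discriminator because
   burst-firing autocorrelograms are overdispersed at *all* lags (each
   pair of bursts contributes ~n² near-coincident lags), which creates
   spurious local maxima everywhere.
2. *regular* — at least three supra-threshold peaks with the 2× and 3×
   harmonics of the first peak's lag each present within ±20% of the
   fundamental. Requiring the specific low harmonics, rather than any
   three peaks at near-integer multiples, matters: a ±20% window tiles
   40% of the lag axis, so arbitrary noise peaks would otherwise pass
   frequently.
3. *irregular* — the first (refractory) bin sits significantly below
   the steady state, rising smoothly to it.
4. otherwise *unclassified* (e.g. a perfectly memoryless train with no
   refractory trough).

All thresholds are exposed in `FiringModeConfig`. On 600 s generated
trains (50 per mode in the test suite; 150 in the acceptance script)
the generator's label is recovered in ≥90% of cases — in practice 100%
at these durations.

## PSTH and the excitation criterion

The PSTH sums spike counts over sweeps in 10 ms bins covering a 2 s
baseline and a 1 s post window. The baseline mean and SD are computed
across the 200 pre-stimulus bins of the *sweep-summed* histogram (the
bin is the unit of variance, since the baseline is defined as the
average number of spikes per bin), using the sample SD for consistency
with the CV convention.

A unit is **excited** when the mean spikes/bin in at least one of the
four 50 ms epochs `[0,50), [50,100), [100,150), [150,200)` ms after
stimulus *onset* strictly exceeds `baseline_mean + 2·SD`; a count
exactly at threshold does not trigger. The multiple-comparison
inflation across the four epochs is part of the published criterion and
deliberately not corrected; the Monte-Carlo null quantifies it (at a
5 Hz baseline with 30 sweeps the empirical false-positive rate is
≈0.1%, matching the independently coded oracle of the same criterion).

**Onset** is the left edge of the first run of ≥2 consecutive
supra-threshold post-stimulus bins (searched over the whole post window
by default; a config flag restricts it to the first 200 ms). A single
isolated supra-threshold bin leaves the onset undefined and the cell
flagged. **Duration** runs from onset to the start of the first run of
≥5 consecutive bins at or below threshold; if no such run occurs the
duration is censored at the window end and flagged. **Magnitude** is
the per-sweep firing rate over `[onset, onset+duration)` minus the
baseline rate, in Hz.

**Normalization.** Each cell's PSTH is divided by the number of sweeps
and the per-sweep baseline mean is subtracted from every bin, making
the baseline-window mean exactly zero (to float precision); population
traces report the pointwise mean ± SEM across cells, which must share
binning.

## Photometry

ΔF/F = (F − F0)/F0 per channel with F0 the median of a baseline window
(default: the first 10 s of the trial, the trial-start convention; for
shock trains a window preceding the train can be passed instead). The
isosbestic correction subtracts ΔF/F₄₀₅ from ΔF/F₄₇₀ verbatim — no
regression scaling by default, because plain subtraction is the stated
pipeline; a least-squares scaled variant sits behind
`scaled_regression=True` for gain-mismatched artifacts. Because the
two channels are interleaved (405 samples offset by half an alternation
period), the 405 ΔF/F is linearly interpolated onto the 470 timestamps
before subtraction; this is the minimal alignment for a
"near-simultaneous" recording and introduces only interpolation-scale
residuals (<2% for the bump artifacts used in validation). No
photobleaching detrend is applied by default.

Plain subtraction cancels *exactly* any contamination that is additive
and equal in ΔF/F units across channels. The generator's
`sampling="simultaneous"` mode puts both channels on a common clock so
this identity can be verified to numerical precision (≤1e−9); the
interleaved default exercises the realistic, interpolation-limited
case.

## Synthetic-data model

Each generator call draws from its own `numpy.random.Generator(seed)`;
identical seeds and parameters reproduce outputs bit-for-bit.

- **Spike trains.** *regular*: gamma renewal, shape 100 (CV 0.1);
  *irregular*: Poisson with a 2 ms absolute refractory period and
  dead-time-corrected rate (CV ≈ 0.98 at 10 Hz — the small deficit from
  1 is the refractory fraction `rate·t_ref`); *bursting*: burst onsets
  Poisson at the given rate, 3–6 spikes per burst at 4–8 ms intra-burst
  ISIs, so every generated burst satisfies the 10/20 ms criteria.
- **Evoked recordings.** Inhomogeneous Poisson as the superposition of
  a homogeneous baseline and an independent per-event Poisson on
  `[event+onset, event+onset+duration)` — exact, not thinned. The
  evoked response is an additive rate step, matching the additive
  threshold logic of the classifier; defaults follow the study regime
  (5 Hz baseline, 60 ms onset, 100 ms duration, 30 events, 5 s
  inter-event interval).
- **Photometry.** 470 = `f0·(1 + transients + artifact) + noise`,
  405 = `f0·(1 + gain_mismatch·artifact) + noise`; transients are
  instantaneous-rise single-exponential kernels (default amplitude
  0.5 ΔF/F, τ = 1 s), the shared artifact Gaussian bumps in ΔF/F units,
  and noise is Gaussian in raw fluorescence units (default σ = 0.05 on
  F0 = 100 detector units, i.e. 5·10⁻⁴ in ΔF/F — small relative to the
  interpolation residual, so amplitude-recovery accuracy is
  interpolation-limited as intended). `gain_mismatch < 1` generates the
  imperfect-cancellation case whose residual is bounded by
  `artifact_amplitude · (1 − gain_mismatch)`.
- **Behavior.** Shuttle sessions: Bernoulli escapes with truncated
  log-normal latencies (defaults: p(escape) = 0.8, median 2 s), 30
  trials, 10 s shocks, 30 s ITI. Looming tracks: wander near the arena
  center, a straight run whose first in-nest sample lands exactly at
  the requested latency (snapped to the 20 Hz sample grid), then
  in-nest movement at ~5 cm/s with requested freeze bouts held at zero
  speed and grid-aligned so scored freezing equals the requested
  duration exactly.
- **Slice cohorts.** Bernoulli connectivity; log-normal I-AMPA and
  I-GABA/I-AMPA ratios (so `exp(ratio_logmean)` is the true median
  ratio); access-resistance series as a small multiplicative random
  walk; optional paired-pulse amplitudes with log-normal PPR, where a
  release-probability drop is emulated by a larger mean PPR.

What the generators do *not* emulate: spike-sorting contamination and
waveform drift, bleaching and wavelength-dependent artifact gain in
photometry beyond a scalar mismatch, realistic GCaMP rise kinetics,
video-tracking noise and body-part ambiguity, and any between-animal
variance structure. Passing the closed-loop suite therefore shows the
estimators are correct for their stated models, not that they are
robust to every pathology of real recordings.

## Behavioral scoring choices

Failed shuttle trials are excluded from the latency mean (failure rate
and latency are separate measures); `impute_failures_at_max=True`
scores them at the 10 s ceiling instead. An escape at exactly 10 s
counts as success, since the shock ends when the animal shuttles.
Freezing is operationalized as speed < 2 cm/s sustained ≥ 1 s (both
configurable — the source assays state that freezing was calculated but
give no threshold), and the looming strategy label is whichever
criterion is met first after stimulus onset: nest entry (escape-first)
or a freezing bout (freeze-first). RTPA occupancy is sample-time
weighted with each inter-sample interval attributed to the side
occupied at its start.

## Numerical and degenerate-input choices

- Zero-length windows, empty cohorts/sessions, <2 ISIs, zero I-AMPA,
  zero first-pulse amplitude, non-positive F0 and missing channels all
  raise typed errors rather than returning NaN.
- With an all-zero baseline the excitation threshold is 0 and any
  post-stimulus spike triggers the (strict) criterion — intended
  behavior for silent-baseline units.
- Access-resistance QC keeps a rise of exactly 20% (the discard rule is
  a strict "more than").
- Connectivity percentages are stored exact and rounded to one decimal
  only for reporting. With 27 recorded cells, 15 connected gives
  55.56% → 55.6% at one decimal; published legends occasionally print
  values (e.g. 89.2% of n = 28) that no integer count reproduces at one
  decimal, so such printed values are not used as test targets.

## Problem sizes in the validation suite

The test suite and `scripts/acceptance.py` use 1,000 trains (60 s) for
the burst oracle, 100 seeds × 600 s for the CV closed forms, 200
replicates for power/recovery, 1,000 replicates each for the null
false-positive comparison (classifier vs. independent oracle), 200
replicates per rung of the five-step evoked-magnitude ladder, 500
seeds × 30 trials for shuttle recovery, and 50 trains per firing mode —
sizes chosen so every Monte-Carlo comparison has binomial error well
inside its tolerance while the whole validation runs in seconds.
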