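# Methods

This note documents the models, statistics and design choices implemented in
`critrange`, the defaults they carry, and what the synthetic data can and
cannot show.

## Network model

The model is a population of `n_neurons = 1000` binary probabilistic
integrate-and-fire units updated in discrete steps of `step_duration = 1 ms`.
At step *t* each neuron fires if an external Bernoulli event (probability
`p_ext`) succeeds, or if a recurrent Bernoulli event succeeds with
probability `p_i(t) = clip(I_i(t), 0, 1)`, where

    I_i(t) = ( Σ_{j≠i} W_ij s_j(t−1) ) / h_i(t).

The two events are independent and combined by OR; `external_flags` records
the external draw outcome regardless of the recurrent draw.  The divisor
`h_i(t)` implements activity-dependent depression: it is neuron *i*'s own
spike count over the causal window of the preceding `T` steps
(`depression_window`, default 80), replaced by 1 when the count is zero, and
identically 1 when `T = 0`.  The window is *causal* (τ = t−T … t−1): a
formulation that includes the undecided current state would make the spike
depend on itself, so we use the causal reading.  Depression counts all
spikes, external and recurrent alike, since it tracks the neuron's own state
variable.

**Coupling matrix.** Entries uniform on [0, 1]; `round(N·0.2)` randomly
chosen columns negated (inhibitory neurons); diagonal zeroed; then the whole
matrix is rescaled once by `1/|λ_max|` so the leading eigenvalue magnitude is
exactly 1 (tolerance 1e-9).  "Leading" means largest magnitude; for this
ensemble it is real and positive (a warning is emitted otherwise).
Rescaling always happens at γ = 1; the inhibitory modulation
(`apply_inhibitory_modulation`, multiplying only the negative entries by
γ ∈ [0, 3]) is applied afterwards, so that modulation moves the eigenvalue
off the critical value — γ = 0 raises it to ≈ 1.34 (supercritical), γ = 3
lowers it to ≈ 0.8 (subcritical).

**RNG protocol.** One seeded `numpy` Generator drives an entire simulation
(matrix construction included, unless a prebuilt matrix is passed).  Per
step, one uniform draw per neuron for the recurrent event, then one per
neuron for the external event, in fixed order — identical `(config, seed)`
therefore give bit-identical rasters, and a naive per-neuron loop
implementing the same protocol reproduces the vectorized engine exactly
(this equivalence is a test).

**Stimulus protocol.** Trials step `p_ext` from the baseline (5e-6 per
neuron per step, i.e. 5 externally driven network spikes/s) up to a level
for a 200-step response window; the response is the network spike count in
that window.  Levels default to 10 log-spaced values spanning 5e-6 … 1e-3
(mirroring the 10 experimental puff intensities), each repeated 20 times in
pseudorandom order.  The session is *continuous* by default: the network
carries its state across trials, separated by 1500 baseline-drive steps.
We chose the continuous protocol over a per-trial reset because regimes
whose stationary state is self-sustained (the no-depression supercritical
network saturates and stays saturated) must be measured in that state; a
quiescent restart per trial gives such regimes a spurious, ignition-driven
response range.  A reset mode remains available
(`reset_between_trials=True`).  The matched ongoing floor R_min is the mean
network count over the final 200 steps of each inter-trial gap, discarding
the first 5 trials' gaps as warm-up — the session starts from quiescence
and slow variables (depression, self-sustained activity) need a few trials
to reach stationarity; without the discard a fully saturated state appears
to rise above its own floor purely through start-up bias.

## Avalanches and κ

The population count series uses half-open bins `[k·dt, (k+1)·dt)`; bins
overlapping stimulus epochs are masked, not zeroed.  An avalanche is a
maximal run of unmasked bins with count **strictly** above the threshold;
size is the raw spike sum over the run, duration the run length, spatial
area the number of channels with ≥ 1 spike during the run.  Runs touching
the series edges or abutting a masked bin are discarded: their true extent
is unknown and keeping them would bias the size distribution.  Defaults:
model path bins of 1 step with threshold 10 spikes; experiment path
DT = 7.5 ms with TH = 11 (the means of the per-recording choices), both
configurable, with the robustness sweep covering DT, TH ∈ 5–20.

κ compares the empirical size CDF with a continuous truncated power law of
density exponent −1.5 at `m = 10` log-spaced points β_k (endpoints
included) between the observed minimum and maximum size:

    κ = 1 + (1/m) Σ_k [F_ref(β_k) − F_emp(β_k)].

Averaging (the 1/m factor) rather than raw summation follows the statistic's
original normalization and is the only convention consistent with the
observed κ range (≈ 0.5–2); the raw sum is available via `aggregate="sum"`.
The reference is anchored at each sample's own observed range — the only
anchoring under which κ = 1 is attainable exactly for a power-law sample.
The sign convention (reference minus empirical) makes large-avalanche-heavy
samples give κ > 1.  Samples with fewer than 30 avalanches are flagged
`low_count`.

The maximum-likelihood size exponent is fit with a truncated *continuous*
power-law likelihood on the observed range, maximized numerically.
Truncation matters: avalanche samples are threshold-limited from below and
system-size-limited from above, and an untruncated estimator is biased on
such data.  Discreteness of sizes is ignored; sizes start above the
detection threshold (≥ 11), where the continuous approximation is good.

## Correlations

Model rasters are channelized into 32 contiguous near-equal groups (1000
neurons → 8 groups of 32 + 24 of 31), mimicking a 32-electrode array, and
binned at 10 steps (~10 ms) by default — the paper-scale DT; the value is
configurable and correlations grow with bin width.  Zero-lag Pearson
coefficients are computed for all n(n−1)/2 unordered pairs over unmasked
bins; zero-variance channels yield undefined pairs which are excluded
pairwise (not dropped globally) and omitted from the mean.  For recordings,
ongoing-activity statistics (κ, correlations, R_min) exclude
`[onset, onset + stimulus duration + 1 s]` around every trial; the 1 s
recovery margin is our choice.

## Response curves and dynamic range

Experiment path: per-trial response = total spikes across channels in the
100 ms after onset; stimulus = per-trial dominant-whisker speed (the whisker
with the largest mean evoked response; ties resolve to the lowest index).
Responses are averaged in 10 equally spaced stimulus bins spanning the
observed range (empty bins flagged and excluded) and fit by least squares
with `f(x) = R_max/(1+exp(−b(x−c))) + R_min`, holding R_min fixed at the
recording's ongoing count per 100 ms.  Initialization: R_max ← max response
− R_min, c ← half-max stimulus, b ← 4/stimulus-range, with b bounded in
(0, 100]; a fit that collapses the amplitude or pins the slope bound is
flagged non-converged and yields no Δ.

Dynamic range uses the response landmarks R_p = R_min + p(R_max − R_min)
(p = 0.1, 0.9) and the analytic inversion
S_p = c − (1/b)·ln(R_max/(R_p − R_min) − 1), with

    Δ = 10 · log10(S90/S10).

Δ is invariant to rescaling of either axis.  A shallow fit can push S10 to
or below zero stimulus; it is then clamped to the smallest positive observed
stimulus (with a warning) — negative speeds are unphysical.

Model path: no sigmoid is fit (model curves are far less noisy).  The mean
response per level is made monotone by weighted pool-adjacent-violators and
interpolated piecewise-linearly on the log10-stimulus axis to locate
S10/S90; levels above 1e-3 are discarded by default (the physiologically
relevant range — stronger drives saturate the network in ways real whisker
stimulation never does), and `truncate_at=None` gives the full range.
Conventions at the extremes: a curve already above a landmark at the weakest
level clamps that landmark's stimulus there (a fully saturated state
traverses nothing and gets Δ = 0); a curve whose monotone regression never
reaches R90 has undefined Δ (the sweep tables record 0 with
`delta_defined = False`).

## Synthetic recordings

`generate_recording` emulates a ~26 min, 32-channel MUA session: 160 s of
ongoing lead-in followed by 200 stimulus trials (10 intensities × 20
repetitions, pseudorandom order, 7 s apart, 1 s nominal puff).  Note the
trial design itself requires ≥ 1400 s, so the default duration is 1560 s.
Each trial's whisker speed is its level mean (2–28 mm/s by default) times a
lognormal jitter (σ = 0.2) — repeated identical puffs move a whisker
differently, with no stated distribution, so lognormal is our choice for a
positive multiplicative jitter.  The evoked response is Poisson with mean
f(speed) − R_min over the 100 ms window, from the planted sigmoid
(R_min = 2, R_max = 50, b = 0.5, c = 10 mm/s by default), distributed across
channels proportionally to their baseline rates (no per-electrode response
profile is specified anywhere, so proportional allocation is the neutral
choice).  `truth_delta` computes the planted Δ analytically with the same
clamping rule as the analysis path, so truth and estimate are comparable.

Ongoing activity comes from one of two sources.  The *parametric* source is
per-channel Poisson spiking modulated by a shared two-state (quiet/burst)
Markov process — a statistical fixture producing tunable inter-channel
correlations and count excursions, not a biophysical model; at the default
low rate (20 Hz network-wide, matching R_min = 2 per 100 ms) it produces no
suprathreshold avalanches, which is intentional — it serves the
response-recovery studies.  The *model-driven* source channelizes a network
simulation at a chosen γ and is the fidelity option for κ/correlation
recovery.  What passing tests on synthetic data do **not** show: recovery
under real MUA nonstationarities (electrode drift, state changes within a
recording), non-Poisson evoked statistics, or per-electrode tuning
heterogeneity.

## Problem sizes and numerical choices

Simulation lengths in the test suite and acceptance script are chosen as the
package's own working sizes: critical-state statistics use 5×10⁵ steps × 3
seeds (≈ 900 avalanches per seed at γ = 1); the γ-grid state sweep uses
1.5×10⁵ steps.  Dynamic-range sweeps default to the full 20 repetitions per
level with 1500-step gaps; the suite's ordering checks run with 800-step
gaps (still an order of magnitude beyond the depression timescale), 5 seeds
and 20 repetitions for the truncated-stimulus comparison (its effect size,
~1.5 dB, is the smallest of the three headline orderings), and 3 seeds with
12 repetitions for the two full-range conditions, whose seed variance is
far smaller.  The stepping engine switches from gathered column sums
to a BLAS matvec above N/4 active neurons; both branches produce identical
draws and identical rasters.  Eigenvalues for N ≥ 64 come from ARPACK
(`scipy.sparse.linalg.eigs`, largest magnitude), smaller matrices from the
dense solver.  Degenerate inputs raise (all-identical sizes, constant
stimuli) or flag (non-converged fits, low avalanche counts) rather than
returning silent numbers.

## Known limitations

* κ depends on DT and TH (it systematically increases with DT); the
  robustness sweep quantifies this but no bias correction is applied.
* The model reproduces the monotone rise of mean pairwise correlation as
  inhibition weakens, but not the experimentally observed *width* maximum of
  the correlation distribution at the critical state: in the model the
  pair-correlation IQR grows monotonically toward the subcritical regime at
  every correlation bin width we examined.  `CorrelationResult.iqr()` makes
  the comparison a one-liner for real recordings.
* The truncated-stimulus dynamic-range peak at γ = 1 is a ~1.5 dB effect at
  the default problem sizes; single-seed comparisons are noisy, which is why
  orderings are always assessed on seed averages.
* The continuous-session protocol makes late trials weakly dependent on
  earlier ones (carry-over through slow variables); pseudorandom level order
  prevents systematic confounds but does not remove the dependence.
* The experiment path consumes a per-trial speed scalar; whisker tracking,
  spike detection from raw voltage, and pharmacology are out of scope.
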