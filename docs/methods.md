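# Methods

## The model

The package reconstructs forelimb EMG envelopes from two simultaneously
recorded neural input classes: *descending* input — high-gamma
(60–180 Hz) band power of motor-cortical ECoG channels (M1, PMd, PMv) —
and *afferent* input — instantaneous firing rates of peripheral
(dorsal-root-ganglion) sensory units.  The decoder is a lagged linear
model on trial-epoched, baseline-subtracted modulation traces sampled
at 200 Hz:

    y_j(t) = Σ_k Σ_l  w_{j,k,l} · x_k(t + l·δ),    δ = 5 ms, l = −10 … −1,

so the EMG of muscle *j* at bin *t* is read out from 5–50 ms of input
history, the conduction-delay window within which cortical and afferent
activity can drive spinal motor neurons without re-entrant reflex
contributions.  One model is fitted per muscle; there is no intercept,
because every trace is a baseline-subtracted modulation.

The *component* of a channel subset S (descending channels, afferent
channels, one cortical area, a single electrode) is the same sum with
all weights outside S zeroed.  Linearity makes components exactly
additive over any partition of the channels; the implementation
accumulates per-channel contributions in index order, so partitions
re-sum to the full reconstruction to within float-64 round-off
(≈1e−16 relative, asserted at 1e−12).

## Estimation: grouped automatic relevance determination

Weights are estimated by Bayesian linear regression with one relevance
precision α_k *per input channel*, shared by that channel's 10 lag
weights (grouped ARD), and a global noise precision β.  Hyperparameters
are optimised by evidence maximisation with MacKay fixed-point updates:

* posterior: Σ = (β XᵀX + A)⁻¹, μ = β Σ Xᵀy, with A = diag(α_k repeated
  over each group);
* per-group effective degrees of freedom γ_k = d_k − α_k tr(Σ_kk),
  then α_k ← γ_k / ‖μ_k‖² and β ← (N − Σγ) / ‖y − Xμ‖².

The fit is deterministic: β starts at 1/(0.1·var y), the α_k start
weakly informative (first iterate ≈ ridge/OLS), and updates run in a
fixed order until the relative evidence change falls below 1e−6 (or 500
iterations, flagged as unconverged).  β is capped at 1e12/var(y) so the
noiseless limit stays finite; there the posterior mean coincides with
ordinary least squares to well under 1%.

Smooth ARD updates cannot reach the boundary optimum α_k = ∞, and with
tens of thousands of autocorrelated samples they leave chance-level
channels with small nonzero weights.  After each convergence the
implementation therefore greedily removes any group whose removal
*raises* the log evidence, requiring each retained group to buy more
than the Occam correction for its type-II-optimised hyperparameter
(0.5·ln N nats per group), and re-converges; rounds repeat until the
active set is stable.  On the synthetic sessions this margin separates
true from null channels by two to three orders of magnitude (null
channels cost ≲0.2 nats; the weakest true channel ≳700), so the
threshold is not delicate.  A final hard mask zeroes any channel whose
posterior weight norm is below 1e−8 of the largest channel norm.

## Preprocessing

All filters are applied forward-only (causal).  The analysis reasons
about millisecond lead/lag relations between cortex, afferents and
muscle; zero-phase filtering would propagate signal backwards in time.
The costs are a few milliseconds of group delay common to all EMG
channels, which the lag window absorbs.

* **EMG** — 2nd-order Butterworth band-pass 1.5–60 Hz, rectification,
  polyphase anti-aliased resampling to 200 Hz (tiny negative ringing
  clipped to zero, as an envelope is nonnegative), and an 11-bin
  (55 ms) centred moving average.
* **ECoG** — 2nd-order Butterworth band-pass 1.5–240 Hz, STFT on 100-ms
  Hann windows at a 5-ms step, power per frequency bin divided by its
  session mean (so each bin's normalized power has session mean exactly
  1), then averaged within high-gamma 1 (60–120 Hz) and high-gamma 2
  (120–180 Hz).  The decoder uses the mean of the two bands per
  electrode by default — keeping one descending input per electrode
  makes per-electrode attribution and ground-truth comparisons
  one-to-one — with both-bands-as-separate-inputs available via
  `RunConfig(hg_mode="separate")`.
* **Afferent rates** — inverse interspike interval held piecewise
  constant on each interval between consecutive spikes (zero outside
  the first-to-last-spike span; fewer than two spikes yields a zero
  trace with a warning), convolved with a causal exponential kernel
  (τ = 50 ms) normalised to unit area, sampled at 200 Hz.  A sustained
  regular train at rate r converges to r within 1% after 5τ.
* **Epoching** — the per-trial baseline is the mean from −1250 to
  −750 ms before movement onset; epochs cover −500 to +1500 ms
  (401 bins).  Events whose context does not fit the recording are
  dropped with a warning; epoched tensors carry a stage tag and refuse
  re-epoching.

## Synthetic sessions

The generator emulates the study conditions and provides exact ground
truth.  Defaults: 32 ECoG channels (deterministic 45/30/25% M1/PMd/PMv
labels on an 8×4 grid), 20 afferent units, 10 muscles, 150 trials
≈4 s apart, cortical lead 150 ms, afferent modulation from movement
onset, per-channel support fraction 0.5, observation noise 0.3 × the
modulation SD, one quarter of muscles with net-negative ("antagonist",
reciprocal-inhibition analog) afferent weights.

* Cortical channels carry smooth trial-locked envelope bumps (100-ms
  half-cosine rise, 500-ms plateau, 300-ms fall) starting one cortical
  lead before each event, with 2–4-fold amplitudes jittered ±30% per
  trial, plus slow background fluctuation.  The raw ECoG is
  amplitude-modulated 60–180 Hz noise (power ∝ envelope) plus
  low-frequency noise, so the STFT pipeline genuinely recovers the
  latent envelope (r ≈ 0.8; the limit is the chi-square noise of
  100-ms band-power estimates).
* Afferent units fire inhomogeneous-Poisson trains (baseline 10–30 Hz,
  onset-locked rate bumps of 20–60 Hz) with a 2-ms absolute refractory
  period, which keeps inverse-ISI estimates bounded as for real units.
* EMG is the lagged mixture of the *recomputed* preprocessed inputs
  (the generator runs the package's own high-gamma and rate estimators
  on its raw signals), with afferent weights rescaled per muscle so the
  afferent contribution is 0.8 × the descending contribution's SD,
  plus white noise and a small tonic offset.  Because the mixture model
  is defined on epoched, baseline-subtracted traces, a per-trial
  constant (the difference between lagged and unlagged baseline-window
  means of the inputs) is added so that the epoched EMG is an *exact*
  lagged mixture of the epoched inputs.  Without this the tiny
  inconsistency, amplified by the ill-conditioned lag design, would
  make even noiseless weight recovery meaningless.
* The raw EMG channel embeds the modulation on a deterministic in-band
  tone carrier (35–48 Hz, random phase) whose rectified mean is
  constant; a stochastic interference-pattern carrier would add
  irreducible rectification noise under 55-ms smoothing.  Envelope
  recovery of the latent EMG reaches r ≥ 0.9 at default noise.
* Joint-angle traces are smoothed ramps from movement onset on one
  moving joint; they document the stretch-reflex sign narrative and are
  not used by the decoder.

What passing tests on these sessions do **not** show about real data:
the generator is exactly linear with white observation noise, inputs
are stationary across a session, and no gain modulation, nonstationary
tuning, artifacts, or line noise are simulated.  Results on real
recordings depend on how far those assumptions hold.

## Evaluation protocol

Sixfold cross-validation per session: disjoint random test sets of 21
trials with 108 random training trials each (the 129-trial session
protocol; `RunConfig.scaled_for(n)` keeps the same proportions at desk
scale).  Accuracy is Pearson correlation and VAF
(1 − Σ(y−f)²/Σ(y−ȳ)²) on concatenated test-trial modulation traces;
session values are fold means.  Shuffled controls permute 2-s blocks
(≈ trial length, configurable) of each input channel's continuous
record independently, retrain, and test on unshuffled data.
Sliding-window models refit the decoder on target bins inside a 500-ms
window stepped by 100 ms; their VAF is computed on the test-trial
*averaged* trace and summarised by the fold median.

Onsets: the threshold is one fifth of the observed-EMG average's
maximum within ±250 ms of movement onset, shared by reconstruction and
components; onset is the first bin of the earliest run of ≥5
consecutive bins strictly above threshold searching from the epoch
start, offset the first bin at/after +500 ms starting ≥5 consecutive
bins strictly below it.  Component sizes are temporal means of the
positive- (or negative-) clipped trial-averaged component over the
modulation period (default −100…1150 ms), with the window length as
denominator (stable when few bins survive the clip; the surviving-bins
denominator is available behind a flag).  The early-movement afferent
size (55–100 ms) keeps its sign and classifies afferent effects as
facilitative or suppressive.

## Numerical and design choices

* The 11-bin EMG smoother is centred (the description of the window
  alignment is open); this symmetrises the envelope at the cost of a
  ±27.5-ms caveat on absolute EMG lead times.
* The STFT taper is Hann (unspecified elsewhere); power normalisation
  is per channel *and* frequency bin.
* Ties at the onset threshold break toward "not exceeded" (strict
  inequality), and the onset search starts at the epoch start, −500 ms,
  consistent with premovement onsets near −60 ms.
* Trial folds, block shuffles, and the generator all draw from seeded
  generators; a single pipeline seed is expanded into independent
  per-stage substreams, so every artifact is bit-reproducible.
* Desk-scale problem sizes in the test-suite and acceptance script
  (sessions of 40–150 trials, 8–35 input channels, 2–8 muscles) were
  chosen so each experiment carries the statistical power its claim
  needs — identifiability and recovery checks use the full 150-trial,
  35-channel setting — while the whole suite stays interactive.

## Known limitations

* The exact hyperpriors of the original channel-sparse regression are
  not published; this implementation guarantees only the grouped-ARD
  contract (per-channel relevance, evidence maximisation, channel
  pruning) plus the evidence-margin elimination described above.
* Group-level inferential statistics (paired t tests, ANOVA) are out of
  scope; per-fold metric tables are exported for external testing.
* The deposited-data layout of the original recordings is not modelled;
  sessions enter through the package's HDF5 container only.
* With strongly collinear channels the individual lag profiles within a
  retained channel are weakly determined (the fit is regularised along
  flat directions); support recovery and component attribution are the
  robust quantities.
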