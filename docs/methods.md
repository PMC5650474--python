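# Methods

This document describes the generative model behind the synthetic sessions,
the analysis conventions, the numerical choices, and the known limitations.
The README covers installation and usage; this file covers *why* the pieces
are built the way they are.

## 1. Scientific model

The package studies a premotor neuron in a gaze-control structure whose
activity both *prepares* and *drives* saccadic eye movements:

- During the delay period of a delayed-saccade task, the neuron's rate ramps
  up linearly (a stochastic accumulator). When the accumulated drive reaches
  an initiation criterion, downstream omnipause (OPN) inhibition is released
  and a saccade follows after a short fixed lead.
- Eye velocity during the movement is a gain-scaled copy of the neuron's
  motor drive, delayed by a fixed **efference delay** (default 12 ms). This
  is the quantity the lagged-correlation analysis recovers.
- On **blink trials**, an air puff delivered 100–250 ms after the GO cue
  evokes a blink. The blink (a) opens the OPN gate early, (b) superimposes a
  stereotyped blink-related eye movement (BREM) loop on the eye, (c) lowers
  the effective initiation criterion (`blink_threshold_fraction`, default
  0.8) and accelerates the accumulation (`post_blink_slope_multiplier`,
  default 3), and (d) lets a fraction of the *preparatory* drive leak onto
  the eye while the gate is open (`leak_gain`, default 0.10 deg/s per
  spike/s, directed at the goal).

Mechanism (d) is the model's expression of *latent motor potential*:
preparatory activity that is normally gated off the plant becomes visible in
eye velocity once inhibition is removed, and it does so at the same efference
delay as the saccadic burst. Mechanisms (c) are the substrate for the
threshold and accumulation-rate analyses.

## 2. Synthetic data generator

### Control trials

Per trial the generator draws a preparatory rate scale `q` (lognormal,
`rate_scale_sd`), an accumulation slope (`prep_slope_mean` ± `prep_slope_sd`),
smooth multiplicative rate noise, a burst-gain jitter, and a direction jitter.
The firing rate is `baseline + q·ramp·(1+noise) + burst·(1+noise)`; the burst
is the saccadic velocity profile divided by `burst_gain`, so velocity equals
`burst_gain × rate` shifted by `efference_delay` — across-trial rate
variability maps one-to-one onto velocity variability at the injected lag.
Spikes are an inhomogeneous Poisson draw from the rate. Saccade amplitude
follows a saturating main sequence `V(A) = vmax·(1 − exp(−A/a0))`; positions
are integrated velocity plus white measurement noise and slow fixational
drift.

### Blink trials

The blink time is drawn in `blink_window` after GO; trial latents are
resampled until the natural saccade would not have pre-empted the blink.
From blink onset the eye carries a BREM draw plus `leak_gain × delayed
preparatory drive` (gate open), and the saccade launches when the accelerated
accumulator reaches the reduced criterion. The saccade is aimed so the final
endpoint compensates for the BREM loop and the expected leak drift, matching
the empirical observation that blink-triggered saccades stay accurate.

### BREM

The BREM velocity template is a smooth biphasic loop per component
(`brem_amplitude_mean`, 180 ms support) whose integral closes (net
displacement ≈ 0). Trials draw a multiplicative gain (`brem_gain_sd`) and
smooth additive noise (`brem_noise_sd`). Dedicated fixation-blink trials
(`n_brem_trials`) provide the data from which analyses rebuild the template —
the analysis never sees the generator's internal template.

### Realism and deliberate simplifications

Realistic: Poisson spiking on top of structured rate variability, main-
sequence kinematics, measurement noise and drift, trial-to-trial latency
variability from the accumulator, closed-loop BREMs with gain and shape
noise, blink-triggered movements whose embedded saccade must be re-detected
from kinematics. Simplified: one neuron per session with the target in its
response field (no tuning curve), a single fixed target, velocity is exactly
linear in rate during the movement (no burst-generator nonlinearity), the
OPN gate is binary, and blink dynamics of the lid itself are not modelled.

## 3. Preprocessing

- **Velocity** is the derivative of position estimated with a Gaussian-
  derivative kernel (s.d. 1.5 ms). A derivative-of-Gaussian filter was chosen
  over a Butterworth-plus-difference chain because it is zero-phase, has an
  analytic impulse response (testable against closed forms), and one
  parameter. Acceptance tolerances are insensitive to the exact cutoff.
- **Movement detection** uses a 50 deg/s onset and 30 deg/s offset criterion
  per component, taking the earlier component as onset.
- **Spike density** convolves the spike train with a Gaussian kernel — 3 ms
  for correlation analyses (temporal precision), 10 ms for accumulation-rate
  fits (smoothness for slope estimation) — with mass conservation verified
  to 1e-6.
- **Normalization**: all rates in a session are divided by the control-trial
  peri-saccadic peak rate, so blink trials share the control-derived divisor.

## 4. Blink kinematics

The BREM template is the pointwise mean ± s.d. of the fixation-blink traces
(s.d. floored at 1e-3 deg/s). The embedded saccade in a blink-triggered
movement is the first sample at which either velocity component leaves the
mean ± 2.5 s.d. envelope and stays outside for ≥ 15 consecutive samples,
with a plausibility check (≥ 80 deg/s within 10 ms of the putative onset)
that rejects slow sustained deviations; the earlier component wins. Trials
with onset delay ≥ 20 ms are "triggered"; neurons need ≥ 7 detected blink
trials for the threshold analysis and ≥ 7 *triggered* trials for the
motor-potential and accumulation analyses.

Residual kinematics subtract the template mean from each component (nothing
beyond template support), and the projected variant projects the residual
vector onto the goal direction — keeping pre-saccadic, goal-directed leakage
signed and BREM-dominated components suppressed.

### Alignment convention

Both conditions are aligned by the same operational rule: the first 50 deg/s
crossing of the analysis kinematic signal (raw for control, residual for
blink, searched at/after the detected embedded onset). A uniform rule keeps
condition comparisons free of alignment-induced offsets.

## 5. Motor-potential analysis

For each neuron, the across-trial Pearson correlation between activity
`a(t+Δ)` and the kinematic signal `v(t)` is computed for lags Δ ∈ [−50, 50]
ms at every movement time; population maps average neurons. The **optimal
efferent delay** at each time is the argmax over lags (ties broken toward
the most causal, i.e. most negative, lag), smoothed for display with a 5 ms
moving average; means over the post-onset (0–40 ms) and pre-onset (−30–0 ms)
windows are the headline numbers. Cells with fewer than 7 finite trials or
zero variance are NaN; correlations use pairwise-complete trials.

**Significance** uses a trial-shuffle bootstrap: per neuron, the trial
pairing between activity and kinematics is permuted (default 100 shuffles),
and the population correlation timecourse at the optimal delay is compared
against the shuffled distribution. The null band uses a conservative order
statistic (k = ⌊0.025·n⌋ − 1) rather than interpolation, so the test errs
toward fewer significant points. The test is **one-sided**: a time point is
significant only when the observed correlation exceeds the upper bound of
the shuffled null band. The motor-potential hypothesis is directional
(positive rate-to-velocity gain), and velocity-threshold alignment
mechanically induces a small *negative* activity–velocity correlation in the
last few milliseconds before onset — trials with steeper bursts sit lower on
the velocity rise just before the 50 deg/s crossing. A two-sided test flags
that artifact; the one-sided test does not, and calibrates at ≤ 5% false
positives on leak-free data.

### Pre/post delay comparison

The pre- vs post-onset delay comparison is a Welch t-test on the unsmoothed
per-time argmax delays with **autocorrelation-corrected effective sample
sizes** (n_eff = n / (1 + 2Σρ_k), positive-ρ truncation). Neighbouring
per-millisecond argmax values share trials and smoothing, with lag-1
autocorrelation up to ~0.9; uncorrected sample sizes would overstate the
evidence for any difference several-fold.

## 6. Threshold (initiation-criterion) analysis

Normalized saccade-aligned activity is averaged in seven half-open 10 ms
bins from −50 to +20 ms. Across neurons, each bin gets a paired Wilcoxon
signed-rank test (blink vs control) and a blink-on-control regression; per
neuron, a rank-sum test across trials at α = 0.001 classifies each bin as
higher/lower/no-diff. Class *traces* are right-edge labeled: the class at
time t uses only activity in [t−10, t), so a pre-onset label never mixes in
the shared saccadic transient at or after t.

## 7. Accumulation-rate analysis

The trial-averaged 10 ms-kernel density around the (pseudo-)blink gets two
independent least-squares lines on [−20, 0) and [0, 20] ms; the slope change
is summarized by the modulation index (post − pre)/(post + pre). The
surrogate control resamples control trials with pseudo-blink times drawn
from the session's empirical blink-time distribution (1000 pseudo-trials),
so the surrogate inherits the real blink-time marginal without any blink
physiology. Blink and surrogate indices are compared per neuron with a
paired signed-rank test.

## 8. Null configurations

Negative controls re-generate data with the mechanism under test switched
off:

- **Motor potential:** `leak_gain = 0` — no preparatory drive reaches the
  eye before the saccade; pre-onset significance must stay at the α level.
- **Threshold:** `blink_threshold_fraction = 1, post_blink_slope_multiplier
  = 1, leak_gain = 0, opn_lead = 12` — blink and control saccades then share
  the initiation criterion, accumulation dynamics, and profile lead
  (`opn_lead` is matched to the efference delay so the natural gate-to-
  movement lead does not differ between conditions), making the two
  conditions statistically exchangeable at the criterion. The null is read
  directionally (a false positive is a *significant blink-below-control*
  pre-onset bin) because the hypothesis is directional and any-of-7-bins
  two-sided significance fires at ~30–40% family-wise by chance.
- **Accumulation:** `post_blink_slope_multiplier = 1` — no slope change at
  the blink; the false-positive rate of the directional call (`blink
  indices significantly above surrogate`) stays at ≈ α over 20 seeds.

## 9. Numerical choices

- 1 kHz sampling everywhere; all times in ms, rates in spikes/s, velocities
  in deg/s.
- All randomness flows from explicit seeds through `numpy` Generators;
  per-session seeds are spawned via `SeedSequence` and reduced mod 2³¹−1.
- Correlation cells are computed by vectorized column gathers and verified
  cell-by-cell against `scipy.stats.pearsonr` to 1e-12.
- On-disk bundles round positions to 5 decimals (0.01 millideg) and spike
  times to 1 µs; round-trips are lossless at analysis precision.

## 10. Limitations

- The generator realizes the efference delay by construction; delay-recovery
  acceptance is parameter recovery, not an empirical discovery.
- Single neuron per session, single target: population analyses treat
  sessions as exchangeable neurons and cannot probe tuning or ensemble
  structure.
- The velocity-threshold alignment artifact (Section 5) is suppressed by the
  one-sided test, not removed; analyses of *negative* pre-onset coupling
  would need a different alignment strategy.
- The BREM model is a smooth closed loop; real blink-related movements have
  heavier-tailed shape variability, so embedded-saccade detection accuracy
  on real data is likely somewhat worse than the synthetic median error
  (~2 ms).
- Wilcoxon-based population tests assume neuron exchangeability and ignore
  session-level covariates (no mixed-effects modelling).
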