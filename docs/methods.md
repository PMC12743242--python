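# Methods

This note documents the models, parameter choices and numerical decisions
behind `lumbargait`, and what the synthetic test substrate does and does
not establish about real recordings.

## Signal model and conventions

Recordings are tri-axial accelerations of a lumbar-worn sensor during one
continuous walking bout, held internally in m/s² (g-unit inputs are
multiplied by standard gravity, 9.80665) on a uniform grid, with time in
seconds from bout start. All event times in public outputs are float
seconds, never sample indices, so downstream comparisons are independent
of sampling rate. The signed vertical channel reads −g at rest.

The Gaussian first-derivative wavelet has normalized centre frequency 0.2
per sample, so a target frequency f at sampling rate fs maps to
scale = 0.2·fs/f (1.25 Hz at 50 Hz ↦ scale 8; scales are continuous and
rounded to 0.1). The pywt `gaus1` coefficient series equals the *negative*
smoothed derivative of its input; wherever a stage needs "smoothed
derivative" polarity (FC detection: coefficient peaks coincide with
forward-acceleration maxima; the legacy detector: peaks of the smoothed
vertical acceleration) the coefficients are negated. The IC stage consumes
the raw pywt polarity, which is exactly the one the midpoint rule is
phrased in. Edge handling: the input is extended symmetrically by
2·scale samples and cropped after the transform; detectors additionally
discard events within a 2·scale-sample margin of either bout edge, and
evaluation on fixtures uses an interior analysis region (default 2 s off
each end), the analogue of an instrumented walkway's active area — the
region filter applies to reference events too, since a reference exists
only inside its measurement area.

All filtering is zero-phase (forward–backward fourth-order Butterworth,
SOS form). Event *timing* is the deliverable of this package; a one-pass
IIR filter's group delay would bias IC/FC times by tens of milliseconds.
The band-pass (0.25–7.5 Hz) serves axis identification and step-frequency
estimation; a 20 Hz low-pass precedes contact detection.

Tilt correction rotates the signal so the time-averaged gravity vector
lies along the signed vertical axis. It is implemented as the minimal
(Rodrigues) rotation between the mean-acceleration direction and the
vertical axis — identical to the classical pair of small-angle rotations
about the horizontal axes for the small tilts it is meant to repair, but
exactly energy-preserving and well-behaved at larger tilts. It is applied
once per bout, not adaptively.

## Mean step time

The AP channel is transformed at ten scales whose target frequencies are
*linearly* spaced over 0.5–5.0 Hz (log spacing is available in the
configuration) and the coefficients are summed sample-wise — the *signed*
sum. A rectified (absolute or squared) sum doubles the frequency content
and introduces an autocovariance peak at the IC→FC transient spacing,
i.e. below the step period; the signed sum preserves the step-periodic
oscillation so that the first positive autocovariance peak is the step
time. Both rectified modes remain selectable. Per 5-s window (50 %
overlap; a single whole-bout window below 5 s) the biased, mean-removed
autocovariance is computed; the window's estimate is its first local
maximum at lag ≥ 0.2 s (≤ 2 s) with prominence above 0.1 of the lag-0
value **and positive height** — a negative "peak" is a ripple in an
anticorrelation trough, not evidence of periodicity. The bout estimate is
the median over windows, using the lower-midpoint convention on even
counts so the estimate is an actually observed lag.

## Contact detection

The adaptive detector ties its wavelet centre frequencies to the bout's
mean step frequency through two affine relations, f_CWT = a·f̄ + b (one
for IC, one for FC), clamped below at 0.5 Hz so any coefficients map the
whole physiologic band to positive frequencies. The packaged default
coefficients — IC (2.01, 8.09), FC (10.07, −10.67) — were obtained by
running `calibrate_scale_relation` (scale sweep per bout, cost
(1 − F1) + λ·RMSE with λ = 1, least-squares affine fit of the per-bout
optima) on noiseless simulator bouts spanning 1.2–2.2 Hz, and can be
overridden from the configuration for sensors or populations with other
morphology. Peak constraints: prominence > 0.6·σ_Wn, where σ_Wn is the SD
of the whole bout's coefficient series (this makes detection exactly
amplitude-invariant), and minimum peak distance 0.5·t̄ — half a step time
is a safe floor since same-type events of alternating feet are one step
time apart. Zero crossings are localized with sub-sample linear
interpolation because event times feed MAE at the 10-ms scale. The IC
backward search is bounded by the previous FC (or bout start); the
latest positive-to-negative crossing is paired with the latest local
minimum preceding it, and FCs without a valid pair yield no IC.

The legacy comparator runs on the vertical axis at 50 Hz (polyphase
antialiased resampling), integrates the mean-removed acceleration, takes
CWT peaks above 0.5·SD as ICs and peaks of a second CWT pass as FCs,
fixed scale 8. On the simulator its IC landmark sits inside the
double-support phase, late relative to the true IC by roughly half the
loading time — the systematic error the AP-signal method removes.

## Step QC and metrics

Steps are one IC plus the next two FCs (opposite then same side). When
two ICs precede the same FC the later IC wins: the earlier would imply an
implausibly long loading phase. Rules: loading time < C_loading·t_max;
stance < t_max/2 + C_loading·t_max (the second term is the rule-1 *limit*,
keeping the rule stateless); stride time < t_max. Dynamic limits
t_max = 2·t̄ + 1 s and C_loading = 0.17·t̄ + 0.05 adapt to cadence — the
limit-to-observed-loading ratio stays nearly constant across speeds,
whereas a static 2.25 s/0.2 leaves a margin that balloons at fast
cadence. Continuity requires one step's same-side FC to be the next
step's opposite-side FC; breaks partition the bout into runs, and stride
time, stride length and gait speed are computed within runs only. The
terminal step of a run has no step time and is excluded from stride
metrics but kept in the step count. Bout summaries are medians across
steps; cadence is summarised as the median of per-row 60/t_step
(median of ratios), not 60 over the median step time.

## Spatial model

Per step (IC to next IC) the window mean of the vertical acceleration —
gravity plus slow drift — is removed, the remainder is double-integrated
(cumulative trapezoid), and the position trace is detrended by the chord
through its endpoint samples. The chord, not a least-squares line: steps
are near-periodic, so the true CoM height at consecutive ICs is equal and
the endpoint chord *is* the unknown drift line (initial-velocity error
plus residual bias), whereas a least-squares fit is tilted by the
asymmetric within-step waveform and inflates the per-phase height changes
by tens of percent. The doubly integrated trace is smooth, so endpoint
samples are not noise-critical. Δh is the max − min of the detrended
trace; δ_bip and δ_sup are max − min over the [IC, FC_opp] and
[FC_opp, IC_next] portions of the same trace.

Step length uses the chord of a circular arc, S = 2·√(2·l·δ − δ²).
Model 1: one inverted pendulum of l_leg = 0.53 × height over the total
Δh. Model 2 (default): a normal pendulum of effective length l₂ over
δ_bip plus an inverted pendulum of l_leg over δ_sup,
S_step = S_bip + S_sup, with l₂ = C·l_leg·(t_bip/t_sup), C = 1.1,
evaluated at the bout-median phase durations to suppress per-step
variance. δ values exceeding their pendulum length are clamped to 0.95 of
it with a warning (a numerical guard for noisy bouts); a negative δ is a
geometry error and discards the step. Stride length is the sum of two
consecutive step lengths; gait speed is stride length over stride time.

## The synthetic walker

The generator is kinematic — trajectories are prescribed, no forces — so
ground truth is exact by construction. The CoM height follows a
C¹-continuous two-phase arc per step: a normal-pendulum valley of length
l₂ during double support and an inverted-pendulum hill of l_leg during
single support, traversed at constant angular rate per phase. Given step
frequency, duty factor (t_bip/t_step), leg length and step length, the
arc half-angles solve the chord-sum and velocity-continuity constraints;
by default l₂ is closed with the same C = 1.1 time-ratio relation real
reference data exhibit (an explicit CoM amplitude instead frees l₂ and
adds a third constraint). The vertical channel is the second derivative
of this height plus −g; the AP channel is the arc forward acceleration
plus two shaped transients per step: a windowed cosine complex whose jerk
is sinusoidal, placed so the smoothed-jerk coefficient series has its
local minimum at t_IC − d and its falling zero crossing at t_IC + d
(d = 0.08·t_step) — the midpoint rule lands on the true IC — and a
Gaussian forward-push bump centred on the true FC (SD 0.07·t_step), whose
symmetric shape keeps the velocity-CWT peak at the true FC under any
smoothing. This placement is the generator's testability contract: in the
noiseless case the detector's definitions coincide with the planted
events. The third channel is pure noise. Signals are synthesized at 8×
oversampling, band-limited with a 10 ms zero-phase Gaussian kernel
(an impact-smear, which also makes sampled trapezoid integration
consistent with the planted trajectory), decimated to the output rate
(default 128 Hz), tilted by a known rotation, and overlaid with seeded
white noise (PCG64 via `numpy.random.default_rng`).

Default study conditions: cadences 1.2 / 1.7 / 2.2 Hz spanning slow to
fast walking, with step length 0.50 / 0.625 / 0.75 m and duty factor
0.32 / 0.295 / 0.27 co-varying the way they do in healthy self-paced
walking; 30 s bouts; leg length 0.9 m (1.70 m stature); tilt 0° or 5°;
noise off or at 10 dB SNR relative to the dynamic AP signal — far above
the noise floor of wearable-grade accelerometers, i.e. a stress
condition. The 12-fixture grid crosses cadence × noise × tilt.

What the simulator does *not* emulate: left/right asymmetry, stride-to-
stride variability, turning, soft-tissue artifacts, pathological
morphologies, and AP waveforms whose IC complex deviates from the
detector's definitions. Passing the recovery suites therefore shows the
pipeline implements its definitions correctly and is robust to noise,
tilt and cadence — it does not certify accuracy on real patient data.

## Known behaviour and limitations

- Spatial recovery is assessed with ground-truth contact events bounding
  the integration windows (subblock isolation, the same way a reference
  system's event times isolate the spatial stage). Under those conditions
  model 2 recovers planted step lengths within a few percent while
  model 1 with the total Δh underestimates by ≈ 20 %. In the fully
  automated chain, FC timing error propagates into the phase split and
  l₂, giving step-length biases up to ≈ +10–20 % at the fastest cadence.
- The generator's 1 % self-consistency (double integration reproduces
  the planted height trace) holds per step window after the estimator's
  own drift removal; absolute position from accelerometry without drift
  removal is ill-conditioned and accumulates low-frequency wander.
- Calibration of the scale relations on the simulator is self-consistent
  with the simulator's morphology; for real sensors the relations should
  be re-fitted on labelled data with `calibrate_scale_relation`.
- Bouts are assumed to be walking; there is no bout segmentation, turn
  detection or activity classification.
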