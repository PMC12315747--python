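# Methods

`eegate` re-implements, end to end and on synthetic data, an analysis chain
that asks how two resting-state EEG markers of cortical
excitation/inhibition (E/I) dynamics relate to working-memory gating
performance: the strength of long-range temporal correlations (LRTC) in the
alpha-band amplitude envelope, quantified by the detrended fluctuation
analysis (DFA) exponent, and the aperiodic 1/f exponent of the broadband
power spectrum. Because no real recordings ship with the package, every
stage is driven by generators whose ground truth is known exactly; the test
suite closes the loop by pushing generated data through the estimation and
inference machinery and checking that the planted parameters come back out.

## The synthetic resting-state EEG

Each channel is an amplitude-modulated alpha rhythm on a power-law
background:

    x(t) = a * env(t) * carrier(t) + background(t)

- **env** is fractional Gaussian noise (fGn) with Hurst exponent H equal to
  the subject's target DFA exponent, shifted by +3 SD and rectified at zero
  so it is a valid (non-negative) amplitude. fGn is the natural choice of
  modulator because its DFA exponent *is* its Hurst parameter, giving an
  exact ground truth. The fGn is synthesized by circulant embedding
  (Davies–Harte), which realizes the closed-form fGn autocovariance
  exactly; a spectral-synthesis fallback handles the (never observed in
  practice) case of a non-positive embedding.
- The modulator is generated at 8 Hz and linearly interpolated to the
  sampling rate. This concentrates its variance at the seconds-to-minutes
  timescales that DFA measures, which is both what real alpha envelopes look
  like (envelope bandwidth of a few Hz) and necessary for recoverability:
  with a full-rate fGn modulator ~95% of the modulator variance sits at fast
  frequencies where it is indistinguishable from in-band background noise,
  and the measured exponent collapses toward 0.5.
- **carrier** is a constant-amplitude alpha tone whose instantaneous
  frequency drifts stochastically within 11 ± 1 Hz (low-passed Gaussian
  frequency noise, cut at 0.5 Hz, clipped at ±2 SD). A band-passed-noise
  carrier would carry Rayleigh-distributed envelope fluctuations and phase
  slips of its own; those contaminate the extracted envelope and destroy
  the DFA ground truth. Keeping the frequency excursion well inside the
  flat region of the 8–14 Hz analysis band also avoids spurious amplitude
  modulation from the filter's edge roll-off.
- **background** is Gaussian noise with an exactly power-law spectrum
  P(f) ∝ f^(−γ), synthesized in the frequency domain, with the amplitude
  response held constant below 0.5 Hz (finite variance, stationarity) and
  scaled to 10 µV SD — the ground truth for the aperiodic-slope estimator.
- The alpha amplitude `a` is set per channel so that alpha-band (8–14 Hz)
  power of the oscillatory component is **32×** the background power in the
  same band (~15 dB). This emulates pronounced eyes-closed posterior alpha
  and is the regime in which the envelope's temporal structure, not the
  background, dominates the measured envelope: at in-band SNR 8 the
  envelope-DFA estimate is biased by up to −0.13, at SNR 32 the closed-loop
  error is within ±0.03 across H ∈ [0.6, 0.9].

Channels are statistically independent: no volume conduction, no shared
sources, no ocular/cardiac artifacts. Consequently, passing tests show that
the *estimators and inference procedures* behave as specified on signals
with the stated statistical structure — they do not show robustness to
correlated sensors, non-stationarity beyond the modeled kind, or real
artifact morphology.

Cohort defaults: envelope exponent targets drawn from N(0.768, 0.09) and
background exponents from N(1.779, 0.121), truncated to valid ranges. The
0.09 between-subject spread follows the subgroup-scale variability (SDs
0.084–0.095 across slope-split subgroups) rather than the much tighter
grand-mean spread (0.014); calibration checks that target the grand mean
pass `dfa_sd=0.014` explicitly. Default sampling rate is 500 Hz (a typical
post-downsampling rate) and default rest duration 600 s; DFA needs ≥ 50 s
(twice the largest window) and is unstable below ~120 s.

## Markers

- **Alpha envelope / DFA.** Zero-phase 4th-order Butterworth band-pass
  8–14 Hz, Hilbert envelope, 2 s trimmed per edge against filter and
  Hilbert edge effects. DFA: cumulative sum of the mean-subtracted
  envelope; 15 log-spaced window sizes in 2–25 s with 50% overlap
  (non-overlap available); per-window linear detrend; RMS fluctuation
  pooled across windows; exponent = OLS slope of log F(n) on log n (natural
  logs; the slope is base-invariant). The exponent is invariant under
  affine transforms of the input, asserted to 1e−10.
- **Welch PSD.** 4-s Hamming windows, 50% overlap, one-sided density
  normalization (integral ≈ variance; Parseval is asserted to 5% for
  stationary noise).
- **Aperiodic fit.** OLS of log power on log frequency over 3–40 Hz with
  *iterated* positive-residual masking: bins whose residual exceeds one
  residual SD (putative oscillatory peaks) are masked and the line refit
  until the mask stabilizes (≤10 rounds, monotone). A single masking pass
  is not enough when the alpha peak is strong — the peak inflates the
  first-pass residual SD, its spectral skirts stay in the fit, and the
  recovered exponent is biased by about +0.09; iterating brings the bias
  to ~+0.01. The fit is exact (≤1e−6) on noiseless power laws. No knee
  term and no Gaussian peak model: validation is closed-loop against the
  generator, not against an external parameterization tool.
- **Relative alpha power** uses the 8–13 Hz band (deliberately distinct
  from the 8–14 Hz DFA band; both bands are kept as given defaults) over
  the total spectrum, trapezoidal integration.
- Note: when spectra are computed after the broadband 0.5–45 Hz band-pass
  (as the full pipeline does), the filter's roll-off near 40–45 Hz steepens
  the upper end of the 3–40 Hz fit and inflates the recovered exponent by
  roughly +0.15. This is a property of measuring a band-limited signal, not
  of the estimator; the calibration checks therefore measure the generator
  output directly, and pipeline-level slope summaries should be read with
  that offset in mind.

## Pre-processing rules

Band-pass 0.5–45 Hz and 50 Hz notch, both zero-phase. Bad channels:
flagged when the best Pearson correlation with any montage neighbor is
< 0.8 (flat channels: correlation undefined, treated as 0); repaired by the
mean of unflagged neighbors — a deliberate simplification of spherical
spline interpolation that avoids a forward-model dependency. Bad segments:
in the 1–15 Hz band an individual threshold of mean + 3 SD of the filtered
signal (per-sample flag rate ≈ P(|z|>3) on clean Gaussian data); in the
15–45 Hz band a fixed 40 µV threshold; flags padded by 0.2 s and merged;
recordings with > 60 s total are flagged for review only (no manual step is
modeled). Independent-component artifact removal is out of scope.

## Behavior and amino acids

The task generator reproduces the 4-condition delayed match-to-sample
design: 4 blocks × 32 trials, 8 per condition per block, probe match/non-
match balanced within each condition of each block, conditions shuffled
within block. Trial success probabilities follow the generative twin of the
accuracy models:

    P(correct) = clip(mean[c] + b_dfa[c]·z(DFA) + b_psd_aa[c]·z(PSD)·z(AA)
                      + u_subject, ε, 1−ε),  u ~ N(0, 0.04²)

with condition intercepts 0.895 / 0.945 / 0.955 / 0.933 (ignore, update,
control short, control long) and default marker effects planted in the
maintenance conditions only (−0.02…−0.03 per SD) — the qualitative pattern
the statistics must recover. Near-ceiling means necessarily censor some
probabilities at 1; a warning fires only if more than 25% of trials clip.
Accuracy is generated at trial level (Bernoulli) although the models
consume subject × condition means, so the RT filters have real work:
reaction times are lognormal (median 650 ms, σ_log 0.3) with 3% planted
contaminants outside the 200–2000 ms window. The RT filters use strict
inequalities (exactly 200 or 2000 ms is kept). Amino-acid panels are
lognormal around typical fasting serum concentrations; the ratio
(Phe+Tyr)/(Ile+Lys+Met+Trp+Tau+Val) is scale-invariant and lands near 0.2.
Whether probe-match and non-match trials should be pooled in accuracy
averages is not specified anywhere; they are pooled.

## Electrode-wise mixed models and cluster-permutation inference

Per electrode, accuracy is modeled as
`accuracy ~ condition * marker + (1|subject)` (or `* marker * AA` for the
three-way family) with treatment coding and `update` as the reference
level, so the marker × condition[ignore] coefficient is directly the
ignore–update contrast of interest. Estimation is REML (statsmodels
MixedLM); optional covariates (age, sex, BMI, IQ, eating/impulsivity
scores, tiredness, concentration, relative alpha power) enter jointly as
z-scored fixed effects. All continuous predictors are z-scored with the
analysis sample's own moments.

**Contrast inference.** For complete balanced designs the interaction
contrast is a purely within-subject quantity, and its exact test lives in
the within-subject error stratum: the package reports t = β̂(REML) / SE
where the SE comes from the subject-level condition-difference regression
(difference of each subject's ignore and update accuracy on the z-scored
marker, or on marker, AA and their product), with df = n_subjects − p.
This is the classical exact approach for balanced repeated measures; it
also makes a provable identity — the REML fixed-effect estimate equals the
difference-regression OLS estimate on balanced data — into a tested
invariant (asserted to 1e−6), which licenses the fast OLS path inside
permutations. For unbalanced data the Wald t with a residual-df
approximation is reported instead (Satterthwaite/Kenward–Roger df are out
of scope). Fits whose optimizer fails are flagged and excluded from
clustering; a random-intercept variance at the boundary (zero) counts as
converged.

**Clustering.** Electrodes with contrast p < .05 are grouped into connected
components under the montage adjacency, separately for positive and
negative t (same-sign clustering, standard for cluster-mass statistics);
components need ≥ 2 members; a cluster's mass is its summed t. Adjacency is
distance-thresholded (unit-sphere Euclidean distance < 0.52), calibrated
once on the 61-channel layout to a median of ~5 neighbors.

**Permutation null.** The null hypothesis is "no marker × condition
interaction anywhere", so each of B = 1000 (reduced scale: 200) permutations
shuffles the subject-level marker vector across subjects — jointly with the
amino-acid ratio in three-way models, preserving their empirical dependence
— leaving each subject's accuracy profile intact. All electrode statistics
are recomputed through the fast balanced path, clusters formed, and the
absolute mass of the largest cluster recorded (0 when none forms). A
cluster is significant when its |mass| strictly exceeds the 95th percentile
(linear interpolation) of the null maxima; per-cluster p-values use the
add-one rule (1 + #{null ≥ observed}) / (B + 1). The procedure is
reproducible from its seed, and its family-wise error under the global null
is verified by simulation to stay at or below the nominal 5% (it is
conservative, as cluster-forming thresholds make such tests under sparse
montages).

**Follow-ups.** Post-hoc per-condition slopes regress accuracy on the
z-scored cluster-average marker (the product term with AA for the
three-way family) via OLS, one observation per subject. The joint
LRTC × slope model `accuracy ~ z(DFA)·z(PSD)·condition + (1|subject)`
(ignore/update only) reports the two- and three-way interaction terms plus
the variance inflation factors VIF = 1/(1−R²) of the two predictors. The
median-split analysis divides the sample at the median PSD slope — with odd
n the median subject joins the lower (flatter) group, ties resolved by
stable sort — and compares group DFA means with a Welch t-test.

## ERP arm

Task epochs span −500…+1800 ms around the interference stimulus at 500 Hz;
baseline correction subtracts each channel's −500…−50 ms mean (idempotent).
The generator plants a Gaussian-in-time positive deflection (center 320 ms,
SD 60 ms) scalp-weighted to peak at Pz on pink-noise background (3 µV SD);
per-trial amplitudes are Gaussian around condition means of 1.651 µV
(ignore) and 1.207 µV (update) — the bump is normalized so these means
refer to the measured quantity, the 310–500 ms window average, not the peak
height. Epoch rejection flags a trial iff at least 3 channels each have
strictly more than 30% of samples above 15 µV in absolute amplitude
("more than two channels", "more than 30%" read strictly); flagged epochs
are removed automatically — the visual confirmation step of an operator is
deliberately not modeled. Subjects lose all epochs when more than 60% are
rejected (exactly 60% is kept). Injected artifacts (40 µV blocks on three
channels, 40% duty, placed after 550 ms to spare baseline and P300 windows)
are constructed to trip the rule exactly.

P300 amplitude is the per-trial 310–500 ms window mean at Pz; trials split
into high (> 0 µV) and low groups for the latency-shift follow-up. Peak
latency is the grand-average argmax in 200–600 ms with three-point
parabolic refinement; ties resolve to the earlier latency; flat input is an
error.

Trial accuracy is modeled by a random-intercept logistic regression
`accuracy ~ z(P300) * condition + (1|subject)`, fitted by Gauss–Hermite
quadrature maximum likelihood (15 nodes; the Laplace approximation used by
common mixed-model software is the 1-node special case, so this is a
strictly finer approximation). Wald SEs come from the numerical Hessian; a
tiny ridge (1e−8) keeps separated fits finite and |β| > 15 on the
standardized scale raises a separation flag. The fit is cross-checked
against an independent adaptive-quadrature implementation (R lme4) in the
test suite. Marker → P300 models (`P300 ~ z(DFA)·condition` and
`P300 ~ z(PSD)·z(AA)·condition`, both with subject intercepts) are linear
mixed models on trial-level amplitudes.

## Pipeline and scale

`run_full` chains simulation → preprocessing → markers → behavior → the
four cluster-permutation model families → post-hoc slopes → the joint
DFA × PSD model with median split and VIF → the ERP arm, and emits a
JSON-serializable report in which every random decision traces to a
recorded seed; identical configs reproduce identical reports bit for bit.
The default configuration is a reduced-scale study — 16 right-centroparietal
electrodes, 40 subjects, 600-s recordings, B = 200 — chosen so a complete
run finishes in a few minutes on one CPU; the full-scale layout
(61 electrodes, 73 subjects, B = 1000) is reachable through config fields.
Tests and the calibration scripts use smaller montages (2–8 channels) and
shorter recordings where the quantity under test permits; the problem sizes
are stated next to each check.

## Known limitations

- The generator models exactly two resting-state statistics plus a P300
  bump; nothing else about EEG morphology is realistic.
- Bad-channel repair by neighbor averaging is cruder than spline
  interpolation and slightly lowers local rank.
- The DFA closed loop carries residual biases of up to ±0.03 at the extremes
  of the H range (interpolation smoothing at low H, background dilution at
  high H); tolerance bands in the tests absorb them.
- Degrees of freedom for unbalanced mixed-model tests are a residual-df
  approximation.
- Mixed logistic SEs rely on a finite-difference Hessian; with very small
  clusters of trials per subject they can be optimistic.
- Source-space analysis (distributed inverse solutions) is out of scope.
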