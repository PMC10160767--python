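# Methods

This package analyses block-design continuous-wave fNIRS recordings made
while trainees practise the FLS suturing-with-intracorporeal-knot-tying
task, together with the behavioral trial log of each repetition.  It has
two arms — a neuroimaging arm (optical preprocessing, HRF estimation,
channel-level inference) and a behavioral arm (trial scoring, LC-CUSUM
learning curves) — plus a forward simulator that generates both kinds of
data with known ground truth, so every stage has a recovery-based test
surface.

## Signal model and preprocessing

A recording holds dual-wavelength (760/850 nm) intensity at 5 Hz for a
montage of long (~30 mm) and short (<15 mm) source–detector channels.
The preprocessing chain is:

1. **Optical density.** OD(t) = −log10(I(t)/Ī) per channel and
   wavelength, with the per-series mean as reference.  The reference
   choice (mean vs first sample) is configurable; the mean makes OD
   zero-mean in the log domain.  Because the reference is internal to
   each series, concentrations are determined only up to an additive
   constant per channel — immaterial downstream, where everything is
   either bandpassed or fitted with a constant regressor.
2. **Motion correction** (hybrid spline + Savitzky–Golay).  Motion
   epochs are flagged where a 1-s moving-window amplitude exceeds
   0.4 OD or the moving SD exceeds 5× the channel's median moving SD.
   Inside each flagged epoch a heavy smoothing spline (csaps-style
   p = 0.99) tracks and removes the artifact trajectory, and subsequent
   segments are re-levelled so baseline shifts do not persist.  A
   Savitzky–Golay smoother (10-s frame, cubic) then suppresses residual
   spike-band content; at 5 Hz its ~3 dB point is ≈0.13 Hz, just above
   the neurovascular band, so task responses pass essentially intact.
   On synthetic artifacts the correction leaves <20% of an injected
   0.5-s spike and <10% of an injected baseline step.  The cited
   method's "default parameters" are not printed anywhere; all values
   above live in `PreprocessConfig` and are overridable.
3. **Bandpass** 0.01–0.1 Hz, 3rd-order Butterworth applied
   forward–backward (zero phase), so HRF timing is not shifted.
4. **Modified Beer–Lambert law.**  Per channel and sample the 2×2
   system ΔOD(λ) = d·PPF(λ)·[ε_HbO(λ)ΔHbO + ε_HbR(λ)ΔHbR] is solved
   for (ΔHbO, ΔHbR), with d in cm, partial pathlength factors (1.0,
   1.0), and the Prahl/Gratzer extinction coefficients in cm⁻¹·mM⁻¹ as
   the shipped default table (explicit and swappable — the table sets
   the μM scale).  Output is micromolar.

## HRF estimation

Each long channel's chromophore series is regressed (OLS) on:

- 125 Gaussian basis functions (σ = 0.5 s, means 0.5 s apart, spanning
  −2…60 s), each time-locked to every task-block onset and normalized
  to unit peak so coefficients are in μM;
- constant + linear drift columns (minimal, so they do not compete with
  the 0.01 Hz filter floor);
- one or more short-separation channel series of the same chromophore
  as nuisance regressors.  Selection modes: `nearest` (Euclidean
  midpoint distance; default), `max_correlation`, `all`, or disabled.

Fits run once per session with all of that session's onsets in one
design; day-level HRFs are pointwise means across a subject's
repetitions/sessions for that day.  The reconstructed HRF is exactly
`basis × β` on the −2…60 s grid.

Two numerical choices matter:

- **The design is not filtered.**  Passing the 0.5-s-spaced Gaussian
  columns through the 0.1 Hz lowpass makes them nearly collinear and
  the solve explodes.  Fitting filtered data with the unfiltered basis
  instead returns the band-attenuated response: on simulated data the
  0–20 s peak reads ≈7% low (inside every tolerance used here), while
  the baseline-subtracted windowed effect used for inference is
  unbiased (0.620 recovered vs 0.621 truth on the reference fixture).
- **Rank deficiency is an error**, reported with the condition number,
  never silently regularized.

## Channel-level inference

The per-subject effect is the mean HRF over 0–20 s minus the mean over
the −2–0 s pre-onset baseline (window closed, baseline half-open, so
the onset sample belongs to the response).  Contrasts are textbook
t-tests at α = 0.05, two-sided, uncorrected across channels (fidelity
to the emulated analysis; Benjamini–Hochberg is available behind a
flag):

- day vs baseline — one-sample t against zero;
- day 15 vs day 1 — paired t on per-subject differences, positive
  meaning later > earlier;
- good vs weak learners — Welch two-sample t, after splitting the
  cohort at the mean final-day score (ties go above).

Zero-variance inputs yield a flagged degenerate result (t = 0, p = 1
for zero mean; ±∞, p = 0 otherwise), never NaN.  A repeated-measures
ANOVA of scores across day 1 / day 15 / retention is provided as a thin
statsmodels wrapper; the paired contrasts carry the claims.

## Trial scoring and LC-CUSUM

The official FLS normalization is unpublished, so the score is the
documented-in-literature parameterized form

    score = max(0, (cutoff − completion_time) − penalty),

with cutoff 600 s and penalty weights per error component in config.
The defaults are mutually consistent with the emulated trained cohort:
600 − 113.81 − 46.27 = 439.92.

LC-CUSUM: repetition t is a success iff score ≥ criterion; the
statistic accumulates base-10 log-likelihood-ratio weights
w_success = log10((1−p1)/(1−p0)) = −0.0792 and
w_failure = log10(p1/p0) = +0.398 for the default rates p0 = 0.10,
p1 = 0.25 (base 10 is forced by those printed values; natural log would
give −0.182/+0.916).  Proficiency is declared when S_t first reaches
the decision threshold −3.7; from S = 0 that takes
⌈3.7/0.0792⌉ = 47 consecutive successes.

By default the statistic holds at a barrier of 0 from above,
S_t = min(0, S_{t−1} + W_t) — the original learning-curve CUSUM form.
Without it, a novice's early failures (≈25 of the 75 repetitions) bank
roughly +10 of score and no learner can cross −3.7 within the training
horizon, which contradicts the behavior the analysis exists to detect;
with it, simulated cohorts reproduce the expected pattern (a minority
of good learners cross, several finish below −3, weak learners hover in
(−0.5, 0]).  `holding_barrier=False` gives raw unbounded accumulation.
The criterion score defaults to 380: any value ≤468 keeps a repetition
at the 112-s proficiency-standard time with a modest penalty a success;
380 additionally makes a sustained success run attainable for good
learners but not weak ones.  Both knobs are config, not constants.

## Synthetic data

The generator mirrors the decomposition the analysis assumes rather
than any photon-transport physics:

- **Long channels** (HbO): amplitude × (canonical HRF ⊛ block drive)
  + gain × superficial + drift + white noise.  The canonical HRF is a
  unit-peak double-gamma (peak 6 s, undershoot 16 s, ratio 1/6) —
  deliberately *not* the Gaussian estimation basis, so recovery never
  depends on fitting with the generating family.  The convolved
  response is normalized to unit peak, so a channel of amplitude a
  peaks at a μM.  Block drive carries exponential within-block
  adaptation (τ = 30 s to a 0.3 floor), exposed rather than fixed,
  since how activation is sustained over multi-minute blocks is an
  open modelling question.
- **HbR** is −1/3 of the HbO task component (typical empirical ratio,
  configurable) plus independent nuisance draws.
- **Superficial signal**, shared across channels with per-channel gain
  (long ~U(0.5, 1.5), short = 1): cardiac 1.1 Hz (0.2 μM), respiration
  0.25 Hz (0.15 μM), Mayer waves 0.10 Hz (0.3 μM — sitting on the
  filter edge on purpose), plus a sub-0.05 Hz fluctuation (0.5 μM).
  Short channels carry superficial + noise only, no task response.
- **Motion artifacts**: additive 0.5-s Gaussian transients (spikes)
  and step offsets (shifts), the two classes the correction targets.
- `to_intensity` pushes concentrations through the forward MBLL and
  I = I₀·10^(−ΔOD), so the whole chain can be tested end to end; it is
  the algebraic inverse of the preprocessing up to the OD reference
  constant.

The synthetic montage reproduces channel *separations* (30 mm long,
8 mm short — the adult optimum), not the real cap's 16×16 optode
topology; anatomical labels are out of scope.  The long-channel
separation is an assumption (not printed in the emulated study) and is
flagged in config.

Behavioral trajectories are exponential in the repetition index with
per-trainee parameters drawn around class presets.  The cohort presets
are calibrated once against the emulated study's summary table: a
21-trainee cohort (12 good / 9 weak) averages ≈486 s day-1 completion
time (target 483.22), ≈124 s on day-15 (target 113.81), day-1 score
≈63 (target 48.6), day-15 score ≈427 (target 439.9).  Trial noise is
30 s / 18 score units.

**What a green test does and does not establish.**  Recovery tests
show the chain is consistent with its own forward model under
physiologically plausible amplitudes; they cannot certify behavior on
real optode-coupling physics, non-stationary physiology, or montages
unlike the simulated one.  Type-I calibration holds under the
generator's Gaussian noise; heavy-tailed real noise may differ.

## Known limitations

- Sustained activation over 10-min blocks is only captured within the
  −2…60 s basis support; the unmodelled plateau tail inflates residuals
  for long-block sessions.
- No autoregressive/prewhitened GLM noise model; dof assume white
  residuals, so single-session p-values are approximate (group-level
  inference across subjects is unaffected).
- No wavelet/PCA motion correction, no risk-adjusted or
  post-proficiency (h⁺) CUSUM variants.
- The FLS score form is a parameterization of an unpublished rule;
  absolute score values are only as meaningful as its constants.
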