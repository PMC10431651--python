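# Methods

`nirsfeed` re-implements, end to end, a single-session fNIRS neurofeedback
experiment and its offline activation analysis: an online gauge driven by
the HbO2 of four dorsolateral-prefrontal (DL-PFC) channels, and an offline
per-channel GLM that decides — with and without short-channel (SC) scalp
regression — which channels were truly activated.  Because no raw
recordings are published for this paradigm, every quantitative claim the
package makes is validated on its own synthetic generator, whose
construction and limits are described below.

## Study conditions

The montage is an 8-source / 8-detector prefrontal cap: 16 frontal long
channels (30 mm; four of them — S1-D1, S1-D2, S7-D5, S7-D7 — over the
bilateral DL-PFC and used for feedback), one motor-area control channel,
and eight 8-mm short channels, one per source, all on detector D8.
Recordings are continuous-wave at 760/850 nm, 7.8125 Hz.  The session is a
120-s baseline followed by 15 trials of 30 s task + 30 s rest (1020 s).

## Synthetic data generator

Each subject's per-channel ΔHbO2 is

* **neural response** — unit-peak 30-s boxcar ⊛ canonical HRF on the active
  channels, scaled by `neural_amplitude` (default 0.5 µM — a typical
  single-trial prefrontal HbO2 response); ΔHbR = −`hbr_ratio`·ΔHbO2
  (default 0.25, the usual HbR/HbO2 magnitude ratio);
* **scalp process**, shared by every channel (gain `scalp_coupling` = 1 on
  long channels, 1 on shorts): a Gaussian random walk low-passed below
  0.05 Hz with expected sd 0.3 µM, plus sinusoidal Mayer (0.09–0.1 Hz),
  breathing (0.2–0.5 Hz) and cardiac (1–1.3 Hz) oscillations with
  per-subject random phase and log-normal amplitude jitter (amplitudes
  0.2 / 0.1 / 0.2 µM).  In cohorts, each subject's three frequencies are
  drawn uniformly within those physiological bands — people differ, and a
  cohort of identical 0.095 Hz Mayer lines would be an artificial
  worst/best case.  The walk is scaled by a *deterministic* expected-std
  factor, not by its own realized std: per-realisation rescaling would put
  every subject on a "unit shell" and silently break the Gaussian
  conditional-regression structure that short-channel correction relies on;
* **drift** — 2·10⁻⁴ µM/s linear trend on long channels;
* **measurement noise** — Gaussian on optical density, sd 0.002 OD.

Concentrations go through the forward modified Beer–Lambert law (MBLL) and
are exponentiated to intensities, so the generator emits exactly what the
instrument would stream.  Scenarios: `responder` (neural signal on the 4 NF
channels), `scalp_false_positive` (no neural signal; a task-locked
0.4 µM-peak ingredient added to the scalp process — superficial blood flow
mimicking activation), `null` (neither).

What the generator does **not** emulate: motion artifacts, per-source scalp
heterogeneity (the scalp process is global, which makes averaged-SC
regression exactly unbiased — real caps are messier), optode-coupling
drifts, and non-sinusoidal physiology.  Passing tests therefore show the
pipeline's statistical machinery is correct under realistic noise *types*,
not that real-data false-positive rates will match these numbers.

## Preprocessing

Raw intensity → optical density against the whole-recording mean
(OD = −log10(I/Ī)) → order-3 Butterworth band-pass, 0.01–0.09 Hz or
0.01–0.2 Hz, zero-phase (forward–backward) → polyphase resampling to 4 Hz →
MBLL inversion with pinned 760/850 nm extinction coefficients
(Gratzer–Kollias tabulation), DPF 6.0 both wavelengths, channel distance in
cm.  Two numerical points matter:

* the zero-phase filter is padded with one full period of the low cutoff
  (≈100 s at 0.01 Hz); the scipy default pad of a few samples leaves a
  startup transient longer than the padding that measurably inflates
  estimator variance;
* concentrations are relative to the mean-intensity reference, so all
  downstream quantities are Δ-values; any constant offset is absorbed by
  the GLM intercept.

## Activation GLM

Per long channel, ΔHbO2 at 4 Hz is modelled with: HRF-convolved task
regressors (one per trial, or one over a selected trial set plus a nuisance
column over the rest), an HRF-convolved rest regressor, a short-channel
nuisance regressor, a linear-drift column and an intercept.  The task/rest/
drift columns pass through the same band-pass as the data — without this
the 0.01–0.09 Hz filter attenuates the modelled response and betas would be
biased low by 10–25%.  The drift column is kept even though the data are
high-passed: a ramp's filtered remnant is deterministic and identical in
every recording, and leaving it unmodelled biases every task beta the same
way.  The canonical HRF is a difference of unit-dispersion gamma densities
with peak at 4 s, undershoot at 16 s, 32-s support and undershoot/peak
ratio 1/6; one 30-s trial's convolved response is normalised to unit peak,
so task betas read directly in µM of peak evoked HbO2.

**Short-channel regressor.**  Default is the mean of the eight short
channels.  A nuisance regressor measured with noise under-corrects in
proportion to its noise share (classical errors-in-variables attenuation);
an 8-mm channel's µM-equivalent noise is ~14× a 30-mm channel's, and with a
single matched short channel the uncancelled task-locked scalp remnant was
large enough to stay significant in a low-residual fit.  Averaging the
eight shorts cuts that noise eight-fold.  `sc_mode="matched"` restores the
source-matched single channel, which is preferable when scalp physiology
differs strongly across the cap.

**Fitting** iterates: least squares → AR(p) estimation on the residuals
(Levinson–Durbin, BIC over p ∈ 0..⌈4·fs⌉) → prewhitening of data and design
→ Tukey-bisquare reweighting (c = 4.685, MAD scale) of the whitened
residuals, until max |Δβ| < 10⁻⁶ or 50 iterations.  With unit weights and
AR order 0 the point estimates are exactly OLS.

**Inference.**  Band-passed noise is not AR-invertible — its spectrum is
essentially zero over >95% of the Nyquist range, so *no* finite AR order
whitens it and the textbook whitened-LS covariance understates variance by
orders of magnitude (we measured 69% type-I error at a nominal 5%).
Standard errors therefore come from a frequency-domain sandwich
var(β) = Gᵀ Σ G, with G the weighted-LS influence matrix and Σ a circulant
covariance whose eigenvalues are a multitaper (NW = 4, K = 7) estimate of
the whitened-residual spectrum, post-processed as follows:

* bins dominated by design-column energy (the task/rest harmonic comb) are
  excluded — under coloured noise the regression redistributes noise power
  onto exactly those bins — and replaced by the local mean of usable bins
  (±32-bin window), flattened by the known filter×AR power envelope so the
  interpolation respects the band edges;
* narrowband physiological lines are kept pointwise at their own bins, with
  their taper-smear zone excluded from the background average;
* outside the filter's pass-band the estimate is pinned to the envelope,
  which removes out-of-band projection junk amplified by regressor leakage.

Degrees of freedom are Satterthwaite, traced through the smoothing kernel
(the variance estimate is a known linear functional of raw periodogram
bins, so the effective χ² dof per regressor follows directly, including the
information reuse between interpolated comb bins).  Two-sided p-values use
Student's t with those dof.  `cov="ols"` switches back to the classical
formula for didactic comparisons.

Measured calibration: channel-wise type-I error 0.037 (pooled over 3060
null-simulation fits across 12 cohort seeds) at α = 0.05, and 0.047 on
band-passed white noise without nuisance structure.  Slight residual
conservatism comes from the comb-bin interpolation; we prefer it to the
liberal alternative.

**Activation rule.**  A channel is active iff its task beta is positive and
its two-sided p is below α/m with m the ROI's channel count (4 NF, 12 other
frontal, 1 motor) — Bonferroni within each region separately, α = 0.05.
A subject is a *responder* when ≥1 NF channel is active.

## Trial selection

A trial-wise GLM (15 single-trial task columns) gives each trial a score:
the mean t-value over the four NF channels.  The k best trials (k ∈ {5, 10,
15}, ties to the lower trial index) form the task regressor of a refitted
pooled GLM, with the unselected trials kept as a nuisance column rather
than dropped — removing them would push their response into the residual
and bias the noise estimate.  k = 15 reduces exactly to the all-trials fit.

## Group statistics

Concordance of responder calls with/without SC regression is exact set
arithmetic (both, no-SC-only = "false positives", SC-only = "false
negatives", neither).  2×2 comparisons use the Pearson chi-square without
continuity correction, df = 1 (e.g. the 9/15-vs-4/15 control-feeling table
gives p = 0.065).  Block averages epoch −5…+60 s around task onsets,
baseline-corrected to the 5-s pre-onset mean.

## Online feedback chain

Causal, chunking-invariant, per sample on the 4 NF channels: OD against a
running-mean intensity reference (a causal stand-in for the offline
whole-recording mean) → MBLL → causal order-3 Butterworth 0.01–0.2 Hz →
2-s moving average → mean of the 4 channels minus the trial baseline (mean
of the 5 s preceding the current task onset, recomputed at every onset).
Gauge height = 0.5 + 0.5·tanh(v/v0), v0 = 1 µM: half height at no change,
smooth saturation at the ends.  No SC correction is applied online by
default.  Note a property discovered in validation: the per-trial baseline
resets decorrelate the raw feedback samples from the instantaneous neural
truth (Pearson r ≈ 0.23 even without noise), while the trial-cycle-averaged
waveform correlates strongly (r ≈ 0.5 at default noise) and the
task-minus-rest shift of the feedback cleanly separates responders and
scalp-driven subjects from null subjects.

## Problem sizes used in the test suite

Monte-Carlo checks run at the study's native scale (1020-s sessions,
7.8125 Hz, 4-Hz analysis): type-I calibration over 150 null subjects ×
17 channels (2550 fits), amplitude recovery over 50 responder subjects
(200 NF-channel fits), and the SC phenomenon on a 15 + 15 mixed cohort with
best-10 selection.  `scripts/acceptance.py` recomputes the same quantities
at 30 / 20 / 10-per-arm subjects to stay brisk; both scales use the default
generator conditions.

## Known limitations

* The spectral-sandwich inference assumes the residual is (conditionally)
  stationary within a recording; slow nonstationarity beyond the modelled
  drift will erode calibration.
* The global scalp process makes averaged-SC regression ideal by
  construction; with spatially heterogeneous scalp flow the matched-SC mode
  may be the better default, at the cost of errors-in-variables attenuation.
* Betas are calibrated in µM only insofar as the pinned extinction
  coefficients, DPF = 6 and nominal 30-mm distances hold; t-statistics are
  invariant to those scale factors.
* The online chain's running-mean OD reference differs from the offline
  whole-recording reference during roughly the first minute; the 120-s
  baseline absorbs this before the first trial.
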