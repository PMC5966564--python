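# Methods

`nirsbci` implements an online passive brain–computer interface that
estimates a pilot's working-memory (WM) load from prefrontal fNIRS signals,
one trial at a time, together with the offline statistics used to evaluate
it and a synthetic session generator that makes every stage testable
without recorded data. This note documents the models, the parameters that
matter, the numerical choices, and what the synthetic tests do and do not
demonstrate.

## Signal model and conversion

A continuous-wave fNIRS optode measures light intensity $I(t,\lambda)$ at
two wavelengths (730 and 850 nm). Relative to the mean intensity $I_0$ over
a 10 s rest baseline recorded before the first trial, the optical-density
change is

$$\Delta OD(\lambda) = -\log_{10}\frac{I}{I_0},$$

so an intensity drop (more absorption) is a positive $\Delta OD$. The
modified Beer–Lambert law relates it linearly to chromophore concentration
changes:

$$\Delta OD(\lambda) = \left[\varepsilon_{HbO_2}(\lambda)\,\Delta[HbO_2] +
\varepsilon_{hHb}(\lambda)\,\Delta[hHb]\right]\, d \cdot DPF,$$

with source–detector separation $d$ = 2.5 cm and differential pathlength
factor DPF = 5.97 (effective pathlength 14.925 cm). Inverting the 2×2
extinction system per sample yields $\Delta[HbO_2]$ and $\Delta[hHb]$ in
µmol/L. The device vendor does not publish its extinction coefficients; we
ship the standard compiled hemoglobin spectra values
(730 nm: 390 / 1102.2; 850 nm: 1058 / 691.32 cm⁻¹ M⁻¹ for HbO₂ / hHb),
overridable in the profile YAML. Absolute concentration values are
therefore coefficient-dependent; the classifier is invariant to any fixed
per-channel linear rescaling, so classification results do not depend on
this choice. Streams already exported in concentration units bypass the
conversion entirely.

Scattering corrections, short-separation regression and motion-artifact
repair are out of scope; the saturation check (ceiling-pinned or
zero-variance channels) is a plumbing safeguard with invented, configurable
thresholds.

## MACD filtering

Each of the 2 × n_optodes concentration channels is band-passed online by
the difference of two exponential moving averages:

$$y_n = \frac{2}{N+1}x_n + \frac{N-1}{N+1}y_{n-1}, \qquad
\mathrm{MACD}(x) = \mathrm{EMA}_{N_s}(x) - \mathrm{EMA}_{N_l}(x),$$

with windows of 6 s and 13 s converted to samples as $N = \mathrm{round}(w
\cdot f_s)$ (12/26 at 2 Hz, 24/52 at 4 Hz). Both EMAs have unit DC gain, so
the difference rejects DC and slow drift exactly; the filter is causal and
O(1) per sample. Each EMA is seeded with the first input sample (default),
which removes the startup transient and makes a constant stream map to
exactly zero from sample one; zero-initialization is available in the
config. The recurrence is evaluated as $y_{n-1} + \alpha(x_n - y_{n-1})$ so
a constant input is an exact floating-point fixed point; the vectorized
batch path (`scipy.signal.lfilter`) matches the streaming path to 1e-12.

The closed-form gain, $H(f) = H_{N_s}(f) - H_{N_l}(f)$ with
$H_N = \alpha / (1 - (1-\alpha)e^{-i2\pi f/f_s})$, is exposed for
validation. At 2 Hz the response peaks (gain 0.37) near 0.036 Hz and the
passband is qualitatively 0.02–0.33 Hz. Quantitatively, the amplitude gain
ratio between 0.1 Hz and 0.002 Hz is 5.63 (31.7 in power), and a 0.002 Hz
drift is suppressed to 4.4 % of its input amplitude; the tests assert these
computed values rather than a nominal band edge, since the window pair
fixes the transfer function completely.

## Protocol and segmentation

A session is a 10 s baseline followed by 20 trials: a pre-recorded
air-traffic-control readback message plays at onset, the trial's analysis
window is the following 30 s (the 18 s response window sits inside it as
metadata with no effect on segmentation). Load labels are drawn uniformly
from the constrained sequence space — 10 low + 10 high, the first 10 trials
containing exactly 5 of each, and never more than two equal loads in a row
— by rejection sampling from uniform shuffles, which is exactly uniform
over the valid set (the valid fraction is large; for the 3+3/max-run-2 toy
space the support is 14 of 20 arrangements and is verified by exhaustive
enumeration). The inter-trial rest is not fixed by the protocol's source;
the default is 5 s, configurable. Trial windows are half-open
$[onset, onset+30)$ with 0-based sample indexing; a trial tensor is
(optode × chromophore × sample) with exactly $\mathrm{round}(30 f_s)$
samples.

## Classifier

All samples of a filtered trial are features — 16 optodes × 2 chromophores
× 60 samples = 1920 features at 2 Hz, or 4 × 2 × 120 = 960 at 4 Hz —
flattened optode-major, HbO₂ before hHb, then time. With only 10 training
trials the model is a soft-margin linear SVM (`sklearn.svm.SVC`,
`kernel="linear"`, tol 1e-6). The regularization parameter C is selected
per subject over the decade grid $10^{-3}\dots10^{4}$ (8 values) by 5-fold
cross-validation on the 10 phase A trials; folds are stratified with one
trial of each load per fold, assigned in presentation order with the seed
permuting order only within class, so both classes appear in every training
split. Ties in CV accuracy resolve to the smallest C (strongest
regularization); the model is then refit on all 10 trials. No feature
scaling is applied by default (the filtered signals are already
baseline-relative and band-passed); a decision value of exactly zero
resolves to low load. High load is the positive class for all metrics.

The online runner consumes one sample at a time through the stream-player
boundary: each sample is filtered on arrival, each trial is segmented the
moment its window closes, training happens once after trial 10, and each
phase C prediction uses no future samples (verified bit-for-bit by
truncation). Trials with stream gaps are skipped with a warning and
excluded from metrics; a missing phase A trial is fatal since the model
cannot be trained as specified.

## Synthetic sessions

The generator renders a load-dependent response in physiological noise.
The response kernel is a single-gamma shape normalized to unit peak,
$h(t) = (t/t_p)^{k-1} e^{(k-1)(1-t/t_p)}$, with time-to-peak $t_p$ = 6 s
and shape $k$ = 6, which decays below 2·10⁻⁴ of peak by 25 s — back to
baseline within a trial window. Each trial adds
$a_{load} \cdot g_o \cdot h(t-onset)$ to optode $o$'s HbO₂ channel, with
the hHb channel at −1/3 of that; $g_o$ is 2 on the anterior-prefrontal
optode group (optodes 5–8 of the 16-optode montage, optode 2 of the
4-optode montage) and 1 elsewhere, mimicking spatially focal activation.
Noise per optode: white noise sd 0.3 µM, cardiac 0.15 µM at 1.1 Hz,
respiration 0.2 µM at 0.25 Hz, Mayer waves 0.3 µM at 0.1 Hz (random phases
per optode), and a linear drift up to ±0.5 µM over the session; hHb noise
is scaled by 0.5. The default response amplitudes are 0.05 µM (low load)
and 0.2 µM (high load), i.e. a 4:1 contrast: with the noise model above
this places single-session testing accuracy in the 50–100 % per-subject
range (mean ≈ 80 %) rather than saturating every session at 100 %, which is
the regime the generator is meant to emulate. A session can optionally be
encoded to raw two-wavelength intensities through the forward Beer–Lambert
model around a flat baseline intensity, exercising the full ingestion path.

All randomness flows from explicit seeds through numpy `SeedSequence`
(protocol, noise and cross-validation seeds are spawned from one session
seed), so sessions are bit-reproducible across platforms.

What passing synthetic tests show: the pipeline is causally correct,
unbiased at zero effect (chance-level accuracy), sensitive (accuracy rises
monotonically with effect size and exceeds the 70 % sufficiency bar at the
default contrast), and exact where it should be (noiseless peaks equal
configured amplitudes; forward/inverse conversion agrees to 1e-9). What
they do not show: robustness to motion artifacts, systemic blood-pressure
confounds, optode repositioning, or the nonstationary noise of a real
cockpit — none of which the noise model contains.

## Offline statistics

Peak response per trial is the maximum of the MACD-filtered, ROI-averaged
signal within the 30 s window minus the mean over the 2 s before onset.
ROIs average optodes 1–4, 5–8, 9–12, 13–16 on the 16-optode montage and are
the identity on the 4-optode montage. Group summaries use the sample
(n−1) standard deviation, which reproduces the published per-subject table
aggregates. Cohen's d uses the pooled sd with (n−1) weights; the two-sample
t-test is the classic equal-variance statistic by default with Welch as an
option. The chance-level threshold is the smallest $k/n$ with exact
binomial tail $P(X \ge k \mid n, 1/2) \le \alpha$: 75 % for n = 20 and 90 %
for n = 10 at $\alpha$ = 0.05 — the operation takes n as a parameter rather
than fixing one interpretation of a "session". Repeated-measures MANOVA
and post-hoc HSD comparisons are not implemented: they require per-subject
raw data that is not available, so only summary-level statistics are
reproduced.

## Problem sizes

The simulation-based checks use 200 sessions per condition for the
chance-level and default-effect estimates and 40 replicates per point on a
6-point amplitude grid for the monotonicity check; at ~0.25 s per session
this keeps the full validation suite within a few minutes on one CPU while
holding the standard error of a 200-session mean accuracy near 1
percentage point.

## Known limitations

- Concentration values are only as good as the configured extinction
  coefficients; compare absolute µM values across devices with care.
- The constrained-sequence sampler is exact but rejection-based; extremely
  tight constraints (long sequences with max-run 1) would be slow, and the
  sampler raises after a bounded number of attempts.
- The online runner replays recorded or synthetic streams; live TCP
  acquisition is out of scope.
- The synthetic noise model is stationary and artifact-free by design (see
  above).
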