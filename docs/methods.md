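# Methods

## Forward model

**Vesicle pool.** A readily releasable pool of capacity `n_rrp` vesicles
releases per stimulus with probability `p_r` per vesicle
(Binomial(N_i, p_r)) and restocks between stimuli with
Poisson(refill_rate · ISI) vesicles, clipped at capacity. A deterministic
mode replaces both draws by their means; depletion then follows the
geometric series N·p_r·(1−p_r)^(i−1) whose closed form is the oracle for
the cumulative analysis. Defaults: `n_rrp = 100`, `p_r = 0.3` (≈ the 2 mM
Ca²⁺ apparent release probability at this synapse; 4 mM analyses use
≈ 0.55), `refill_rate = 400` vesicles/s (≈ 4 vesicles per 10 ms interval,
matching the scale of measured replenishment of ~0.05 nA/ms against pools
of 5–10 nA with 127 pA quanta).

**Electrical readout.** Each stimulus contributes
quanta × `quantal_amp` as an instant-rise exponential (decay `quantal_tau`)
at the stimulus time plus a synaptic delay (0.9 ms default, the measured
scale), with additive Gaussian noise, sampled at 40 kHz. Inward currents
are stored negative; summaries report magnitudes. Defaults
`quantal_amp = 127 pA` and `quantal_tau = 0.145 ms` are the control-group
quantal values; evoked-train analyses use `quantal_tau = 0.33 ms` (the
multi-quantal evoked decay).

**Optical readout.** The release impulse train is convolved with the
monoexponential reporter kernel (`tau` = 38.43 ms at 2 mM Ca²⁺, 68.66 ms
at 4 mM; `s0` = ΔF/F per vesicle, default 0.025 so that ~12 quanta give a
peak ΔF/F of 0.30). Because the indicator decay is comparable to the 10 ms
frame, each frame reports the **exposure-window average** of
F0·(1 + s(t)), computed in closed form per stimulus — point-sampling would
misstate both amplitude and integrals. Frame noise is Gaussian in counts
(default 5 counts rms on a baseline of 1000, i.e. 0.5% ΔF/F).

**Spontaneous events.** Poisson times at `mini_rate` (7 Hz default, the
measured spontaneous rate), log-normal amplitudes around `quantal_amp`
with CV 0.25 (a typical within-cell quantal spread), instant-rise
exponential shape.

**Image mode.** The per-frame ROI intensity is painted into a cup-shaped
region — a 240° arc of an annulus (inner radius 8 px, width 4 px) — over a
dimmer noisy background, emulating the calyceal terminal's appearance in a
ΔF image; the exact mask is returned as ground truth.

**What the generator does not emulate:** cleft glutamate diffusion and
buffering, AMPA-receptor desensitization/saturation (reporter saturation
is available as an explicit opt-in Hill transform `apply_saturation`, with
unit small-signal gain so calibrations are comparable), photobleaching,
lateral motion, structured autofluorescence, multi-synapse contamination,
and any dependence of the indicator decay on glutamate load. Passing tests
therefore demonstrate the correctness of the estimators under the stated
linear model, not robustness to these real-data effects.

Determinism: every stochastic routine takes a numpy `Generator`; a fixed
`SynthConfig.seed` reproduces outputs bitwise.

## Signal primitives

Corner frequencies are −3 dB **amplitude** points. The Gaussian filter
uses time-domain σ = √(ln 2)/(2π f_c) with reflective edges; the binomial
filter iterates the [1,2,1]/4 kernel n = max(1, ln 2^(−1/2) / (2 ln cos(π
f_c Δt))) times (one pass for an 8 kHz corner at 40 kHz). Exponential fits
use log-linear initialization followed by Levenberg–Marquardt on
(A, log τ, offset), tolerance 1e−8; failures are returned flagged, never
as silent NaN. Baseline noise is estimated as 1.4826 × MAD of the linearly
detrended window — analysis windows contain events, so a raw rms would be
inflated; the estimator needs ≳100 samples to be within a few percent.

Event measures treat a rise that completes within one sample as a jump at
the peak sample: the trapezoid/interpolation that is correct for resolved
waveforms would otherwise add half a sample of spurious charge and width
to quantal events, whose rise is unresolved at 40 kHz. Charge integrates
from onset to return-to-baseline, capped at 5 decay constants.

## Miniature-EPSC detection

Pipeline: binomial smoothing (8 kHz corner); candidates where the 2 kHz
Gaussian-filtered trace deviates ≥ 5σ **and** the 4 kHz-filtered central
difference derivative deviates ≥ 5σ within ±0.5 ms; candidates closer
than 1 ms merged keeping the larger. σ is the robust MAD estimate of the
respective filtered trace. Manual inspection is replaced by explicit
rules — an event is rejected when its rise slope has the wrong sign for an
inward current, its width is under two samples, or its decay fit fails —
a deliberate deviation from bench practice required for reproducibility.
The coincidence (±0.5 ms) and merge (1 ms) windows are far below the mean
inter-event interval at 7 Hz and above the event rise time.

Reported amplitudes are corrected (switchable) by the closed-form peak
attenuation that binomial smoothing plus the random sub-sample onset
phase impose on an unresolved rise (≈ 0.85 × 0.92 at τ = 0.145 ms,
40 kHz); without it median amplitudes read ~20% low. The correction
assumes the rise is faster than one sample and is skipped when the decay
fit is implausible.

## Evoked trains and pool analysis

Per stimulus: local baseline = mean of the 1 ms pre-stimulus window;
amplitude = peak deviation within the inter-stimulus window; synaptic
delay = latency to 10% of peak; rise time 10–90%. Decay fits are
restricted to the actual decay phase (peak until the trace returns below
5% of peak) — fitting across the mostly flat remainder of a 100 ms window
lets amplitude and offset trade off into a degenerate huge-τ solution.
Overlapping tails are handled by sequential peeling: each response's
fitted exponential continuation is subtracted before the next response is
measured, guarded against non-decaying fits.

The cumulative analysis fits an ordinary least-squares line through the
last 10 of 25 cumulative points and evaluates it at stimulus index 0
(the ordinate). `fit_last_k = 10` leaves the geometric transient below
0.1% of steady state for p_r ≥ 0.35; at lower release probabilities the
uncorrected estimator carries the known incomplete-depletion bias (e.g.
+0.014 at p_r = 0.2), which is inherent to the method — the deliberate
choice here is to report y₁/y_intercept without depletion correction so
that optical and electrical readouts share one estimator with identical
bias. The replenishment rate is reported per millisecond of ISI (slope /
ISI_ms), matching the convention in which pool size and responses share
units. Single stochastic trains at these steady-state counts (~4 vesicles
per ISI) give very noisy intercepts; per-cell averaging over ~10 repeats,
as in the analysis scripts, is assumed.

## Imaging

ΔF image: mean of response frames minus mean of baseline frames,
pixelwise; the default response window is the first 10 frames (~100 ms)
of a 100 Hz train. Segmentation blurs with a 2-D Gaussian (σ = 3 px),
thresholds globally (Otsu by default, percentile switchable), keeps the
component containing the seed point (else the largest), and fills holes.
The result is an **outer bound** of the terminal — liberal blurring
dilates the footprint — so overlap with ground truth is scored against
the truth mask dilated by the blur radius. ΔF/F divides the ROI mean by
the pre-stimulus ROI mean; no further background subtraction is applied.

Per-pulse areas integrate the ΔF/F with the **left Riemann sum**: frame
values are exposure averages, so their Riemann sum is the exact time
integral (a trapezoid half-weights the onset frame, −11% on a
single-pulse area). Preceding responses are peeled off with a per-pulse
amplitude fitted to the frame-averaged exponential shape and a shared
decay constant estimated from the post-train tail. The last window is
capped at one ISI so all pulses integrate over equal spans.

## Deconvolution

The Wiener route samples the unit-integral instant-rise exponential on
the trace grid, zero-pads to the next power of two ≥ 2× the length, and
applies a constant 1/SNR regularizer (the SNR is a per-recording scalar,
squared peak over baseline rms; a noiseless baseline yields the
infinite-SNR sentinel and the plain inverse filter). Deconvolution runs
on the native 100 Hz grid; no upsampling.

The linear-kernel route evaluates r = (s[k+1] − s[k])/Δt + s[k]/τ. Two
discretization conventions follow from the forward difference at
Δt/τ ≈ 0.26: the onset jump of a response lands on the sample *before*
the stimulus frame (per-stimulus windows are advanced one sample), and
the operator is not the exact inverse of the sampled exponential, leaving
a geometric residual tail of ~1% of each release in the following window.
`cumulative_release` therefore peels each pulse's analytically predicted
operator response before measuring later windows (default on); without
it, per-pulse ratios err by ~2% per 2:1 amplitude step and the
100 Hz-train pool estimate reads 0.27 instead of 0.30. Per-sample
uncertainty uses quadrature propagation σ_r² = 2σ_s²/Δt² + σ_s²/τ² +
(s/τ²)²σ_τ²; a verbatim signed linear combination of the same terms is
available behind `formula="printed"` but is not a valid variance
propagation. The decay constant estimated from a train's falling phase is
flagged as an upper bound: it assumes all release and reporter activation
were simultaneous.

## Statistics

Origin-constrained regression: slope = Σxy/Σx²; R² is computed about the
mean of y, which can be negative for a poor constrained fit (reported
as-is and flagged); p from the slope's t statistic with n−1 df; the mean
squared distance to the identity d = mean((y−x)²) summarizes absolute
agreement. When comparing readouts, note the normalization caveat:
dividing each train by its first pulse pins (1, 1), so a *saturating*
optical readout lies **above** the identity (slope > 1); on a common
absolute calibration (both readouts scaled by their single-quantum gain)
saturation compresses the optical values **below** the identity
(slope < 1). Both modes are available; nonlinearity screens should use
the calibrated mode.

Wilcoxon rank sum: exact enumeration of all rank assignments (midranks
for ties) for combined n ≤ 12, normal approximation with tie and
continuity correction otherwise; two-sided throughout.

The clustered comparison uses a Gaussian random-intercept model per cell,
fitted by direct maximization of the marginal likelihood (the per-cell
block structure V = σ²I + τ²J gives closed-form GLS profiles). Variance
components use REML by default; plain ML is available but its
downward-biased τ² makes the Wald test anticonservative. The Wald p uses
a t reference with (cells − 2) degrees of freedom, since the condition
effect is a between-cell contrast — with a normal reference the type-I
error at 12 cells per condition is ~0.07 rather than ~0.05. Agreement
with statsmodels' MixedLM is maintained to better than three significant
figures on balanced data (both REML and ML).

Derived-quantity standard errors use first-order Gaussian propagation
with analytically supplied gradients, assuming independence; adequate for
coefficients of variation up to ~0.1 (checked against Monte Carlo).

Bonferroni-adjusted levels α* = α/m are reported at three decimals.

## Problem sizes

The test suite and the reproduction script run the detector on one 60 s
recording (~420 events), pool recovery on 25-stimulus trains (20
stochastic repeats), deconvolution round-trips on 4-pulse 10 Hz trains,
50 null simulations of the mixed model at 12 cells × 20 observations per
condition, 10⁵ Monte-Carlo draws for the propagation check, and one
48 × 48 × 54 image stack — sizes at which every stochastic check has
comfortable statistical margin while the whole suite completes in about a
minute.

## Known limitations

- The cumulative-pool estimator is reported deliberately uncorrected; its
  incomplete-depletion and replenishment biases are real and shared
  between readouts, not removed.
- The mini detector's amplitude correction presumes unresolved rises;
  events with genuinely slow rises would be over-corrected (disable the
  flag).
- Reporter nonlinearity, bleaching, motion and diffusion are outside the
  generator; conclusions about such effects require the opt-in saturation
  transform or real data.
- The Wiener SNR is a single scalar per recording; strongly colored noise
  would call for a frequency-dependent regularizer.
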