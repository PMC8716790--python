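# Methods

This note records the models, defaults, and numerical conventions behind
`cldbs`, and what the synthetic data can and cannot show about real
recordings.

## Symptom model

The pain score s(t) on a uniform grid (default 1 s) is

    s(t) = clip( b + A·sin(2πt/T + φ) + M·g(t) + ε(t), 0, 10 )

with baseline b (default 4), diurnal amplitude A (1.5) and period T (24 h),
a two-state symmetric telegraph process g(t) with switch rate r (1/600 s⁻¹)
and episode magnitude M (3), and white observation noise ε (sd 0.3). The
telegraph term produces abrupt episode boundaries, the sinusoid slow drift —
the two symptom timescales that matter for choosing onset/termination
durations. The binary state is s ≥ cutoff with cutoff 5 on the 0–10 scale
(the scale's midpoint; the dichotomization level is always an explicit
parameter). By default a degenerate draw (one state only) is returned as-is
— a constant score genuinely has one state; `require_both_states=True`
redraws up to 20 times and then errors.

## LFP synthesis

Each channel is broadband background plus optional biomarker components:

* **Background**: white noise shaped by a 513-tap FIR filter whose
  magnitude response is (f/f₀)^(−α/2) above f₀ = 0.5 Hz (flat below, to
  bound low-frequency energy), normalized to a configurable RMS. Default
  exponent α = 1 (pink), the standard LFP stand-in.
* **Biomarker**: state-gated band-limited Gaussian noise — unit-variance
  4th-order Butterworth-bandpassed white noise (variance-normalized through
  the filter's mean |H|²), scaled per sample by √power(state). Filtered
  noise rather than a sinusoid is deliberate: band-power estimates then
  fluctuate chi-square-like, which is what makes percentile thresholds,
  LD averaging, and counters meaningful.
* **Artifacts**: EKG (biphasic ~60 ms template at 1.2 beats/s, motivated by
  volume conduction into left-sided devices; waveform is our choice),
  movement (0.5–2 s low-passed bursts with Hann envelope at a Poisson
  rate), elevated 0 mA noise floor (extra white noise of free amplitude —
  the magnitude of the 0 mA-vs-off difference is not characterized anywhere,
  so it is exposed as a parameter), and stimulation-locked artifacts:
  per-channel tonic sinusoids with gain µV/mA at configurable frequencies,
  plus an exponentially decaying transient on every 0 → on step across all
  channels. Coupling acts on the *time series*, pre-FFT, so blanking and LD
  averaging interact with artifacts realistically.

Synthesis is streaming (persistent filter state, chunk-by-chunk) so the
closed-loop simulator can interleave generation with stimulation feedback;
batch generation runs the identical path.

## Sensing

Band power at update k is computed from the trailing power-of-two window
ending at t = kΔ using a Hann window (device FFT internals are proprietary;
Hann is the conventional default) and 'spectrum'-scaled periodogram bins.
A band [low, high) collects bins with low ≤ f < high (half-open on bin
centers, preventing double counting at shared edges) and reports their
**mean** — "average power in band" — with a `sum` option; the Parseval
identity over a band partition therefore holds after weighting means by bin
counts. The update interval may exceed the window length (sparse FFTs for
minutes-scale control). Feature ranking uses Pearson correlation on the
score by default (Spearman optional), with the symptom resampled to the
feature clock by previous-value hold (a pain report stays valid until the
next); numerically constant features (relative sd ≤ 1e-12) are flagged with
importance 0. Window selection keeps the smallest candidate whose top
correlation reaches 95% (configurable) of the best candidate.

## Discriminant

At most two features, matching the devices; more raise an error.
Normalization fits sample mean and sd (ddof = 1). Fisher weights are
w ∝ S_w⁻¹(m₁ − m₀) with pooled within-class covariance, rescaled to unit
norm (so thresholds are comparable across fits — our convention) and signed
so the high-symptom class has the larger LD mean. Covariance condition
number > 1e10 raises (collinear features). The LD moving average is a
trailing (causal) mean — required for a real-time device — with a growing
window at stream start. Batch and streaming paths use an identical
multiply-add order, so they agree bit-for-bit. Computation is floating
point; device fixed-point scaling is not emulated.

## Detector

Threshold comparison is ≥ (an LD exactly at threshold counts as above; ties
must be decided somewhere and this choice is tested). Counters require
consecutive qualifying updates; one non-qualifying update resets to zero.
With two thresholds, states are ordered bands reached only via adjacent
transitions, and both thresholds share the onset/termination counters
unless per-threshold overrides are given. Blanking ignores the next
B/Δ updates for counting (the weakest reading of "stops the classifier
from changing state"); `strict_blanking` additionally clears counters when
blanking ends. Whether device blanking also clears the LD averaging buffer
is unknown; the average here keeps running.

## Stimulation and patient response

Amplitude slews toward the current state's target at `max(target)/ramp_s`
mA/s, retargeting from the current value on mid-ramp state changes (no
snap — continuity is physically required); `ramp_mode="step"` is available
without any claim about device truth. The energy proxy is the TEED form
Σ a²·f·pw·Δt with unit impedance (no formula is standard; this correlates
with battery drain). The patient model is first-order: the score relaxes
toward baseline(t) − relief·(a/a_max) with τ_in while the relief effect
deepens and τ_out while it wears off — the simplest model exhibiting both
wash-in and wash-out. Defaults τ_in = 60 s, τ_out = 90 s, relief = 2 score
units are plausible magnitudes for stimulation-responsive chronic pain.

## Tuning

Percentiles use linear interpolation between order statistics (recorded in
every report). The grid-search objective is
w_miss·(1 − agreement) + w_energy·energy/max(energy) + w_lock·1[lock]
with defaults (1, 0.2, 10) — the lock term is a soft-hard penalty an order
of magnitude above the rest. Latency is the agreement-maximizing lag within
±10 updates (a window is needed to make "closely follows" measurable).
Wash-in/wash-out fitting is per-segment least squares of a single
exponential (scipy `curve_fit`), flagged if non-converged.

## Packaged scenarios

`high_snr_scenario`: theta 4–8 Hz band power 1 → 10 µV² across the cutoff,
0.5 µV RMS pink background, fs 250 Hz, 256-sample window, Δ = 0.5 s, LD
average L = 4, counters 3/3, blanking 1 s, threshold at the midpoint of the
calibration class means, 2 mA target with a 2 s ramp, 10-minute runs. The
averaging and counters were sized to the band-power estimator's dispersion:
with ~4 theta bins per periodogram, unaveraged band power dips below the
class midpoint often enough to flicker a counter-1 detector even at 10×
power separation.

`artifact_lock_scenario`: deterministic slow symptom cycle (high
mid-recording), stimulation coupling 3 µV/mA at 6 Hz straight into the
sensed theta band (and, for the two-feature variant, at 32 Hz into a
30–34 Hz stimulation-tracking band), plus a 20 µV onset transient. The
plain single-threshold detector locks on. The "catch" variant measures the
artifact-inflated LD level from an open-loop recording *during* stimulation
(features must be characterized under the stimulation that will be used)
and places t2 midway between the genuine high-symptom level and that
artifact level; t1 gets a 1-update termination counter and 0.5 s blanking
so release from the stimulation-on state outruns the artifact re-entering
the analysis window as stimulation ramps back up. The negative-weight
variant uses fixed weights (0.8, −0.6): the stimulation-band feature is
z-scored against its (near-zero, tight) stimulation-free calibration
distribution, so any delivered amplitude drives its z-score large and the
LD far below threshold, terminating stimulation.

## Problem sizes

Tests and the acceptance script run simulations of 2–10 minutes at
250 Hz and LD streams of 10,000 updates — sizes chosen so every check
completes in seconds while Monte-Carlo tolerances (±5 percentage points on
occupancies, 10% on time constants) are comfortably resolved.

## What passing tests do and do not show

The generator reproduces the *structure* practitioners program against —
state-dependent band power, diurnal and episodic symptom dynamics, the
listed artifact classes, stimulation feedback — with Gaussian statistics
and stationary parameters. Real LFP has heavier tails, nonstationary
background spectra, impedance drift, and biomarkers that correlate
imperfectly with the reported symptom; passing tests therefore validate
the *pipeline logic and heuristics* (counter arithmetic, percentile-duty
identities, lock mechanics, estimator recovery), not clinical performance.
Multiclass discrimination, regularized covariance estimation, event-
triggered snippet storage, bilateral device interaction, and plotting are
out of scope.
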