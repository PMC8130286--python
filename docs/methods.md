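# Methods

This note documents the models and procedures implemented in
`fastripple`, the assumptions behind them, the default parameters and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely
open.

## Signals and conventions

All signals are local field potentials (LFP) in microvolts, one channel
per hippocampal region (DG, CA3, CA1), sampled at a common rate
(default 5 kHz). Times are seconds internally; durations are reported in
milliseconds. A *fast ripple* (FR) is a burst of 250–600 Hz oscillation;
a *sharp wave* is a slow (< 30 Hz) deflection lasting more than 70 ms on
which an FR can ride.

Every filtering step uses forward–backward (zero-phase) FIR filters of
order 512, windowed-sinc design with a Hamming window. The two-pass
application squares the designed magnitude response and cancels phase,
so band-limited features keep their timing; edges are handled with
reflected padding of 3× the filter order so that no transient reaches a
200-ms analysis window. The 512-order/5-kHz combination gives roughly
10 Hz of transition width, adequate for the 250–600 Hz band.

## Detection

Candidates come either from an external table (mirroring a visually
curated workflow) or from an automatic proposer: the 250–600 Hz Hilbert
envelope (smoothed over 10 ms to remove carrier ripple) must exceed a
rolling baseline mean + 3 SD for at least 6 ms. The rolling statistics
are computed on an envelope clipped at a global robust ceiling
(median + 3·1.4826·MAD) so that the events being sought do not inflate
their own threshold; threshold crossings separated by less than 100 ms
are bridged, and of proposals closer than half a window the strongest
is kept.

The screen removes windows whose 60-Hz Fourier component (2|X_k|/N,
Hann-compensated) exceeds 15 µV or whose raw peak-to-peak strictly
exceeds 150 µV; a window at exactly 150 µV is retained. Confirmation
uses a complex Morlet scalogram (center-frequency parameter 6) bound to
250–600 Hz and normalized to its peak: the band power must peak inside
the candidate window, stand at least 4× above the window median
(temporal localization), and the PSD above 200 Hz must be dominated by
the 250–600 Hz band — a broadband (delta-like) transient or plain 1/f
noise fails that last check. The comparison starts at 200 Hz so that
physiological content below the band (theta, gamma, inter-regional
coupling) does not count against a genuine oscillation.

Parameters are computed on the band-filtered segment: the center is the
sample of maximum peak-to-peak excursion between consecutive extrema;
the duration is the full width at half prominence of the smoothed
envelope, with the baseline taken from the whole-trace envelope median
(long events can fill a window, which would bias a window-local
median); amplitude is the peak-to-peak of that extent; the periodogram
(Hann taper over the event extent) gives the power frequency (highest
in-band peak), the power (the PSD value there, µV²/Hz) and the
PSD-weighted mean frequency within the band. Sharp-wave association
low-passes the channel below 30 Hz, finds the peak excursion within
±300 ms of the event, measures its width at 25 % of peak, and flags the
event when that width exceeds 70 ms, the deflection overlaps the event
center, and the excursion stands at least 3 robust SDs above the
slow-band background — without the amplitude condition any smooth
background rhythm would qualify, being trivially wider than 70 ms at a
quarter of its own height.

## Bayesian parameter estimation

Each parameter x in each region follows the robust Student-t model of
the BEST family:

    x  ~ T(ν, µ_region, σ_region)
    µ  ~ Normal(x̄, 2s)            x̄, s from the sample pooled across regions
    σ  ~ Uniform(min, max)         the parameter's physical range
    ν  ~ Exponential(mean 30)      shared across regions within a parameter

The σ ranges are the parameter ranges themselves: amplitude 1–150 µV,
power frequency 250–600 Hz, duration 1–500 ms, power 1–150 µV²/Hz. For
the frequency parameters this puts the lower σ bound far above typical
empirical spreads, so the σ posterior can concentrate against the
boundary; the sampler therefore works in unconstrained coordinates
(logit-mapped σ, log ν, with Jacobians) so the walkers mix freely there.
µ inference is insensitive to this: simulation-based calibration (t
data with ν=30, n=200, 50 seeds) shows ≥ 90 % coverage of the 95 %
credible interval for µ.

Sampling is affine-invariant ensemble MCMC (emcee), default 4 chain
groups × 8 walkers, 1000 retained draws per chain group after 500–1000
warm-up steps. Convergence is summarized by the split-chain R-hat and
effective sample size of µ with walkers pooled into chain groups
(individual ensemble walkers are strongly autocorrelated, so treating
each walker as a chain grossly overstates R-hat); R-hat > 1.05 is
recorded as a warning in the output, never silently dropped. The MAP is
the mode of a Gaussian-kernel density (Silverman bandwidth) over the
standardized joint (µ, σ) draws, evaluated at the draws, with ties
broken toward lower µ. The spectral-composition summary pairs the µ
posteriors of power frequency and mean frequency per region and reports
the shift Δ = E[mean-frequency µ] − E[power-frequency µ]: Δ ≈ 0 is the
synchronous in-phase regime, Δ > 0 indicates energy above the carrier
(out-of-phase firing).

## Multiunit activity

Spikes are local extrema of the z-scored > 300 Hz trace with |z| ≥ 2
(two-sided, since extracellular spikes are biphasic) and a 1-ms
refractory interval; the z baseline excludes event windows so
event-driven variance does not inflate the threshold. On Gaussian
background the two-sided threshold-crossing rate follows the analytic
level-crossing (Rice) rate of the filtered process — the test suite
checks this — so on noisy traces the detected train contains a
noise-floor component; event-locked analyses rely on the rate
*modulation* around events.

Event-locked histograms take 400-ms windows centered on each event's
maximum peak-to-peak sample, count spikes in 20-ms bins and convert to
probability = count / (n_obs × bin width); the conservation identity
Σ prob·Δt·n_obs = counted spikes holds exactly. Cumulative dominance
normalizes each histogram to unit mass and measures, on each side of
the event center, the mass accumulated *from that side's first bin*:
the region accumulating faster dominates that side, so a leading region
dominates pre and a persisting region dominates post. A tolerance of
0.05 in normalized mass absorbs counting noise in sparse bins. (With
globally-cumulative curves a pure time shift can never produce the
post-side reversal; the per-side accumulation is what expresses
"CA3 leads, CA1 persists".)

## Wavelet coherence

Complex Morlet transforms (center-frequency parameter 6) at 12
frequencies per band; coherence is |⟨W_x W_y*⟩|²/(⟨|W_x|²⟩⟨|W_y|²⟩) with
boxcar time smoothing of 4 wavelet periods per frequency, averaged over
the band. Without smoothing the quantity is identically 1; the suite
asserts the degenerate case is avoided. Coherence is symmetric,
amplitude-scale invariant and bounded in [0, 1].

A 400-ms readout centered on the event is split exactly at the center
sample into 200-ms pre/post means, compared across events by paired
Wilcoxon signed-rank (at least 6 events; otherwise an "insufficient n"
report). Because 400 ms covers fewer than 3 theta cycles, the transform
runs on a 2-s context window and only the central 400 ms is read out —
the short window is the readout, not the computation, support. Even so,
at 4–7 Hz the estimator's time resolution is set by its cycle-scaled
smoothing (~0.6–1 s), which also fixes a bias floor of roughly 0.45 for
narrowband signals on these supports; the theta band is 4–7 Hz
(a 3–7 Hz variant is exposed in the band constants).

## Granger causality

Directed influence is tested in the classical bivariate autoregressive
frame: X Granger-causes Y when adding X's past to Y's own past lowers
the residual sum of squares, assessed by the F statistic with the model
order chosen by BIC (orders 1..max_lag scored on the common sample).
Segments are 200 ms immediately before and after the event, placed
adjacent to the event *extent* (center ± one duration, ~2.4 envelope
sigma): inside that guard the burst envelope still holds up to half its
peak, and burst leakage into the windows both fails the stationarity
screen and masks the inter-regional signal. Segments are linearly
detrended and decimated to 1 kHz (zero-phase FIR anti-alias) before
fitting: at 5 kHz a BIC-selected order of a few samples spans well under
a millisecond, far short of the LFP's correlation time, which both
starves the test of power and lets under-fitted own-past models
masquerade as reverse causality. At 1 kHz the same orders span several
milliseconds — the timescale of synaptic delays — and both artifacts
disappear. Decimation can be disabled per call.

The covariance-stationarity screen passes a channel iff (i) split-half
means differ by < 2 autocorrelation-adjusted standard errors, (ii)
split-half log-variances differ by < 2 standard errors with the
effective sample size n/(1 + 2Σρ(k)²) — for a Gaussian process the
autocorrelation of the squared signal is ρ², so narrowband or rhythmic
signals get the wide SE they deserve — and (iii) the sample
autocorrelation falls inside the white-noise 95 % band within a quarter
of the segment. A segment passes iff all channels pass; events with a
failing segment are excluded from pooling (reducing n for every
connection of that event). Calibration: a stationary AR(1) passes
≥ 90 % of the time; linear trends fail on mean drift; random walks fail
predominantly (their detection by split-half moments is inherently
probabilistic).

## Meta-analysis and network metrics

Within one event × epoch the six directed p-values are Bonferroni
adjusted (×6, capped at 1). Each directed connection is pooled across
events by the normal-curve method, Z = (x̄ − 0.5)/(0.2887/√n) with
0.2887 the SD of U[0, 1], and overall p = Φ(Z), one-sided toward small
p-values. Pooling operates on the adjusted p-values by default (a
switch allows raw pooling); note the null center of *adjusted* p-values
lies near 0.92, making the pooled test conservative for spurious edges.
Significant-connection counts are emitted for both adjusted and raw
p-values. Edges with overall p < 0.05 form the network; unit causal
density = (significant interactions involving the node)/(number of
nodes), causal flow = out-degree − in-degree (Σ flow = 0 exactly), hubs
are density maxima (ties shared), sources/sinks have positive/negative
flow.

## The synthetic generator

The generator renders, per channel: 1/f background (5 µV RMS), theta
4–7 Hz (5 µV) built from a shared source mixed with per-channel
independent sources under a time-varying weight, gamma 30–90 Hz
(2.5 µV, independent), a directed-coupling component (10 µV), FR bursts
(Gaussian-windowed sinusoids; `duration_ms` is the envelope FWHM,
`amplitude_pp` the peak-to-peak), sharp waves (negative Gaussian whose
width at 25 % of peak equals the requested duration, plus a small
rebound), and biphasic ~1-ms spike transients from an inhomogeneous
Poisson process whose rate peaks around events earlier in CA3 (−40 ms)
than CA1 (0 ms). Identical seeds give bit-identical arrays.

Amplitudes were fixed in one calibration pass to sit in the regime the
analysis presumes: the composite raw 400-ms peak-to-peak must pass the
150 µV artifact screen (hence sharp waves of 30 µV and cohort burst
amplitudes of 35–65 µV within the 8–105 µV plausible range), while the
250–600 Hz background stays low enough that a default burst exceeds 5×
the band RMS of event-free signal.

The directed coupling is a regime-switching VAR: cross-region terms act
at a 3-ms lag (a realistic synaptic delay), each channel keeps a lag-1
self term, and the adjacency switches from a baseline (uncoupled) to a
"pre" matrix in the 200-ms window before each event's extent and a
"post" matrix in the window after it; innovations are scaled per regime
by the closed-form stationary variance so a coupling switch changes
cross-structure, not power. The recursion runs on innovations colored
with a smooth low-pass profile (Butterworth-6 magnitude, 180 Hz cutoff)
rather than filtering the output: a zero-phase filter applied to the
output smears one-directional lag structure symmetrically in time and
destroys exactly the weak feed-forward edges, whereas the causal
recursion preserves the planted directed structure exactly. The default
cohort plants the pre-event loop {DG↔CA3, CA3↔CA1} at weight 0.32 and
the post-event circuit {DG→CA3 (×1.6), CA3→CA1 (×1.2), CA1→CA3}; the
multipliers equalize detectability, since a lone feed-forward edge into
a node with competing inputs is intrinsically harder for bivariate
Granger tests than a loop member.

The theta coherence schedule raises the shared-source mixing from 0.05
to 0.95 over the 800 ms preceding each event center (~3–4 theta
cycles). A literal 200-ms synchronization burst would be invisible to
*any* honest coherence estimator at 4–7 Hz — below one and a half
cycles — so the generator creates the physiologically plausible version
of the same phenomenon: theta synchronization that builds up ahead of
the event and collapses at it.

### What the generator does not emulate

Electrode drift, chewing/movement artifacts beyond a static amplitude
criterion, inter-animal variability, seizures, non-Gaussian background,
volume conduction, and any biophysical (conductance-based) account of
how fast ripples arise. Passing tests on this generator demonstrate
that the pipeline recovers the structures it assumes when those
structures are present at realistic amplitudes — not that real
recordings satisfy those assumptions.

## Numerical choices and degenerate inputs

Filters reject signals shorter than 3× their order; confirmation
rejects windows shorter than 3 cycles at 250 Hz; flat channels raise
errors in z-scoring, lag selection and coherence; identical channels
raise a singularity error in the Granger regressions; events whose
windows leave the recording are skipped with a warning and reduce the
observation count. Bonferroni caps at 1; pooled connections need n ≥ 2;
paired coherence tests need n ≥ 6. All stochastic stages take explicit
seeds, and the pipeline writes a provenance log (config hash, seed,
version) sufficient to reproduce every output.

## Problem sizes

The standard validation cohort is 40 sharp-wave-associated CA1 events
at 1.6-s spacing (~66 s of 3-channel signal at 5 kHz); Granger
calibration uses 200 epochs of 500–1000 samples; Bayesian calibration
uses 50 seeded fits of n = 200 observations with 4×1000 retained draws;
network recovery is assessed over 10 seeded cohorts. These sizes give
stable pass/fail behavior for the statistical properties while keeping
a full validation run in the tens of minutes on one CPU.

## Known limitations

Bivariate Granger causality cannot distinguish direct from relayed
influence; with strong coupling, two-hop paths (e.g. DG→CA3→CA1)
produce genuine predictive leakage on the unlinked pair, which the
conservative adjusted-pooling absorbs only up to a point. The
stationarity screen's random-walk rejection is probabilistic. The σ
priors inherited from the parameter ranges are arguably too wide (and
for frequencies, bounded away from small values); they are kept because
they are part of the model family being implemented. EDF output is
16-bit quantized over a configurable physical range, and the writer
pads the final 0.1-s record with zeros.
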