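# Methods

This note documents the models, estimators and numerical choices behind
`thetalink`, what the synthetic generator does and does not emulate, and the
known limitations of the statistics involved.

## Signal conditioning

Raw wideband signals (nominally 30–32 kHz) are low-pass filtered below
1000 Hz with a 3rd-order Butterworth, polyphase-resampled to exactly
2000 Hz, and notch-filtered at 50 Hz (2nd-order IIR, quality factor Q = 30,
exposed as a parameter). The spike-band path is a 2nd-order Butterworth
high-pass above 400 Hz at the native rate.

All filters are applied forward–backward (`sosfiltfilt`), so the effective
order doubles and the phase response is identically zero. This choice is
load-bearing: the phase-locking analysis attributes spike times to LFP
phases, and any filter-induced phase lag would bias every preferred angle.
A conditioned signal re-conditioned changes its 0–100 Hz RMS by < 1 %
(idempotence), and the first and last second of every recording are excluded
from window statistics and spike-phase sampling, where two-pass filtering
and wavelet support make estimates unreliable.

## Spectra and coherence

Power spectral densities use Welch's method with a 10-s Hamming window and
50 % overlap, density-scaled so the integral over frequency recovers the
signal variance (Parseval, verified to ±5 % in tests).

Magnitude-squared coherence C_xy(f) = |P_xy|²/(P_xx·P_yy) is Welch-averaged
over 3-s Hamming windows with 50 % overlap of the 0–100 Hz band-passed
signals; with FFT length equal to the window, the frequency resolution is
1/3 Hz. A single window makes the estimator degenerate (C ≡ 1), so at least
8 windows are required. The estimator is implemented on a windowed-FFT path
that is verified in tests to agree with `scipy.signal.coherence` to 1e-10.

### Shuffle confidence limit

Finite window counts bias MSC upward under independence, so significance is
judged against a Monte-Carlo surrogate: in each of 100 iterations the
region-A signal is randomised within every contiguous 3-s block (random
sample permutation by default; a circular-time-shift variant is available
behind `method="shift"`), region B is left intact, the shuffled signal is
re-windowed with the same 50 % overlap, and the MSC recomputed. The 95th
percentile of the pooled surrogate distribution is the per-frequency
confidence limit.

Two design points matter here:

- *Permutation within blocks of the continuous signal*, rather than within
  each overlapping analysis window independently. The null distribution of
  the true MSC carries correlation between overlapping windows; a surrogate
  that destroys it is too tight. Measured on independent white-noise pairs,
  per-window shuffling yields ≈ 8 % exceedance of the 95 % limit where
  ≈ 5 % is nominal; block-wise in-place shuffling yields ≈ 5.2 %.
- The surrogate destroys *all* temporal structure. For strongly narrowband
  signals whose coherence time exceeds the 3-s block (such as a slow
  coherent oscillator), the true null MSC between independent signals is
  additionally inflated by cross-window signal coherence that no
  structure-destroying surrogate reproduces; exceedance rates on such pairs
  run ≈ 8–9 % rather than 5 %. This is a property of surrogate tests on
  narrowband data, not of the implementation.

Band coupling is summarised as the trapezoidal integral of the MSC over
3–5 Hz with the band edges linearly interpolated onto the frequency grid;
for piecewise-linear MSC this equals the analytic integral exactly.
Developmental fold change divides each older animal's band AUC by the mean
AUC of the younger group (a cross-sectional convention — the animals differ
between ages) and reports median (IQR).

## Single-unit metrics

Mean rate is spike count over duration. The Fano factor is the
variance-over-mean of spike counts in non-overlapping bins; the bin width
defaults to 1.0 s (exposed), long enough to average over theta cycles while
leaving hundreds of bins per recording. Units with no spikes have an
undefined Fano factor and are flagged rather than zero-filled.

Waveform features are measured on the mean waveform with parabolic
sub-sample interpolation: the valley-to-peak time runs from the global
trough to the first interior local maximum within 2 ms; the FWHM is the
width of the trough at half its depth below baseline (median of the
pre-trough samples), with linear interpolation at the half-depth crossings.
Waveforms without a rebound peak are flagged undefined. Classification is a
pure threshold rule: fast-spiking iff FWHM < 0.3 ms *and* valley-to-peak
< 0.3 ms, both strict; everything else is regular-spiking.

QC mirrors standard sorter acceptance: SNR at or above the
acquisition-specific threshold (5 for OpenEphys, 11 for Neuralynx — the two
systems' sorters define SNR differently, and the thresholds are honoured as
given), Isolation Distance > 25, L-Ratio < 0.5, and zero inter-spike
intervals below 1 ms (tolerance exposed). SNR is defined here as
peak-to-peak template amplitude over twice the residual noise SD. Isolation
Distance is the squared Mahalanobis distance (w.r.t. the cluster's mean and
covariance) of the n-th closest non-member, n the cluster size; L-Ratio is
Σ χ²-sf(D², df)/n over non-members.

Log-rate distributions use 0.3-decade bins on the log₁₀ rate axis with the
left edge at the floor of the minimum; zero-rate units cannot be placed on a
log axis and are excluded with a count. Bimodality is reported descriptively
(histogram modes), never as a formal test.

## Phase locking

Instantaneous phase comes from a complex Morlet wavelet with n_cycles = 4
(σ_t = n_cycles/(2πf), kernel truncated at ±5σ_t, L1-normalised) at the five
analysis frequencies 3.0–5.0 Hz in 0.5 Hz steps. The convention is fixed by
the kernel: a pure cosine has phase 0° at its peaks, ±180° at its troughs,
and the descending flank spans 0°→+180° (so "firing on the descending
phase" means positive angles). The convention is verified against the
analytic-signal (Hilbert) phase of the band-passed signal — an independent
estimator.

Phases are sampled at the nearest LFP sample to each spike time; spikes in
the excluded edges are dropped and counted. Each unit gets five Rayleigh
tests (finite-n approximation
p = exp(√(1+4n+4(n²−(nR̄)²)) − (1+2n))), and is called locked if any p falls
below 0.05/5 = 0.01. Units with fewer than 5 usable spikes are excluded with
a recorded reason. The preferred angle (circular mean) and mean resultant
length are reported at the minimum-p frequency, ties broken toward the
lowest frequency. Group angles are circular means over locked units only.

Group comparisons: the two-sample Watson–Williams circular ANOVA with the
von Mises correction factor 1 + 3/(8κ̂), κ̂ from the pooled resultant length
via Fisher's approximation. The test assumes comparable and sufficiently
large concentrations; when the pooled R̄ is below 0.45 or the group κ̂ ratio
exceeds 2 the test still runs (matching how it is used in practice) but a
warning is emitted. Locked/non-locked proportions use the two-sided Fisher
exact test, verified in tests against exhaustive hypergeometric enumeration.

### Calibration and a known limitation

The Rayleigh test assumes independent angles. Spike phases sampled from an
oscillation are serially dependent whenever the firing rate approaches the
reciprocal of the phase coherence time (≈ 0.3–0.5 s for the 4-cycle wavelet
in this band); dense-firing units therefore see a mildly inflated
per-frequency false-positive rate (measured ≈ 1.4 % at 3 Hz for a 2 spk/s
unit, nominal 1 %). This applies to any use of the Rayleigh statistic on
phase-sampled spike trains, not to this implementation specifically.
Calibration runs therefore use a sparse probe unit (0.5 spk/s over 400 s,
inside the empirically observed rate range), for which the family-wise
locked-call rate of unmodulated (κ = 0) units measures 1.0 % over 500 runs —
within the ≤ 2 % budget of the Bonferroni rule.

## Synthetic data

The generator's purpose is ground-truth recovery, so each component is the
simplest process with the statistical structure the analyses assume.

- **Composition.** Each region's LFP is delta + theta + 1/f^α background
  (+ optional 50 Hz line), each component synthesised in the frequency
  domain at an internal 1 kHz rate (exact band limitation, bit-reproducible
  from the seed) and polyphase-resampled to the requested raw rate. The
  published descriptions give no quantitative amplitude ratios; the defaults
  (delta RMS 2, theta RMS 1, background RMS 0.5 with α = 1, line off)
  reflect delta-dominated urethane activity and are config-exposed, not
  claimed faithful.
- **Theta source.** A coherent oscillator whose instantaneous frequency is
  a slow (≤ 0.1 Hz) stationary process mapped through the normal CDF, hence
  uniform over 3–5 Hz, with mild slow log-normal amplitude modulation. This
  was chosen over band-passed white noise deliberately: a physiological
  theta rhythm keeps phase coherence over many cycles, which is what makes
  the wavelet phases at the five analysis frequencies track one oscillator
  and the five Rayleigh tests correlated. Band-passed noise decorrelates
  them (measured family-wise rate ≈ 4–4.5 %, the independent-test limit
  1−0.99⁵ ≈ 4.9 %), misrepresenting the statistics of the real analysis.
  The oscillator still spreads its long-run spectrum over the whole band,
  so coherence estimates are exercised with realistic spectral width and
  MSC is not trivially 1.
- **Coupling.** B's theta = c·(A's source) + √(1−c²)·(independent source),
  both unit RMS: B's theta power is independent of c (verified ±5 % over
  seeds) while band MSC grows monotonically with c (Spearman ρ ≈ 0.98
  across c ∈ {0, …, 1}).
- **Spikes.** Gamma-renewal processes (shape k; k = 1 is Poisson) generated
  by time rescaling of λ(t) = λ₀·exp(κ cos(θ(t)−φ_pref))/I₀(κ), with θ(t)
  from the same Morlet machinery the analysis uses — the shared element is
  the phase *convention*, not the code path under test, which is exercised
  end-to-end by recovery tests. A 1.5 ms dead time is imposed so refractory
  QC passes by construction; an optional slow log-normal rate modulation
  (`rate_mod_sigma`) produces Fano factors above 1, since overdispersion
  needs a source beyond renewal variability.
- **Waveforms.** Two opposed Gaussians (trough, rebound) tuned by a damped
  fixed-point iteration against the package's own feature extractor at 10×
  oversampling, so the measured valley-to-peak and FWHM equal the configured
  values to within one sample at the target rate. Additive white noise is
  scaled so that peak-to-peak/(2·SD) equals the configured SNR, matching the
  QC definition. Waveforms are always sampled at the acquisition rate
  (30 kHz by default) even when a scaled-down cohort generates its
  continuous channels at a lower rate.
- **Cohorts.** Groups differ in coupling, rate mixture (log₁₀ λ₀ from a
  normal mixture; two components a decade apart give a bimodal log-rate
  histogram), preferred phase and κ. One master seed is expanded through
  `numpy.random.SeedSequence.spawn`, so any subject regenerates identically
  in isolation.

**What the generator does not emulate:** biophysics (no conductance-based
dynamics, no urethane pharmacology), anatomy and channel geometry, movement
or heartbeat artifacts, spike sorting errors, non-stationarity beyond slow
amplitude/frequency drift, and cross-frequency structure such as
delta–theta nesting. Passing recovery tests therefore demonstrates that the
estimators measure what they claim under the assumed statistical structure —
not that real recordings satisfy that structure.

## Group statistics

Two-group comparisons follow a normality-gated policy: both groups screened
with the D'Agostino–Pearson omnibus test at α = 0.05; if both pass, an
unpaired two-sided t-test (Welch's variant when the variance ratio exceeds
4 — the gate between the two t variants is a documented package choice);
otherwise the two-sided Mann–Whitney U. Groups below n = 8 cannot be
screened and fall straight to Mann–Whitney, logged. Summaries are mean ±
SEM, mean ± SD, or median (IQR) with linear-interpolation quantiles. No
multiple-testing correction is applied across metrics.

## Problem sizes and determinism

Simulation-based tests and the acceptance script scale the study conditions
to desk size as documented analysis choices: continuous channels are
generated at 2–4 kHz rather than the 30 kHz default (all analyses operate on
the 2 kHz conditioned LFP regardless), durations are 100–400 s, and
Monte-Carlo sweeps use 20 seeds per condition (200 for calibration rates).
Every stochastic stage takes an explicit seed; identical configs produce
bit-identical outputs, and the pipeline writes a manifest with SHA-256
checksums of every output file (HDF5 files are hashed by dataset content,
since the container format embeds timestamps).

## Known limitations

- The Rayleigh/locking calibration is exact only for spike trains sparse
  relative to the wavelet phase-coherence time (above).
- The shuffle confidence limit is mildly conservative or anticonservative
  depending on the signal's coherence time relative to the 3-s block
  (above); it is a screening device, not an exact test.
- The Watson–Williams test is applied even when its concentration
  assumptions fail (with a warning), mirroring field practice.
- Isolation Distance is infinite when non-members are fewer than cluster
  members, and undefined for clusters smaller than the feature dimension;
  such units should be judged on the remaining criteria.
- `fold_change` assumes cross-sectional groups; a longitudinal design would
  pair animals instead.
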