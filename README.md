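# thetalink

Analysis pipeline for in-vivo prefrontal–amygdala electrophysiology under
urethane anaesthesia: LFP conditioning, Welch spectra, magnitude-squared
coherence with a Monte-Carlo shuffle confidence limit, single-unit firing and
waveform metrics with regular-/fast-spiking classification, and Morlet-wavelet
spike–LFP phase locking with circular statistics. A synthetic generator of
coupled two-region recordings with full ground truth makes every stage
verifiable by parameter recovery.

Intended users: systems-neuroscience labs analysing paired continuous
recordings (e.g. prelimbic/infralimbic cortex and basolateral amygdala in
developing mice) with sorted single-unit spike times, and anyone who needs a
tested, scriptable re-implementation of this analysis chain.

## The analyses

**Coherence.** For conditioned LFPs x(t), y(t) from the two regions, the
magnitude-squared coherence

&nbsp;&nbsp;&nbsp;&nbsp;C_xy(f) = |P_xy(f)|² / (P_xx(f) · P_yy(f))

is Welch-averaged over 3-s Hamming windows with 50 % overlap of the 0–100 Hz
band-passed signals. Significance is judged against a surrogate: samples of
the region-A signal are permuted within each 3-s block (100 iterations),
the MSC is recomputed, and the 95th percentile of the surrogate distribution
is the per-frequency confidence limit. Band-limited coupling is summarised by
trapezoidal integration of C_xy over the low-theta band (3–5 Hz), and
developmental change as each older animal's band AUC over the mean of the
younger group, reported as median (IQR).

**Single units.** Mean rate, Fano factor (variance/mean of 1-s spike counts),
valley-to-peak time (trough to rebound peak; a proxy for the medium
afterhyperpolarisation duration) and the FWHM of the negative trough, both
with parabolic sub-sample interpolation. Units are fast-spiking iff both
features are strictly below 0.3 ms. QC follows standard sorter criteria
(SNR ≥ 5 OpenEphys / ≥ 11 Neuralynx, Isolation Distance > 25, L-Ratio < 0.5,
no inter-spike intervals below 1 ms).

**Phase locking.** Instantaneous LFP phase from a complex Morlet wavelet
(4 cycles) at 3.0–5.0 Hz in 0.5 Hz steps, with 0° at the oscillation peak,
±180° at the trough, and the descending flank spanning 0°→+180°. The phase at
each spike time feeds per-frequency Rayleigh tests; a unit is *locked* if any
test survives Bonferroni correction (0.05/5 = 0.01). Preferred angle and mean
resultant length R are reported at the minimum-p frequency; groups are
compared with the Watson–Williams circular ANOVA (angles) and the two-sided
Fisher exact test (locked proportions).

**Synthesis.** The generator emulates urethane-like activity: high-amplitude
delta (0.3–0.5 Hz), a coherent low-theta oscillator drifting inside 3–5 Hz,
1/f^α background and optional 50 Hz line noise. Region B's theta is
c·(A's source) + √(1−c²)·(independent source), so its power is independent of
the coupling dial c while coherence scales with c². Spikes are gamma-renewal
processes with von Mises phase modulation
λ(t) = λ₀·exp(κ·cos(θ(t)−φ_pref))/I₀(κ), giving mean rate λ₀ and resultant
length I₁(κ)/I₀(κ). Waveforms are biphasic templates whose measured features
match the configured values to within one sample.

## Worked example

Simulate one subject with coupling 0.8 and three units locked at 135° with
κ = 2, then run coherence and phase locking:

```bash
cat > demo.yaml << 'EOF'
seed: 11
base: {duration: 120.0, fs_raw: 4000.0, base_rate_lambda0: 4.0}
groups:
  - label: demo
    n_subjects: 1
    coupling_c: 0.8
    n_units: 3
    vonmises_kappa: 2.0
    preferred_phase_deg: 135.0
EOF
thetalink simulate --spec demo.yaml --out demo_cohort
thetalink coherence --a demo_cohort/demo_s00_regionA.h5 \
    --b demo_cohort/demo_s00_regionB.h5 --n-shuffle 100 --seed 0 \
    --out demo_coh.csv
thetalink phaselock --lfp demo_cohort/demo_s00_regionA.h5 \
    --spikes demo_cohort/demo_s00_spikes.csv --out demo_lock.csv
```

which prints

```
wrote 1 subjects to demo_cohort
band AUC [3.0-5.0 Hz]: 1.2870
3/3 units locked
```

and `demo_lock.csv` contains

```
     unit_id  locked  best_freq  preferred_angle_deg  resultant_length  n_spikes
demo_s00_u00    True        3.5           139.792088          0.641876        84
demo_s00_u01    True        4.5           139.081377          0.741274       138
demo_s00_u02    True        5.0           138.432008          0.692807       105
```

Reading the numbers: a band AUC of 1.29 over the 2-Hz-wide low-theta band
means an average coherence of ≈ 0.64 — consistent with the configured
coupling (0.8² = 0.64). All three units are called locked, their preferred
angles recover the configured 135° within a few degrees, and the resultant
lengths scatter around I₁(2)/I₀(2) ≈ 0.698, the theoretical locking strength
at κ = 2.

The same stages run end-to-end from one config with `thetalink run
config.yaml`, which writes per-subject coherence, unit-metric and locking
tables, group comparisons, and a checksummed run manifest; identical configs
and seeds reproduce identical outputs.

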