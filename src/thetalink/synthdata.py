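"""Synthetic coupled two-region recordings with known ground truth.

Emulates the statistical structure of urethane-anaesthetised
prefrontal-amygdala recordings: a dominant high-amplitude delta rhythm
(0.3-0.5 Hz) superimposed by a low-theta (3-5 Hz) oscillation, a 1/f^a
background, and optional 50 Hz line noise.  Cross-region coupling is a
single dial ``coupling_c`` in [0, 1]: region B's theta component is
``c * (A's theta source) + sqrt(1 - c^2) * (independent theta)`` with
both sources at unit power, so B's theta power is independent of c while
the expected magnitude-squared coherence at theta scales as c^2.

Spike trains are gamma-renewal point processes whose intensity is
von-Mises-modulated by the instantaneous theta phase,

    lambda(t) = lambda0 * exp(kappa * cos(theta(t) - phi_pref)) / I0(kappa),

so the time-averaged rate stays ~lambda0 and spike phases are von Mises
with concentration kappa (mean resultant length I1(kappa)/I0(kappa)).
The phase theta(t) comes from the same Morlet machinery the analysis
uses, guaranteeing the 0 deg = peak convention is shared by construction
of the *convention*, not of the code path under test.

All oscillatory components are synthesised in the frequency domain at an
internal 1 kHz rate (exact band limitation, bit-reproducible) and
polyphase-resampled to the requested raw rate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal as sps
from scipy.special import i0

from .io import (Recording, SpikeTrain, UnitWaveform, save_recording,
                 save_spike_trains, save_waveforms)
from .phaselock import morlet_phase
from .preprocess import condition_lfp
from .units import waveform_features

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "GroupSpec",
    "CohortSpec",
    "generate_lfp_pair",
    "generate_locked_spikes",
    "generate_renewal_train",
    "generate_waveforms",
    "generate_cohort",
]

FS_GEN = 1000.0  # internal synthesis rate, Hz
REFRACTORY_DEAD_TIME_S = 1.5e-3
LINE_FREQ = 50.0


@dataclass
class SynthConfig:
    """Generative parameters for one synthetic recording pair.

    Amplitudes are RMS values in arbitrary signal units.  The delta
    component occupies ``delta_freq +/- 0.1`` Hz and the theta component
    ``theta_freq +/- 1`` Hz (the 3-5 Hz low-theta band at the default
    centre of 4 Hz).  ``preferred_phase_deg`` uses the analysis
    convention: 0 deg = oscillation peak, +/-180 deg = trough.
    """

    duration: float = 120.0
    fs_raw: float = 30000.0
    delta_freq: float = 0.4
    delta_amp: float = 2.0
    theta_freq: float = 4.0
    theta_amp: float = 1.0
    coupling_c: float = 0.5
    noise_exponent: float = 1.0
    noise_amp: float = 0.5
    line_amp: float = 0.0
    base_rate_lambda0: float = 2.0
    vonmises_kappa: float = 2.0
    preferred_phase_deg: float = 0.0
    fano_shape_k: float = 1.0
    rate_mod_sigma: float = 0.0
    waveform_valley_to_peak_ms: float = 0.40
    waveform_fwhm_ms: float = 0.27
    waveform_snr: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        finite = [self.duration, self.fs_raw, self.delta_freq, self.delta_amp,
                  self.theta_freq, self.theta_amp, self.coupling_c,
                  self.noise_exponent, self.noise_amp, self.line_amp,
                  self.base_rate_lambda0, self.vonmises_kappa,
                  self.preferred_phase_deg, self.fano_shape_k,
                  self.rate_mod_sigma, self.waveform_valley_to_peak_ms,
                  self.waveform_fwhm_ms]
        if not np.all(np.isfinite(finite)):
            raise ValueError("non-finite value in SynthConfig")
        if np.isnan(self.waveform_snr) or self.waveform_snr <= 0:
            raise ValueError("waveform_snr must be > 0 (inf = noiseless)")
        if not 0 <= self.coupling_c <= 1:
            raise ValueError(f"coupling_c must lie in [0, 1], got {self.coupling_c}")
        for name in ("delta_amp", "theta_amp", "noise_amp", "line_amp",
                     "base_rate_lambda0", "vonmises_kappa", "noise_exponent",
                     "rate_mod_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.fano_shape_k <= 0:
            raise ValueError("fano_shape_k must be > 0")
        if self.duration <= 0 or self.fs_raw < 2000:
            raise ValueError("duration must be > 0 and fs_raw >= 2000 Hz")
        if not -180 < self.preferred_phase_deg <= 180:
            raise ValueError("preferred_phase_deg must lie in (-180, 180]")
        if self.duration * self.theta_freq < 10:
            raise ValueError("need at least 10 theta cycles (duration too short)")

    @property
    def theta_band(self) -> tuple[float, float]:
        return (self.theta_freq - 1.0, self.theta_freq + 1.0)


@dataclass
class GroundTruth:
    """Generative parameters actually used, one entry per generated unit/pair."""

    coupling_c: float | None = None
    theta_band: tuple[float, float] | None = None
    units: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# frequency-domain component synthesis
# ---------------------------------------------------------------------------

def _spectral_noise(rng: np.random.Generator, n: int, fs: float,
                    shaping) -> np.ndarray:
    """Real signal with Gaussian coefficients shaped by ``shaping(freqs)``."""
    freqs = np.fft.rfftfreq(n, 1 / fs)
    amp = shaping(freqs)
    coef = (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    coef *= amp
    coef[0] = 0.0
    x = np.fft.irfft(coef, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _narrowband(rng: np.random.Generator, n: int, fs: float,
                lo: float, hi: float) -> np.ndarray:
    """Unit-RMS Gaussian process exactly band-limited to [lo, hi] Hz."""
    return _spectral_noise(rng, n, fs,
                           lambda f: ((f >= lo) & (f <= hi)).astype(float))


def _slow_noise(rng: np.random.Generator, n: int, fs: float,
                cutoff_hz: float) -> np.ndarray:
    return _spectral_noise(rng, n, fs,
                           lambda f: ((f > 0) & (f <= cutoff_hz)).astype(float))


def _theta_oscillator(rng: np.random.Generator, n: int, fs: float,
                      lo: float, hi: float) -> np.ndarray:
    """Unit-RMS coherent oscillator drifting stochastically inside [lo, hi] Hz.

    The instantaneous frequency is a slow (<= 0.1 Hz) stationary process
    mapped through the normal CDF, so its marginal distribution is
    uniform over the band; the amplitude carries a mild slow log-normal
    modulation.  Unlike band-passed white noise, the resulting rhythm
    keeps phase coherence over many cycles — wavelet phases at nearby
    analysis frequencies all track the same oscillator, as they do for a
    physiological theta rhythm — while its long-run spectrum still
    covers the whole band.
    """
    from scipy.special import ndtr

    drive = _slow_noise(rng, n, fs, 0.1)
    sd = drive.std()
    f_inst = lo + (hi - lo) * (ndtr(drive / sd) if sd > 0
                               else np.full(n, 0.5))
    phase = 2 * np.pi * np.cumsum(f_inst) / fs + rng.uniform(0, 2 * np.pi)
    env = np.exp(0.25 * _slow_noise(rng, n, fs, 0.2) - 0.25 ** 2 / 2)
    x = env * np.cos(phase)
    return x / x.std()


def _powerlaw(rng: np.random.Generator, n: int, fs: float,
              alpha: float) -> np.ndarray:
    """Unit-RMS 1/f^alpha background (alpha in power units)."""

    def shaping(f):
        a = np.zeros_like(f)
        nz = f > 0
        a[nz] = f[nz] ** (-alpha / 2)
        return a

    return _spectral_noise(rng, n, fs, shaping)


def _resample_to(x: np.ndarray, fs_from: float, fs_to: float) -> np.ndarray:
    if fs_from == fs_to:
        return x
    frac = Fraction(int(round(fs_to)), int(round(fs_from)))
    return sps.resample_poly(x, frac.numerator, frac.denominator)


def generate_lfp_pair(config: SynthConfig
                      ) -> tuple[Recording, Recording, GroundTruth]:
    """Two single-channel recordings with tunable theta-band coupling."""
    rng = np.random.default_rng(config.seed)
    n_gen = int(round(config.duration * FS_GEN))
    lo, hi = config.theta_band

    theta_shared = _theta_oscillator(rng, n_gen, FS_GEN, lo, hi)
    theta_indep = _theta_oscillator(rng, n_gen, FS_GEN, lo, hi)
    c = config.coupling_c
    theta_a = theta_shared
    theta_b = c * theta_shared + np.sqrt(1 - c ** 2) * theta_indep

    t_gen = np.arange(n_gen) / FS_GEN
    signals = []
    for theta in (theta_a, theta_b):
        sig = config.theta_amp * theta
        if config.delta_amp > 0:
            sig = sig + config.delta_amp * _narrowband(
                rng, n_gen, FS_GEN, config.delta_freq - 0.1, config.delta_freq + 0.1)
        if config.noise_amp > 0:
            sig = sig + config.noise_amp * _powerlaw(
                rng, n_gen, FS_GEN, config.noise_exponent)
        if config.line_amp > 0:
            phi = rng.uniform(0, 2 * np.pi)
            sig = sig + config.line_amp * np.sqrt(2) * np.sin(
                2 * np.pi * LINE_FREQ * t_gen + phi)
        signals.append(_resample_to(sig, FS_GEN, config.fs_raw))

    n_raw = int(round(config.duration * config.fs_raw))
    meta = [{"region": r, "subject": "synthetic"} for r in ("A", "B")]
    rec_a = Recording(signal=signals[0][:n_raw], fs=config.fs_raw,
                      channel_meta=[meta[0]])
    rec_b = Recording(signal=signals[1][:n_raw], fs=config.fs_raw,
                      channel_meta=[meta[1]])
    truth = GroundTruth(coupling_c=c, theta_band=(lo, hi))
    return rec_a, rec_b, truth


# ---------------------------------------------------------------------------
# spike trains
# ---------------------------------------------------------------------------

def _theta_phase_deg(lfp: Recording, config: SynthConfig,
                     channel: int = 0) -> tuple[np.ndarray, float]:
    """Instantaneous theta phase of the LFP on a <= 2 kHz grid."""
    rec = lfp
    if rec.fs > 2000:
        rec = condition_lfp(rec) if rec.fs >= 4000 else rec
    ps = morlet_phase(rec, channel=channel, freqs=(config.theta_freq,))
    return ps.phase_deg[0], ps.fs


def _apply_dead_time(times: np.ndarray,
                     dead_s: float = REFRACTORY_DEAD_TIME_S) -> np.ndarray:
    # never emit gaps below the duplicate tolerance of SpikeTrain
    dead_s = max(dead_s, 1.01e-4)
    if times.size == 0:
        return times
    kept = [times[0]]
    last = times[0]
    for t in times[1:]:
        if t - last >= dead_s:
            kept.append(t)
            last = t
    return np.asarray(kept)


def _rescaled_renewal(cum_intensity: np.ndarray, t_grid: np.ndarray,
                      shape_k: float, rng: np.random.Generator) -> np.ndarray:
    """Gamma-renewal spikes via time rescaling of the cumulative intensity."""
    total = cum_intensity[-1]
    if total <= 0:
        return np.array([])
    n_draw = int(total + 4 * np.sqrt(total) + 20)
    gaps = rng.gamma(shape_k, 1.0 / shape_k, size=n_draw)
    s = np.cumsum(gaps)
    while s[-1] < total:  # rare under-draw
        extra = rng.gamma(shape_k, 1.0 / shape_k, size=n_draw)
        s = np.concatenate([s, s[-1] + np.cumsum(extra)])
    s = s[s < total]
    return np.interp(s, cum_intensity, t_grid)


def generate_locked_spikes(lfp: Recording, config: SynthConfig,
                           rng: np.random.Generator | None = None,
                           unit_id: str = "u0",
                           phase_deg: np.ndarray | None = None,
                           phase_fs: float | None = None) -> SpikeTrain:
    """Theta-phase-modulated spike train with known preferred angle and kappa.

    ``phase_deg``/``phase_fs`` may carry a precomputed phase series to
    amortise the wavelet transform over many units of one recording.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if phase_deg is None:
        phase_deg, phase_fs = _theta_phase_deg(lfp, config)
    duration = phase_deg.size / phase_fs

    kappa = config.vonmises_kappa
    lam0 = config.base_rate_lambda0
    if lam0 * duration < 1:
        warnings.warn("expected spike count below 1; train may be empty",
                      stacklevel=2)
    phi = np.radians(config.preferred_phase_deg)
    lam = lam0 * np.exp(kappa * np.cos(np.radians(phase_deg) - phi)) / i0(kappa)
    if config.rate_mod_sigma > 0:
        # slow log-normal modulation (Fano factor > 1 knob); unit mean
        slow = _spectral_noise(rng, phase_deg.size, phase_fs,
                               lambda f: ((f > 0) & (f <= 0.1)).astype(float))
        lam = lam * np.exp(config.rate_mod_sigma * slow
                           - config.rate_mod_sigma ** 2 / 2)

    t_grid = np.arange(phase_deg.size) / phase_fs
    cum = np.concatenate([[0.0], np.cumsum(lam[:-1] + lam[1:]) / (2 * phase_fs)])
    times = _rescaled_renewal(cum, t_grid, config.fano_shape_k, rng)
    times = _apply_dead_time(np.sort(times))
    return SpikeTrain(unit_id=unit_id, spike_times=times,
                      recording_duration=duration, region="A", channel=0)


def generate_renewal_train(rate: float, duration: float, shape_k: float = 1.0,
                           rng: np.random.Generator | int | None = None,
                           unit_id: str = "u0",
                           dead_time_s: float = REFRACTORY_DEAD_TIME_S
                           ) -> SpikeTrain:
    """Homogeneous gamma-renewal train (shape 1 = Poisson) with dead time."""
    rng = np.random.default_rng(rng)
    if rate <= 0 or duration <= 0:
        raise ValueError("rate and duration must be positive")
    total = rate * duration
    n_draw = int(total + 4 * np.sqrt(total) + 20)
    gaps = rng.gamma(shape_k, 1.0 / (shape_k * rate), size=n_draw)
    s = np.cumsum(gaps)
    while s.size and s[-1] < duration:
        s = np.concatenate(
            [s, s[-1] + np.cumsum(rng.gamma(shape_k, 1.0 / (shape_k * rate),
                                            size=n_draw))])
    times = _apply_dead_time(s[s < duration], dead_time_s)
    return SpikeTrain(unit_id=unit_id, spike_times=times,
                      recording_duration=duration)


# ---------------------------------------------------------------------------
# waveforms
# ---------------------------------------------------------------------------

def _waveform_template(fs: float, v2p_ms: float, fwhm_ms: float,
                       pos_frac: float = 0.35) -> np.ndarray:
    """Biphasic template whose measured features equal the targets.

    Two opposed Gaussians (trough then rebound) interact, so the shape
    parameters are tuned by fixed-point iteration against the same
    feature extractor used in analysis, at 10x temporal oversampling.
    """
    over = 10
    fs_hi = fs * over
    sigma1 = fwhm_ms / (2 * np.sqrt(2 * np.log(2)))
    d = v2p_ms
    sigma2 = 0.3 * v2p_ms

    def build(sig1, dd):
        t = np.arange(-1.0, 2.5, 1e3 / fs_hi)  # ms grid
        w = -np.exp(-t ** 2 / (2 * sig1 ** 2)) \
            + pos_frac * np.exp(-(t - dd) ** 2 / (2 * sigma2 ** 2))
        return w

    for _ in range(30):  # damped fixed point against the analysis extractor
        wf = UnitWaveform(unit_id="tmpl", samples=build(sigma1, d), fs=fs_hi)
        feats = waveform_features(wf)
        if not feats.defined:
            break
        err_v = v2p_ms - feats.valley_to_peak_ms
        err_f = fwhm_ms / feats.fwhm_ms
        if abs(err_v) < 1e-4 and abs(err_f - 1) < 1e-4:
            break
        d += 0.7 * err_v
        sigma1 *= err_f ** 0.7
    w_hi = build(sigma1, d)
    return w_hi[::over].copy()


def generate_waveforms(config: SynthConfig, n_units: int,
                       rng: np.random.Generator | None = None,
                       fs: float | None = None
                       ) -> tuple[list[UnitWaveform], list[dict]]:
    """Noisy copies of a biphasic template with configured features.

    ``fs`` defaults to ``config.fs_raw`` (waveforms are sampled at the
    acquisition rate).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if fs is None:
        fs = config.fs_raw
    dt_ms = 2e3 / fs
    if config.waveform_fwhm_ms <= dt_ms or config.waveform_valley_to_peak_ms <= dt_ms:
        raise ValueError("waveform features narrower than 2 sample intervals")
    template = _waveform_template(fs, config.waveform_valley_to_peak_ms,
                                  config.waveform_fwhm_ms)
    noise_sd = np.ptp(template) / (2 * config.waveform_snr) \
        if np.isfinite(config.waveform_snr) and config.waveform_snr > 0 else 0.0
    out, truth = [], []
    for i in range(n_units):
        w = template + noise_sd * rng.standard_normal(template.size)
        out.append(UnitWaveform(unit_id=f"u{i}", samples=w, fs=fs))
        truth.append({"unit_id": f"u{i}",
                      "valley_to_peak_ms": config.waveform_valley_to_peak_ms,
                      "fwhm_ms": config.waveform_fwhm_ms,
                      "snr": config.waveform_snr})
    return out, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class GroupSpec:
    """One experimental group of a synthetic cohort.

    ``rate_log10_means``/``sds``/``weights`` parameterise a mixture of
    log-normal base rates (two components a decade apart produce a
    bimodal log-rate histogram).
    """

    label: str
    n_subjects: int
    coupling_c: float = 0.5
    n_units: int = 5
    rate_log10_means: tuple[float, ...] = (0.0,)
    rate_log10_sds: tuple[float, ...] = (0.25,)
    rate_weights: tuple[float, ...] = (1.0,)
    preferred_phase_deg: float = 0.0
    vonmises_kappa: float = 2.0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0 or self.n_units < 0:
            raise ValueError("n_subjects must be > 0 and n_units >= 0")
        if not (len(self.rate_log10_means) == len(self.rate_log10_sds)
                == len(self.rate_weights)):
            raise ValueError("rate mixture parameter lengths must match")
        if not np.isclose(sum(self.rate_weights), 1.0):
            raise ValueError("rate mixture weights must sum to 1")


@dataclass
class CohortSpec:
    groups: list[GroupSpec]
    base: SynthConfig = field(default_factory=SynthConfig)
    seed: int = 0


def generate_cohort(spec: CohortSpec, out_dir: str | Path) -> dict:
    """Write a cohort of recordings + spike tables with a ground-truth manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(spec.seed)
    manifest: dict = {"seed": spec.seed, "base_config": asdict(spec.base),
                      "subjects": []}
    children = iter(ss.spawn(sum(g.n_subjects for g in spec.groups)))
    for grp in spec.groups:
        for si in range(grp.n_subjects):
            child = next(children)
            sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
            rng = np.random.default_rng(child)
            subject = f"{grp.label}_s{si:02d}"
            cfg = replace(spec.base, coupling_c=grp.coupling_c,
                          vonmises_kappa=grp.vonmises_kappa,
                          preferred_phase_deg=grp.preferred_phase_deg,
                          seed=sub_seed)
            rec_a, rec_b, _ = generate_lfp_pair(cfg)
            path_a = save_recording(rec_a, out_dir / f"{subject}_regionA.h5")
            path_b = save_recording(rec_b, out_dir / f"{subject}_regionB.h5")

            phase_deg, phase_fs = (None, None)
            trains, unit_truth = [], []
            if grp.n_units:
                phase_deg, phase_fs = _theta_phase_deg(rec_a, cfg)
            for ui in range(grp.n_units):
                comp = rng.choice(len(grp.rate_weights), p=grp.rate_weights)
                lam0 = float(10 ** rng.normal(grp.rate_log10_means[comp],
                                              grp.rate_log10_sds[comp]))
                ucfg = replace(cfg, base_rate_lambda0=lam0)
                tr = generate_locked_spikes(rec_a, ucfg, rng=rng,
                                            unit_id=f"{subject}_u{ui:02d}",
                                            phase_deg=phase_deg,
                                            phase_fs=phase_fs)
                trains.append(tr)
                unit_truth.append({"unit_id": tr.unit_id, "lambda0": lam0,
                                   "kappa": grp.vonmises_kappa,
                                   "preferred_phase_deg": grp.preferred_phase_deg})
            spikes_path = save_spike_trains(trains, out_dir / f"{subject}_spikes.csv")
            # waveforms keep the acquisition-rate sampling even when the
            # continuous channels are generated at a reduced rate
            waveforms, wf_truth = generate_waveforms(
                cfg, grp.n_units, rng=rng, fs=max(cfg.fs_raw, 30000.0))
            wf_path = save_waveforms(waveforms, out_dir / f"{subject}_waveforms.h5")
            manifest["subjects"].append({
                "subject": subject, "group": grp.label, "seed": sub_seed,
                "coupling_c": grp.coupling_c,
                "files": {"regionA": path_a.name, "regionB": path_b.name,
                          "spikes": spikes_path.name, "waveforms": wf_path.name},
                "units": unit_truth, "waveform_truth": wf_truth,
            })
    with open(out_dir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1)
    return manifest
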