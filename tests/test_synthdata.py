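import numpy as np
import pytest
from scipy.special import i0, i1

from thetalink.phaselock import morlet_phase, resultant_length, spike_phases
from thetalink.preprocess import bandpass
from thetalink.spectral import msc
from thetalink.synthdata import (CohortSpec, GroupSpec, SynthConfig,
                                 generate_cohort, generate_lfp_pair,
                                 generate_locked_spikes, generate_renewal_train,
                                 generate_waveforms)
from thetalink.units import firing_metrics, waveform_features


class TestSynthConfig:
    @pytest.mark.parametrize("kwargs", [
        {"coupling_c": 1.5},
        {"coupling_c": -0.1},
        {"theta_amp": -1.0},
        {"fano_shape_k": 0.0},
        {"duration": 1.0},            # < 10 theta cycles
        {"preferred_phase_deg": 270.0},
        {"delta_amp": np.nan},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SynthConfig(**kwargs)

    def test_theta_band_centred(self):
        assert SynthConfig().theta_band == (3.0, 5.0)


class TestGenerateLfpPair:
    def test_seed_determinism(self):
        cfg = SynthConfig(duration=20.0, fs_raw=2000.0, seed=7)
        a1, b1, _ = generate_lfp_pair(cfg)
        a2, b2, _ = generate_lfp_pair(cfg)
        np.testing.assert_array_equal(a1.signal, a2.signal)
        np.testing.assert_array_equal(b1.signal, b2.signal)

    def test_full_coupling_noiseless_gives_unit_coherence(self):
        cfg = SynthConfig(duration=100.0, fs_raw=2000.0, coupling_c=1.0,
                          delta_amp=0.0, noise_amp=0.0, seed=1)
        a, b, _ = generate_lfp_pair(cfg)
        res = msc(a, b)
        band = (res.freqs >= 3.2) & (res.freqs <= 4.8)
        assert np.all(res.msc[band] > 0.95)

    def test_theta_power_independent_of_coupling(self):
        powers = {}
        for c in (0.0, 0.5, 1.0):
            vals = []
            for seed in range(15):
                cfg = SynthConfig(duration=60.0, fs_raw=2000.0, coupling_c=c,
                                  delta_amp=0.0, noise_amp=0.0, seed=seed)
                _, b, _ = generate_lfp_pair(cfg)
                theta = bandpass(b, 3.0, 5.0).signal[0, 2000:-2000]
                vals.append(np.mean(theta ** 2))
            powers[c] = np.mean(vals)
        ref = powers[0.0]
        assert all(abs(p - ref) / ref < 0.05 for p in powers.values())

    def test_coupling_monotone_band_msc(self):
        aucs = []
        for c in (0.3, 0.8):
            cfg = SynthConfig(duration=100.0, fs_raw=2000.0, coupling_c=c, seed=11)
            a, b, _ = generate_lfp_pair(cfg)
            aucs.append(msc(a, b).band_auc)
        assert aucs[1] > aucs[0]

    def test_line_noise_present_when_enabled(self):
        cfg = SynthConfig(duration=30.0, fs_raw=2000.0, line_amp=1.0,
                          noise_amp=0.0, delta_amp=0.0, seed=2)
        a, _, _ = generate_lfp_pair(cfg)
        spec = np.abs(np.fft.rfft(a.signal[0]))
        freqs = np.fft.rfftfreq(a.n_samples, 1 / a.fs)
        i50 = np.argmin(np.abs(freqs - 50))
        assert spec[i50] > 10 * np.median(spec)


class TestGenerateLockedSpikes:
    def test_mean_rate_near_lambda0(self):
        cfg = SynthConfig(duration=200.0, fs_raw=2000.0, base_rate_lambda0=5.0,
                          vonmises_kappa=2.0, seed=3)
        rec, _, _ = generate_lfp_pair(cfg)
        train = generate_locked_spikes(rec, cfg)
        assert abs(train.mean_rate - 5.0) / 5.0 < 0.15

    @pytest.mark.parametrize("kappa", [0.5, 1.0, 2.0, 4.0])
    def test_resultant_length_matches_bessel_ratio(self, kappa):
        cfg = SynthConfig(duration=250.0, fs_raw=2000.0, base_rate_lambda0=6.0,
                          vonmises_kappa=kappa, preferred_phase_deg=45.0, seed=4)
        rec, _, _ = generate_lfp_pair(cfg)
        train = generate_locked_spikes(rec, cfg,
                                       rng=np.random.default_rng(int(10 * kappa)))
        phases = morlet_phase(rec, freqs=(4.0,))
        angles, _ = spike_phases(train, phases)
        assert angles[0].size >= 1000
        expected = i1(kappa) / i0(kappa)
        assert abs(resultant_length(angles[0]) - expected) < 0.05

    def test_kappa_zero_uniform_phases(self):
        from thetalink.phaselock import rayleigh_test
        cfg = SynthConfig(duration=150.0, fs_raw=2000.0, base_rate_lambda0=5.0,
                          vonmises_kappa=0.0, seed=5)
        rec, _, _ = generate_lfp_pair(cfg)
        phases = morlet_phase(rec, freqs=(4.0,))
        nonsig = 0
        for seed in range(30):
            train = generate_locked_spikes(rec, cfg, rng=np.random.default_rng(seed),
                                           phase_deg=phases.phase_deg[0],
                                           phase_fs=phases.fs)
            angles, _ = spike_phases(train, phases)
            nonsig += rayleigh_test(angles[0]) > 0.01
        assert nonsig >= 27

    def test_refractory_dead_time_enforced(self):
        cfg = SynthConfig(duration=100.0, fs_raw=2000.0, base_rate_lambda0=30.0,
                          vonmises_kappa=0.0, seed=6)
        rec, _, _ = generate_lfp_pair(cfg)
        train = generate_locked_spikes(rec, cfg)
        assert np.all(np.diff(train.spike_times) >= 1.5e-3 - 1e-12)

    def test_expected_empty_train_warns(self):
        cfg = SynthConfig(duration=30.0, fs_raw=2000.0, base_rate_lambda0=0.01,
                          seed=7)
        rec, _, _ = generate_lfp_pair(cfg)
        with pytest.warns(UserWarning, match="empty"):
            generate_locked_spikes(rec, cfg)

    def test_gamma_renewal_fano_below_one(self):
        regular = firing_metrics(generate_renewal_train(5.0, 200.0, shape_k=8.0,
                                                        rng=1))
        poisson = firing_metrics(generate_renewal_train(5.0, 200.0, rng=1))
        assert regular.fano < poisson.fano
        assert regular.fano < 0.5


class TestGenerateWaveforms:
    @pytest.mark.parametrize("v2p,fwhm", [(0.2, 0.2), (0.40, 0.27), (0.5, 0.4)])
    def test_noiseless_feature_round_trip(self, v2p, fwhm):
        cfg = SynthConfig(waveform_valley_to_peak_ms=v2p, waveform_fwhm_ms=fwhm,
                          waveform_snr=np.inf)
        wfs, truth = generate_waveforms(cfg, 1)
        feats = waveform_features(wfs[0])
        assert feats.defined
        assert abs(feats.valley_to_peak_ms - v2p) < 1 / 30
        assert abs(feats.fwhm_ms - fwhm) < 1 / 30
        assert truth[0]["valley_to_peak_ms"] == v2p

    def test_noiseless_copies_identical(self):
        cfg = SynthConfig(waveform_snr=np.inf)
        wfs, _ = generate_waveforms(cfg, 3)
        np.testing.assert_array_equal(wfs[0].samples, wfs[1].samples)
        np.testing.assert_array_equal(wfs[1].samples, wfs[2].samples)

    def test_features_narrower_than_two_samples_rejected(self):
        cfg = SynthConfig(fs_raw=30000.0, waveform_fwhm_ms=0.05,
                          waveform_valley_to_peak_ms=0.05)
        with pytest.raises(ValueError, match="2 sample"):
            generate_waveforms(cfg, 1)

    def test_noise_scales_with_snr(self):
        cfg_hi = SynthConfig(waveform_snr=50.0, seed=8)
        cfg_lo = SynthConfig(waveform_snr=5.0, seed=8)
        w_hi, _ = generate_waveforms(cfg_hi, 1)
        w_lo, _ = generate_waveforms(cfg_lo, 1)
        template, _ = generate_waveforms(SynthConfig(waveform_snr=np.inf), 1)
        res_hi = np.std(w_hi[0].samples - template[0].samples)
        res_lo = np.std(w_lo[0].samples - template[0].samples)
        assert res_lo == pytest.approx(10 * res_hi, rel=0.05)


@pytest.fixture(scope="module")
def small_spec():
    base = SynthConfig(duration=30.0, fs_raw=2000.0, base_rate_lambda0=3.0)
    return CohortSpec(groups=[
        GroupSpec(label="control", n_subjects=2, coupling_c=0.3, n_units=2),
        GroupSpec(label="els", n_subjects=2, coupling_c=0.7, n_units=2),
    ], base=base, seed=99)


class TestGenerateCohort:

    def test_writes_complete_dataset(self, small_spec, tmp_path):
        manifest = generate_cohort(small_spec, tmp_path / "cohort")
        assert len(manifest["subjects"]) == 4
        for sub in manifest["subjects"]:
            for f in sub["files"].values():
                assert (tmp_path / "cohort" / f).exists()
            assert len(sub["units"]) == 2

    def test_deterministic_manifest(self, small_spec, tmp_path):
        m1 = generate_cohort(small_spec, tmp_path / "c1")
        m2 = generate_cohort(small_spec, tmp_path / "c2")
        u1 = [u for s in m1["subjects"] for u in s["units"]]
        u2 = [u for s in m2["subjects"] for u in s["units"]]
        assert u1 == u2

    def test_bimodal_group_rates(self, tmp_path):
        base = SynthConfig(duration=30.0, fs_raw=2000.0)
        spec = CohortSpec(groups=[GroupSpec(
            label="bimodal", n_subjects=1, n_units=40,
            rate_log10_means=(-0.5, 0.5), rate_log10_sds=(0.1, 0.1),
            rate_weights=(0.5, 0.5))], base=base, seed=5)
        manifest = generate_cohort(spec, tmp_path / "bi")
        lams = np.log10([u["lambda0"] for u in manifest["subjects"][0]["units"]])
        assert np.sum(lams < 0) >= 10 and np.sum(lams > 0) >= 10

    def test_invalid_group_rejected(self):
        with pytest.raises(ValueError):
            GroupSpec(label="bad", n_subjects=0)
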