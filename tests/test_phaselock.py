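import numpy as np
import pytest
from scipy import signal as sps
from scipy.special import i0, i1
from scipy.stats import hypergeom

from thetalink.io import Recording, SpikeTrain
from thetalink.phaselock import (LOW_THETA_FREQS, circular_mean_deg, group_summary,
                                 lock_unit, locked_proportion_test, morlet_phase,
                                 rayleigh_test, resultant_length, spike_phases,
                                 watson_williams)
from thetalink.preprocess import bandpass
from thetalink.synthdata import SynthConfig, generate_lfp_pair, generate_locked_spikes


class TestMorletPhase:
    def test_peak_trough_convention(self, cosine_recording):
        ps = morlet_phase(cosine_recording, freqs=(4.0,))
        fs = cosine_recording.fs
        peaks = (np.arange(8, 112) * fs / 4).astype(int)
        troughs = ((np.arange(8, 112) + 0.5) * fs / 4).astype(int)
        assert np.max(np.abs(ps.phase_deg[0, peaks])) < 2.0
        assert np.max(np.abs(np.abs(ps.phase_deg[0, troughs]) - 180)) < 2.0

    def test_descending_flank_positive(self, cosine_recording):
        ps = morlet_phase(cosine_recording, freqs=(4.0,))
        falling = ((np.arange(8, 112) + 0.25) * cosine_recording.fs / 4).astype(int)
        assert np.allclose(ps.phase_deg[0, falling], 90.0, atol=2.0)

    def test_phase_advances_one_cycle_per_period(self, cosine_recording):
        ps = morlet_phase(cosine_recording, freqs=(4.0,))
        fs = cosine_recording.fs
        mid = slice(int(5 * fs), int(25 * fs))
        unwrapped = np.unwrap(np.radians(ps.phase_deg[0, mid]))
        slope = np.polyfit(np.arange(unwrapped.size) / fs, unwrapped, 1)[0]
        assert abs(slope / (2 * np.pi) - 4.0) / 4.0 < 0.01

    def test_agrees_with_hilbert_phase(self):
        """Independent route: analytic-signal phase of the band-passed LFP."""
        cfg = SynthConfig(duration=60.0, fs_raw=2000.0, seed=9, noise_amp=0.2)
        rec, _, _ = generate_lfp_pair(cfg)
        ps = morlet_phase(rec, freqs=(4.0,))
        narrow = bandpass(rec, 3.0, 5.0)
        hil = np.degrees(np.angle(sps.hilbert(narrow.signal[0])))
        mid = slice(4000, -4000)
        diff = np.angle(np.exp(1j * np.radians(ps.phase_deg[0, mid] - hil[mid])))
        assert np.percentile(np.abs(np.degrees(diff)), 90) < 25.0

    def test_above_nyquist_rejected(self, cosine_recording):
        with pytest.raises(ValueError, match="Nyquist"):
            morlet_phase(cosine_recording, freqs=(1500.0,))


class TestSpikePhases:
    def test_spikes_at_peaks_read_zero_degrees(self, cosine_recording):
        times = np.arange(2, 28, 0.25)  # every 4 Hz peak
        train = SpikeTrain("u", times, cosine_recording.duration)
        ps = morlet_phase(cosine_recording, freqs=(4.0,))
        angles, dropped = spike_phases(train, ps)
        assert dropped == 0
        assert np.max(np.abs(angles[0])) < 2.0

    def test_edge_spikes_dropped(self, cosine_recording):
        train = SpikeTrain("u", [0.2, 15.0, 29.9], cosine_recording.duration)
        ps = morlet_phase(cosine_recording, freqs=(4.0,))
        angles, dropped = spike_phases(train, ps)
        assert dropped == 2 and angles[0].size == 1

    def test_empty_train(self, cosine_recording):
        ps = morlet_phase(cosine_recording, freqs=(4.0,))
        angles, dropped = spike_phases(SpikeTrain("u", [], 30.0), ps)
        assert angles[0].size == 0 and dropped == 0


class TestRayleigh:
    def test_identical_angles_tiny_p(self):
        assert rayleigh_test(np.full(30, 45.0)) < 1e-10

    def test_uniform_angles_calibrated(self):
        rng = np.random.default_rng(0)
        keep = sum(rayleigh_test(np.degrees(rng.uniform(-np.pi, np.pi, 1000))) > 0.05
                   for _ in range(100))
        assert keep >= 94

    def test_antipodal_pairs_p_near_one(self):
        angles = np.concatenate([np.arange(5) * 10.0, np.arange(5) * 10.0 + 180])
        assert rayleigh_test(angles) > 0.99

    def test_monotone_in_resultant_length(self):
        n = 50
        ps = []
        for spread in (120.0, 60.0, 30.0, 10.0):
            angles = np.linspace(-spread, spread, n)
            ps.append(rayleigh_test(angles))
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        a = np.degrees(rng.vonmises(0.5, 1.5, 80))
        _, p_ref = pg.circ_rayleigh(np.radians(a))
        assert rayleigh_test(a) == pytest.approx(p_ref, rel=1e-9)

    def test_too_few_angles_rejected(self):
        with pytest.raises(ValueError):
            rayleigh_test(np.array([0.0, 10.0, 20.0]))


@pytest.fixture(scope="module")
def locked_setup():
    cfg = SynthConfig(duration=120.0, fs_raw=2000.0, base_rate_lambda0=6.0,
                      vonmises_kappa=2.0, preferred_phase_deg=90.0, seed=21)
    rec, _, _ = generate_lfp_pair(cfg)
    phases = morlet_phase(rec)
    return cfg, rec, phases


class TestLockUnit:
    def test_recovers_preferred_angle(self, locked_setup):
        cfg, rec, phases = locked_setup
        train = generate_locked_spikes(rec, cfg,
                                       rng=np.random.default_rng(2))
        res = lock_unit(train, phases)
        assert res.locked
        assert abs(res.preferred_angle_deg - 90.0) < 10.0
        assert res.n_spikes >= 300

    def test_few_spikes_excluded_with_reason(self, locked_setup):
        _, rec, phases = locked_setup
        train = SpikeTrain("u", [10.0, 20.0, 30.0], rec.duration)
        res = lock_unit(train, phases)
        assert not res.locked and "usable spikes" in res.excluded_reason

    def test_tied_pvalues_break_to_lowest_frequency(self, cosine_recording):
        # one spike per 4 Hz peak: extreme locking at every frequency
        times = np.arange(2, 28, 1.0)
        train = SpikeTrain("u", times, cosine_recording.duration)
        ps = morlet_phase(cosine_recording)
        res = lock_unit(train, ps)
        floor = np.min(res.p_values)
        if np.sum(res.p_values == floor) > 1:
            assert res.best_freq == min(
                f for f, p in zip(res.freqs, res.p_values) if p == floor)


class TestGroupSummary:
    @staticmethod
    def result(angle, locked=True, uid="u"):
        from thetalink.phaselock import UnitLockingResult
        return UnitLockingResult(unit_id=uid, freqs=LOW_THETA_FREQS,
                                 p_values=np.full(5, 0.001 if locked else 0.5),
                                 locked=locked, best_freq=4.0,
                                 preferred_angle_deg=angle,
                                 resultant_length=0.5, n_spikes=100)

    def test_circular_mean_of_locked(self):
        s = group_summary([self.result(0.0), self.result(90.0)])
        assert s.group_preferred_angle_deg == pytest.approx(45.0)
        assert s.n_locked == 2 and s.n_total == 2

    def test_wraparound(self):
        s = group_summary([self.result(-170.0), self.result(170.0)])
        assert s.group_preferred_angle_deg == pytest.approx(180.0)

    def test_no_locked_units(self):
        s = group_summary([self.result(0.0, locked=False)])
        assert s.group_preferred_angle_deg is None and s.n_total == 1


class TestWatsonWilliams:
    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(3)
        rejections = 0
        for _ in range(200):
            a = np.degrees(rng.vonmises(0.0, 2.0, 50))
            b = np.degrees(rng.vonmises(0.0, 2.0, 50))
            rejections += watson_williams(a, b)[1] < 0.05
        assert rejections <= 16  # <= 8% of 200

    def test_power_at_90_degree_offset(self):
        rng = np.random.default_rng(4)
        hits = 0
        for _ in range(100):
            a = np.degrees(rng.vonmises(0.0, 2.0, 30))
            b = np.degrees(rng.vonmises(np.pi / 2, 2.0, 30))
            hits += watson_williams(a, b)[1] < 0.01
        assert hits >= 95

    def test_identical_groups(self):
        a = np.array([10.0, 25.0, 40.0, 55.0, 70.0])
        f, p = watson_williams(a, a)
        assert f == pytest.approx(0.0, abs=1e-9) and p > 0.99


class TestLockedProportionTest:
    def test_fisher_worked_example(self):
        # 1 of 54 fast-spiking vs 10 of 90: printed two-sided p = 0.0531
        _, p = locked_proportion_test(1, 54, 10, 90)
        assert p == pytest.approx(0.0531, abs=5e-5)

    def test_identical_proportions(self):
        _, p = locked_proportion_test(5, 10, 5, 10)
        assert p == pytest.approx(1.0)

    def test_strong_contrast_tables(self):
        assert locked_proportion_test(30, 54, 7, 90)[1] < 1e-4
        assert locked_proportion_test(20, 31, 3, 55)[1] < 1e-4

    def test_matches_hypergeometric_enumeration(self, rng):
        """Oracle: exhaustive enumeration of tables with fixed margins."""
        for _ in range(25):
            na, nb = rng.integers(2, 30), rng.integers(2, 30)
            ka, kb = rng.integers(0, na + 1), rng.integers(0, nb + 1)
            n, big_k = na + nb, ka + kb
            probs = hypergeom.pmf(np.arange(max(0, big_k - nb),
                                            min(big_k, na) + 1), n, big_k, na)
            obs = hypergeom.pmf(ka, n, big_k, na)
            brute = probs[probs <= obs * (1 + 1e-9)].sum()
            _, p = locked_proportion_test(int(ka), int(na), int(kb), int(nb))
            assert p == pytest.approx(min(brute, 1.0), rel=1e-7)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            locked_proportion_test(5, 3, 0, 10)


class TestCircularHelpers:
    def test_resultant_length_limits(self):
        assert resultant_length(np.full(10, 33.0)) == pytest.approx(1.0)
        assert resultant_length(np.array([0.0, 90.0, 180.0, -90.0])) \
            == pytest.approx(0.0, abs=1e-12)

    def test_circular_mean_range(self):
        assert -180 < circular_mean_deg(np.array([179.0, -179.0])) <= 180
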