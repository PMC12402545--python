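"""Spiking-band features: filtering, RMS/NRMS, envelope spectra."""

import numpy as np
import pytest
from scipy import signal

import stnmer as sm
from stnmer.containers import SiteRecording, Trajectory
from stnmer.features import (
    FeatureConfig,
    band_fraction,
    bandpass_spiking,
    beta_timeseries,
    compute_rms,
    envelope_psd,
    featurize_site,
    normalize_rms,
)

FS = 44000.0


def _sine(freq, fs=FS, duration=1.0, amp=1.0):
    t = np.arange(0, duration, 1 / fs)
    return amp * np.sin(2 * np.pi * freq * t)


class TestBandpass:
    def test_in_band_tone_preserved(self):
        x = _sine(1000.0)
        y = bandpass_spiking(x, fs=FS)
        mid = slice(len(x) // 4, 3 * len(x) // 4)
        assert np.max(np.abs(y[mid])) == pytest.approx(1.0, rel=0.01)
        assert y.size == x.size

    def test_out_of_band_tone_attenuated(self):
        # >= 40 dB at 50 Hz, consistent with the squared (zero-phase)
        # analytic response of the designed filter
        x = _sine(50.0)
        y = bandpass_spiking(x, fs=FS)
        mid = slice(len(x) // 4, 3 * len(x) // 4)  # avoid edge transients
        atten_db = 20 * np.log10(np.max(np.abs(y[mid])) / 1.0)
        assert atten_db < -40.0
        sos = signal.butter(2, [300, 6000], btype="bandpass", fs=FS, output="sos")
        _, h = signal.sosfreqz(sos, worN=[50.0], fs=FS)
        analytic_db = 40 * np.log10(np.abs(h[0]))  # doubled: forward-backward
        assert atten_db == pytest.approx(analytic_db, abs=3.0)

    def test_zero_in_zero_out(self):
        assert np.allclose(bandpass_spiking(np.zeros(1000), fs=FS), 0.0)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            bandpass_spiking(np.zeros(100), low=300, high=7000, fs=12500.0)


class TestRms:
    def test_constant(self):
        assert compute_rms(np.full(100, -3.0)) == pytest.approx(3.0)

    def test_sine_closed_form(self):
        x = _sine(100.0, duration=0.5, amp=2.0)  # integer number of periods
        assert compute_rms(x) == pytest.approx(2.0 / np.sqrt(2), abs=1e-6)

    def test_concatenation_invariance(self):
        x = np.random.default_rng(0).standard_normal(500)
        assert compute_rms(np.concatenate([x, x])) == pytest.approx(compute_rms(x))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_rms(np.array([]))


class TestNormalizeRms:
    def test_worked_example(self):
        sites = list(zip(range(7), [2, 2, 2, 2, 2, 4, 6]))
        out = normalize_rms(sites, n_baseline=5)
        assert [v for _, v in out] == pytest.approx([1, 1, 1, 1, 1, 2, 3])

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        rms = rng.uniform(0.5, 3.0, 10)
        a = normalize_rms(list(zip(range(10), rms)))
        b = normalize_rms(list(zip(range(10), 7.3 * rms)))
        assert [v for _, v in a] == pytest.approx([v for _, v in b])

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError):
            normalize_rms([(0, 1.0)] * 4, n_baseline=5)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            normalize_rms([(0, 0.0)] * 6)


class TestEnvelopePsd:
    def test_fractions_sum_to_one(self):
        x = np.random.default_rng(2).standard_normal(int(4 * FS))
        _, fracs = envelope_psd(x, FS)
        assert fracs.sum() == pytest.approx(1.0, abs=1e-6)

    def test_scale_invariance(self):
        x = np.random.default_rng(3).standard_normal(int(4 * FS))
        _, f1 = envelope_psd(x, FS)
        _, f2 = envelope_psd(4.2 * x, FS)
        assert np.allclose(f1, f2, rtol=1e-9)

    def test_bin_resolution(self):
        freqs, _ = envelope_psd(
            np.random.default_rng(4).standard_normal(int(4 * FS)), FS
        )
        assert np.allclose(np.diff(freqs), 1.0 / 3.0)

    def test_modulation_frequency_recovered(self):
        # rate-modulated Poisson spikes: envelope-PSD argmax lands on the
        # modulation frequency (median over seeds, within one 1/3 Hz bin)
        cfg = sm.SimConfig(beta_mod_depth=0.8, beta_freq=20.0)
        errors = []
        for s in range(9):
            rec = sm.simulate_site(0.5, "DLOR", cfg, np.random.default_rng(s))
            filt = bandpass_spiking(rec)
            freqs, fracs = envelope_psd(filt, cfg.sampling_rate)
            sel = (freqs >= 5) & (freqs <= 45)
            errors.append(abs(freqs[sel][np.argmax(fracs[sel])] - 20.0))
        assert np.median(errors) <= 1.0 / 3.0 + 1e-9

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            envelope_psd(np.ones(int(2 * FS)), FS)  # 2 s < one 3 s window


class TestBandFraction:
    def test_point_mass(self):
        freqs = np.arange(0, 301) / 3.0
        fracs = np.zeros_like(freqs)
        fracs[60] = 1.0  # 20 Hz bin
        assert band_fraction(freqs, fracs, (13, 30)) == pytest.approx(1.0)

    def test_uniform_brute_force(self):
        freqs = np.arange(1, 301) / 3.0
        fracs = np.full_like(freqs, 1.0 / freqs.size)
        expected = sum(
            fracs[i] for i in range(freqs.size) if 13 <= freqs[i] < 30
        )
        assert band_fraction(freqs, fracs, (13, 30)) == pytest.approx(expected)

    def test_partition_sums_to_total(self):
        rng = np.random.default_rng(5)
        freqs = np.arange(0, 1501) / 3.0
        fracs = rng.uniform(size=freqs.size)
        fracs /= fracs.sum()
        total = (
            band_fraction(freqs, fracs, (0, 13))
            + band_fraction(freqs, fracs, (13, 30))
            + band_fraction(freqs, fracs, (30, 501))
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError):
            band_fraction(np.array([0.0, 10.0]), np.array([0.5, 0.5]), (2, 3))


class TestBetaTimeseries:
    def test_passband_preserved_stopband_matches_design(self):
        fs = 1000.0
        t = np.arange(0, 8.0, 1 / fs)
        for freq, check in ((20.0, "pass"), (50.0, "stop")):
            x = 2.0 + np.sin(2 * np.pi * freq * t)  # positive: rectify = identity
            y = beta_timeseries(x, fs, envelope_fs=fs)
            amp = np.max(np.abs(y[1000:-1000]))
            sos = signal.butter(2, [13, 30], btype="bandpass", fs=fs, output="sos")
            _, h = signal.sosfreqz(sos, worN=[freq], fs=fs)
            expected = np.abs(h[0]) ** 2  # forward-backward
            if check == "pass":
                assert amp == pytest.approx(1.0, rel=0.1)
            assert amp == pytest.approx(expected, rel=0.1)

    def test_zero_in_zero_out(self):
        assert np.allclose(beta_timeseries(np.zeros(5000), 1000.0, envelope_fs=1000.0), 0.0)


class TestFeaturizeTrajectory:
    def test_identical_sites_have_unit_nrms(self, compact_pd_cfg):
        rec = sm.simulate_site(8.0, "PRE", compact_pd_cfg, np.random.default_rng(0))
        sites = [
            SiteRecording(depth=10.0 - 0.1 * i, sampling_rate=rec.sampling_rate,
                          samples=rec.samples.copy())
            for i in range(8)
        ]
        prof = sm.featurize_trajectory(Trajectory(sites=sites))
        assert prof.nrms == pytest.approx(np.ones(8))

    def test_baseline_mean_nrms_is_one(self, pd_profile):
        cfg = FeatureConfig()
        assert np.mean(pd_profile.nrms[: cfg.n_baseline]) == pytest.approx(1.0, abs=1e-9)

    def test_psd_rows_sum_to_one(self, pd_profile):
        assert pd_profile.psd_matrix.sum(axis=1) == pytest.approx(
            np.ones(len(pd_profile)), abs=1e-6
        )

    def test_dlor_beta_exceeds_pre_beta(self, pd_sim, pd_profile):
        _, gt = pd_sim
        beta = pd_profile.band("beta")
        dlor = np.array([l == "DLOR" for l in gt.labels])
        pre = np.array([l == "PRE" for l in gt.labels])
        assert beta[dlor].mean() > beta[pre].mean()

    def test_batch_path_matches_per_site_reference(self, pd_sim):
        traj, _ = pd_sim
        cfg = FeatureConfig()
        prof = sm.featurize_trajectory(traj, cfg)
        for i in (0, len(traj) // 2, len(traj) - 1):
            ref = featurize_site(traj.sites[i], cfg)
            assert prof.sites[i].rms == pytest.approx(ref.rms, rel=1e-10)
            assert np.allclose(
                prof.sites[i].psd_fractions, ref.psd_fractions, rtol=1e-8, atol=1e-12
            )

    def test_amplitude_scale_invariance(self, pd_sim, pd_profile):
        traj, _ = pd_sim
        scaled = Trajectory(
            sites=[
                SiteRecording(depth=s.depth, sampling_rate=s.sampling_rate,
                              samples=3.7 * s.samples)
                for s in traj.sites
            ],
            trajectory_id=traj.trajectory_id,
        )
        prof2 = sm.featurize_trajectory(scaled)
        assert np.allclose(prof2.nrms, pd_profile.nrms, rtol=1e-9)
        assert np.allclose(prof2.psd_matrix, pd_profile.psd_matrix, rtol=1e-7, atol=1e-12)
        for band in ("beta", "theta", "gamma"):
            assert np.allclose(prof2.band(band), pd_profile.band(band), rtol=1e-7)

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            Trajectory(sites=[])
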