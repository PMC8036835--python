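"""Range-FFT, subject detection, displacement recovery, and rate estimation."""

import dataclasses

import numpy as np
import pytest

import radarvitals as rv
from radarvitals.errors import ConfigurationError, NoMotionDetected, ShapeError
from radarvitals.vitals_extraction import _out_of_band_residual


def breathing_echo(cfg, distance, amplitude, freq_hz, duration, attenuation=1.0):
    fps = cfg.frames_per_second
    t = np.arange(int(round(duration * fps))) / fps
    return rv.TargetEcho(distance + amplitude * np.sin(2 * np.pi * freq_hz * t),
                         attenuation=attenuation)


def brute_force_subject_bin(rpm):
    """Independent exhaustive scan: slow-time variance of the complex series per bin."""
    best, best_var = None, -1.0
    for b in range(rpm.n_bins):
        series = rpm.profiles[:, b]
        var = float(np.mean(np.abs(series - series.mean()) ** 2))
        if var > best_var + 0.0:  # strict improvement keeps the nearer bin on ties
            best, best_var = b, var
    return best


class TestRangeFFT:
    def test_static_target_bin(self, table2):
        cube = rv.synthesize_if_cube([rv.TargetEcho.static(1.0, 20)], table2, 1.0)
        rpm = rv.range_fft(cube)
        assert int(np.abs(rpm.profiles).mean(axis=0).argmax()) == 25

    def test_zero_cube_gives_zero_matrix(self, table2):
        cube = rv.synthesize_if_cube([], table2, 1.0)
        assert np.all(rv.range_fft(cube).profiles == 0)

    def test_two_targets_two_peaks(self, table2):
        echoes = [rv.TargetEcho.static(0.6, 20), rv.TargetEcho.static(2.0, 20)]
        rpm = rv.range_fft(rv.synthesize_if_cube(echoes, table2, 1.0))
        mag = np.abs(rpm.profiles).mean(axis=0)
        top2 = sorted(np.argsort(mag)[-2:].tolist())
        assert top2 == [15, 50]

    def test_rejects_bad_rx_index(self, table2):
        cube = rv.synthesize_if_cube([], table2, 1.0)
        with pytest.raises(ShapeError):
            rv.range_fft(cube, rx_index=4)


class TestSubjectDetection:
    def test_variance_beats_strong_static_clutter(self, table2):
        """A 10x stronger static reflector at 0.4 m must not mask the breather at 1 m."""
        echoes = [
            breathing_echo(table2, 1.0, 4e-3, 0.3, 10.0, attenuation=0.1),
            rv.TargetEcho.static(0.4, 200, attenuation=1.0),
        ]
        cfg = dataclasses.replace(table2, tx_power=10.0)
        rpm = rv.range_fft(rv.synthesize_if_cube(echoes, cfg, 10.0))
        assert rv.detect_subject_bin(rpm) == 25

    def test_single_moving_target(self, table2):
        rpm = rv.range_fft(rv.synthesize_if_cube(
            [breathing_echo(table2, 2.0, 4e-3, 0.3, 10.0)], table2, 10.0))
        assert rv.detect_subject_bin(rpm) == 50

    def test_constant_matrix_raises(self, table2):
        cube = rv.synthesize_if_cube([rv.TargetEcho.static(1.0, 40)], table2, 2.0)
        with pytest.raises(NoMotionDetected):
            rv.detect_subject_bin(rv.range_fft(cube))

    def test_zero_cube_raises(self, table2):
        with pytest.raises(NoMotionDetected):
            rv.detect_subject_bin(rv.range_fft(rv.synthesize_if_cube([], table2, 1.0)))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_variance_scan(self, vital_cfg, seed):
        """Implementation equals the brute-force per-bin variance scan."""
        rng = np.random.default_rng(seed)
        d0 = rng.uniform(0.5, 8.0)
        echoes = [breathing_echo(vital_cfg, d0, rng.uniform(1e-3, 6e-3),
                                 rng.uniform(0.15, 0.6), 3.0)]
        if rng.random() < 0.5:
            echoes.append(rv.TargetEcho.static(rng.uniform(0.2, 9.0), 60))
        cube = rv.synthesize_if_cube(echoes, vital_cfg, 3.0,
                                     noise_std=rng.uniform(0, 0.3), seed=seed)
        rpm = rv.range_fft(cube)
        assert rv.detect_subject_bin(rpm) == brute_force_subject_bin(rpm)


class TestDisplacement:
    def test_recovers_one_millimeter_amplitude(self, table2):
        rpm = rv.range_fft(rv.synthesize_if_cube(
            [breathing_echo(table2, 1.0, 1e-3, 0.3, 30.0)], table2, 30.0))
        disp = rv.extract_displacement(rpm, rv.detect_subject_bin(rpm))
        assert np.ptp(disp) / 2 == pytest.approx(1e-3, rel=0.05)

    def test_static_target_gives_zero_sequence(self, table2):
        rpm = rv.range_fft(rv.synthesize_if_cube(
            [rv.TargetEcho.static(1.0, 40)], table2, 2.0))
        disp = rv.extract_displacement(rpm, 25)
        assert np.allclose(disp, 0.0, atol=1e-12)

    def test_unwrapping_handles_amplitude_beyond_quarter_wavelength(self, table2):
        """3 mm swing (> lambda/4 ~ 1.24 mm) survives phase unwrapping."""
        rpm = rv.range_fft(rv.synthesize_if_cube(
            [breathing_echo(table2, 1.0, 3e-3, 0.3, 30.0)], table2, 30.0))
        disp = rv.extract_displacement(rpm, rv.detect_subject_bin(rpm))
        assert np.ptp(disp) == pytest.approx(6e-3, rel=0.05)


class TestBandpass:
    def test_passband_tone_preserved(self):
        t = np.arange(1200) / 20.0
        x = np.sin(2 * np.pi * 0.3 * t)
        y = rv.bandpass(x, (0.1, 0.7), 20.0)
        assert np.ptp(y[200:-200]) / 2 == pytest.approx(1.0, rel=0.05)

    def test_stopband_tone_attenuated_20db(self):
        t = np.arange(1200) / 20.0
        x = np.sin(2 * np.pi * 1.5 * t)
        y = rv.bandpass(x, (0.1, 0.7), 20.0)
        assert np.sqrt(np.mean(y[200:-200] ** 2)) < 10 ** (-20 / 20) / np.sqrt(2)

    def test_zero_in_zero_out(self):
        assert np.allclose(rv.bandpass(np.zeros(500), (0.1, 0.7), 20.0), 0.0)

    def test_rejects_band_outside_nyquist(self):
        with pytest.raises(ConfigurationError):
            rv.bandpass(np.zeros(100), (0.9, 11.0), 20.0)


class TestRateEstimation:
    @pytest.mark.parametrize("freq,band,expected", [
        (0.3, (0.1, 0.7), 18.0),
        (1.5, (0.9, 3.0), 90.0),
    ])
    def test_pure_tone_rates(self, freq, band, expected):
        t = np.arange(1200) / 20.0
        _, bpm = rv.estimate_rate(np.sin(2 * np.pi * freq * t), 20.0, band)
        assert np.all(np.abs(bpm - expected) <= 0.5)

    def test_two_tone_after_band_separation(self):
        t = np.arange(1200) / 20.0
        x = 4e-3 * np.sin(2 * np.pi * 0.3 * t) + 3e-4 * np.sin(2 * np.pi * 1.5 * t)
        _, br = rv.estimate_rate(rv.bandpass(x, (0.1, 0.7), 20.0), 20.0, (0.1, 0.7))
        _, hr = rv.estimate_rate(rv.bandpass(x, (0.9, 3.0), 20.0), 20.0, (0.9, 3.0))
        assert np.nanmean(br) == pytest.approx(18.0, abs=1.0)
        assert np.nanmean(hr) == pytest.approx(90.0, abs=1.0)

    def test_window_longer_than_signal_raises(self):
        with pytest.raises(ConfigurationError):
            rv.estimate_rate(np.zeros(100), 20.0, (0.1, 0.7))  # 5 s < 15 s window


class TestMovementIndex:
    lam = 4.979e-3

    def trace(self, events, duration=60.0):
        prof = rv.VitalProfile(breathing_rate=18, heart_rate=90,
                               baseline_distance=1.0, movement_events=events)
        d = rv.generate_chest_motion(prof, duration, 20.0).displacement
        return d - d.mean()

    def test_pure_vitals_near_zero(self):
        _, idx = rv.movement_index(self.trace([]), 20.0, carrier_wavelength=self.lam)
        assert np.all(idx < 0.1)

    def test_peak_localizes_injected_event(self):
        t, idx = rv.movement_index(self.trace([(10.0, 1.0, 0.02)]), 20.0,
                                   carrier_wavelength=self.lam)
        center = t[int(np.argmax(idx))]
        assert abs(center - 10.5) <= 7.5  # argmax window contains the event

    def test_peak_monotone_in_amplitude(self):
        peaks = []
        for amp in (0.01, 0.02, 0.04):
            _, idx = rv.movement_index(self.trace([(30.0, 1.0, amp)]), 20.0,
                                       carrier_wavelength=self.lam)
            peaks.append(idx.max())
        assert peaks[0] < peaks[1] < peaks[2]


class TestEndToEnd:
    def make_estimate(self, cfg, br, hr, duration=60.0, noise_std=0.0, seed=0,
                      events=()):
        prof = rv.VitalProfile(breathing_rate=br, heart_rate=hr,
                               baseline_distance=1.0, movement_events=list(events))
        motion = rv.generate_chest_motion(prof, duration, cfg.frames_per_second)
        cube = rv.synthesize_if_cube([rv.TargetEcho(motion.displacement)], cfg,
                                     duration, noise_std=noise_std, seed=seed)
        return rv.extract_vitals(cube)

    def test_noiseless_child_rates(self, vital_cfg):
        est = self.make_estimate(vital_cfg, 18, 90)
        assert np.nanmean(est.br) == pytest.approx(18.0, abs=1.0)
        assert np.nanmean(est.hr) == pytest.approx(90.0, abs=1.0)
        assert est.valid.all()

    def test_zero_cube_raises_no_motion(self, vital_cfg):
        with pytest.raises(NoMotionDetected):
            rv.extract_vitals(rv.synthesize_if_cube([], vital_cfg, 20.0))

    def test_rate_invariant_to_amplitude_scaling(self, vital_cfg):
        """The chain is phase-based: scaling the cube leaves rates unchanged."""
        est1 = self.make_estimate(vital_cfg, 24, 120)
        cfg10 = dataclasses.replace(vital_cfg, tx_power=10.0)
        est2 = self.make_estimate(cfg10, 24, 120)
        assert np.allclose(est1.hr, est2.hr, atol=1e-6, equal_nan=True)
        assert np.allclose(est1.br, est2.br, atol=1e-6, equal_nan=True)

    def test_movement_windows_flagged_invalid(self, vital_cfg):
        """Flagged windows coincide with the injected event (Jaccard >= 0.8)."""
        est = self.make_estimate(vital_cfg, 18, 90, events=[(30.0, 1.0, 0.02)])
        half = 7.5
        overlaps = (est.times - half < 31.0) & (est.times + half > 30.0)
        flagged = ~est.valid
        jaccard = (overlaps & flagged).sum() / (overlaps | flagged).sum()
        assert jaccard >= 0.8
        assert np.all(np.isnan(est.hr[flagged]))

    def test_grid_recovery_noiseless(self, vital_cfg):
        """4x4 BR/HR grid recovered within 1 bpm in every cell (noiseless)."""
        for br in (12, 18, 24, 36):
            for hr in (70, 100, 130, 160):
                est = self.make_estimate(vital_cfg, br, hr)
                assert np.nanmean(est.br) == pytest.approx(br, abs=1.0), (br, hr)
                assert np.nanmean(est.hr) == pytest.approx(hr, abs=1.0), (br, hr)
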