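import numpy as np
import pytest
import scipy.signal as sps

from phm._quat import angle_between, from_axis_angle, rotate_inv
from phm.preprocessing import (
    BesselSpec,
    bessel_lowpass,
    denoise_gyro,
    estimate_calibration,
    fit_mag_sphere,
    fuse_orientation,
)
from phm.synthetic import (
    EARTH_FIELD_DIR,
    GRAVITY_DIR,
    ActivityProfile,
    ActivitySchedule,
    Segment,
    SensorConfig,
    generate_recording,
)


def _still_recording(cfg, seed=0, seconds=20.0):
    prof = {"rest": ActivityProfile(regime="static")}
    sch = ActivitySchedule((Segment("rest", seconds, "static"),))
    return generate_recording(sch, cfg, seed, profiles=prof, subject_jitter=0.0)


class TestCalibration:
    def test_accel_bias_recovery(self):
        cfg = SensorConfig(accel_bias=(0.3, -0.2, 0.1))
        imu, _, _ = _still_recording(cfg, seed=4)
        cal = estimate_calibration(imu, (0.0, 10.0))
        n = 1000
        tol = 3 * cfg.noise_sd["acc"] / np.sqrt(n)
        assert np.all(np.abs(cal.accel_bias - (0.3, -0.2, 0.1)) < 10 * tol)

    def test_zero_noise_zero_bias(self):
        cfg = SensorConfig(
            accel_bias=(0, 0, 0), gyro_bias=(0, 0, 0), gyro_drift_rate=0.0,
            mag_hard_iron=(0, 0, 0),
            noise_sd={k: 0.0 for k in ("acc", "gyro", "mag", "emg", "ecg")},
        )
        imu, _, _ = _still_recording(cfg)
        cal = estimate_calibration(imu, (0.0, 10.0))
        assert np.all(np.abs(cal.accel_bias) < 1e-9)
        assert np.all(np.abs(cal.gyro_bias) < 1e-9)
        assert np.all(np.abs(cal.mag_offset) < 1e-9)

    def test_sphere_fit_oracle(self, rng):
        v = rng.normal(size=(500, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        center, radius = fit_mag_sphere(50.0 * v + np.array([5.0, 5.0, 5.0]))
        assert np.all(np.abs(center - 5.0) < 0.1)
        assert abs(radius - 50.0) < 0.1

    def test_short_interval_rejected(self):
        imu, _, _ = _still_recording(SensorConfig())
        with pytest.raises(ValueError, match="10 samples"):
            estimate_calibration(imu, (0.0, 0.05))

    def test_median_recovery_over_seeded_configs(self):
        """Median bias error < 5% of bias magnitude over many configs."""
        acc_err, gyro_err, mag_err = [], [], []
        for seed in range(50):
            r = np.random.default_rng(seed + 1000)
            ab = r.uniform(-0.5, 0.5, 3)
            gb = r.uniform(-0.05, 0.05, 3)
            mh = r.uniform(-10, 10, 3)
            cfg = SensorConfig(accel_bias=tuple(ab), gyro_bias=tuple(gb),
                               mag_hard_iron=tuple(mh))
            imu, _, _ = _still_recording(cfg, seed=seed, seconds=10.0)
            cal = estimate_calibration(imu, (0.0, 10.0))
            acc_err.append(np.linalg.norm(cal.accel_bias - ab) / np.linalg.norm(ab))
            gyro_err.append(np.linalg.norm(cal.gyro_bias - gb) / np.linalg.norm(gb))
            mag_err.append(np.linalg.norm(cal.mag_offset - mh))
        assert np.median(acc_err) < 0.05
        assert np.median(gyro_err) < 0.05
        assert np.median(mag_err) < 0.5


class TestDenoise:
    def test_noise_reduction_on_sine(self, rng):
        t = np.arange(1024) / 100.0
        clean = np.sin(2 * np.pi * t)
        noisy = clean + rng.normal(0, 0.2, len(t))
        den = denoise_gyro(noisy)
        assert len(den) == len(noisy)
        rmse = lambda x: np.sqrt(np.mean((x - clean) ** 2))
        assert rmse(den) < rmse(noisy)

    def test_zero_in_zero_out(self):
        assert np.allclose(denoise_gyro(np.zeros(256)), 0.0)

    def test_noise_free_smooth_passthrough(self):
        t = np.arange(512) / 100.0
        x = np.sin(2 * np.pi * 0.5 * t)
        out = denoise_gyro(x)
        assert np.sqrt(np.mean((out - x) ** 2)) < 0.05 * np.sqrt(np.mean(x**2))

    def test_idempotent_ish(self, rng):
        t = np.arange(1024) / 100.0
        noisy = np.sin(2 * np.pi * t) + rng.normal(0, 0.2, len(t))
        once = denoise_gyro(noisy)
        twice = denoise_gyro(once)
        first_change = np.sqrt(np.mean((once - noisy) ** 2))
        second_change = np.sqrt(np.mean((twice - once) ** 2))
        assert second_change < 0.10 * first_change

    def test_unknown_wavelet_rejected(self):
        with pytest.raises(ValueError, match="wavelet"):
            denoise_gyro(np.zeros(64), wavelet="not_a_wavelet")


class TestOrientation:
    def test_motionless_identity(self):
        n, g, b = 500, 9.81, 50.0
        acc = np.tile(g * GRAVITY_DIR, (n, 1))
        mag = np.tile(b * EARTH_FIELD_DIR, (n, 1))
        gyro = np.zeros((n, 3))
        o = fuse_orientation(acc, gyro, mag, 100.0)
        err = np.degrees(angle_between(o.quaternions, np.array([1.0, 0, 0, 0])))
        assert err.max() < 0.1

    def test_constant_rate_rotation_tracked(self):
        rate, wz, n = 100.0, 0.5, 1000
        t = np.arange(n) / rate
        q_true = from_axis_angle(np.array([0.0, 0, 1]), wz * t)
        acc = rotate_inv(q_true, np.broadcast_to(9.81 * GRAVITY_DIR, (n, 3)))
        mag = rotate_inv(q_true, np.broadcast_to(50 * EARTH_FIELD_DIR, (n, 3)))
        gyro = np.tile([0.0, 0, wz], (n, 1))
        o = fuse_orientation(acc, gyro, mag, rate, beta=0.1)
        err = np.degrees(angle_between(o.quaternions, q_true))
        assert err[n // 2 :].mean() < 2.0

    def test_unit_norm_and_zero_acc_skipped(self):
        n = 200
        acc = np.tile(9.81 * GRAVITY_DIR, (n, 1))
        acc[50] = 0.0  # dropped sample
        mag = np.tile(50 * EARTH_FIELD_DIR, (n, 1))
        o = fuse_orientation(acc, np.zeros((n, 3)), mag, 100.0)
        assert np.all(np.abs(np.linalg.norm(o.quaternions, axis=1) - 1) < 1e-9)
        assert 50 in o.skipped

    def test_negative_beta_rejected(self):
        z = np.zeros((20, 3))
        with pytest.raises(ValueError):
            fuse_orientation(z, z, z, 100.0, beta=-0.1)


class TestBessel:
    def test_unity_dc_gain(self):
        x = np.full(500, 3.3)
        y = bessel_lowpass(x, BesselSpec(4, 20.0), 250.0)
        assert abs(y[-1] - 3.3) < 1e-6

    def test_order1_gain_at_cutoff(self):
        """θ1(t) = t + 1 ⇒ prototype gain 1/|1+j| = 0.7071 at ω0."""
        b, a = sps.bessel(1, 5.0, "low", fs=100.0, norm="phase")
        _, h = sps.freqz(b, a, worN=[5.0], fs=100.0)
        assert abs(abs(h[0]) - 1 / np.sqrt(2)) < 1e-6

    def test_stopband_attenuation(self, rng):
        rate = 250.0
        x = rng.normal(0, 1, 2**14)
        y = bessel_lowpass(x, BesselSpec(4, 5.0), rate)
        f, pxx = sps.periodogram(x, rate)
        _, pyy = sps.periodogram(y, rate)
        hi = f > 25.0
        atten_db = 10 * np.log10(pxx[hi].mean() / pyy[hi].mean())
        assert atten_db >= 20.0

    def test_monotone_magnitude_response(self):
        for order in (1, 2, 4, 6):
            b, a = sps.bessel(order, 20.0, "low", fs=250.0, norm="phase")
            _, h = sps.freqz(b, a, worN=512, fs=250.0)
            mag = np.abs(h)
            assert np.all(np.diff(mag) <= 1e-8)

    def test_zero_phase_mode_on_tone(self):
        rate, f0 = 250.0, 10.0
        t = np.arange(2048) / rate
        x = np.sin(2 * np.pi * f0 * t)
        y = bessel_lowpass(x, BesselSpec(4, 40.0), rate, zero_phase=True)
        # projection phase of the filtered tone equals the input phase
        # (60 whole periods so leakage does not bias the estimate)
        core = slice(200, 200 + 1500)
        num = np.sum(y[core] * np.cos(2 * np.pi * f0 * t[core]))
        den = np.sum(y[core] * np.sin(2 * np.pi * f0 * t[core]))
        phase = np.arctan2(num, den)
        assert abs(phase) < 1e-3

    def test_group_delay_flatter_than_butterworth(self):
        rate, fc, order = 250.0, 20.0, 4
        bb, ab = sps.bessel(order, fc, "low", fs=rate, norm="phase")
        bu, au = sps.butter(order, fc, "low", fs=rate)
        w = np.linspace(0.5, fc / 2, 64)
        _, gd_bessel = sps.group_delay((bb, ab), w=w, fs=rate)
        _, gd_butter = sps.group_delay((bu, au), w=w, fs=rate)
        flatness = lambda gd: np.ptp(gd) / np.mean(gd)
        assert flatness(gd_bessel) < flatness(gd_butter)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bessel_lowpass(np.zeros(100), BesselSpec(4, 200.0), 250.0)


def test_quaternion_norm_on_real_corpus(processed_seed0):
    _, _, orient, _, _ = processed_seed0
    assert np.all(np.abs(np.linalg.norm(orient.quaternions, axis=1) - 1) < 1e-9)
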