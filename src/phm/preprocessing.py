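"""Noise reduction: three-phase calibration-based IMU filtering and a Bessel
low-pass for physiological channels.

The IMU path has three phases:

1. *Calibration* — per-axis accelerometer bias (gravity reference on a
   designated still interval), gyroscope bias (still-interval mean) and
   magnetometer hard-iron offset (earth-field reference, or a least-squares
   sphere fit when the recording covers enough orientations).
2. *Error correction* — per-axis discrete-wavelet-transform shrinkage of the
   gyroscope (soft thresholding at the universal threshold, with the noise
   scale taken from the median absolute deviation of the finest detail
   coefficients).
3. *Mapping & optimization* — quaternion orientation tracking: gyroscope
   kinematics integration with one gradient-descent correction step per
   sample against the measured gravity/magnetic field directions (step gain
   β), which bounds gyroscope drift.

Physiological channels receive only the Bessel low-pass (maximally flat
group delay; the analog prototype is the ratio of reverse Bessel polynomials
θ_n(0)/θ_n(s/ω0), discretized by the bilinear transform with cutoff
pre-warping).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pywt
from numba import njit
from scipy import signal as sps

from ._quat import enforce_sign_convention
from .synthetic import EARTH_FIELD_DIR, GRAVITY_DIR, RawRecording

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Phase 1: calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationEstimate:
    """Recovered sensor calibration (biases in sensor units, scales unitless)."""

    accel_bias: np.ndarray
    accel_scale: np.ndarray
    gyro_bias: np.ndarray
    mag_offset: np.ndarray
    mag_scale: np.ndarray

    def to_dict(self) -> dict:
        return {k: np.asarray(v).tolist() for k, v in self.__dict__.items()}


def fit_mag_sphere(samples: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares sphere fit ``|m - c| = r`` on magnetometer samples.

    Solves the linear system of the algebraic sphere fit; requires samples
    spread over enough of the sphere to condition the normal equations.
    Returns (center, radius).
    """
    m = np.asarray(samples, float)
    A = np.column_stack([2 * m, np.ones(len(m))])
    b = np.sum(m**2, axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    radius = np.sqrt(sol[3] + np.sum(center**2))
    return center, float(radius)


def estimate_calibration(
    rec: RawRecording,
    still_interval: tuple[float, float],
    gravity: float = 9.81,
    earth_field: float = 50.0,
    sphere_fit: bool = False,
) -> CalibrationEstimate:
    """Estimate sensor biases from a motionless reference interval.

    The still interval is assumed motionless in the reference pose (gravity
    along +z, the nominal earth-field direction in the sensor frame), so the
    accelerometer bias is the still-interval mean minus the gravity vector
    and the magnetometer offset the mean minus the nominal field.  With
    ``sphere_fit=True`` the magnetometer offset instead comes from a
    least-squares sphere fit over the whole recording — preferable when the
    recording sweeps a wide range of orientations.
    """
    t0, t1 = still_interval
    mask = (rec.timestamps >= t0) & (rec.timestamps <= t1)
    if mask.sum() < 10:
        raise ValueError("still interval must contain at least 10 samples")

    acc = rec.by_kind("acc")[mask]
    acc_mean = acc.mean(axis=0)
    accel_bias = acc_mean - gravity * GRAVITY_DIR
    # with per-axis offsets removed the still mean sits on the gravity sphere
    resid = np.linalg.norm(acc_mean - accel_bias)
    accel_scale = np.full(3, gravity / resid if resid > 0 else 1.0)

    gyro_bias = rec.by_kind("gyro")[mask].mean(axis=0)

    mag = rec.by_kind("mag")
    if sphere_fit:
        mag_offset, radius = fit_mag_sphere(mag)
    else:
        mag_offset = mag[mask].mean(axis=0) - earth_field * EARTH_FIELD_DIR
        radius = np.linalg.norm(mag[mask].mean(axis=0) - mag_offset)
    mag_scale = np.full(3, earth_field / radius if radius > 0 else 1.0)

    return CalibrationEstimate(accel_bias, accel_scale, gyro_bias, mag_offset, mag_scale)


def apply_calibration(rec: RawRecording, cal: CalibrationEstimate) -> RawRecording:
    """Return a copy of ``rec`` with biases removed and scales applied."""
    out = rec.channels.copy()
    for i, (_, kind, _) in enumerate(rec.channel_meta):
        axis = i % 3
        if kind == "acc":
            out[:, i] = (out[:, i] - cal.accel_bias[axis]) * cal.accel_scale[axis]
        elif kind == "gyro":
            out[:, i] = out[:, i] - cal.gyro_bias[axis]
        elif kind == "mag":
            out[:, i] = (out[:, i] - cal.mag_offset[axis]) * cal.mag_scale[axis]
    return RawRecording(rec.timestamps, out, list(rec.channel_meta), rec.labels)


# ---------------------------------------------------------------------------
# Phase 2: wavelet gyro denoising
# ---------------------------------------------------------------------------

def denoise_gyro(
    gyro: np.ndarray, wavelet: str = "db4", level: int = 3
) -> np.ndarray:
    """Per-axis DWT soft-threshold shrinkage at the universal threshold.

    σ is estimated per axis from the median absolute deviation of the finest
    detail coefficients (MAD/0.6745); the threshold is σ√(2 ln N).  Output
    length equals input length.
    """
    if wavelet not in pywt.wavelist(kind="discrete"):
        raise ValueError(f"unsupported wavelet {wavelet!r}")
    x = np.atleast_2d(np.asarray(gyro, float).T).T  # (n,) -> (n,1)
    squeeze = np.asarray(gyro).ndim == 1
    n = x.shape[0]
    if n < 2**level:
        raise ValueError(f"series length {n} < 2^level = {2**level}")
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        coeffs = pywt.wavedec(x[:, j], wavelet, level=level)
        sigma = np.median(np.abs(coeffs[-1])) / 0.6745
        uth = sigma * np.sqrt(2.0 * np.log(n))
        if uth > 0:
            coeffs = [coeffs[0]] + [
                pywt.threshold(c, uth, mode="soft") for c in coeffs[1:]
            ]
        out[:, j] = pywt.waverec(coeffs, wavelet)[:n]
    return out[:, 0] if squeeze else out


# ---------------------------------------------------------------------------
# Phase 3: gradient-descent orientation filter
# ---------------------------------------------------------------------------

@dataclass
class OrientationSeries:
    """Unit quaternion trajectory (scalar-first, body-to-world)."""

    timestamps: np.ndarray
    quaternions: np.ndarray
    skipped: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self):
        norms = np.linalg.norm(self.quaternions, axis=-1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("quaternions must be unit norm within 1e-9")


@njit(cache=True)
def _madgwick_marg(acc, gyro, mag, dt, beta, q0):  # pragma: no cover - jit
    n = acc.shape[0]
    q = np.empty((n, 4))
    skipped = np.zeros(n, np.bool_)
    w, x, y, z = q0[0], q0[1], q0[2], q0[3]
    for i in range(n):
        gx, gy, gz = gyro[i, 0], gyro[i, 1], gyro[i, 2]
        # quaternion kinematics from the gyroscope
        qdw = 0.5 * (-x * gx - y * gy - z * gz)
        qdx = 0.5 * (w * gx + y * gz - z * gy)
        qdy = 0.5 * (w * gy - x * gz + z * gx)
        qdz = 0.5 * (w * gz + x * gy - y * gx)

        an = np.sqrt(acc[i, 0] ** 2 + acc[i, 1] ** 2 + acc[i, 2] ** 2)
        mn = np.sqrt(mag[i, 0] ** 2 + mag[i, 1] ** 2 + mag[i, 2] ** 2)
        if an > 1e-12 and mn > 1e-12:
            ax, ay, az = acc[i, 0] / an, acc[i, 1] / an, acc[i, 2] / an
            mx, my, mz = mag[i, 0] / mn, mag[i, 1] / mn, mag[i, 2] / mn

            # reference magnetic field in the world frame (x-z plane)
            hx = (
                mx * (w * w + x * x - y * y - z * z)
                + 2 * my * (x * y - w * z)
                + 2 * mz * (x * z + w * y)
            )
            hy = (
                2 * mx * (x * y + w * z)
                + my * (w * w - x * x + y * y - z * z)
                + 2 * mz * (y * z - w * x)
            )
            hz = (
                2 * mx * (x * z - w * y)
                + 2 * my * (y * z + w * x)
                + mz * (w * w - x * x - y * y + z * z)
            )
            bx = np.sqrt(hx * hx + hy * hy)
            bz = hz

            # objective: predicted body-frame gravity/field minus measurements
            f1 = 2 * (x * z - w * y) - ax
            f2 = 2 * (w * x + y * z) - ay
            f3 = (w * w - x * x - y * y + z * z) - az
            f4 = bx * (w * w + x * x - y * y - z * z) + 2 * bz * (x * z - w * y) - mx
            f5 = 2 * bx * (x * y - w * z) + 2 * bz * (w * x + y * z) - my
            f6 = 2 * bx * (x * z + w * y) + bz * (w * w - x * x - y * y + z * z) - mz

            # gradient = J^T f for the objective above
            gw = (
                -2 * y * f1 + 2 * x * f2 + 2 * w * f3
                + (2 * bx * w - 2 * bz * y) * f4
                + (-2 * bx * z + 2 * bz * x) * f5
                + (2 * bx * y + 2 * bz * w) * f6
            )
            gxx = (
                2 * z * f1 + 2 * w * f2 - 2 * x * f3
                + (2 * bx * x + 2 * bz * z) * f4
                + (2 * bx * y + 2 * bz * w) * f5
                + (2 * bx * z - 2 * bz * x) * f6
            )
            gyy = (
                -2 * w * f1 + 2 * z * f2 - 2 * y * f3
                + (-2 * bx * y - 2 * bz * w) * f4
                + (2 * bx * x + 2 * bz * z) * f5
                + (2 * bx * w - 2 * bz * y) * f6
            )
            gzz = (
                2 * x * f1 + 2 * y * f2 + 2 * z * f3
                + (-2 * bx * z + 2 * bz * x) * f4
                + (-2 * bx * w + 2 * bz * y) * f5
                + (2 * bx * x + 2 * bz * z) * f6
            )
            gnorm = np.sqrt(gw * gw + gxx * gxx + gyy * gyy + gzz * gzz)
            if gnorm > 1e-12:
                qdw -= beta * gw / gnorm
                qdx -= beta * gxx / gnorm
                qdy -= beta * gyy / gnorm
                qdz -= beta * gzz / gnorm
        else:
            skipped[i] = True

        w += qdw * dt
        x += qdx * dt
        y += qdy * dt
        z += qdz * dt
        norm = np.sqrt(w * w + x * x + y * y + z * z)
        w, x, y, z = w / norm, x / norm, y / norm, z / norm
        q[i, 0], q[i, 1], q[i, 2], q[i, 3] = w, x, y, z
    return q, skipped


def fuse_orientation(
    acc: np.ndarray,
    gyro: np.ndarray,
    mag: np.ndarray,
    rate: float,
    beta: float = 0.1,
    q0: np.ndarray | None = None,
    timestamps: np.ndarray | None = None,
) -> OrientationSeries:
    """Track orientation by gyro integration + gradient-descent correction.

    Per sample the quaternion kinematics are integrated from the (calibrated,
    denoised) gyroscope and corrected by one normalized gradient step of gain
    ``beta`` on ‖predicted field directions − measured acc/mag‖².  Samples
    with a zero-norm accelerometer or magnetometer are integrated without
    correction and reported in ``skipped``.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    acc = np.ascontiguousarray(acc, float)
    gyro = np.ascontiguousarray(gyro, float)
    mag = np.ascontiguousarray(mag, float)
    if not (acc.shape == gyro.shape == mag.shape):
        raise ValueError("acc, gyro, mag must be equal-shaped (n, 3) arrays")
    q0 = np.array([1.0, 0.0, 0.0, 0.0]) if q0 is None else np.asarray(q0, float)
    q0 = q0 / np.linalg.norm(q0)
    if q0[0] < 0:
        q0 = -q0
    q, skipped = _madgwick_marg(acc, gyro, mag, 1.0 / rate, beta, q0)
    q = enforce_sign_convention(q / np.linalg.norm(q, axis=1, keepdims=True))
    idx = np.flatnonzero(skipped)
    if idx.size:
        log.warning("orientation correction skipped for %d zero-norm samples", idx.size)
    t = timestamps if timestamps is not None else np.arange(len(q)) / rate
    return OrientationSeries(np.asarray(t, float), q, idx)


# ---------------------------------------------------------------------------
# Bessel low-pass for physiological channels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BesselSpec:
    """Low-pass Bessel filter: order ``n`` ≥ 1 and cutoff ``omega0`` (Hz)."""

    order: int = 4
    cutoff: float = 40.0

    def __post_init__(self):
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")


#: Default cutoffs (Hz) per physiological channel kind.
BESSEL_CUTOFFS = {"emg": 20.0, "ecg": 40.0, "hr": 5.0}


def bessel_lowpass(
    x: np.ndarray,
    spec: BesselSpec,
    rate: float,
    zero_phase: bool = False,
) -> np.ndarray:
    """Apply the Bessel low-pass (phase-normalized prototype, bilinear
    transform with cutoff pre-warping).  DC gain is exactly unity;
    ``zero_phase`` runs the filter forward–backward."""
    if spec.cutoff >= rate / 2.0:
        raise ValueError(
            f"cutoff {spec.cutoff} Hz must be below Nyquist {rate / 2.0} Hz"
        )
    b, a = sps.bessel(spec.order, spec.cutoff, btype="low", fs=rate, norm="phase")
    x = np.asarray(x, float)
    if zero_phase:
        return sps.filtfilt(b, a, x, axis=0)
    return sps.lfilter(b, a, x, axis=0)


def filter_physiological(
    rec: RawRecording,
    order: int = 4,
    cutoffs: dict[str, float] | None = None,
    zero_phase: bool = True,
) -> RawRecording:
    """Bessel-filter every physiological channel with its per-kind cutoff."""
    cutoffs = {**BESSEL_CUTOFFS, **(cutoffs or {})}
    out = rec.channels.copy()
    for i, (_, kind, _) in enumerate(rec.channel_meta):
        if kind in cutoffs:
            spec = BesselSpec(order, cutoffs[kind])
            out[:, i] = bessel_lowpass(out[:, i], spec, rec.rate, zero_phase)
    return RawRecording(rec.timestamps, out, list(rec.channel_meta), rec.labels)


# ---------------------------------------------------------------------------
# Convenience: the full IMU + physiological preprocessing pass
# ---------------------------------------------------------------------------

def preprocess(
    imu: RawRecording,
    phy: RawRecording,
    still_interval: tuple[float, float] = (0.0, 5.0),
    beta: float = 0.1,
    wavelet: str = "db4",
    level: int = 3,
    bessel_order: int = 4,
    gravity: float = 9.81,
    earth_field: float = 50.0,
) -> tuple[RawRecording, RawRecording, OrientationSeries, CalibrationEstimate]:
    """Run calibration → gyro denoising → orientation on the IMU stream and
    the Bessel low-pass on the physiological stream."""
    cal = estimate_calibration(imu, still_interval, gravity, earth_field)
    imu_cal = apply_calibration(imu, cal)
    gyro_idx = [i for i, m in enumerate(imu_cal.channel_meta) if m[1] == "gyro"]
    imu_cal.channels[:, gyro_idx] = denoise_gyro(
        imu_cal.channels[:, gyro_idx], wavelet, level
    )
    orient = fuse_orientation(
        imu_cal.by_kind("acc"),
        imu_cal.by_kind("gyro"),
        imu_cal.by_kind("mag"),
        imu_cal.rate,
        beta=beta,
        timestamps=imu_cal.timestamps,
    )
    phy_f = filter_physiological(phy, order=bessel_order)
    return imu_cal, phy_f, orient, cal
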