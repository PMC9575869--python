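"""Synthetic multi-sensor activity recordings.

Emulates the structure of wrist/arm-worn recordings used in activity
recognition studies: a 9-channel IMU stream (tri-axial accelerometer,
gyroscope, magnetometer) plus a physiological stream (surface EMG and ECG)
sampled on a different clock, with a per-sample activity label track.

The generative model is explicit so that downstream stages can be tested by
parameter and label *recovery* rather than dataset replication:

* an internal ground-truth orientation trajectory ``q(t)`` (unit quaternions,
  body-to-world) — near-constant with low-amplitude tremor for *static*
  activities, periodic single-axis oscillation (0.5–3 Hz) for *kinematic*
  activities;
* accelerometer = gravity rotated into the sensor frame + linear-motion term
  + per-axis bias + white noise;
* gyroscope = true body angular rate + bias + linear drift + noise;
* magnetometer = earth field rotated into the sensor frame + hard-iron
  offset + noise;
* EMG = band-limited zero-mean noise whose envelope scales with activity
  intensity; ECG = an R-peak pulse train at an activity-dependent heart
  rate + noise.

All randomness is driven by a single integer seed; the ground truth
(trajectory, per-recording activity parameters, configuration) is returned
as a sidecar for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from ._quat import from_axis_angle, rotate_inv, enforce_sign_convention

SENSOR_KINDS = ("acc", "gyro", "mag", "emg", "ecg", "hr")

#: Direction of the geomagnetic field in the world frame (unit vector,
#: 60° inclination north-down); magnitude comes from SensorConfig.
EARTH_FIELD_DIR = np.array([0.5, 0.0, -np.sqrt(3.0) / 2.0])

#: Gravity direction in the world frame (z up; an accelerometer at rest with
#: identity orientation reads (0, 0, +g)).
GRAVITY_DIR = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class Segment:
    """One scheduled activity bout."""

    activity: str
    duration: float  # seconds
    regime: str  # "kinematic" | "static"

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError(f"segment duration must be > 0, got {self.duration}")
        if self.regime not in ("kinematic", "static"):
            raise ValueError(f"regime must be kinematic|static, got {self.regime!r}")


@dataclass(frozen=True)
class ActivitySchedule:
    """Ordered activity bouts; total duration is the recording length."""

    segments: tuple[Segment, ...]

    def __post_init__(self):
        if len(self.segments) == 0:
            raise ValueError("schedule must contain at least one segment")

    @property
    def total_duration(self) -> float:
        return float(sum(s.duration for s in self.segments))

    @property
    def boundaries(self) -> np.ndarray:
        return np.cumsum([s.duration for s in self.segments])

    def labels_at(self, t: np.ndarray) -> np.ndarray:
        """Per-sample activity token (right boundary belongs to next bout)."""
        idx = np.searchsorted(self.boundaries, t, side="right")
        idx = np.clip(idx, 0, len(self.segments) - 1)
        names = np.array([s.activity for s in self.segments])
        return names[idx]

    def regime_of(self, activity: str) -> str:
        for s in self.segments:
            if s.activity == activity:
                return s.regime
        raise KeyError(activity)


@dataclass
class SensorConfig:
    """Sampling rates, calibration ground truth and noise levels.

    Units: rates Hz, accelerometer m/s², gyroscope rad/s, magnetometer µT.
    """

    imu_rate: float = 100.0
    phy_rate: float = 250.0
    accel_bias: tuple[float, float, float] = (0.2, -0.1, 0.15)
    gyro_bias: tuple[float, float, float] = (0.01, -0.02, 0.005)
    gyro_drift_rate: float = 1e-4  # rad/s per second, applied to each axis
    mag_hard_iron: tuple[float, float, float] = (5.0, -3.0, 8.0)
    noise_sd: dict = field(
        default_factory=lambda: {
            "acc": 0.05,
            "gyro": 0.01,
            "mag": 0.3,
            "emg": 0.01,
            "ecg": 0.05,
        }
    )
    gravity: float = 9.81
    earth_field: float = 50.0

    def __post_init__(self):
        if self.imu_rate <= 0 or self.phy_rate <= 0:
            raise ValueError("sample rates must be > 0")
        if any(v < 0 for v in self.noise_sd.values()):
            raise ValueError("noise SDs must be >= 0")


@dataclass(frozen=True)
class ActivityProfile:
    """Signal signature of one activity.

    ``osc_freq``/``acc_amp``/``rot_amp`` drive the kinematic oscillation
    (Hz, m/s², rad); ``tremor_*`` the residual motion of static activities;
    ``emg_intensity`` scales the EMG envelope (arbitrary units ~mV);
    ``heart_rate`` in beats per minute.
    """

    regime: str
    osc_freq: float = 0.0
    acc_amp: float = 0.0
    rot_amp: float = 0.0
    rot_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    acc_dir: tuple[float, float, float] = (1.0, 0.0, 0.0)
    tremor_amp: float = 0.0
    tremor_freq: float = 0.0
    emg_intensity: float = 0.1
    heart_rate: float = 60.0


# Activity signatures for the 4-activity wrist/arm profile (rest, typing,
# push-ups, lifting).  Amplitudes and rates are plausible wrist-worn values;
# kinematic oscillation frequencies stay in the 0.5–3 Hz band.
PAD_PROFILES: dict[str, ActivityProfile] = {
    "resting": ActivityProfile(
        regime="static", tremor_amp=0.03, tremor_freq=9.0,
        emg_intensity=0.10, heart_rate=60.0,
    ),
    "typing": ActivityProfile(
        regime="static", tremor_amp=0.12, tremor_freq=6.0,
        emg_intensity=0.35, heart_rate=66.0,
    ),
    "push_ups": ActivityProfile(
        regime="kinematic", osc_freq=0.8, acc_amp=3.0, rot_amp=0.25,
        rot_axis=(1.0, 0.0, 0.0), acc_dir=(0.0, 0.0, 1.0),
        emg_intensity=1.0, heart_rate=110.0,
    ),
    "lifting": ActivityProfile(
        regime="kinematic", osc_freq=0.5, acc_amp=2.0, rot_amp=0.35,
        rot_axis=(0.0, 1.0, 0.0), acc_dir=(0.6, 0.0, 0.8),
        emg_intensity=0.8, heart_rate=95.0,
    ),
}

# 16-activity elderly-monitoring profile (lying/sitting/standing variants are
# static; locomotion and household tasks kinematic).
GOTOV_PROFILES: dict[str, ActivityProfile] = {
    "jumping": ActivityProfile("kinematic", 2.4, 6.0, 0.30, (1, 0, 0), (0, 0, 1), emg_intensity=1.0, heart_rate=130),
    "standing": ActivityProfile("static", tremor_amp=0.04, tremor_freq=8.0, emg_intensity=0.15, heart_rate=70),
    "step": ActivityProfile("kinematic", 1.8, 3.5, 0.25, (0, 1, 0), (0, 0, 1), emg_intensity=0.8, heart_rate=105),
    "lying_down_left": ActivityProfile("static", tremor_amp=0.02, tremor_freq=7.0, emg_intensity=0.05, heart_rate=58),
    "lying_down_right": ActivityProfile("static", tremor_amp=0.02, tremor_freq=9.5, emg_intensity=0.06, heart_rate=60),
    "sitting_sofa": ActivityProfile("static", tremor_amp=0.03, tremor_freq=8.5, emg_intensity=0.08, heart_rate=63),
    "sitting_couch": ActivityProfile("static", tremor_amp=0.035, tremor_freq=6.5, emg_intensity=0.09, heart_rate=64),
    "sitting_chair": ActivityProfile("static", tremor_amp=0.04, tremor_freq=7.5, emg_intensity=0.10, heart_rate=65),
    "walking_stairs_up": ActivityProfile("kinematic", 1.6, 4.0, 0.30, (1, 0, 0), (0, 0, 1), emg_intensity=0.9, heart_rate=115),
    "washing_dishes": ActivityProfile("kinematic", 0.9, 1.5, 0.20, (0, 0, 1), (1, 0, 0), emg_intensity=0.5, heart_rate=80),
    "stacking_shelves": ActivityProfile("kinematic", 0.6, 2.0, 0.30, (0, 1, 0), (0, 0, 1), emg_intensity=0.7, heart_rate=90),
    "vacuum_cleaning": ActivityProfile("kinematic", 1.1, 2.5, 0.25, (0, 0, 1), (1, 0, 0), emg_intensity=0.6, heart_rate=95),
    "walking_slow": ActivityProfile("kinematic", 1.4, 2.0, 0.20, (0, 1, 0), (1, 0, 0), emg_intensity=0.5, heart_rate=85),
    "walking_normal": ActivityProfile("kinematic", 1.8, 3.0, 0.25, (0, 1, 0), (1, 0, 0), emg_intensity=0.6, heart_rate=95),
    "walking_fast": ActivityProfile("kinematic", 2.2, 4.5, 0.30, (0, 1, 0), (1, 0, 0), emg_intensity=0.8, heart_rate=110),
    "cycling": ActivityProfile("kinematic", 1.5, 2.5, 0.35, (1, 0, 0), (0, 1, 0), emg_intensity=0.7, heart_rate=105),
}


def pad_schedule(seconds: float = 70.0) -> ActivitySchedule:
    """Four equal bouts: resting, typing, push-ups, lifting."""
    d = seconds / 4.0
    return ActivitySchedule(
        (
            Segment("resting", d, "static"),
            Segment("typing", d, "static"),
            Segment("push_ups", d, "kinematic"),
            Segment("lifting", d, "kinematic"),
        )
    )


def gotov_schedule(seconds: float = 3400.0) -> ActivitySchedule:
    names = list(GOTOV_PROFILES)
    d = seconds / len(names)
    return ActivitySchedule(
        tuple(Segment(n, d, GOTOV_PROFILES[n].regime) for n in names)
    )


@dataclass
class RawRecording:
    """Timestamped multichannel signal block.

    ``channels`` is n_samples × n_channels; ``channel_meta`` is a list of
    (name, sensor_kind, units) triples; ``labels`` one activity token per
    sample.
    """

    timestamps: np.ndarray
    channels: np.ndarray
    channel_meta: list[tuple[str, str, str]]
    labels: np.ndarray

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, float)
        self.channels = np.atleast_2d(np.asarray(self.channels, float))
        if len(self.timestamps) != self.channels.shape[0]:
            raise ValueError("n_samples mismatch between timestamps and channels")
        if self.channels.shape[1] != len(self.channel_meta):
            raise ValueError("channel_meta length must match channel count")
        if len(self.labels) != len(self.timestamps):
            raise ValueError("labels must align with timestamps")
        if len(self.timestamps) > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        for _, kind, _ in self.channel_meta:
            if kind not in SENSOR_KINDS:
                raise ValueError(f"unknown sensor kind {kind!r}")

    @property
    def names(self) -> list[str]:
        return [m[0] for m in self.channel_meta]

    @property
    def rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.timestamps)))

    def by_kind(self, kind: str) -> np.ndarray:
        cols = [i for i, m in enumerate(self.channel_meta) if m[1] == kind]
        if not cols:
            raise KeyError(f"no channels of kind {kind!r}")
        return self.channels[:, cols]


@dataclass
class GroundTruth:
    """Sidecar returned with every generated recording."""

    config: SensorConfig
    schedule: ActivitySchedule
    quaternions: np.ndarray  # n_imu × 4 body-to-world, scalar-first
    angular_rate: np.ndarray  # n_imu × 3 true body rates, rad/s
    profiles: dict[str, ActivityProfile]  # per-recording (jittered) parameters
    seed: int


def _jitter_profiles(
    profiles: dict[str, ActivityProfile], rng: np.random.Generator, rel: float
) -> dict[str, ActivityProfile]:
    """Per-recording subject variability: ±rel multiplicative jitter."""
    out = {}
    for name, p in profiles.items():
        j = lambda v: float(v) * (1.0 + rel * rng.uniform(-1, 1)) if v else float(v)
        out[name] = ActivityProfile(
            regime=p.regime,
            osc_freq=j(p.osc_freq),
            acc_amp=j(p.acc_amp),
            rot_amp=j(p.rot_amp),
            rot_axis=p.rot_axis,
            acc_dir=p.acc_dir,
            tremor_amp=j(p.tremor_amp),
            tremor_freq=j(p.tremor_freq),
            emg_intensity=j(p.emg_intensity),
            heart_rate=j(p.heart_rate),
        )
    return out


def _segment_slices(schedule: ActivitySchedule, t: np.ndarray):
    starts = np.concatenate([[0.0], schedule.boundaries[:-1]])
    for seg, t0 in zip(schedule.segments, starts):
        mask = (t >= t0) & (t < t0 + seg.duration)
        yield seg, t0, mask


def generate_recording(
    schedule: ActivitySchedule,
    config: SensorConfig | None = None,
    seed: int = 0,
    profiles: dict[str, ActivityProfile] | None = None,
    subject_jitter: float = 0.1,
) -> tuple[RawRecording, RawRecording, GroundTruth]:
    """Simulate one (IMU, physiological) recording pair plus ground truth.

    The IMU stream carries 9 channels (acc/gyro/mag × x/y/z) at
    ``config.imu_rate``; the physiological stream carries EMG and ECG at
    ``config.phy_rate``.  ``seed`` fixes all randomness bit-for-bit.
    """
    config = config or SensorConfig()
    profiles = profiles or PAD_PROFILES
    rng = np.random.default_rng(seed)
    prof = _jitter_profiles(profiles, rng, subject_jitter) if subject_jitter else dict(profiles)

    total = schedule.total_duration
    n_imu = int(round(total * config.imu_rate))
    t_imu = np.arange(n_imu) / config.imu_rate
    n_phy = int(round(total * config.phy_rate))
    t_phy = np.arange(n_phy) / config.phy_rate

    # --- ground-truth orientation and body angular rate -------------------
    angle = np.zeros(n_imu)
    axis_per_sample = np.zeros((n_imu, 3))
    rate_mag = np.zeros(n_imu)
    a_lin_world = np.zeros((n_imu, 3))
    for seg, t0, mask in _segment_slices(schedule, t_imu):
        p = prof[seg.activity]
        tau = t_imu[mask] - t0
        axis = np.asarray(p.rot_axis, float)
        axis = axis / np.linalg.norm(axis)
        if seg.regime == "kinematic":
            w = 2 * np.pi * p.osc_freq
            angle[mask] = p.rot_amp * np.sin(w * tau)
            rate_mag[mask] = p.rot_amp * w * np.cos(w * tau)
            d = np.asarray(p.acc_dir, float)
            d = d / np.linalg.norm(d)
            a_lin_world[mask] = p.acc_amp * np.sin(w * tau)[:, None] * d
        else:
            w = 2 * np.pi * max(p.tremor_freq, 1e-9)
            # tremor tilt kept small and frequency-independent in *rate*:
            # angle amplitude shrinks with tremor frequency
            rot_trem = 0.1 * p.tremor_amp / config.gravity  # rad
            angle[mask] = rot_trem * np.sin(w * tau)
            rate_mag[mask] = rot_trem * w * np.cos(w * tau)
            a_lin_world[mask] = (
                p.tremor_amp * np.sin(w * tau)[:, None] * np.array([1.0, 0.0, 0.0])
            )
        axis_per_sample[mask] = axis

    quat = from_axis_angle_rows(axis_per_sample, angle)
    quat = enforce_sign_convention(quat)
    omega_body = axis_per_sample * rate_mag[:, None]

    # --- IMU channels ------------------------------------------------------
    g_world = config.gravity * GRAVITY_DIR
    acc = rotate_inv(quat, g_world + a_lin_world)
    acc = acc + np.asarray(config.accel_bias)
    acc = acc + rng.normal(0.0, config.noise_sd["acc"], acc.shape)

    gyro = (
        omega_body
        + np.asarray(config.gyro_bias)
        + config.gyro_drift_rate * t_imu[:, None]
        + rng.normal(0.0, config.noise_sd["gyro"], (n_imu, 3))
    )

    m_world = config.earth_field * EARTH_FIELD_DIR
    mag = rotate_inv(quat, np.broadcast_to(m_world, (n_imu, 3)))
    mag = mag + np.asarray(config.mag_hard_iron)
    mag = mag + rng.normal(0.0, config.noise_sd["mag"], (n_imu, 3))

    imu_channels = np.column_stack([acc, gyro, mag])
    imu_meta = (
        [(f"acc_{a}", "acc", "m/s^2") for a in "xyz"]
        + [(f"gyro_{a}", "gyro", "rad/s") for a in "xyz"]
        + [(f"mag_{a}", "mag", "uT") for a in "xyz"]
    )
    imu = RawRecording(t_imu, imu_channels, imu_meta, schedule.labels_at(t_imu))

    # --- physiological channels -------------------------------------------
    env = np.zeros(n_phy)
    hr = np.full(n_phy, 60.0)
    for seg, t0, mask in _segment_slices(schedule, t_phy):
        p = prof[seg.activity]
        env[mask] = p.emg_intensity
        hr[mask] = p.heart_rate
    # EMG carrier: white noise band-limited to 15–45 Hz (survives the later
    # low-pass in part, so intensity remains observable after filtering).
    carrier = rng.normal(0.0, 1.0, n_phy)
    ny = config.phy_rate / 2.0
    b, a = sps.butter(4, [15.0 / ny, min(45.0, 0.95 * ny) / ny], btype="band")
    carrier = sps.filtfilt(b, a, carrier)
    emg = 0.5 * env * carrier + rng.normal(0.0, config.noise_sd["emg"], n_phy)

    phase = np.cumsum(hr / 60.0) / config.phy_rate  # beats
    frac = np.mod(phase, 1.0)
    ecg = np.exp(-((frac - 0.5) ** 2) / (2 * 0.02**2))  # R peaks
    ecg = ecg + 0.15 * np.sin(2 * np.pi * phase)  # baseline wave
    ecg = ecg + rng.normal(0.0, config.noise_sd["ecg"], n_phy)

    phy = RawRecording(
        t_phy,
        np.column_stack([emg, ecg]),
        [("emg", "emg", "mV"), ("ecg", "ecg", "mV")],
        schedule.labels_at(t_phy),
    )

    truth = GroundTruth(
        config=config,
        schedule=schedule,
        quaternions=quat,
        angular_rate=omega_body,
        profiles=prof,
        seed=seed,
    )
    return imu, phy, truth


def from_axis_angle_rows(axes: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """Row-wise axis-angle to quaternion (axes already unit or zero)."""
    norms = np.linalg.norm(axes, axis=-1, keepdims=True)
    safe = np.where(norms > 0, norms, 1.0)
    u = axes / safe
    half = np.asarray(angles, float) / 2.0
    return np.concatenate(
        [np.cos(half)[:, None], np.sin(half)[:, None] * u], axis=-1
    )


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------

def _rle(labels: np.ndarray) -> list[list]:
    """Run-length encode labels as [start_index, count, token]."""
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append([int(start), int(i - start), str(labels[start])])
            start = i
    return runs


def _rle_decode(runs: list, n: int) -> np.ndarray:
    out = np.empty(n, dtype=object)
    for start, count, token in runs:
        out[start : start + count] = token
    return out.astype(str)


def write_recording(rec: RawRecording, path: str | Path) -> None:
    """Write ``time,<channel>...`` CSV plus a ``*.meta.json`` sidecar."""
    path = Path(path)
    df = pd.DataFrame(rec.channels, columns=rec.names)
    df.insert(0, "time", rec.timestamps)
    df.to_csv(path, index=False, float_format="%.12g")
    meta = {
        "channels": [list(m) for m in rec.channel_meta],
        "labels_rle": _rle(rec.labels),
        "n_samples": int(len(rec.timestamps)),
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))


def read_recording(path: str | Path) -> RawRecording:
    """Inverse of :func:`write_recording`; validates header and timestamps."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as e:
        raise ValueError(f"{path}: empty recording file") from e
    if df.shape[0] == 0:
        raise ValueError(f"{path}: recording has no samples")
    if df.columns[0] != "time":
        raise ValueError(f"{path}: malformed header, first column must be 'time'")
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(meta_path.read_text())
    channel_meta = [tuple(m) for m in meta["channels"]]
    names = [m[0] for m in channel_meta]
    if list(df.columns[1:]) != names:
        raise ValueError(f"{path}: header channels do not match sidecar metadata")
    t = df["time"].to_numpy(float)
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: timestamps must be strictly increasing")
    labels = _rle_decode(meta["labels_rle"], len(t))
    return RawRecording(t, df[names].to_numpy(float), channel_meta, labels)


# ---------------------------------------------------------------------------
# Two-filament semi-supervised benchmark
# ---------------------------------------------------------------------------

def two_filaments(
    n: int = 200, noise: float = 0.08, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Two interleaved half-circle filaments (the classic semi-supervised
    benchmark geometry).  Returns (X, y) with y ∈ {0, 1}."""
    rng = np.random.default_rng(seed)
    n0 = n // 2
    n1 = n - n0
    th0 = rng.uniform(0, np.pi, n0)
    th1 = rng.uniform(0, np.pi, n1)
    x0 = np.column_stack([np.cos(th0), np.sin(th0)])
    x1 = np.column_stack([1.0 - np.cos(th1), 0.5 - np.sin(th1)])
    X = np.vstack([x0, x1]) + rng.normal(0, noise, (n, 2))
    y = np.concatenate([np.zeros(n0, int), np.ones(n1, int)])
    return X, y
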