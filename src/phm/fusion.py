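"""Time-based fusion of IMU and physiological streams and 2-s overlapping
windowing.

Fusion linearly interpolates both streams onto one common clock restricted
to the intersection of their time supports (default target rate: the IMU
rate, decimating the faster physiological stream) and concatenates the
channels.  Windowing slices the fused matrix into fixed-duration windows
with a configurable overlap fraction; each window carries the majority
per-sample activity label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import RawRecording


@dataclass
class FusedSignal:
    """All filtered channels, time-aligned on one common clock."""

    timestamps: np.ndarray
    matrix: np.ndarray  # n_samples × n_channels
    channel_meta: list[tuple[str, str, str]]
    labels: np.ndarray
    rate: float

    @property
    def names(self) -> list[str]:
        return [m[0] for m in self.channel_meta]

    def kind_columns(self, kind: str) -> list[int]:
        return [i for i, m in enumerate(self.channel_meta) if m[1] == kind]


@dataclass
class Window:
    """One fixed-duration slice of a fused signal."""

    start: float
    duration: float
    data: np.ndarray  # m × n_channels
    channel_meta: list[tuple[str, str, str]]
    label: str | None = None
    label_purity: float = 1.0
    pattern: str = "undecided"  # kinematic | static | undecided

    def kind_columns(self, kind: str) -> list[int]:
        return [i for i, m in enumerate(self.channel_meta) if m[1] == kind]

    def magnitude(self, kind: str) -> np.ndarray:
        """Euclidean norm across the axes of a tri-axial sensor kind (or the
        single channel itself for scalar kinds)."""
        cols = self.kind_columns(kind)
        if not cols:
            raise KeyError(f"no channels of kind {kind!r}")
        block = self.data[:, cols]
        return np.linalg.norm(block, axis=1) if block.shape[1] > 1 else block[:, 0]


def fuse_streams(
    imu: RawRecording,
    phy: RawRecording,
    target_rate: float | None = None,
) -> FusedSignal:
    """Interpolate both streams onto one clock and concatenate channels.

    The common clock covers the intersection of the two time supports at
    ``target_rate`` (default: the IMU rate).  Labels are taken from the IMU
    stream by nearest-sample lookup.
    """
    target_rate = float(target_rate or imu.rate)
    if target_rate <= 0:
        raise ValueError("target_rate must be > 0")
    t0 = max(imu.timestamps[0], phy.timestamps[0])
    t1 = min(imu.timestamps[-1], phy.timestamps[-1])
    if t1 <= t0:
        raise ValueError(
            f"disjoint time supports: IMU [{imu.timestamps[0]}, {imu.timestamps[-1]}]"
            f" vs PHY [{phy.timestamps[0]}, {phy.timestamps[-1]}]"
        )
    n = int(np.floor((t1 - t0) * target_rate + 1e-9)) + 1
    t = t0 + np.arange(n) / target_rate

    cols = []
    for src in (imu, phy):
        for j in range(src.channels.shape[1]):
            cols.append(np.interp(t, src.timestamps, src.channels[:, j]))
    matrix = np.column_stack(cols)
    meta = list(imu.channel_meta) + list(phy.channel_meta)

    idx = np.clip(
        np.searchsorted(imu.timestamps, t, side="left"), 0, len(imu.timestamps) - 1
    )
    left = np.clip(idx - 1, 0, len(imu.timestamps) - 1)
    use_left = np.abs(imu.timestamps[left] - t) <= np.abs(imu.timestamps[idx] - t)
    labels = np.where(use_left, imu.labels[left], imu.labels[idx])

    return FusedSignal(t, matrix, meta, labels, target_rate)


def _majority_label(labels: np.ndarray, order: dict[str, int]) -> tuple[str, float]:
    """Majority token; ties broken toward the earlier activity in the
    recording (first appearance order)."""
    tokens, counts = np.unique(labels, return_counts=True)
    best = counts.max()
    cands = [t for t, c in zip(tokens, counts) if c == best]
    label = min(cands, key=lambda t: order.get(t, len(order)))
    return str(label), float(best) / len(labels)


def make_windows(
    fus: FusedSignal,
    duration: float = 2.0,
    overlap: float = 0.5,
) -> list[Window]:
    """Slice the fused signal into overlapping fixed-duration windows.

    Per-window sample count is ``round(duration × rate)``; the stride is
    ``duration × (1 − overlap)``; a trailing partial window is dropped.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if not (0 <= overlap < 1):
        raise ValueError("overlap must be in [0, 1)")
    m = int(round(duration * fus.rate))
    stride = int(round(m * (1.0 - overlap)))
    if stride < 1:
        raise ValueError("overlap too close to 1 for this rate")
    n = fus.matrix.shape[0]
    if n < m:
        raise ValueError("recording shorter than one window")

    order: dict[str, int] = {}
    for token in fus.labels:
        if token not in order:
            order[token] = len(order)

    windows = []
    for s in range(0, n - m + 1, stride):
        label, purity = _majority_label(fus.labels[s : s + m], order)
        windows.append(
            Window(
                start=float(fus.timestamps[s]),
                duration=duration,
                data=fus.matrix[s : s + m],
                channel_meta=fus.channel_meta,
                label=label,
                label_purity=purity,
            )
        )
    return windows
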