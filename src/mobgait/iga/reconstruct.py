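"""Strapdown trajectory reconstruction with zero-velocity updates.

Orientation is tracked by integrating the gyroscope from an initial attitude
anchored to the gravity direction measured during the opening stance.
Gravity-free world acceleration is double-integrated; the velocity drift is
removed with an affine correction that forces zero mean velocity inside both
stance anchor windows (the classic ZUPT de-drift for foot-mounted sensors).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.spatial.transform import Rotation

from ..config import IgaConfig
from ..recording import G0, ImuRecording
from .segmentation import StrideSegment


@dataclass
class TrajectoryEstimate:
    """Reconstructed stride trajectory relative to the flat-foot position."""

    pos: np.ndarray  # (n, 3) m, drift-corrected
    vel: np.ndarray  # (n, 3) m/s
    height: np.ndarray  # (n,) m above the flat-foot baseline
    stride_length: float  # horizontal displacement, m
    max_lift: float  # peak of ``height``, m
    heading_change_deg: float
    anchor_speeds: tuple[float, float]  # |mean velocity| in the two anchors


def _orientations(gyr_dps: np.ndarray, dt: float, r0: Rotation) -> np.ndarray:
    """Sequential body-frame attitude integration; returns (n, 3, 3) matrices."""
    w = np.deg2rad(gyr_dps)
    inc = 0.5 * (w[:-1] + w[1:]) * dt
    steps = Rotation.from_rotvec(inc)
    mats = np.empty((w.shape[0], 3, 3))
    r = r0
    mats[0] = r.as_matrix()
    for k in range(inc.shape[0]):
        r = r * steps[k]
        mats[k + 1] = r.as_matrix()
    return mats


def reconstruct_trajectory(
    imu: ImuRecording, segment: StrideSegment, cfg: IgaConfig | None = None
) -> TrajectoryEstimate | None:
    """Reconstruct one stride's foot path; None when integration diverges."""
    cfg = cfg or IgaConfig()
    fs = imu.fs
    dt = 1.0 / fs
    acc = imu.acc[segment.start:segment.end]
    gyr = imu.gyr[segment.start:segment.end]
    n = acc.shape[0]
    na = min(max(2, int(round(cfg.anchor_window_s * fs))), max(n // 4, 2))
    if n < 2 * na + 2:
        return None

    # initial attitude from the gravity direction in the opening stance
    g_meas = acc[:na].mean(axis=0)
    norm = np.linalg.norm(g_meas)
    if not np.isfinite(norm) or norm < 1e-6:
        return None
    g_hat = g_meas / norm
    z = np.array([0.0, 0.0, 1.0])
    cross = np.cross(g_hat, z)
    s = np.linalg.norm(cross)
    c = float(np.dot(g_hat, z))
    if s < 1e-12:
        r0 = Rotation.identity() if c > 0 else Rotation.from_rotvec([np.pi, 0, 0])
    else:
        r0 = Rotation.from_rotvec(cross / s * np.arctan2(s, c))

    mats = _orientations(gyr, dt, r0)
    a_world = np.einsum("nij,nj->ni", mats, acc) * G0
    a_world[:, 2] -= G0
    if not np.isfinite(a_world).all():
        return None

    t = np.arange(n) * dt
    vel = cumulative_trapezoid(a_world, dx=dt, initial=0.0, axis=0)
    t0m, t1m = t[:na].mean(), t[-na:].mean()
    v0m, v1m = vel[:na].mean(axis=0), vel[-na:].mean(axis=0)
    ramp = (t - t0m)[:, None] / (t1m - t0m)
    vel = vel - (v0m[None, :] + ramp * (v1m - v0m)[None, :])
    pos = cumulative_trapezoid(vel, dx=dt, initial=0.0, axis=0)
    if not np.isfinite(pos).all():
        return None

    p0, p1 = pos[:na].mean(axis=0), pos[-na:].mean(axis=0)
    length = float(np.hypot(*(p1 - p0)[:2]))
    zbase = p0[2] + ramp.ravel() * (p1[2] - p0[2])
    height = pos[:, 2] - zbase
    yaw = np.unwrap(np.arctan2(mats[:, 1, 0], mats[:, 0, 0]))
    heading_change = float(np.rad2deg(yaw[-na:].mean() - yaw[:na].mean()))
    anchors = (
        float(np.linalg.norm(vel[:na].mean(axis=0))),
        float(np.linalg.norm(vel[-na:].mean(axis=0))),
    )
    return TrajectoryEstimate(
        pos=pos, vel=vel, height=height, stride_length=length,
        max_lift=float(height.max()), heading_change_deg=heading_change,
        anchor_speeds=anchors,
    )
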