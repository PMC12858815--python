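"""Kinematic stride-trajectory model and IMU signal synthesis.

A stride runs from mid-stance to mid-stance: the foot is flat and motionless
for half the stance phase, swings forward along a smooth arc, and is flat
again for the second half of the stance phase.  The horizontal progression
follows a minimum-jerk (fifth-order polynomial) profile so position, velocity
and acceleration are all available in closed form; the vertical excursion is
a raised cosine peaking at the requested maximum sensor lift.

The sagittal (pitch) rotation is modelled as three lobes of angular rate:
a sharp plantarflexion lobe peaking exactly at toe-off, a broad dorsiflexion
lobe at mid-swing, and a second sharp negative lobe peaking at heel strike.
The lobe areas balance so the net pitch over a stride is zero.  This gives
gyroscope signals whose negative peaks coincide with the true gait events,
which is the convention event detection relies on.

Sensor frame: x forward, y left, z up when the foot is flat; the
accelerometer reads specific force in g (+1 g on z at rest), the gyroscope
body rates in deg/s.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ..recording import G0, ImuRecording

#: default white-noise levels per channel class (acc in g, gyro in deg/s)
DEFAULT_NOISE = (0.02, 0.5)

#: peak plantarflexion rate of the toe-off / heel-strike lobes, deg/s
PITCH_EDGE_RATE_DPS = 350.0
#: width of the edge lobes as a fraction of swing time
PITCH_EDGE_WIDTH = 0.12


@dataclass(frozen=True)
class StrideTemplate:
    """Ground-truth parameters of one stride.

    ``stride_length`` (m), ``stride_time`` (s), ``stance_percentage`` (% of
    stride time with the foot flat on the ground), ``max_lift`` (m, peak
    vertical sensor excursion), ``heading`` (deg, walking direction) and
    ``turn_angle`` (deg, heading change accumulated during the swing; zero
    for straight strides).
    """

    stride_length: float
    stride_time: float
    stance_percentage: float
    max_lift: float
    heading: float = 0.0
    turn_angle: float = 0.0

    def __post_init__(self) -> None:
        if not self.stride_length > 0:
            raise ValueError("stride_length must be > 0")
        if not self.stride_time > 0:
            raise ValueError("stride_time must be > 0")
        if not 0 < self.stance_percentage < 100:
            raise ValueError("stance_percentage must be in (0, 100)")
        if self.max_lift < 0:
            raise ValueError("max_lift must be >= 0")

    @property
    def gait_velocity(self) -> float:
        """Derived parameter: stride length over stride time, m/s."""
        return self.stride_length / self.stride_time

    @property
    def stance_time(self) -> float:
        return self.stride_time * self.stance_percentage / 100.0

    @property
    def swing_time(self) -> float:
        return self.stride_time - self.stance_time


@dataclass
class FootTrajectory:
    """Sampled foot position and orientation, with closed-form derivatives."""

    fs: float
    t: np.ndarray  # (n,) seconds
    pos: np.ndarray  # (n, 3) metres, world frame (x east, y north, z up)
    vel: np.ndarray  # (n, 3) m/s
    acc: np.ndarray  # (n, 3) m/s^2 (gravity-free, world frame)
    pitch: np.ndarray  # (n,) rad
    pitch_rate: np.ndarray  # (n,) rad/s
    yaw: np.ndarray  # (n,) rad
    yaw_rate: np.ndarray  # (n,) rad/s

    @property
    def n(self) -> int:
        return self.t.shape[0]


# ----------------------------------------------------------------------
# closed-form profiles
# ----------------------------------------------------------------------

def _minjerk(tau: np.ndarray) -> np.ndarray:
    return tau**3 * (10.0 + tau * (-15.0 + 6.0 * tau))


def _minjerk_d1(tau: np.ndarray) -> np.ndarray:
    return tau**2 * (30.0 + tau * (-60.0 + 30.0 * tau))


def _minjerk_d2(tau: np.ndarray) -> np.ndarray:
    return tau * (60.0 + tau * (-180.0 + 120.0 * tau))


def _pitch_rate_unit(tau: np.ndarray, w: float) -> np.ndarray:
    """d(theta)/d(tau) with unit edge-lobe amplitude; integrates to zero."""
    out = np.zeros_like(tau)
    b = 2.0 * w / (1.0 - 2.0 * w)
    lo = tau < w
    hi = tau > 1.0 - w
    mid = ~lo & ~hi
    out[lo] = -np.cos(np.pi * tau[lo] / (2.0 * w)) ** 2
    out[hi] = -np.cos(np.pi * (1.0 - tau[hi]) / (2.0 * w)) ** 2
    out[mid] += b * np.sin(np.pi * (tau[mid] - w) / (1.0 - 2.0 * w)) ** 2
    return out


def _pitch_unit(tau: np.ndarray, w: float) -> np.ndarray:
    """Integral of :func:`_pitch_rate_unit` from 0 to tau (closed form)."""
    b = 2.0 * w / (1.0 - 2.0 * w)
    # toe-off lobe integral
    tc = np.clip(tau, 0.0, w)
    i1 = tc / 2.0 + (w / (2.0 * np.pi)) * np.sin(np.pi * tc / w)
    # heel-strike lobe integral
    uc = np.clip(1.0 - tau, 0.0, w)
    i2 = w / 2.0 - (uc / 2.0 + (w / (2.0 * np.pi)) * np.sin(np.pi * uc / w))
    # mid-swing lobe integral
    mc = np.clip(tau, w, 1.0 - w)
    span = 1.0 - 2.0 * w
    i3 = (mc - w) / 2.0 - (span / (4.0 * np.pi)) * np.sin(2.0 * np.pi * (mc - w) / span)
    return -(i1 + i2) + b * i3


def stride_kinematics(template: StrideTemplate, t: np.ndarray) -> FootTrajectory:
    """Evaluate the stride model at times ``t`` (seconds within the stride).

    Times outside the swing window (the first and last half of the stance
    phase) give a motionless, flat foot.
    """
    t = np.asarray(t, dtype=float)
    T = template.stride_time
    half = template.stance_time / 2.0
    tsw = template.swing_time
    if not tsw > 0:
        raise ValueError("swing time must be positive")
    tau = np.clip((t - half) / tsw, 0.0, 1.0)

    h0 = np.deg2rad(template.heading)
    dh = np.deg2rad(template.turn_angle)
    u = np.array([np.cos(h0), np.sin(h0), 0.0])

    s = _minjerk(tau)
    s1 = _minjerk_d1(tau) / tsw
    s2 = _minjerk_d2(tau) / tsw**2
    in_swing = (t >= half) & (t < half + tsw)
    s1 = np.where(in_swing, s1, 0.0)
    s2 = np.where(in_swing, s2, 0.0)

    L, H = template.stride_length, template.max_lift
    pos = np.outer(L * s, u)
    vel = np.outer(L * s1, u)
    acc = np.outer(L * s2, u)
    # vertical arc: sin^3 bump peaking at max_lift; unlike a raised cosine
    # its acceleration is continuous at the swing boundaries, so quadrature
    # of the resulting accelerometer signal is unbiased
    sp, cp = np.sin(np.pi * tau), np.cos(np.pi * tau)
    pos[:, 2] = H * sp**3
    vel[:, 2] = np.where(in_swing, 3.0 * H * np.pi * sp**2 * cp / tsw, 0.0)
    acc[:, 2] = np.where(
        in_swing,
        3.0 * H * np.pi**2 * sp * (2.0 * cp**2 - sp**2) / tsw**2,
        0.0,
    )

    w = PITCH_EDGE_WIDTH
    amp = np.deg2rad(PITCH_EDGE_RATE_DPS) * tsw  # rad per unit tau
    pitch = amp * _pitch_unit(tau, w)
    pitch_rate = np.where(in_swing, amp * _pitch_rate_unit(tau, w) / tsw, 0.0)
    yaw = h0 + dh * s
    yaw_rate = np.where(in_swing, dh * s1, 0.0)

    return FootTrajectory(
        fs=np.nan, t=t, pos=pos, vel=vel, acc=acc,
        pitch=pitch, pitch_rate=pitch_rate, yaw=yaw, yaw_rate=yaw_rate,
    )


def make_stride_trajectory(template: StrideTemplate, fs: float) -> FootTrajectory:
    """Sample one stride at ``fs`` Hz (half-open sample grid [0, stride_time))."""
    if not fs > 0:
        raise ValueError("sampling rate must be positive")
    n = int(round(template.stride_time * fs))
    traj = stride_kinematics(template, np.arange(n) / fs)
    traj.fs = fs
    return traj


def make_standing_trajectory(duration: float, fs: float, heading: float = 0.0) -> FootTrajectory:
    """A motionless, flat-foot trajectory (used for lead-in/out phases)."""
    n = int(round(duration * fs))
    z = np.zeros(n)
    return FootTrajectory(
        fs=fs, t=np.arange(n) / fs, pos=np.zeros((n, 3)), vel=np.zeros((n, 3)),
        acc=np.zeros((n, 3)), pitch=z, pitch_rate=z.copy(),
        yaw=np.full(n, np.deg2rad(heading)), yaw_rate=z.copy(),
    )


# ----------------------------------------------------------------------
# trajectory -> IMU
# ----------------------------------------------------------------------

def imu_channels(traj: FootTrajectory) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free sensor channels: specific force (g) and body rates (deg/s).

    The body-to-world rotation is R = Rz(yaw) @ Ry(pitch); the accelerometer
    reads R^T (a_world / g0 + z_hat), the gyroscope the body angular rates
    (-sin(pitch)*yaw_rate, pitch_rate, cos(pitch)*yaw_rate).
    """
    cy, sy = np.cos(traj.yaw), np.sin(traj.yaw)
    cp, sp = np.cos(traj.pitch), np.sin(traj.pitch)
    fw = traj.acc / G0
    fx, fy = fw[:, 0], fw[:, 1]
    fz = fw[:, 2] + 1.0
    # Rz(-yaw)
    v1x = cy * fx + sy * fy
    v1y = -sy * fx + cy * fy
    # Ry(-pitch)
    acc = np.column_stack([cp * v1x - sp * fz, v1y, sp * v1x + cp * fz])
    gyr = np.rad2deg(
        np.column_stack([-sp * traj.yaw_rate, traj.pitch_rate, cp * traj.yaw_rate])
    )
    return acc, gyr


def trajectory_to_imu(
    traj: FootTrajectory,
    fs: float | None = None,
    noise_sd: tuple[float, float] = DEFAULT_NOISE,
    seed: int | np.random.Generator | None = None,
    foot: str = "left",
) -> ImuRecording:
    """Convert a sampled trajectory into a (optionally noisy) IMU recording.

    ``noise_sd`` is (accelerometer sd in g, gyroscope sd in deg/s); noise is
    white Gaussian per channel and deterministic given ``seed``.
    """
    fs = traj.fs if fs is None else fs
    if not np.isfinite(traj.pos).all() or not np.isfinite(traj.acc).all():
        raise ValueError("trajectory contains non-finite samples")
    acc, gyr = imu_channels(traj)
    sd_a, sd_g = noise_sd
    if sd_a or sd_g:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        acc = acc + rng.normal(0.0, sd_a, acc.shape)
        gyr = gyr + rng.normal(0.0, sd_g, gyr.shape)
    return ImuRecording(acc=acc, gyr=gyr, fs=fs, foot=foot)


def scaled_template(template: StrideTemplate, **changes) -> StrideTemplate:
    """Return a copy of ``template`` with the given fields replaced."""
    return replace(template, **changes)
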