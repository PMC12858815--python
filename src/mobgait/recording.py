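"""In-memory container for a 6-axis foot-worn IMU recording."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Standard gravity, m/s^2. Accelerometer channels are expressed in g.
G0 = 9.80665

#: Column order of the on-disk CSV signal format.
CSV_COLUMNS = ("t_s", "ax_g", "ay_g", "az_g", "gx_dps", "gy_dps", "gz_dps")


@dataclass
class ImuRecording:
    """One foot's accelerometer + gyroscope stream.

    Parameters
    ----------
    acc
        (n, 3) accelerometer samples in g, sensor frame (x forward, y left,
        z up when the foot lies flat; at rest the z channel reads +1 g).
    gyr
        (n, 3) gyroscope samples in deg/s, same frame.
    fs
        Sampling rate in Hz.
    foot
        ``"left"`` or ``"right"``.
    subject
        Optional subject identifier.
    start
        Time of the first sample, seconds since the start of the recording
        day.  Stride/bout times derived from this recording are absolute
        (``start + index / fs``).
    """

    acc: np.ndarray
    gyr: np.ndarray
    fs: float
    foot: str = "left"
    subject: str | None = None
    start: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyr = np.asarray(self.gyr, dtype=float)
        if self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise ValueError("acc must have shape (n, 3)")
        if self.gyr.shape != self.acc.shape:
            raise ValueError("gyr must have the same shape as acc")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if self.foot not in ("left", "right"):
            raise ValueError("foot must be 'left' or 'right'")

    # -- basic views -------------------------------------------------
    @property
    def n(self) -> int:
        return self.acc.shape[0]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n / self.fs

    @property
    def t(self) -> np.ndarray:
        """Absolute sample times in seconds (since day start)."""
        return self.start + np.arange(self.n) / self.fs

    def acc_norm(self) -> np.ndarray:
        return np.linalg.norm(self.acc, axis=1)

    def gyr_norm(self) -> np.ndarray:
        return np.linalg.norm(self.gyr, axis=1)

    def slice(self, i0: int, i1: int) -> "ImuRecording":
        """Half-open sample slice as a new recording (views, not copies)."""
        i0 = max(0, int(i0))
        i1 = min(self.n, int(i1))
        return ImuRecording(
            acc=self.acc[i0:i1],
            gyr=self.gyr[i0:i1],
            fs=self.fs,
            foot=self.foot,
            subject=self.subject,
            start=self.start + i0 / self.fs,
            meta=self.meta,
        )

    # -- tabular round trip ------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.column_stack([self.t, self.acc, self.gyr]), columns=list(CSV_COLUMNS)
        )

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        fs: float,
        foot: str = "left",
        subject: str | None = None,
    ) -> "ImuRecording":
        missing = [c for c in CSV_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"signal table is missing column(s): {', '.join(missing)}")
        t = frame["t_s"].to_numpy(dtype=float)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        return cls(
            acc=frame[["ax_g", "ay_g", "az_g"]].to_numpy(dtype=float),
            gyr=frame[["gx_dps", "gy_dps", "gz_dps"]].to_numpy(dtype=float),
            fs=fs,
            foot=foot,
            subject=subject,
            start=float(t[0]) if t.size else 0.0,
        )
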