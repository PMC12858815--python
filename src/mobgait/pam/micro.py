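"""Micro (gait-quality) parameters: kernel-density mode and 95th percentile.

Per-bout medians of a gait metric (velocity, stride length, cadence) are
pooled over the recording period; a Gaussian kernel density with the classic
Silverman bandwidth, evaluated on a 512-point grid spanning the data range
plus three bandwidths, gives the distribution mode (the usual gait
pattern), and the empirical 95th percentile gives the maximum performance.
Estimates are only available with more than a minimum number of walking
bouts (n >= 10).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from ..config import PamConfig


@dataclass(frozen=True)
class MicroEstimate:
    mode: float
    p95: float
    available: bool
    n: int


def silverman_bandwidth(values: np.ndarray) -> float:
    """0.9 * min(sd, IQR/1.349) * n^(-1/5) (classic rule of thumb)."""
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=1)
    q75, q25 = np.percentile(x, [75, 25])
    spread = min(sd, (q75 - q25) / 1.349)
    if spread <= 0:
        spread = sd if sd > 0 else 1.0
    return 0.9 * spread * x.size ** (-0.2)


def estimate_micro(values, cfg: PamConfig | None = None) -> MicroEstimate:
    """Mode and 95th percentile of per-bout metric values."""
    cfg = cfg or PamConfig()
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = int(x.size)
    if n < cfg.min_wb_for_micro:
        return MicroEstimate(mode=float("nan"), p95=float("nan"), available=False, n=n)
    if np.ptp(x) == 0.0:
        # degenerate density: all mass at one value
        return MicroEstimate(mode=float(x[0]), p95=float(x[0]), available=True, n=n)
    bw = silverman_bandwidth(x)
    kde = gaussian_kde(x, bw_method=lambda _: bw / x.std(ddof=1))
    grid = np.linspace(x.min() - cfg.kde_grid_pad_bw * bw,
                       x.max() + cfg.kde_grid_pad_bw * bw,
                       cfg.kde_grid_points)
    density = kde(grid)
    return MicroEstimate(
        mode=float(grid[np.argmax(density)]),
        p95=float(np.percentile(x, 95)),
        available=True,
        n=n,
    )
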