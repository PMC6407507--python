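"""Bias-aware background (pseudo-absence) sampling.

Background pixels are drawn without replacement with probability proportional
to a kernel-smoothed occurrence-density surface, so the background mirrors
the geographic (and hence environmental) space actually sampled by the
occurrence data.  ``bias_bandwidth=None`` (or infinity) recovers a uniform
background over all eligible pixels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from ..grid import GridSpec

__all__ = ["BackgroundSample", "sample_background"]


@dataclass
class BackgroundSample:
    """Distinct background pixel locations plus the bias descriptor."""

    rows: np.ndarray
    cols: np.ndarray
    grid: GridSpec
    bias_bandwidth: float | None

    @property
    def n(self) -> int:
        return self.rows.size

    def lonlat(self) -> tuple[np.ndarray, np.ndarray]:
        return self.grid.center_of(self.rows, self.cols)


def sample_background(
    occurrences: pd.DataFrame,
    grid: GridSpec,
    n_max: int = 10_000,
    bias_bandwidth: float | None = None,
    seed: int = 0,
) -> BackgroundSample:
    """Draw up to ``n_max`` distinct non-nodata pixels, bias-aware.

    Weighted sampling without replacement uses Gumbel top-k keys
    (Efraimidis-Spirakis), which is exactly proportional-to-weights and
    deterministic given the seed.  When fewer eligible pixels than ``n_max``
    exist, all of them are returned with a warning.
    """
    rng = np.random.default_rng(seed)
    rows, cols = np.nonzero(grid.valid_mask)
    n_eligible = rows.size
    if n_eligible == 0:
        raise ValueError("no eligible (non-nodata) pixels to sample")

    if bias_bandwidth is None or not math.isfinite(bias_bandwidth):
        weights = np.ones(n_eligible)
    else:
        if bias_bandwidth <= 0:
            raise ValueError("bias_bandwidth must be positive")
        counts = np.zeros(grid.shape)
        r, c = grid.cell_of(
            occurrences["lon"].to_numpy(dtype=float),
            occurrences["lat"].to_numpy(dtype=float),
        )
        ok = (r >= 0) & (r < grid.n_rows) & (c >= 0) & (c < grid.n_cols)
        np.add.at(counts, (r[ok], c[ok]), 1.0)
        smoothed = gaussian_filter(counts, sigma=bias_bandwidth, mode="constant")
        # tiny floor keeps every eligible pixel reachable (and n_max attainable)
        weights = smoothed[rows, cols] + 1e-12 * max(smoothed.max(), 1.0)

    if n_max >= n_eligible:
        if n_max > n_eligible:
            warnings.warn(
                f"only {n_eligible} eligible pixels for n_max={n_max}; taking all",
                stacklevel=2,
            )
        order = np.arange(n_eligible)
    else:
        keys = np.log(weights) + rng.gumbel(size=n_eligible)
        order = np.argsort(keys)[::-1][:n_max]
        order = np.sort(order)  # row-major pixel order; selection already random
    return BackgroundSample(
        rows=rows[order], cols=cols[order], grid=grid, bias_bandwidth=bias_bandwidth
    )
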