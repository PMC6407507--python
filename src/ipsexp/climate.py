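"""Bioclimatic stack management: collinearity screening, GCM ensembling,
and point extraction."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .stack import BIO_CODES, ClimateStack

__all__ = ["screen_collinearity", "ensemble_mean", "extract_values"]


def screen_collinearity(
    stack: ClimateStack,
    sample_pixels: int | None = None,
    threshold: float = 0.85,
    seed: int = 0,
) -> tuple[list[str], pd.DataFrame]:
    """Greedy elimination of collinear variables by pairwise Pearson |r|.

    While any retained pair has ``|r| > threshold``, the member of the worst
    pair with the larger mean absolute correlation against all remaining
    variables is dropped (ties drop the later code in canonical table order).
    Constant layers are dropped first with a warning.  Correlations are
    computed over non-nodata pixels (optionally a random subsample of
    ``sample_pixels`` of them, seeded).

    Returns the retained codes in canonical order and a report of dropped
    variables with columns ``dropped, against, r, reason``.
    """
    codes = stack.codes
    if len(codes) < 2:
        raise ValueError("need at least two variables to screen")
    values, _, _ = stack.to_matrix()
    if sample_pixels is not None and sample_pixels < values.shape[0]:
        rng = np.random.default_rng(seed)
        pick = rng.choice(values.shape[0], size=sample_pixels, replace=False)
        values = values[pick]

    dropped_rows: list[dict] = []
    retained = list(codes)

    # constant layers cannot enter a correlation matrix
    sds = values.std(axis=0)
    for code, sd in zip(list(codes), sds):
        if sd == 0:
            warnings.warn(f"variable {code} is constant; dropped before screening", stacklevel=2)
            retained.remove(code)
            dropped_rows.append({"dropped": code, "against": "", "r": np.nan, "reason": "constant"})

    col_of = {c: i for i, c in enumerate(codes)}
    order = {c: i for i, c in enumerate(BIO_CODES)}

    while len(retained) >= 2:
        sub = values[:, [col_of[c] for c in retained]]
        corr = np.corrcoef(sub, rowvar=False)
        absr = np.abs(corr)
        np.fill_diagonal(absr, 0.0)
        worst = absr.max()
        if worst <= threshold:
            break
        i, j = np.unravel_index(np.argmax(absr), absr.shape)  # first occurrence in scan order
        a, b = retained[i], retained[j]
        mean_a = absr[i].sum() / (len(retained) - 1)
        mean_b = absr[j].sum() / (len(retained) - 1)
        if mean_a > mean_b:
            drop = a
        elif mean_b > mean_a:
            drop = b
        else:  # tie: drop the later in canonical table order
            drop = a if order[a] > order[b] else b
        keep = b if drop == a else a
        dropped_rows.append(
            {"dropped": drop, "against": keep, "r": float(corr[i, j]), "reason": "collinear"}
        )
        retained.remove(drop)

    report = pd.DataFrame(dropped_rows, columns=["dropped", "against", "r", "reason"])
    return retained, report


def ensemble_mean(stacks: list[ClimateStack]) -> ClimateStack:
    """Per-pixel arithmetic mean of co-registered stacks (e.g. across GCMs).

    All members must share grid geometry, scenario and variable set; a pixel
    is nodata in the output when it is nodata in any member.
    """
    if not stacks:
        raise ValueError("need at least one stack to ensemble")
    first = stacks[0]
    for s in stacks[1:]:
        if not s.grid.same_geometry(first.grid):
            raise ValueError("ensemble members are not co-registered")
        if s.scenario != first.scenario:
            raise ValueError("ensemble members must share a scenario label")
        if s.codes != first.codes:
            raise ValueError("ensemble members must share the variable set")
    mask = np.zeros(first.grid.shape, dtype=bool)
    for s in stacks:
        mask |= s.grid.nodata_mask
    grid = first.grid.copy()
    grid.nodata_mask = mask
    layers = {
        code: np.mean([s.layers[code] for s in stacks], axis=0) for code in first.codes
    }
    return ClimateStack(grid, layers, scenario=first.scenario, gcm=None)


def extract_values(
    points, stack: ClimateStack, codes=None
) -> tuple[np.ndarray, np.ndarray]:
    """Values of the containing pixel for each ``(lon, lat)`` point.

    Returns ``(matrix, valid)`` where ``matrix`` is (n points x n variables)
    with NaN rows for flagged points, and ``valid`` is False for points
    outside the grid extent or on nodata pixels.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[None, :]
    lon, lat = pts[:, 0], pts[:, 1]
    inside = stack.grid.contains(lon, lat)
    row, col = stack.grid.cell_of(lon, lat)
    row_c = np.clip(row, 0, stack.grid.n_rows - 1)
    col_c = np.clip(col, 0, stack.grid.n_cols - 1)
    valid = inside & ~stack.grid.nodata_mask[row_c, col_c]
    out = stack.values_at(row_c, col_c, codes)
    out[~valid] = np.nan
    return out, valid
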