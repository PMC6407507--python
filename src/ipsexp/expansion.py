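"""Expansion-potential statistics.

Per pixel, the multi-species suitability is the sum of retained species'
logistic suitabilities; the change map is its future-minus-current
difference.  The per-ecoregion potential is the unweighted zonal sum of the
change map; ecoregions with potential strictly greater than 0 are flagged as
included, the rest are kept in the table with ``included=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .regions import BIOME_REALM, EcoregionMap

__all__ = [
    "MultiSuitabilityMap",
    "ChangeMap",
    "multi_species_suitability",
    "suitability_change",
    "ecoregion_potential",
    "group_potentials",
    "scenario_regression",
]


@dataclass
class MultiSuitabilityMap:
    """Per-pixel summed suitability over k species (values in [0, k])."""

    values: np.ndarray
    n_species: int
    scenario: str
    nodata_contributions: np.ndarray | None = None  # count of species-nodata pixels


@dataclass
class ChangeMap:
    """Per-pixel future-minus-current summed-suitability change."""

    values: np.ndarray
    n_species: int
    scenario_pair: tuple[str, str]


def multi_species_suitability(
    maps: list[np.ndarray],
    scenario: str = "current",
) -> MultiSuitabilityMap:
    """Sum per-species suitability maps per pixel.

    ``maps`` are co-registered 2D arrays with NaN at nodata.  A species with
    nodata at a pixel contributes 0 there; the tally of such contributions is
    kept.  Pixels that are NaN in every map stay NaN.
    """
    if not maps:
        raise ValueError("need at least one species map")
    arr = np.stack([np.asarray(m, dtype=float) for m in maps])
    if arr.ndim != 3:
        raise ValueError("species maps must be 2D and co-registered")
    nan = np.isnan(arr)
    total = np.where(nan, 0.0, arr).sum(axis=0)
    all_nan = nan.all(axis=0)
    total[all_nan] = np.nan
    return MultiSuitabilityMap(
        values=total,
        n_species=arr.shape[0],
        scenario=scenario,
        nodata_contributions=nan.sum(axis=0),
    )


def suitability_change(future: MultiSuitabilityMap, current: MultiSuitabilityMap) -> ChangeMap:
    """Per-pixel difference of summed suitability (future − current)."""
    if future.n_species != current.n_species:
        raise ValueError("species sets differ between future and current maps")
    if future.values.shape != current.values.shape:
        raise ValueError("maps are not co-registered")
    return ChangeMap(
        values=future.values - current.values,
        n_species=future.n_species,
        scenario_pair=(current.scenario, future.scenario),
    )


def ecoregion_potential(change: ChangeMap, regions: EcoregionMap) -> pd.DataFrame:
    """Zonal sums of the change map per ecoregion with the >0 inclusion rule.

    Returns one row per ecoregion: ``ecoregion_id, name, biome, realm,
    scenario, n_pixels, potential, included``.  Ecoregions with zero
    non-nodata pixels get NaN potential and ``included=False`` (flagged via
    ``n_pixels == 0``).
    """
    values = np.asarray(change.values, dtype=float)
    if values.shape != regions.grid.shape:
        raise ValueError("change map is not co-registered with the ecoregion map")
    labels = regions.labels
    valid = regions.grid.valid_mask & (labels >= 0) & ~np.isnan(values)
    n_regions = len(regions.meta)
    sums = np.bincount(labels[valid], weights=values[valid], minlength=n_regions)
    counts = np.bincount(labels[valid], minlength=n_regions)
    out = regions.meta.copy()
    out["scenario"] = change.scenario_pair[1]
    out["n_pixels"] = counts[out["ecoregion_id"].to_numpy()]
    pot = sums[out["ecoregion_id"].to_numpy()]
    pot = np.where(out["n_pixels"].to_numpy() == 0, np.nan, pot)
    out["potential"] = pot
    out["included"] = out["potential"] > 0  # NaN compares False
    return out


def group_potentials(table: pd.DataFrame, by: str = "biome") -> pd.DataFrame:
    """Sum potentials of included ecoregions per group.

    ``by`` is ``"biome"`` (realms reported separately via the realm column)
    or any column of the table (e.g. ``growth_form`` after stratified runs).
    Groups with no included ecoregion report 0.
    """
    if by == "biome":
        bad = set(table["biome"]) - set(BIOME_REALM)
        if bad:
            raise ValueError(f"unknown biome codes: {sorted(bad)}")
    if by not in table.columns:
        raise ValueError(f"no column {by!r} to group by")
    inc = table[table["included"]]
    keys = [by] if by == "growth_form" else [by, "realm"]
    grouped = inc.groupby(keys)["potential"].sum()
    # keep empty groups (0) for every group present in the full table
    all_groups = table[keys].drop_duplicates().set_index(keys).index
    grouped = grouped.reindex(all_groups, fill_value=0.0)
    return grouped.reset_index().rename(columns={"potential": "potential_sum"})


def scenario_regression(potentials_x, potentials_y) -> dict:
    """OLS of one scenario's potentials on another's, paired by ecoregion.

    Returns ``slope, intercept, r2, p, n`` with a two-sided slope test.
    """
    x = np.asarray(potentials_x, dtype=float)
    y = np.asarray(potentials_y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 paired values for a regression")
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
        "p": float(res.pvalue),
        "n": int(x.size),
    }
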