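"""Ecoregion label rasters and biome/realm metadata.

Terrestrial and freshwater realms carry separate biome vocabularies; the two
realms are represented as independent label rasters (they may overlap in
space), each with its own metadata table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GridSpec

__all__ = [
    "TERRESTRIAL_BIOMES",
    "FRESHWATER_BIOMES",
    "BIOME_REALM",
    "EcoregionMap",
]

#: Terrestrial biome codes (the published code list).
TERRESTRIAL_BIOMES: tuple[str, ...] = (
    "BF",      # boreal forests / taiga
    "DXS",     # deserts and xeric shrublands
    "FGS",     # flooded grasslands and savannas
    "IW",      # inland water
    "MG",      # mangroves
    "MFWS",    # Mediterranean forests, woodlands and scrub
    "MGS",     # montane grasslands and shrublands
    "RI",      # rock and ice
    "TBMF",    # temperate broadleaf and mixed forests
    "TCF",     # temperate conifer forests
    "TGSS",    # temperate grasslands, savannas and shrublands
    "TSCF",    # tropical and subtropical coniferous forests
    "TSDBF",   # tropical and subtropical dry broadleaf forests
    "TSGSS",   # tropical and subtropical grasslands, savannas and shrublands
    "TSMBF",   # tropical and subtropical moist broadleaf forests
    "TD",      # tundra
)

#: Freshwater biome codes.
FRESHWATER_BIOMES: tuple[str, ...] = (
    "LL",      # large lakes
    "LRD",     # large river deltas
    "MF",      # montane freshwaters
    "OI",      # oceanic islands
    "PF",      # polar freshwaters
    "TCR",     # temperate coastal rivers
    "TFRW",    # temperate floodplain rivers and wetlands
    "TUR",     # temperate upland rivers
    "TSCR",    # tropical and subtropical coastal rivers
    "TSFRWC",  # tropical and subtropical floodplain rivers and wetland complexes
    "TSUR",    # tropical and subtropical upland rivers
    "XFEB",    # xeric freshwaters and endorheic basins
)

BIOME_REALM: dict[str, str] = {
    **{b: "terrestrial" for b in TERRESTRIAL_BIOMES},
    **{b: "freshwater" for b in FRESHWATER_BIOMES},
}


@dataclass
class EcoregionMap:
    """Pixel labels plus per-ecoregion metadata.

    ``labels`` is an integer grid co-registered with ``grid``; ``-1`` marks
    nodata.  ``meta`` has one row per ecoregion with columns
    ``ecoregion_id, name, biome, realm``.
    """

    grid: GridSpec
    labels: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != self.grid.shape:
            raise ValueError("labels shape does not match grid shape")
        required = {"ecoregion_id", "name", "biome", "realm"}
        if not required.issubset(self.meta.columns):
            raise ValueError(f"meta must have columns {sorted(required)}")
        bad = set(self.meta["biome"]) - set(BIOME_REALM)
        if bad:
            raise ValueError(f"unknown biome codes: {sorted(bad)}")

    @property
    def region_ids(self) -> np.ndarray:
        return self.meta["ecoregion_id"].to_numpy()

    def pixels_of(self, ecoregion_id: int) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of a region's non-nodata pixels."""
        mask = (self.labels == ecoregion_id) & self.grid.valid_mask
        return np.nonzero(mask)

    def pixel_counts(self) -> pd.Series:
        """Non-nodata pixel count per ecoregion id."""
        valid = self.grid.valid_mask & (self.labels >= 0)
        ids, counts = np.unique(self.labels[valid], return_counts=True)
        out = pd.Series(0, index=self.meta["ecoregion_id"], dtype=int)
        out.loc[ids] = counts
        return out
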