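"""Bioclimatic raster stacks.

A :class:`ClimateStack` bundles co-registered layers of the nine bioclimatic
summary variables used throughout the package, under a scenario label
(``current``, ``RCP4.5``, ``RCP8.5``) and an optional GCM tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import GridSpec

__all__ = ["BIO_CODES", "BIO_UNITS", "ClimateStack"]

#: Accepted variable codes, in canonical table order.  This order is the
#: deterministic tie-break used by collinearity screening and variable ranking.
BIO_CODES: tuple[str, ...] = (
    "Bio1",
    "Bio2",
    "Bio4",
    "Bio5",
    "Bio6",
    "Bio12",
    "Bio13",
    "Bio14",
    "Bio15",
)

BIO_UNITS: dict[str, str] = {
    "Bio1": "degC",  # annual mean temperature
    "Bio2": "degC",  # mean diurnal range
    "Bio4": "SD*100",  # temperature seasonality
    "Bio5": "degC",  # max temperature of warmest month
    "Bio6": "degC",  # min temperature of coldest month
    "Bio12": "mm",  # annual precipitation
    "Bio13": "mm",  # precipitation of wettest month
    "Bio14": "mm",  # precipitation of driest month
    "Bio15": "CV",  # precipitation seasonality
}


def sort_codes(codes) -> list[str]:
    """Return ``codes`` sorted into canonical table order."""
    order = {c: i for i, c in enumerate(BIO_CODES)}
    return sorted(codes, key=lambda c: order[c])


@dataclass
class ClimateStack:
    """Co-registered grids of bioclimatic variables for one scenario."""

    grid: GridSpec
    layers: dict[str, np.ndarray]
    scenario: str = "current"
    gcm: str | None = None

    def __post_init__(self) -> None:
        for code, layer in self.layers.items():
            if code not in BIO_CODES:
                raise ValueError(f"unknown bioclimatic variable code: {code!r}")
            layer = np.asarray(layer, dtype=float)
            if layer.shape != self.grid.shape:
                raise ValueError(f"layer {code} shape {layer.shape} != grid {self.grid.shape}")
            self.layers[code] = layer
        # keep canonical ordering for deterministic iteration
        self.layers = {c: self.layers[c] for c in sort_codes(self.layers)}

    @property
    def codes(self) -> list[str]:
        """Variable codes in canonical order."""
        return list(self.layers)

    def values_at(self, rows, cols, codes=None) -> np.ndarray:
        """Matrix (n points x n variables) of layer values at pixel indices."""
        codes = list(codes) if codes is not None else self.codes
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        out = np.empty((rows.size, len(codes)), dtype=float)
        for j, code in enumerate(codes):
            out[:, j] = self.layers[code][rows, cols]
        return out

    def to_matrix(self, codes=None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Values at all non-nodata pixels.

        Returns ``(values, rows, cols)`` where ``values`` is
        (n_valid x n variables) and rows/cols index the valid pixels in
        row-major order.
        """
        rows, cols = np.nonzero(self.grid.valid_mask)
        return self.values_at(rows, cols, codes), rows, cols

    def subset(self, codes) -> "ClimateStack":
        """A stack restricted to the given variable codes (views, not copies)."""
        return ClimateStack(
            self.grid,
            {c: self.layers[c] for c in sort_codes(codes)},
            scenario=self.scenario,
            gcm=self.gcm,
        )

    def copy(self, scenario: str | None = None, gcm: str | None = None) -> "ClimateStack":
        return ClimateStack(
            self.grid.copy(),
            {c: v.copy() for c, v in self.layers.items()},
            scenario=self.scenario if scenario is None else scenario,
            gcm=self.gcm if gcm is None else gcm,
        )
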