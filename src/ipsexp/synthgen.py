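"""Synthetic world generation: climate, scenarios, ecoregions, occurrences.

Every generator is deterministic given its seed.  The random-number contract
is ``numpy.random.default_rng(seed)`` (PCG64), whose stream is stable across
platforms and numpy releases; a single global seed can be fanned out to
per-component child seeds by fixed offsets (see :func:`child_seed`).

The generated world has analytic ground truth: each species' occupancy
probability is a product of per-variable Gaussian kernels
(:class:`NicheSpec`), so downstream suitability models can be scored against
the exact surface they are trying to recover.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grid import GridSpec
from .regions import BIOME_REALM, EcoregionMap
from .stack import BIO_CODES, ClimateStack

__all__ = [
    "GROWTH_FORMS",
    "NicheSpec",
    "ScenarioDelta",
    "child_seed",
    "generate_climate",
    "apply_scenario",
    "generate_ecoregions",
    "sample_occurrences",
]

GROWTH_FORMS: tuple[str, ...] = (
    "palm",
    "succulent",
    "alga",
    "fern",
    "aquatic plant",
    "vine",
    "shrub",
    "tree",
    "herb",
)

# Fixed offsets fanning one global seed out to per-component streams, so each
# module run is reproducible in isolation.
_SEED_OFFSETS = {
    "climate": 1000,
    "ecoregions": 2000,
    "occurrences": 3000,
    "background": 4000,
    "folds": 5000,
}


def child_seed(seed: int, component: str, index: int = 0) -> int:
    """Derive a per-component child seed from a global seed."""
    return int(seed) * 100_000 + _SEED_OFFSETS[component] + index


# ---------------------------------------------------------------------------
# climate fields
# ---------------------------------------------------------------------------

# (mean, sd of the random field, gradient amplitude over the normalised
#  latitude span [-1, 1], nonnegative?)  Negative amplitude = warmer toward
#  low latitudes regardless of grid extent.
_VAR_PARAMS: dict[str, tuple[float, float, float, bool]] = {
    "Bio1": (14.0, 4.0, -8.0, False),
    "Bio2": (10.0, 2.0, 0.0, False),
    "Bio4": (600.0, 150.0, 300.0, True),
    "Bio5": (26.0, 4.0, -8.0, False),
    "Bio6": (2.0, 4.0, -8.0, False),
    "Bio12": (1000.0, 400.0, 0.0, True),
    "Bio13": (180.0, 80.0, 0.0, True),
    "Bio14": (40.0, 30.0, 0.0, True),
    "Bio15": (50.0, 20.0, 0.0, True),
}


def _smooth_field(rng: np.random.Generator, shape, autocorr_scale: float) -> np.ndarray:
    """Unit-variance spatially autocorrelated Gaussian field."""
    noise = rng.standard_normal(shape)
    smoothed = gaussian_filter(noise, sigma=autocorr_scale, mode="reflect")
    sd = smoothed.std()
    if sd == 0:  # pragma: no cover - only for degenerate 1x1 grids
        return smoothed
    return smoothed / sd


def generate_climate(
    grid: GridSpec,
    seed: int,
    autocorr_scale: float = 5.0,
    consistent: bool = True,
) -> ClimateStack:
    """Generate the nine bioclimatic layers as smoothed random fields.

    Temperature variables receive a latitudinal gradient (warmer toward low
    latitudes); precipitation variables are clipped to be nonnegative.  With
    ``consistent=True`` (default) the per-pixel ordering
    ``Bio6 <= Bio1 <= Bio5`` is enforced by sorting, so the world is
    physically plausible; independent fields (``consistent=False``) are
    useful when uncorrelated drivers are needed.
    """
    if autocorr_scale <= 0:
        raise ValueError("autocorr_scale must be positive")
    rng = np.random.default_rng(seed)
    lat = grid.lat_grid()
    half_span = max((lat.max() - lat.min()) / 2.0, 1e-12)
    lat_norm = (lat - lat.mean()) / half_span  # in [-1, 1]
    layers: dict[str, np.ndarray] = {}
    for code in BIO_CODES:
        mean, sd, amp, nonneg = _VAR_PARAMS[code]
        layer = mean + amp * lat_norm + sd * _smooth_field(rng, grid.shape, autocorr_scale)
        if nonneg:
            layer = np.clip(layer, 0.0, None)
        layers[code] = layer
    if consistent:
        triple = np.sort(np.stack([layers["Bio6"], layers["Bio1"], layers["Bio5"]]), axis=0)
        layers["Bio6"], layers["Bio1"], layers["Bio5"] = triple[0], triple[1], triple[2]
    return ClimateStack(grid, layers, scenario="current")


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------


@dataclass
class ScenarioDelta:
    """Per-variable additive shifts turning a current stack into a future one.

    ``deltas`` maps variable codes to scalars or grids; variables absent from
    the mapping are unchanged.  The ``current`` scenario must carry all-zero
    deltas.
    """

    scenario: str
    deltas: dict[str, object] = field(default_factory=dict)
    gcm: str | None = None

    def __post_init__(self) -> None:
        if self.scenario == "current":
            for code, d in self.deltas.items():
                if np.any(np.asarray(d, dtype=float) != 0.0):
                    raise ValueError("current scenario must have all-zero deltas")

    def delta_grid(self, code: str, grid: GridSpec) -> np.ndarray:
        d = np.asarray(self.deltas.get(code, 0.0), dtype=float)
        if d.ndim == 0:
            return np.full(grid.shape, float(d))
        if d.shape != grid.shape:
            raise ValueError(f"delta grid for {code} is not co-registered with the stack")
        return d

    def scaled(self, factor: float, scenario: str | None = None) -> "ScenarioDelta":
        """A delta with every shift multiplied by ``factor``."""
        return ScenarioDelta(
            scenario=self.scenario if scenario is None else scenario,
            deltas={c: np.asarray(d, dtype=float) * factor for c, d in self.deltas.items()},
            gcm=self.gcm,
        )


def apply_scenario(stack: ClimateStack, delta: ScenarioDelta) -> ClimateStack:
    """Future stack = current + per-pixel deltas."""
    layers = {
        code: layer + delta.delta_grid(code, stack.grid)
        for code, layer in stack.layers.items()
    }
    return ClimateStack(stack.grid, layers, scenario=delta.scenario, gcm=delta.gcm)


# ---------------------------------------------------------------------------
# ecoregions
# ---------------------------------------------------------------------------


def generate_ecoregions(
    grid: GridSpec,
    n_regions: int,
    biome_table,
    seed: int,
    realm: str | None = None,
) -> EcoregionMap:
    """Tessellate the grid into contiguous ecoregions by nearest-seed growth.

    ``n_regions`` seed pixels are drawn among non-nodata pixels; every valid
    pixel is labelled with the nearest seed (Euclidean distance in pixel
    space, ties broken by lowest seed index).  Biomes are assigned by cycling
    through ``biome_table``; realm is inferred from the biome vocabulary.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    rows, cols = np.nonzero(grid.valid_mask)
    if n_regions > rows.size:
        raise ValueError("n_regions exceeds the number of non-nodata pixels")
    biome_table = list(biome_table)
    bad = set(biome_table) - set(BIOME_REALM)
    if bad:
        raise ValueError(f"unknown biome codes: {sorted(bad)}")
    rng = np.random.default_rng(seed)
    pick = rng.choice(rows.size, size=n_regions, replace=False)
    seed_rc = np.stack([rows[pick], cols[pick]], axis=1).astype(float)
    pix = np.stack([rows, cols], axis=1).astype(float)
    # distance from every valid pixel to every seed; argmin gives the lowest
    # seed index on ties, which keeps the tessellation deterministic
    d2 = ((pix[:, None, :] - seed_rc[None, :, :]) ** 2).sum(axis=2)
    nearest = np.argmin(d2, axis=1)
    labels = np.full(grid.shape, -1, dtype=int)
    labels[rows, cols] = nearest
    biomes = [biome_table[i % len(biome_table)] for i in range(n_regions)]
    meta = pd.DataFrame(
        {
            "ecoregion_id": np.arange(n_regions),
            "name": [f"region_{i:03d}" for i in range(n_regions)],
            "biome": biomes,
            "realm": [BIOME_REALM[b] if realm is None else realm for b in biomes],
        }
    )
    return EcoregionMap(grid, labels, meta)


# ---------------------------------------------------------------------------
# species and occurrences
# ---------------------------------------------------------------------------


@dataclass
class NicheSpec:
    """Axis-aligned Gaussian niche with analytic occupancy surface."""

    species_id: str
    growth_form: str
    optimum: dict[str, float]
    breadth: dict[str, float]
    max_prob: float = 1.0

    def __post_init__(self) -> None:
        if self.growth_form not in GROWTH_FORMS:
            raise ValueError(f"unknown growth form: {self.growth_form!r}")
        if not 0 < self.max_prob <= 1:
            raise ValueError("max_prob must be in (0, 1]")
        if set(self.optimum) != set(self.breadth):
            raise ValueError("optimum and breadth must cover the same variables")
        for code, b in self.breadth.items():
            if b <= 0:
                raise ValueError(f"breadth for {code} must be positive")

    def occupancy(self, stack: ClimateStack) -> np.ndarray:
        """True occupancy probability grid, in [0, 1] everywhere."""
        occ = np.full(stack.grid.shape, self.max_prob)
        for code, opt in self.optimum.items():
            z = (stack.layers[code] - opt) / self.breadth[code]
            occ = occ * np.exp(-0.5 * z * z)
        occ[stack.grid.nodata_mask] = 0.0
        return occ

    @property
    def name(self) -> str:
        """A binomial-style display name passing the default validity check."""
        return "Invasia " + self.species_id.replace("_", "").lower()


@dataclass
class Contamination:
    """Counts of contaminant records to inject, one per cleaning rule."""

    n_cell_duplicates: int = 0
    n_zero_zero: int = 0
    n_lon_eq_lat: int = 0
    n_bad_names: int = 0


def sample_occurrences(
    niche: NicheSpec,
    stack: ClimateStack,
    n_clean: int,
    contamination: Contamination | None = None,
    seed: int = 0,
    replace: bool = False,
) -> pd.DataFrame:
    """Draw occurrence records from the niche's true occupancy surface.

    Clean records are drawn over non-nodata pixels with probability
    proportional to occupancy and jittered uniformly within their pixel.
    With ``replace=False`` (default) pixels are distinct, so clean records
    never trigger the cell-duplicate cleaning rule and injected contaminant
    counts are exactly recoverable; ``replace=True`` gives exact
    proportionality to occupancy (the sampling contract tested by the
    goodness-of-fit property).

    Contaminant records are appended after the clean block and flagged in the
    hidden ground-truth column ``_truth`` with one of ``cell_duplicate``,
    ``zero_zero``, ``lon_eq_lat``, ``bad_name`` (clean rows carry ``clean``).
    """
    if n_clean < 1:
        raise ValueError("n_clean must be >= 1")
    contamination = contamination or Contamination()
    rng = np.random.default_rng(seed)
    # warn (not error) when the optimum sits outside the climate's range
    for code, opt in niche.optimum.items():
        layer = stack.layers[code][stack.grid.valid_mask]
        if opt < layer.min() or opt > layer.max():
            warnings.warn(
                f"niche optimum for {code} lies outside the climate range; species may be rare",
                stacklevel=2,
            )
    occ = niche.occupancy(stack)
    rows, cols = np.nonzero(stack.grid.valid_mask)
    weights = occ[rows, cols]
    total = weights.sum()
    if total <= 0:
        raise ValueError("occupancy surface is zero everywhere on valid pixels")
    n_positive = int((weights > 0).sum())
    if not replace and n_clean > n_positive:
        raise ValueError(
            f"cannot draw {n_clean} distinct occupied pixels; only {n_positive} have occupancy > 0"
        )
    idx = rng.choice(rows.size, size=n_clean, replace=replace, p=weights / total)
    jitter_lon = rng.uniform(0.0, 1.0, size=n_clean)
    jitter_lat = rng.uniform(0.0, 1.0, size=n_clean)
    cell = stack.grid.cell_size
    lon = stack.grid.origin_lon + (cols[idx] + jitter_lon) * cell
    lat = stack.grid.origin_lat + (rows[idx] + jitter_lat) * cell

    records: list[dict] = [
        {
            "species": niche.species_id,
            "growth_form": niche.growth_form,
            "lon": lon[i],
            "lat": lat[i],
            "name_raw": niche.name,
            "_truth": "clean",
        }
        for i in range(n_clean)
    ]

    def _base(truth: str, lon_v: float, lat_v: float, name: str | None = None) -> dict:
        return {
            "species": niche.species_id,
            "growth_form": niche.growth_form,
            "lon": lon_v,
            "lat": lat_v,
            "name_raw": niche.name if name is None else name,
            "_truth": truth,
        }

    for _ in range(contamination.n_cell_duplicates):
        j = int(rng.integers(n_clean))
        # re-jitter inside the same cell as a clean record
        records.append(
            _base(
                "cell_duplicate",
                stack.grid.origin_lon + (cols[idx[j]] + rng.uniform()) * cell,
                stack.grid.origin_lat + (rows[idx[j]] + rng.uniform()) * cell,
            )
        )
    for _ in range(contamination.n_zero_zero):
        records.append(_base("zero_zero", 0.0, 0.0))
    for _ in range(contamination.n_lon_eq_lat):
        v = float(rng.uniform(1.0, 60.0))
        records.append(_base("lon_eq_lat", v, v))
    for i in range(contamination.n_bad_names):
        r, c = rows[int(rng.integers(rows.size))], cols[int(rng.integers(cols.size))]
        records.append(
            _base(
                "bad_name",
                stack.grid.origin_lon + (c + rng.uniform()) * cell,
                stack.grid.origin_lat + (r + rng.uniform()) * cell,
                name=f"??badname{i}!!",
            )
        )
    return pd.DataFrame.from_records(records)
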