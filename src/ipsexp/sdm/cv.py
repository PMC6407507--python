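"""k-fold cross-validated model fitting and averaged suitability maps."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..stack import ClimateStack
from .background import BackgroundSample, sample_background
from .features import FeatureSet, build_hinge_features
from .maxent import SuitabilityModel, fit_maxent

__all__ = ["CvResult", "cross_validate"]


@dataclass
class CvResult:
    """Per-fold models plus the fold-averaged logistic suitability map."""

    species_id: str
    models: list[SuitabilityModel]
    folds: list[tuple[np.ndarray, np.ndarray]]  # (train_idx, test_idx) per fold
    logistic_maps: list[np.ndarray]
    mean_logistic: np.ndarray
    background: BackgroundSample
    presence_values: np.ndarray  # climate values at presence pixels
    presence_rows: np.ndarray
    presence_cols: np.ndarray
    codes: list[str]

    @property
    def k(self) -> int:
        return len(self.models)

    def mean_logistic_on(self, stack: ClimateStack) -> np.ndarray:
        """Fold-averaged logistic suitability projected onto another stack."""
        maps = [m.predict(stack, "logistic") for m in self.models]
        return np.mean(maps, axis=0)


def _partition(n: int, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Disjoint folds of near-equal size; deterministic given seed."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_sets = np.array_split(perm, k)
    folds = []
    for t in test_sets:
        train = np.setdiff1d(perm, t)
        folds.append((np.sort(train), np.sort(t)))
    return folds


def cross_validate(
    occurrences: pd.DataFrame,
    stack: ClimateStack,
    k: int = 10,
    seed: int = 0,
    n_background: int = 10_000,
    bias_bandwidth: float | None = None,
    beta: float = 1.5,
    n_knots: int = 20,
    codes: list[str] | None = None,
    background: BackgroundSample | None = None,
    tol: float = 1e-8,
    max_iter: int = 5000,
) -> CvResult:
    """Fit one model per fold and average the per-pixel logistic maps.

    ``occurrences`` holds one species' cleaned records (columns ``lon``,
    ``lat``).  Presences on nodata pixels or outside the grid are dropped.
    The background is sampled once per species and shared across folds; knot
    placement is refit per fold from that fold's training presences plus the
    background.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    species_id = str(occurrences["species"].iloc[0]) if "species" in occurrences else ""
    lon = occurrences["lon"].to_numpy(dtype=float)
    lat = occurrences["lat"].to_numpy(dtype=float)
    inside = stack.grid.contains(lon, lat)
    row, col = stack.grid.cell_of(lon, lat)
    row, col = row[inside], col[inside]
    ok = ~stack.grid.nodata_mask[row, col]
    row, col = row[ok], col[ok]
    m = row.size
    if k > m:
        raise ValueError(f"k={k} exceeds usable presence count {m}")

    codes = list(codes) if codes is not None else stack.codes
    if background is None:
        background = sample_background(
            occurrences.iloc[np.nonzero(inside)[0][ok]],
            stack.grid,
            n_max=n_background,
            bias_bandwidth=bias_bandwidth,
            seed=seed + 1,
        )
    pres_values = stack.values_at(row, col, codes)
    bg_values = stack.values_at(background.rows, background.cols, codes)

    folds = _partition(m, k, seed)
    models: list[SuitabilityModel] = []
    maps: list[np.ndarray] = []
    for fold_i, (train_idx, _test_idx) in enumerate(folds):
        train_values = pres_values[train_idx]
        fs = build_hinge_features(
            np.vstack([train_values, bg_values]), codes, n_knots_per_variable=n_knots
        )
        model = fit_maxent(
            fs.transform(train_values),
            fs.transform(bg_values),
            fs,
            beta=beta,
            tol=tol,
            max_iter=max_iter,
            meta={"species": species_id, "fold": fold_i, "k": k, "seed": seed},
        )
        models.append(model)
        maps.append(model.predict(stack, "logistic"))

    return CvResult(
        species_id=species_id,
        models=models,
        folds=folds,
        logistic_maps=maps,
        mean_logistic=np.mean(maps, axis=0),
        background=background,
        presence_values=pres_values,
        presence_rows=row,
        presence_cols=col,
        codes=codes,
    )
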