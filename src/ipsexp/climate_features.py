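"""Climate-feature attribution.

Variable importance is defined from jackknife training-gain drops: the full
model's gain minus the gain of a model refit without the variable, floored at
zero and normalised to percent contributions summing to 100.  With-only
gains (one variable at a time) are reported alongside.  Downstream, the
change of a climate variable per ecoregion is the difference of its zonal
spatial means between future and current stacks, which feeds per-biome OLS
regressions against expansion potential and per-biome mean/SD summaries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .regions import EcoregionMap
from .stack import BIO_CODES, ClimateStack
from .sdm.features import build_hinge_features
from .sdm.maxent import SuitabilityModel, fit_maxent

__all__ = [
    "training_gain",
    "jackknife_importance",
    "mean_importance",
    "select_top_variables",
    "variable_change",
    "potential_vs_change_regression",
    "biome_change_summary",
]


def training_gain(model: SuitabilityModel, presence_values: np.ndarray) -> float:
    """Mean presence log-likelihood above the uniform-background baseline."""
    raw = model.raw_from_values(presence_values)
    n_bg = model.bg_raw_sorted.size
    with np.errstate(divide="ignore"):
        ll = np.log(raw)
    return float(np.mean(ll) + np.log(n_bg))


def jackknife_importance(
    presence_values: np.ndarray,
    background_values: np.ndarray,
    codes,
    beta: float = 1.5,
    n_knots: int = 20,
    tol: float = 1e-8,
    max_iter: int = 5000,
    with_only: bool = True,
) -> pd.DataFrame:
    """Jackknife variable importance for one species.

    Returns a frame indexed by variable code with columns ``gain_without``,
    ``gain_with_only``, ``raw_importance`` (``max(0, G_full − G_without)``)
    and ``percent`` (normalised to sum to 100).  A single-variable model is
    trivially 100%.  ``with_only=False`` skips the with-only refits (the
    percent contributions do not depend on them).
    """
    codes = list(codes)
    pres = np.asarray(presence_values, dtype=float)
    bg = np.asarray(background_values, dtype=float)

    def _fit(sub_codes):
        cols = [codes.index(c) for c in sub_codes]
        fs = build_hinge_features(
            np.vstack([pres[:, cols], bg[:, cols]]), sub_codes, n_knots_per_variable=n_knots
        )
        model = fit_maxent(
            fs.transform(pres[:, cols]),
            fs.transform(bg[:, cols]),
            fs,
            beta=beta,
            tol=tol,
            max_iter=max_iter,
        )
        return training_gain(model, pres[:, cols])

    g_full = _fit(codes)
    rows = []
    for code in codes:
        if len(codes) == 1:
            rows.append({"code": code, "gain_without": 0.0, "gain_with_only": g_full})
            continue
        without = [c for c in codes if c != code]
        rows.append(
            {
                "code": code,
                "gain_without": _fit(without),
                "gain_with_only": _fit([code]) if with_only else np.nan,
            }
        )
    out = pd.DataFrame(rows).set_index("code")
    out["raw_importance"] = np.maximum(0.0, g_full - out["gain_without"])
    total = out["raw_importance"].sum()
    if total > 0:
        out["percent"] = 100.0 * out["raw_importance"] / total
    else:  # nothing explains anything: spread uniformly so percents still sum to 100
        out["percent"] = 100.0 / len(out)
    out.attrs["gain_full"] = g_full
    return out


def mean_importance(per_species: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Cross-species mean percent contribution per variable."""
    frames = {sp: df["percent"] for sp, df in per_species.items()}
    wide = pd.DataFrame(frames)
    out = pd.DataFrame({"mean_percent": wide.mean(axis=1)})
    return out


def select_top_variables(importance: pd.DataFrame, k: int = 2) -> list[str]:
    """Top-k variables by mean percent contribution, canonical-order ties."""
    col = "mean_percent" if "mean_percent" in importance.columns else "percent"
    order = {c: i for i, c in enumerate(BIO_CODES)}
    ranked = sorted(
        importance.index, key=lambda c: (-float(importance.loc[c, col]), order.get(c, 99))
    )
    return ranked[:k]


def variable_change(
    current: ClimateStack,
    future: ClimateStack,
    regions: EcoregionMap,
    variable: str,
) -> pd.DataFrame:
    """Per-ecoregion change of a variable's zonal spatial mean.

    Returns ``ecoregion_id, biome, realm, v_current, v_future, cv`` where
    ``cv = v_future − v_current``; empty ecoregions are flagged with NaN.
    """
    if not current.grid.same_geometry(regions.grid):
        raise ValueError("stacks are not co-registered with the ecoregion map")
    cur = current.layers[variable]
    fut = future.layers[variable]
    labels = regions.labels
    valid = regions.grid.valid_mask & (labels >= 0)
    n = len(regions.meta)
    counts = np.bincount(labels[valid], minlength=n).astype(float)
    sum_c = np.bincount(labels[valid], weights=cur[valid], minlength=n)
    sum_f = np.bincount(labels[valid], weights=fut[valid], minlength=n)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_c = np.where(counts > 0, sum_c / counts, np.nan)
        mean_f = np.where(counts > 0, sum_f / counts, np.nan)
    ids = regions.meta["ecoregion_id"].to_numpy()
    out = regions.meta[["ecoregion_id", "biome", "realm"]].copy()
    out["variable"] = variable
    out["v_current"] = mean_c[ids]
    out["v_future"] = mean_f[ids]
    out["cv"] = out["v_future"] - out["v_current"]
    return out


def potential_vs_change_regression(
    potentials: pd.DataFrame,
    cv: pd.DataFrame,
    biome: str | None = None,
    min_n: int = 3,
) -> pd.DataFrame:
    """Per-biome OLS of ecoregion expansion potential on variable change.

    ``potentials`` is an ecoregion potential table; ``cv`` comes from
    :func:`variable_change`.  One row per biome with ``r2, p, slope, n`` and
    a ``flag`` column (``ok``, ``too_few``, ``zero_variance``); biomes below
    ``min_n`` ecoregions are flagged, not dropped.
    """
    merged = potentials.merge(
        cv[["ecoregion_id", "cv"]], on="ecoregion_id", how="inner"
    ).dropna(subset=["potential", "cv"])
    biomes = [biome] if biome is not None else sorted(merged["biome"].unique())
    rows = []
    for b in biomes:
        sub = merged[merged["biome"] == b]
        row = {
            "biome": b,
            "realm": sub["realm"].iloc[0] if len(sub) else "",
            "variable": cv["variable"].iloc[0] if "variable" in cv.columns else "",
            "n": len(sub),
        }
        if len(sub) < min_n:
            row.update({"r2": np.nan, "p": np.nan, "slope": np.nan, "flag": "too_few"})
        elif sub["cv"].std() == 0:
            row.update({"r2": np.nan, "p": np.nan, "slope": np.nan, "flag": "zero_variance"})
        else:
            res = stats.linregress(sub["cv"].to_numpy(), sub["potential"].to_numpy())
            row.update(
                {
                    "r2": float(res.rvalue**2),
                    "p": float(res.pvalue),
                    "slope": float(res.slope),
                    "flag": "ok",
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)


def biome_change_summary(cv: pd.DataFrame, potentials: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample SD of variable change per biome, over included
    ecoregions only; biomes with fewer than two included ecoregions report
    SD as NaN."""
    inc = potentials[potentials["included"]][["ecoregion_id", "biome"]]
    merged = inc.merge(cv[["ecoregion_id", "cv"]], on="ecoregion_id", how="inner")
    rows = []
    for b, sub in merged.groupby("biome"):
        vals = sub["cv"].dropna().to_numpy()
        rows.append(
            {
                "biome": b,
                "variable": cv["variable"].iloc[0] if "variable" in cv.columns else "",
                "n": vals.size,
                "mean": float(vals.mean()) if vals.size else np.nan,
                "sd": float(vals.std(ddof=1)) if vals.size >= 2 else np.nan,
            }
        )
    return pd.DataFrame(rows)
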