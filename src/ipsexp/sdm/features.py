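"""Hinge feature construction.

For each variable, the feature set holds the training min/max and a strictly
increasing list of interior knots placed at empirical quantiles of the
combined presence + background sample.  Features (all min-max bounded to
[0, 1]):

* the raw linear term ``(x - min) / (max - min)``;
* a left hinge per knot, ``max(0, (x - k) / (max - k))``;
* a right hinge per knot, ``max(0, (k - x) / (k - min))``.

At projection time values are clamped to the training range, so feature
values never extrapolate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["VariableFeatures", "FeatureSet", "build_hinge_features"]


@dataclass
class VariableFeatures:
    code: str
    vmin: float
    vmax: float
    knots: np.ndarray  # strictly increasing, strictly inside (vmin, vmax)

    @property
    def n_features(self) -> int:
        if self.vmax <= self.vmin:
            return 0
        return 1 + 2 * len(self.knots)

    def transform(self, x: np.ndarray) -> np.ndarray:
        """Feature columns for one variable; clamps to the training range."""
        if self.n_features == 0:
            return np.empty((x.shape[0], 0))
        x = np.clip(np.asarray(x, dtype=float), self.vmin, self.vmax)
        cols = [(x - self.vmin) / (self.vmax - self.vmin)]
        for k in self.knots:
            cols.append(np.maximum(0.0, (x - k) / (self.vmax - k)))
        for k in self.knots:
            cols.append(np.maximum(0.0, (k - x) / (k - self.vmin)))
        return np.stack(cols, axis=1)

    def feature_names(self) -> list[str]:
        names = [f"{self.code}:linear"]
        names += [f"{self.code}:hingeL@{k:.6g}" for k in self.knots]
        names += [f"{self.code}:hingeR@{k:.6g}" for k in self.knots]
        return names if self.n_features else []


@dataclass
class FeatureSet:
    """Ordered hinge features over a list of variables."""

    variables: list[VariableFeatures]

    @property
    def codes(self) -> list[str]:
        return [v.code for v in self.variables]

    @property
    def n_features(self) -> int:
        return sum(v.n_features for v in self.variables)

    def transform(self, values: np.ndarray) -> np.ndarray:
        """Design matrix (n rows x n features) from a values matrix whose
        columns follow ``self.codes`` order."""
        values = np.asarray(values, dtype=float)
        if values.ndim == 1:
            values = values[None, :]
        if values.shape[1] != len(self.variables):
            raise ValueError(
                f"expected {len(self.variables)} variable columns, got {values.shape[1]}"
            )
        blocks = [v.transform(values[:, j]) for j, v in enumerate(self.variables)]
        return np.concatenate(blocks, axis=1) if blocks else np.empty((values.shape[0], 0))

    def feature_names(self) -> list[str]:
        out: list[str] = []
        for v in self.variables:
            out.extend(v.feature_names())
        return out

    def subset(self, codes) -> "FeatureSet":
        """Features restricted to the given variables (training ranges kept)."""
        keep = set(codes)
        return FeatureSet([v for v in self.variables if v.code in keep])

    def to_dict(self) -> dict:
        return {
            "variables": [
                {
                    "code": v.code,
                    "vmin": v.vmin,
                    "vmax": v.vmax,
                    "knots": [float(k) for k in v.knots],
                }
                for v in self.variables
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSet":
        return cls(
            [
                VariableFeatures(
                    code=v["code"],
                    vmin=float(v["vmin"]),
                    vmax=float(v["vmax"]),
                    knots=np.asarray(v["knots"], dtype=float),
                )
                for v in d["variables"]
            ]
        )


def build_hinge_features(
    values: np.ndarray,
    codes,
    n_knots_per_variable: int = 20,
) -> FeatureSet:
    """Place hinge knots at empirical quantiles of the combined sample.

    ``values`` is the stacked presence + background values matrix, one column
    per code.  Constant variables yield zero features (with a warning).
    """
    values = np.asarray(values, dtype=float)
    codes = list(codes)
    if values.ndim != 2 or values.shape[1] != len(codes):
        raise ValueError("values must be a matrix with one column per variable code")
    if n_knots_per_variable < 1:
        raise ValueError("need at least one knot per variable")
    variables: list[VariableFeatures] = []
    qs = np.linspace(0.0, 1.0, n_knots_per_variable + 2)[1:-1]
    for j, code in enumerate(codes):
        x = values[:, j]
        x = x[~np.isnan(x)]
        vmin, vmax = float(x.min()), float(x.max())
        if vmax <= vmin:
            warnings.warn(f"variable {code} is constant; no features built", stacklevel=2)
            variables.append(VariableFeatures(code, vmin, vmax, np.empty(0)))
            continue
        knots = np.unique(np.quantile(x, qs))
        knots = knots[(knots > vmin) & (knots < vmax)]
        variables.append(VariableFeatures(code, vmin, vmax, knots))
    return FeatureSet(variables)
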