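"""Penalised Gibbs-density estimation (the maximum-entropy SDM core).

The model is the Gibbs distribution ``q(x) ∝ exp(λ·f(x))`` normalised over
the background sample.  Fitting minimises the convex objective

    J(λ) = logsumexp_background(λ·f) − mean_presence(λ·f)
           + Σ_f β · s_f / √m · |λ_f|

where ``s_f`` is the feature's standard deviation over presences and ``m``
the presence count.  The L1 term is handled by the standard split
``λ = a − b`` with ``a, b ≥ 0``, which leaves a smooth bound-constrained
problem solved with L-BFGS-B.

Outputs follow the three conventional scales:

* raw — ``q`` normalised over the training background (sums to 1 there);
* cumulative — ``100 · Σ_{y: raw(y) ≤ raw(x)} raw(y)`` over the background;
* logistic — ``e^H q / (1 + e^H q)`` with ``H`` the entropy of the fitted
  raw distribution, a value in (0, 1) read as suitability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from ..stack import ClimateStack
from .features import FeatureSet

__all__ = ["ConvergenceError", "SuitabilityModel", "fit_maxent"]

_REG_FLOOR = 1e-4  # lower bound on s_f so no feature is entirely unpenalised


class ConvergenceError(RuntimeError):
    """Raised when the optimiser stops before meeting tolerance."""

    def __init__(self, message: str, grad_norm: float):
        super().__init__(f"{message} (final gradient norm {grad_norm:.3e})")
        self.grad_norm = grad_norm


@dataclass
class SuitabilityModel:
    """A fitted maximum-entropy suitability model."""

    featureset: FeatureSet
    weights: np.ndarray  # λ per feature
    beta: float
    log_z: float  # logsumexp of λ·f over the training background
    entropy: float  # H of the fitted raw distribution over the background
    bg_raw_sorted: np.ndarray = field(repr=False)  # ascending training raws
    bg_raw_cumsum: np.ndarray = field(repr=False)
    trace: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    meta: dict = field(default_factory=dict)

    # -- score computation ----------------------------------------------

    def eta(self, design: np.ndarray) -> np.ndarray:
        return design @ self.weights

    def raw_from_values(self, values: np.ndarray) -> np.ndarray:
        """Raw density at climate-values rows (normalised over training bg)."""
        design = self.featureset.transform(values)
        with np.errstate(over="ignore"):
            return np.exp(self.eta(design) - self.log_z)

    def cumulative_from_raw(self, raw: np.ndarray) -> np.ndarray:
        """Cumulative score: 100 x total background raw mass at or below."""
        raw = np.asarray(raw, dtype=float)
        idx = np.searchsorted(self.bg_raw_sorted, raw, side="right")
        cum = np.concatenate([[0.0], self.bg_raw_cumsum])
        return 100.0 * cum[idx]

    def logistic_from_raw(self, raw: np.ndarray) -> np.ndarray:
        # expit(H + log raw) = e^H raw / (1 + e^H raw), stable for huge raws
        raw = np.asarray(raw, dtype=float)
        with np.errstate(divide="ignore"):
            return expit(self.entropy + np.log(raw))

    # -- projection -------------------------------------------------------

    def predict(self, stack: ClimateStack, output: str = "logistic") -> np.ndarray:
        """Project onto a stack; returns a grid with NaN at nodata pixels.

        ``output`` is one of ``raw``, ``cumulative``, ``logistic``.  Feature
        values are clamped to the training range (no extrapolation).
        """
        missing = set(self.featureset.codes) - set(stack.codes)
        if missing:
            raise ValueError(f"stack is missing model variables: {sorted(missing)}")
        values, rows, cols = stack.to_matrix(self.featureset.codes)
        raw = self.raw_from_values(values)
        if output == "raw":
            scores = raw
        elif output == "cumulative":
            scores = self.cumulative_from_raw(raw)
        elif output == "logistic":
            scores = self.logistic_from_raw(raw)
        else:
            raise ValueError(f"unknown output scale: {output!r}")
        out = np.full(stack.grid.shape, np.nan)
        out[rows, cols] = scores
        return out

    # -- serialisation ----------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "featureset": self.featureset.to_dict(),
            "weights": self.weights.tolist(),
            "beta": self.beta,
            "log_z": self.log_z,
            "entropy": self.entropy,
            "bg_raw_sorted": self.bg_raw_sorted.tolist(),
            "meta": self.meta,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "SuitabilityModel":
        d = json.loads(Path(path).read_text())
        bg_raw = np.asarray(d["bg_raw_sorted"], dtype=float)
        return cls(
            featureset=FeatureSet.from_dict(d["featureset"]),
            weights=np.asarray(d["weights"], dtype=float),
            beta=float(d["beta"]),
            log_z=float(d["log_z"]),
            entropy=float(d["entropy"]),
            bg_raw_sorted=bg_raw,
            bg_raw_cumsum=np.cumsum(bg_raw),
            meta=d.get("meta", {}),
        )


def fit_maxent(
    presence_design: np.ndarray,
    background_design: np.ndarray,
    featureset: FeatureSet,
    beta: float = 1.5,
    tol: float = 1e-8,
    max_iter: int = 5000,
    meta: dict | None = None,
) -> SuitabilityModel:
    """Fit the penalised Gibbs model; see module docstring for the objective.

    ``presence_design`` and ``background_design`` are design matrices from
    ``featureset.transform``.  Raises :class:`ConvergenceError` when the
    optimiser fails to meet tolerance within ``max_iter`` iterations.
    """
    Fp = np.asarray(presence_design, dtype=float)
    Fb = np.asarray(background_design, dtype=float)
    if Fp.ndim != 2 or Fb.ndim != 2 or Fp.shape[1] != Fb.shape[1]:
        raise ValueError("presence and background designs must share feature columns")
    m, d = Fp.shape
    if m < 1 or Fb.shape[0] < 2:
        raise ValueError("need >= 1 presence row and >= 2 background rows")

    fbar = Fp.mean(axis=0)
    s_f = Fp.std(axis=0)
    reg = beta * np.maximum(s_f, _REG_FLOOR) / np.sqrt(m)

    trace: list[float] = []

    def objective(theta: np.ndarray):
        lam = theta[:d] - theta[d:]
        eta_bg = Fb @ lam
        lse = logsumexp(eta_bg)
        nll = lse - fbar @ lam
        q = np.exp(eta_bg - lse)
        grad_lam = Fb.T @ q - fbar
        obj = nll + reg @ (theta[:d] + theta[d:])
        grad = np.concatenate([grad_lam + reg, -grad_lam + reg])
        return obj, grad

    def callback(theta: np.ndarray) -> None:
        trace.append(objective(theta)[0])

    theta0 = np.zeros(2 * d)
    res = minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * (2 * d),
        callback=callback,
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-5, "maxfun": 20 * max_iter},
    )
    if not res.success and "ABNORMAL" in str(res.message).upper():
        raise ConvergenceError("maxent optimisation failed", float(np.linalg.norm(res.jac)))
    if res.nit >= max_iter:
        raise ConvergenceError(
            "maxent optimisation hit max_iter", float(np.linalg.norm(res.jac))
        )

    lam = res.x[:d] - res.x[d:]
    eta_bg = Fb @ lam
    log_z = float(logsumexp(eta_bg))
    q = np.exp(eta_bg - log_z)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = float(-np.sum(np.where(q > 0, q * np.log(q), 0.0)))
    raw_sorted = np.sort(q)
    model_meta = {"n_presence": int(m), "n_background": int(Fb.shape[0])}
    if meta:
        model_meta.update(meta)
    return SuitabilityModel(
        featureset=featureset,
        weights=lam,
        beta=beta,
        log_z=log_z,
        entropy=h,
        bg_raw_sorted=raw_sorted,
        bg_raw_cumsum=np.cumsum(raw_sorted),
        trace=np.asarray(trace),
        meta=model_meta,
    )
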