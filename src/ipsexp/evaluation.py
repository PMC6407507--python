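"""Model scoring: AUC, six-threshold omission rates, and the retention rule.

A species' model is retained when mean AUC exceeds ``auc_min`` (default 0.7)
AND its mean training omission rate is below ``omission_max`` (default
0.017).  Omission is averaged first over the six threshold rules within a
fold, then over folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .sdm.cv import CvResult
from .sdm.maxent import SuitabilityModel

__all__ = [
    "THRESHOLD_RULES",
    "Threshold",
    "EvaluationReport",
    "compute_auc",
    "derive_thresholds",
    "omission_rate",
    "retain",
    "evaluate_species",
]

THRESHOLD_RULES: tuple[str, ...] = (
    "fixed_cumulative_5",
    "fixed_cumulative_10",
    "equal_train_sens_spec",
    "max_train_sens_spec",
    "max_test_sens_spec",
    "equate_entropy",
)


def compute_auc(scores_presence, scores_background) -> float:
    """Rank-based AUC: P(random presence outranks random background), ties ½.

    Invariant under strictly monotone transforms of the scores, so raw,
    cumulative and logistic scales give identical values.
    """
    p = np.asarray(scores_presence, dtype=float)
    b = np.asarray(scores_background, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("score vectors must be non-empty")
    ranks = rankdata(np.concatenate([p, b]))
    u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2.0
    return float(u / (p.size * b.size))


@dataclass(frozen=True)
class Threshold:
    """A named presence/absence threshold on a specific score scale."""

    rule: str
    scale: str  # "raw", "cumulative" or "logistic"
    value: float


def _sens_spec_curves(pres: np.ndarray, bg: np.ndarray):
    """Candidate thresholds plus sensitivity/specificity at each.

    Sensitivity counts presences scoring at or above the threshold (ties
    predicted present); specificity counts background strictly below.
    """
    cand = np.unique(np.concatenate([pres, bg]))
    sens = (pres[None, :] >= cand[:, None]).mean(axis=1)
    spec = (bg[None, :] < cand[:, None]).mean(axis=1)
    return cand, sens, spec


def derive_thresholds(
    model: SuitabilityModel,
    train_raw: np.ndarray,
    test_raw: np.ndarray | None = None,
) -> dict[str, Threshold]:
    """The six named thresholds for one fitted model.

    ``train_raw`` / ``test_raw`` are raw-scale scores of training and test
    presences.  When test scores are missing the test-based rule is omitted
    (a warning is the caller's concern; the returned dict simply lacks it).
    """
    train_raw = np.asarray(train_raw, dtype=float)
    bg_raw = model.bg_raw_sorted
    out: dict[str, Threshold] = {
        "fixed_cumulative_5": Threshold("fixed_cumulative_5", "cumulative", 5.0),
        "fixed_cumulative_10": Threshold("fixed_cumulative_10", "cumulative", 10.0),
    }

    pres_log = model.logistic_from_raw(train_raw)
    bg_log = model.logistic_from_raw(bg_raw)
    cand, sens, spec = _sens_spec_curves(pres_log, bg_log)
    eq_idx = int(np.argmin(np.abs(sens - spec)))
    out["equal_train_sens_spec"] = Threshold(
        "equal_train_sens_spec", "logistic", float(cand[eq_idx])
    )
    max_idx = int(np.argmax(sens + spec))
    out["max_train_sens_spec"] = Threshold(
        "max_train_sens_spec", "logistic", float(cand[max_idx])
    )
    if test_raw is not None and np.asarray(test_raw).size:
        t_log = model.logistic_from_raw(np.asarray(test_raw, dtype=float))
        cand_t, sens_t, spec_t = _sens_spec_curves(t_log, bg_log)
        out["max_test_sens_spec"] = Threshold(
            "max_test_sens_spec", "logistic", float(cand_t[int(np.argmax(sens_t + spec_t))])
        )

    # equate entropy: uniform-above-threshold distribution over the k largest
    # background raws has entropy log k; pick the smallest k with log k >= H
    n_bg = bg_raw.size
    k = int(np.ceil(np.exp(min(model.entropy, np.log(n_bg)))))
    k = min(max(k, 1), n_bg)
    out["equate_entropy"] = Threshold("equate_entropy", "raw", float(bg_raw[n_bg - k]))
    return out


def omission_rate(train_presence_scores, threshold: Threshold | float) -> float:
    """Fraction of presences scoring strictly below the threshold."""
    scores = np.asarray(train_presence_scores, dtype=float)
    value = threshold.value if isinstance(threshold, Threshold) else float(threshold)
    if scores.size == 0:
        return 0.0
    return float((scores < value).mean())


def retain(mean_auc: float, mean_omission: float, auc_min: float = 0.7, omission_max: float = 0.017) -> bool:
    """The conjunction retention rule."""
    return bool(mean_auc > auc_min and mean_omission < omission_max)


@dataclass
class EvaluationReport:
    """Per-species evaluation across folds."""

    species_id: str
    fold_auc: list[float]
    fold_train_auc: list[float]
    fold_omission: list[float]  # mean over the six rules, per fold
    per_rule: pd.DataFrame  # fold x rule omission rates
    mean_auc: float = 0.0
    mean_train_auc: float = 0.0
    mean_omission: float = 0.0
    retained: bool = False
    thresholds: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in range(len(self.fold_auc)):
            row = {
                "species": self.species_id,
                "fold": f,
                "auc_test": self.fold_auc[f],
                "auc_train": self.fold_train_auc[f],
                "omission_mean": self.fold_omission[f],
            }
            row.update(self.per_rule.iloc[f].to_dict())
            rows.append(row)
        rows.append(
            {
                "species": self.species_id,
                "fold": "mean",
                "auc_test": self.mean_auc,
                "auc_train": self.mean_train_auc,
                "omission_mean": self.mean_omission,
                "retained": self.retained,
            }
        )
        return pd.DataFrame(rows)


def _score_on_scale(model: SuitabilityModel, raw: np.ndarray, scale: str) -> np.ndarray:
    if scale == "raw":
        return np.asarray(raw, dtype=float)
    if scale == "cumulative":
        return model.cumulative_from_raw(raw)
    if scale == "logistic":
        return model.logistic_from_raw(raw)
    raise ValueError(f"unknown scale {scale!r}")


def evaluate_species(
    cv: CvResult,
    auc_min: float = 0.7,
    omission_max: float = 0.017,
) -> EvaluationReport:
    """Score a cross-validated species model fold by fold.

    Test-fold AUC is computed presence-vs-background under each fold's model;
    omission rates are computed on training presences at the six thresholds.
    """
    fold_auc: list[float] = []
    fold_train_auc: list[float] = []
    fold_omission: list[float] = []
    per_rule_rows: list[dict] = []
    for model, (train_idx, test_idx) in zip(cv.models, cv.folds):
        train_raw = model.raw_from_values(cv.presence_values[train_idx])
        test_raw = model.raw_from_values(cv.presence_values[test_idx])
        bg_raw = model.bg_raw_sorted
        fold_train_auc.append(compute_auc(train_raw, bg_raw))
        fold_auc.append(compute_auc(test_raw, bg_raw))
        thresholds = derive_thresholds(model, train_raw, test_raw)
        rates = {}
        for rule in THRESHOLD_RULES:
            if rule not in thresholds:
                rates[rule] = np.nan
                continue
            t = thresholds[rule]
            scores = _score_on_scale(model, train_raw, t.scale)
            rates[rule] = omission_rate(scores, t)
        per_rule_rows.append(rates)
        fold_omission.append(float(np.nanmean(list(rates.values()))))

    per_rule = pd.DataFrame(per_rule_rows, columns=list(THRESHOLD_RULES))
    mean_auc = float(np.mean(fold_auc))
    mean_train_auc = float(np.mean(fold_train_auc))
    mean_omission = float(np.mean(fold_omission))
    return EvaluationReport(
        species_id=cv.species_id,
        fold_auc=fold_auc,
        fold_train_auc=fold_train_auc,
        fold_omission=fold_omission,
        per_rule=per_rule,
        mean_auc=mean_auc,
        mean_train_auc=mean_train_auc,
        mean_omission=mean_omission,
        retained=retain(mean_auc, mean_omission, auc_min, omission_max),
    )
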