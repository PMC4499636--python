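"""Screening performance evaluation: leakage-aware CV and the metrics panel.

Fellow eyes of one patient are strongly correlated, so ordinary k-fold
cross-validation leaks information when one eye of a patient lands in the
training set while the other is being validated.  The evaluator here keeps
the random eye-level folds but, for each validation fold, drops from the
training set every record whose fellow eye (same patient, other
laterality) is in that fold.  Excluded records are dropped from training
only for the affected fold, never from validation.

Per fold, predictions are tallied into a 2x2 confusion table (DR is the
positive class) and eight screening measures are derived: sensitivity,
specificity, accuracy, precision (PPV), NPV, F-measure (harmonic mean of
precision and sensitivity), and the positive/negative likelihood ratios
LRP = sens / (1 - spc), LRN = (1 - sens) / spc.  Measures with an
undefined denominator are flagged as NaN and excluded from aggregation;
the report counts how often each measure was defined.  Aggregates are the
mean and SD over all k x repeats fold-level values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .records import EyeRecord
from . import models as _models
from .models import ModelSpec

__all__ = [
    "CVConfig",
    "ConfusionCounts",
    "FoldPlan",
    "MetricsReport",
    "METRIC_NAMES",
    "make_pair_aware_folds",
    "confusion",
    "metrics_from_counts",
    "metrics_from_rates",
    "run_cv",
    "cross_validated_auroc",
    "round_half_away",
]

METRIC_NAMES = ("sens", "spc", "acc", "prec", "npv", "f1", "lrp", "lrn")


@dataclass(frozen=True)
class CVConfig:
    """Repeated k-fold configuration with fellow-eye exclusion."""

    k: int = 10
    repeats: int = 10
    pair_exclusion: bool = True
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass(frozen=True)
class FoldPlan:
    """One validation fold: record indices to validate on, and the training
    indices excluded because their fellow eye sits in this fold."""

    val_indices: tuple[int, ...]
    excluded_train_indices: tuple[int, ...]


def make_pair_aware_folds(
    records: list[EyeRecord], config: CVConfig
) -> list[list[FoldPlan]]:
    """Plan repeated k-fold splits with per-fold fellow-eye exclusion lists.

    Within each repeat the records are partitioned into k folds whose sizes
    differ by at most one; when ``stratified`` the two label classes are
    dealt evenly across folds.  For each fold the exclusion list holds every
    non-validation record whose fellow eye is in the fold (empty when
    ``pair_exclusion`` is off).  Deterministic per seed.
    """
    n = len(records)
    if config.k > n:
        raise ValueError(f"k={config.k} exceeds the number of records n={n}")
    rng = np.random.default_rng(config.seed)
    key_to_idx = {r.key: i for i, r in enumerate(records)}
    labels = np.array([int(r.dr_label) for r in records])

    plans: list[list[FoldPlan]] = []
    for _ in range(config.repeats):
        if config.stratified:
            # deal class by class round-robin with a continuing pointer so
            # fold sizes stay within one of each other overall
            order = np.concatenate(
                [rng.permutation(np.flatnonzero(labels == c)) for c in (0, 1)]
            )
        else:
            order = rng.permutation(n)
        fold_of = np.empty(n, dtype=int)
        fold_of[order] = np.arange(n) % config.k

        repeat_plans: list[FoldPlan] = []
        for f in range(config.k):
            val = np.flatnonzero(fold_of == f)
            excluded: list[int] = []
            if config.pair_exclusion:
                val_set = set(val.tolist())
                for i in val:
                    j = key_to_idx.get(records[i].fellow_key)
                    if j is not None and j not in val_set:
                        excluded.append(j)
            repeat_plans.append(
                FoldPlan(
                    val_indices=tuple(val.tolist()),
                    excluded_train_indices=tuple(sorted(set(excluded))),
                )
            )
        plans.append(repeat_plans)
    return plans


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 tally with DR as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(pred, truth) -> ConfusionCounts:
    """Tally predicted vs true binary labels."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    return ConfusionCounts(
        tp=int((pred & truth).sum()),
        fp=int((pred & ~truth).sum()),
        tn=int((~pred & ~truth).sum()),
        fn=int((~pred & truth).sum()),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def metrics_from_counts(c: ConfusionCounts) -> dict[str, float]:
    """Eight-measure panel from a confusion table.

    Undefined denominators yield NaN (flagged, never raised).
    """
    sens = _ratio(c.tp, c.tp + c.fn)
    spc = _ratio(c.tn, c.tn + c.fp)
    acc = _ratio(c.tp + c.tn, c.n)
    prec = _ratio(c.tp, c.tp + c.fp)
    npv = _ratio(c.tn, c.tn + c.fn)
    f1 = (
        _ratio(2 * prec * sens, prec + sens)
        if not (math.isnan(prec) or math.isnan(sens))
        else math.nan
    )
    lrp = _ratio(sens, 1 - spc) if not math.isnan(spc) and not math.isnan(sens) else math.nan
    lrn = _ratio(1 - sens, spc) if not math.isnan(spc) and not math.isnan(sens) else math.nan
    return {
        "sens": sens,
        "spc": spc,
        "acc": acc,
        "prec": prec,
        "npv": npv,
        "f1": f1,
        "lrp": lrp,
        "lrn": lrn,
    }


def metrics_from_rates(sens: float, spc: float, prec: float) -> dict[str, float]:
    """Derived measures from published sensitivity/specificity/precision.

    Useful as an identity check on a printed metrics panel: F1, LRP and LRN
    are determined by the three primary rates.
    """
    for name, v in (("sens", sens), ("spc", spc), ("prec", prec)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    f1 = _ratio(2 * prec * sens, prec + sens)
    lrp = _ratio(sens, 1 - spc)
    lrn = _ratio(1 - sens, spc)
    return {"f1": f1, "lrp": lrp, "lrn": lrn}


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (display convention for the metrics panel)."""
    if math.isnan(x):
        return x
    factor = 10**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


@dataclass
class MetricsReport:
    """Fold-wise and aggregate screening metrics."""

    model_kind: str
    k: int
    repeats: int
    seed: int
    per_fold: list[dict[str, float]]
    aggregate: dict[str, dict[str, float]]
    n_folds_skipped: int = 0

    def as_dict(self) -> dict:
        return {
            "model": self.model_kind,
            "k": self.k,
            "repeats": self.repeats,
            "seed": self.seed,
            "n_folds_skipped": self.n_folds_skipped,
            "per_fold": self.per_fold,
            "aggregate": self.aggregate,
        }


def _aggregate(per_fold: list[dict[str, float]]) -> dict[str, dict[str, float]]:
    agg: dict[str, dict[str, float]] = {}
    for m in METRIC_NAMES:
        vals = np.array([f[m] for f in per_fold], dtype=float)
        defined = vals[~np.isnan(vals)]
        agg[m] = {
            "mean": float(defined.mean()) if defined.size else math.nan,
            "sd": float(defined.std(ddof=1)) if defined.size > 1 else math.nan,
            "n_defined": int(defined.size),
        }
    return agg


def run_cv(
    records: list[EyeRecord], model_spec: ModelSpec, cv_config: CVConfig
) -> MetricsReport:
    """Repeated pair-aware k-fold CV of one screening model.

    Each fold trains on all records outside the fold minus the fellow-eye
    exclusion list, predicts the fold, and contributes one row of metrics.
    Folds whose training set collapses to a single class are skipped and
    counted.  Deterministic for fixed records, specs and seeds.
    """
    plans = make_pair_aware_folds(records, cv_config)
    per_fold: list[dict[str, float]] = []
    n_skipped = 0
    all_idx = np.arange(len(records))
    for repeat_plans in plans:
        for plan in repeat_plans:
            val = list(plan.val_indices)
            banned = set(plan.val_indices) | set(plan.excluded_train_indices)
            train_idx = [i for i in all_idx if i not in banned]
            train_records = [records[i] for i in train_idx]
            labels = {records[i].dr_label for i in train_idx}
            if len(labels) < 2:
                n_skipped += 1
                continue
            model = _models.train(train_records, model_spec)
            val_records = [records[i] for i in val]
            probs = _models.predict_proba(model, val_records)
            preds = probs >= model_spec.decision_threshold
            truth = np.array([r.dr_label for r in val_records])
            per_fold.append(metrics_from_counts(confusion(preds, truth)))
    return MetricsReport(
        model_kind=model_spec.model_kind,
        k=cv_config.k,
        repeats=cv_config.repeats,
        seed=cv_config.seed,
        per_fold=per_fold,
        aggregate=_aggregate(per_fold),
        n_folds_skipped=n_skipped,
    )


def cross_validated_auroc(
    records: list[EyeRecord], model_spec: ModelSpec, cv_config: CVConfig
) -> float:
    """Area under the ROC curve from pooled out-of-fold probabilities.

    Uses the same pair-aware folds as :func:`run_cv`; probabilities from
    every validation fold (first repeat onward) are pooled and scored once.
    """
    from sklearn.metrics import roc_auc_score

    plans = make_pair_aware_folds(records, cv_config)
    probs: list[float] = []
    truth: list[int] = []
    all_idx = np.arange(len(records))
    for repeat_plans in plans:
        for plan in repeat_plans:
            banned = set(plan.val_indices) | set(plan.excluded_train_indices)
            train_records = [records[i] for i in all_idx if i not in banned]
            if len({r.dr_label for r in train_records}) < 2:
                continue
            model = _models.train(train_records, model_spec)
            val_records = [records[i] for i in plan.val_indices]
            probs.extend(_models.predict_proba(model, val_records).tolist())
            truth.extend(int(r.dr_label) for r in val_records)
    return float(roc_auc_score(truth, probs))
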