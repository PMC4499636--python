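"""Eye-level DR screening classifiers.

Three models mirror the three screening routes:

* ``image_nb`` — naive Bayes on a single feature, the per-eye MA count.
  The default class-conditional is Gaussian; a Poisson conditional (the
  natural family for counts) is available via ``nb_variant="poisson"``.
* ``proteomics_gbm`` — gradient boosting on the 34 protein concentrations.
* ``combined_gbm`` — gradient boosting on proteins plus the MA count
  (35 features, MA count appended after the proteins).

All models emit class-1 (DR) probabilities; the hard label is
``probability >= decision_threshold``.  Tree ensembles are scale-invariant
and naive Bayes sees one feature, so no feature scaling is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import joblib
import numpy as np
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.naive_bayes import GaussianNB

from .records import EyeRecord, N_PROTEINS

__all__ = [
    "ModelSpec",
    "ScreeningModel",
    "MODEL_KINDS",
    "assemble_features",
    "train",
    "predict",
    "predict_proba",
    "save_model",
    "load_model",
]

MODEL_KINDS = ("image_nb", "proteomics_gbm", "combined_gbm")


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of one screening model."""

    model_kind: str = "combined_gbm"
    decision_threshold: float = 0.5
    seed: int = 0
    nb_variant: str = "gaussian"  # or "poisson"
    gbm_n_estimators: int = 200
    gbm_max_depth: int = 2
    gbm_learning_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
        if self.nb_variant not in ("gaussian", "poisson"):
            raise ValueError("nb_variant must be 'gaussian' or 'poisson'")
        if not 0 <= self.decision_threshold <= 1:
            raise ValueError("decision_threshold must lie in [0, 1]")


def assemble_features(record: EyeRecord, model_kind: str) -> np.ndarray:
    """Build the model-specific feature vector for one eye.

    ``image_nb`` consumes [ma_count]; ``proteomics_gbm`` the 34-protein
    vector; ``combined_gbm`` the proteins with the MA count appended last.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
    needs_count = model_kind in ("image_nb", "combined_gbm")
    needs_proteins = model_kind in ("proteomics_gbm", "combined_gbm")
    if needs_count and record.ma_count is None:
        raise ValueError(
            f"record {record.key} is missing ma_count, required by {model_kind}"
        )
    if needs_proteins:
        if record.proteins is None:
            raise ValueError(
                f"record {record.key} is missing proteins, required by {model_kind}"
            )
        if record.proteins.shape != (N_PROTEINS,):
            raise ValueError(
                f"record {record.key}: expected {N_PROTEINS} proteins, "
                f"got {record.proteins.shape}"
            )
    if model_kind == "image_nb":
        return np.array([float(record.ma_count)])
    if model_kind == "proteomics_gbm":
        return np.asarray(record.proteins, dtype=float)
    return np.concatenate([record.proteins, [float(record.ma_count)]])


class _PoissonNB:
    """Naive Bayes with a Poisson class-conditional on a single count feature."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_PoissonNB":
        counts = X[:, 0]
        self.priors_ = np.array([(y == k).mean() for k in (0, 1)])
        # +0.5 smoothing keeps the rate positive for an all-zero class
        self.rates_ = np.array(
            [(counts[y == k].sum() + 0.5) / ((y == k).sum() + 1.0) for k in (0, 1)]
        )
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        counts = np.round(X[:, 0]).astype(int)
        loglik = np.stack(
            [
                stats.poisson.logpmf(counts, self.rates_[k]) + np.log(self.priors_[k])
                for k in (0, 1)
            ],
            axis=1,
        )
        loglik -= loglik.max(axis=1, keepdims=True)
        post = np.exp(loglik)
        post /= post.sum(axis=1, keepdims=True)
        return post


@dataclass
class ScreeningModel:
    """A trained probability-emitting screening classifier."""

    spec: ModelSpec
    estimator: object

    def predict_proba_matrix(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict_proba(X))[:, 1]


def train(records: list[EyeRecord], spec: ModelSpec) -> ScreeningModel:
    """Fit the configured screening model on eye records.

    Raises on single-class data or on records missing the model's features.
    """
    X = np.array([assemble_features(r, spec.model_kind) for r in records])
    y = np.array([int(r.dr_label) for r in records])
    if len(np.unique(y)) < 2:
        raise ValueError("training records contain a single class")
    if spec.model_kind == "image_nb":
        est = _PoissonNB() if spec.nb_variant == "poisson" else GaussianNB()
        est.fit(X, y)
    else:
        est = GradientBoostingClassifier(
            n_estimators=spec.gbm_n_estimators,
            max_depth=spec.gbm_max_depth,
            learning_rate=spec.gbm_learning_rate,
            random_state=spec.seed,
        )
        est.fit(X, y)
    return ScreeningModel(spec=spec, estimator=est)


def predict_proba(model: ScreeningModel, records: list[EyeRecord]) -> np.ndarray:
    """DR probabilities for a list of eyes."""
    if not records:
        return np.array([])
    X = np.array([assemble_features(r, model.spec.model_kind) for r in records])
    p = model.predict_proba_matrix(X)
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise RuntimeError("model emitted probabilities outside [0, 1]")
    return p


def predict(model: ScreeningModel, record: EyeRecord) -> tuple[float, bool]:
    """(probability, label) for one eye; label = prob >= decision_threshold."""
    p = float(predict_proba(model, [record])[0])
    return p, p >= model.spec.decision_threshold


def save_model(model: ScreeningModel, path) -> None:
    joblib.dump({"format_version": 1, "spec": model.spec, "estimator": model.estimator}, path)


def load_model(path) -> ScreeningModel:
    payload = joblib.load(path)
    return ScreeningModel(spec=payload["spec"], estimator=payload["estimator"])
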