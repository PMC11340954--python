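"""Probability stacking and the meta-classifier.

The out-of-fold probability vectors of all single-feature models are
stacked column-wise into a matrix with one row per training sample and one
column per model; a second-level *meta-classifier* (logistic regression by
default) is then trained on that matrix against the class labels. For the
logistic-regression meta-classifier the fitted log-odds are the linear form

    ln(p / (1 - p)) = beta_0 + beta_1 x_1 + ... + beta_n x_n

and the absolute weight coefficients |beta_i| (AWCLR) rank the importance
of each member model — the quantity the selection algorithms consume.

The meta level is itself cross-validated, reusing the base-level fold
assignment so that no information leaks between levels, and its out-of-fold
probabilities supply the MCC-maximising decision threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .base import SingleFeatureModel, make_classifier, predict_single, _positive_proba
from .data import LabeledDataset
from .metrics import MetricsReport, evaluate_probabilities, mcc_optimal_threshold

__all__ = ["ProbabilityMatrix", "MetaModel", "build_probability_matrix",
           "fit_meta", "extract_awclr", "predict_meta", "META_NAMES"]

META_NAMES = ("LR", "SVM", "LGBM", "XGB", "RF", "NB", "KN")


@dataclass
class ProbabilityMatrix:
    """Stacked OOF probabilities: n_train x n_models, plus labels/folds."""

    values: np.ndarray
    model_keys: list[str]
    labels: np.ndarray
    folds: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.model_keys):
            raise ValueError("values must be n_samples x n_models")
        if self.values.shape[0] != len(self.labels):
            raise ValueError("labels misaligned with rows")
        if ((self.values < 0) | (self.values > 1)).any():
            raise ValueError("probabilities outside [0, 1]")

    @property
    def n_models(self) -> int:
        return self.values.shape[1]

    def select(self, keys: list[str]) -> "ProbabilityMatrix":
        idx = [self.model_keys.index(k) for k in keys]
        return ProbabilityMatrix(self.values[:, idx], list(keys),
                                 self.labels, self.folds)


def build_probability_matrix(models: list[SingleFeatureModel],
                             labels) -> ProbabilityMatrix:
    """Stack OOF probability columns against the training labels.

    All models must share one fold assignment over the same training split
    (checked), otherwise the stacked columns would be incomparable.
    """
    if not models:
        raise ValueError("no models to stack")
    ref = models[0]
    for m in models[1:]:
        if m.oof_probs.shape != ref.oof_probs.shape or \
                not np.array_equal(m.fold_of_sample, ref.fold_of_sample):
            raise ValueError(
                f"{m.model_key}: fold assignment differs from "
                f"{ref.model_key}; stacked columns would be incomparable")
    labels = np.asarray(labels, dtype=float)
    if labels.shape[0] != ref.oof_probs.shape[0]:
        raise ValueError("labels misaligned with OOF probabilities")
    values = np.column_stack([m.oof_probs for m in models])
    return ProbabilityMatrix(values, [m.model_key for m in models],
                             labels, ref.fold_of_sample.copy())


@dataclass
class MetaModel:
    """Fitted meta-classifier over a set of member single-feature models."""

    meta_name: str
    model_keys: list[str]
    estimator: object = field(repr=False)
    threshold: float = 0.5
    weights: np.ndarray | None = None   # (beta_0, beta_1..beta_n) for LR
    oof_probs: np.ndarray | None = field(default=None, repr=False)
    cv_metrics: MetricsReport | None = None

    def predict_proba(self, prob_columns: np.ndarray) -> np.ndarray:
        return _positive_proba(self.estimator, np.asarray(prob_columns))

    def predict(self, prob_columns: np.ndarray) -> np.ndarray:
        return (self.predict_proba(prob_columns) >= self.threshold).astype(int)


def fit_meta(pm: ProbabilityMatrix, meta_name: str = "LR",
             seed: int = 0) -> MetaModel:
    """Fit the meta-classifier on a probability matrix.

    The meta learner is cross-validated with the base-level folds to obtain
    meta-level OOF probabilities; the decision threshold is the MCC
    maximiser over those, and the reported CV metrics are computed from
    them. The final estimator is refitted on all rows. For logistic
    regression the weight vector (intercept first) is exposed; probability
    features already share the [0, 1] scale, so no standardisation is
    applied and the weights stay comparable across members.
    """
    if meta_name not in META_NAMES:
        raise ValueError(
            f"unsupported meta-classifier {meta_name!r}; choose one of "
            f"{list(META_NAMES)}")
    X, y, folds = pm.values, np.asarray(pm.labels, float), pm.folds
    if X.shape[1] == 0:
        raise ValueError("empty probability matrix")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required to fit the meta-classifier")

    def _make():
        if meta_name == "LR":
            from sklearn.linear_model import LogisticRegression
            return LogisticRegression(C=1.0, max_iter=5000, random_state=seed)
        return make_classifier(meta_name, seed=seed)

    oof = np.full(len(y), np.nan)
    for f in np.unique(folds):
        tr, va = folds != f, folds == f
        est = _make()
        est.fit(X[tr], y[tr])
        oof[va] = _positive_proba(est, X[va])
    assert not np.isnan(oof).any()

    final = _make()
    final.fit(X, y)
    theta = mcc_optimal_threshold(y, oof)
    metrics = evaluate_probabilities(y, oof, threshold=theta)
    weights = None
    if meta_name == "LR":
        weights = np.concatenate([final.intercept_, final.coef_.ravel()])
    return MetaModel(meta_name, list(pm.model_keys), final, theta,
                     weights, oof, metrics)


def extract_awclr(meta: MetaModel) -> dict[str, float]:
    """AWCLR_i = |beta_i| per member model (the intercept is excluded)."""
    if meta.meta_name != "LR" or meta.weights is None:
        raise ValueError("AWCLR is defined only for the LR meta-classifier")
    return {k: abs(float(b))
            for k, b in zip(meta.model_keys, meta.weights[1:])}


def predict_meta(meta: MetaModel, models: list[SingleFeatureModel],
                 ds: LabeledDataset | list[str]):
    """Meta probabilities and threshold calls for new sequences.

    Member probabilities come from each member's refit full-train model, in
    the member order stored on the meta-model.
    """
    by_key = {m.model_key: m for m in models}
    missing = [k for k in meta.model_keys if k not in by_key]
    if missing:
        raise ValueError(f"member models missing: {missing}")
    cols = [predict_single(by_key[k], ds) for k in meta.model_keys]
    X = np.column_stack(cols)
    probs = meta.predict_proba(X)
    return probs, (probs >= meta.threshold).astype(int)
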