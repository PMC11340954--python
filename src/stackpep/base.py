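"""Single-feature models: one classifier per (encoding, classifier) grid cell.

A *single-feature model* couples one encoding scheme with one classifier.
Each is trained by stratified 5-fold cross-validation on the training
split: for every fold, a fresh classifier is fitted on the other folds and
predicts probabilities on the held-out fold, so every training sample
receives exactly one out-of-fold (OOF) probability from a model that never
saw it. Those OOF probability vectors are the features the meta-classifier
stacks. After CV the classifier is refitted on the full training split for
test-time prediction.

The default grid pairs 7 classical classifiers with 21 fixed-vector
encodings and 3 further learners with the 7 sequence-level encodings,
168 cells in total. When the optional deep-learning plugin is absent the
latter cells fall back to multilayer-perceptron learners on the flattened
sequence encodings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import LabeledDataset
from .encoders import Encoder, FeatureMatrix, make_encoder, encoder_names
from .metrics import MetricsReport, evaluate_probabilities

__all__ = [
    "ClassifierSpec", "SingleFeatureModel", "ModelGrid",
    "make_classifier", "classifier_names", "default_grid",
    "train_single", "predict_single", "rank_models_by_auc", "audit_oof",
]

#: The seven classical classifiers of the core path.
CLASSICAL = ("RF", "XGB", "LGBM", "SVM", "KN", "NB", "LR")

#: Learners applied to the sequence-level encodings (deep plugin slots).
DEEP = ("TX", "CNN", "BLSTM")

#: Encodings consumed by the deep slots (per-residue / embedding schemes).
DEEP_ENCODINGS = ("BE", "NN", "ESM2", "W2V_1", "W2V_2", "W2V_3", "W2V_4")

_SCALED = {"SVM", "LR", "KN", "TX", "CNN", "BLSTM"}


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier by registry name plus hyperparameter overrides."""

    name: str
    hyperparams: tuple = ()
    seed: int = 0

    def __str__(self) -> str:
        return self.name


def classifier_names(include_deep: bool = True) -> list[str]:
    return list(CLASSICAL) + (list(DEEP) if include_deep else [])


def make_classifier(name: str, seed: int = 0, **hyperparams):
    """Instantiate a probability-producing sklearn estimator by name.

    Margin/distance learners (SVM, LR, KN and the MLP fallbacks) are wrapped
    in a pipeline with a standard scaler fitted on the training folds only;
    tree ensembles consume raw features. All estimators run single-threaded
    so results do not depend on worker scheduling.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.neural_network import MLPClassifier
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    if name == "RF":
        est = RandomForestClassifier(n_estimators=100, random_state=seed,
                                     n_jobs=1, **hyperparams)
    elif name == "XGB":
        from xgboost import XGBClassifier
        est = XGBClassifier(n_estimators=100, max_depth=4, learning_rate=0.1,
                            random_state=seed, n_jobs=1, verbosity=0,
                            eval_metric="logloss", **hyperparams)
    elif name == "LGBM":
        from lightgbm import LGBMClassifier
        est = LGBMClassifier(n_estimators=100, random_state=seed, n_jobs=1,
                             verbose=-1, **hyperparams)
    elif name == "SVM":
        est = SVC(probability=True, random_state=seed, **hyperparams)
    elif name == "KN":
        est = KNeighborsClassifier(**hyperparams)
    elif name == "NB":
        est = GaussianNB(**hyperparams)
    elif name == "LR":
        est = LogisticRegression(max_iter=2000, random_state=seed,
                                 **hyperparams)
    elif name in DEEP:
        # fallback learners for the deep slots when no torch plugin is present
        hidden = {"TX": (128, 64), "CNN": (64, 32), "BLSTM": (96,)}[name]
        est = MLPClassifier(hidden_layer_sizes=hidden, max_iter=300,
                            random_state=seed, **hyperparams)
    else:
        raise ValueError(f"unknown classifier {name!r}")
    if name in _SCALED:
        return make_pipeline(StandardScaler(), est)
    return est


@dataclass
class ModelGrid:
    """The (classifier, encoding) cells to train."""

    pairs: list[tuple[str, str]]

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


def default_grid(classical_only: bool = False,
                 include_plm: bool = True) -> ModelGrid:
    """The default model grid.

    7 classical classifiers x 21 fixed-vector encodings plus 3 deep-slot
    learners x 7 sequence encodings = 168 cells. ``classical_only`` keeps
    the 147 classical cells; ``include_plm=False`` drops the
    language-model column from both halves.
    """
    enc_classical = encoder_names()  # the 21 fixed-vector encodings
    pairs = [(c, e) for c in CLASSICAL for e in enc_classical]
    if not classical_only:
        pairs += [(c, e) for c in DEEP for e in DEEP_ENCODINGS]
    if not include_plm:
        pairs = [(c, e) for c, e in pairs if e != "ESM2"]
    return ModelGrid(pairs)


@dataclass
class SingleFeatureModel:
    """One trained (encoding, classifier) cell with its OOF probabilities."""

    encoding: str
    classifier: str
    encoder: Encoder = field(repr=False)
    oof_probs: np.ndarray = field(repr=False)
    fold_of_sample: np.ndarray = field(repr=False)
    fold_train_indices: dict[int, np.ndarray] = field(repr=False)
    fold_models: dict[int, object] = field(repr=False)
    full_model: object = field(repr=False)
    cv_metrics: MetricsReport = None
    train_features: FeatureMatrix | None = field(default=None, repr=False)

    @property
    def model_key(self) -> str:
        return f"{self.classifier}-{self.encoding}"

    @property
    def cv_auc(self) -> float:
        return self.cv_metrics.AUC


def _positive_proba(est, X: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        # lightgbm's sklearn wrapper invents feature names for plain arrays
        warnings.filterwarnings("ignore",
                                message=".*does not have valid feature names.*")
        proba = est.predict_proba(X)
    classes = getattr(est, "classes_", None)
    if classes is None:  # pipeline
        classes = est[-1].classes_
    col = int(np.flatnonzero(classes == 1)[0])
    return proba[:, col]


def train_single(ds: LabeledDataset, encoding: str, classifier: str,
                 seed: int = 0, encoder: Encoder | None = None,
                 features: FeatureMatrix | None = None,
                 **clf_params) -> SingleFeatureModel:
    """Train one grid cell by 5-fold CV on the training split of ``ds``.

    ``ds`` must carry fold assignments (see :func:`stackpep.data.assign_folds`);
    the same assignment must be shared by every cell of a grid so that the
    stacked OOF columns are comparable. A pre-fitted encoder and/or
    pre-computed training features may be passed to avoid re-encoding when
    many classifiers share one encoding.
    """
    train = ds.train() if (ds.table["split"] == "train").any() else ds
    y = train.labels
    folds = train.folds
    if (folds < 0).any():
        raise ValueError("training split lacks fold assignments")
    if np.isnan(y).any():
        raise ValueError("training split has unlabeled records")

    if encoder is None:
        encoder = make_encoder(encoding, seed=seed)
        encoder.fit(train.sequences)
    if features is None:
        features = encoder.transform(train.sequences)
    X = features.values
    if not np.isfinite(X).all():
        raise ValueError(f"non-finite features from encoding {encoding}")

    oof = np.full(len(y), np.nan)
    fold_models: dict[int, object] = {}
    fold_train_indices: dict[int, np.ndarray] = {}
    for f in np.unique(folds):
        tr = np.flatnonzero(folds != f)
        va = np.flatnonzero(folds == f)
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"fold {f}: single-class training partition")
        est = make_classifier(classifier, seed=seed, **clf_params)
        est.fit(X[tr], y[tr])
        oof[va] = _positive_proba(est, X[va])
        fold_models[int(f)] = est
        fold_train_indices[int(f)] = tr
    assert not np.isnan(oof).any(), "OOF coverage incomplete"

    full = make_classifier(classifier, seed=seed, **clf_params)
    full.fit(X, y)
    cv_metrics = evaluate_probabilities(y, oof)
    return SingleFeatureModel(
        encoding=encoding, classifier=classifier, encoder=encoder,
        oof_probs=oof, fold_of_sample=folds.copy(),
        fold_train_indices=fold_train_indices, fold_models=fold_models,
        full_model=full, cv_metrics=cv_metrics, train_features=features)


def predict_single(model: SingleFeatureModel,
                   ds: LabeledDataset | list[str]) -> np.ndarray:
    """Probabilities from the refit full-train model, aligned to ``ds``."""
    seqs = ds.sequences if isinstance(ds, LabeledDataset) else list(ds)
    fm = model.encoder.transform(seqs)
    if model.train_features is not None and \
            fm.n_features != model.train_features.n_features:
        raise ValueError(
            f"{model.model_key}: encoding width {fm.n_features} != "
            f"training width {model.train_features.n_features}")
    return _positive_proba(model.full_model, fm.values)


def rank_models_by_auc(models) -> list[SingleFeatureModel]:
    """Descending CV AUC; ties broken lexicographically by model key."""
    return sorted(models, key=lambda m: (-m.cv_auc, m.model_key))


def audit_oof(model: SingleFeatureModel, atol: float = 1e-9) -> bool:
    """Verify the out-of-fold contract of a trained cell.

    Checks that (1) the per-fold training index sets exclude every sample
    of their own fold, (2) folds cover each training sample exactly once,
    and (3) re-predicting each fold with its stored fold model reproduces
    the stored OOF slice. Raises AssertionError on violation.
    """
    folds = model.fold_of_sample
    n = folds.size
    covered = np.zeros(n, dtype=int)
    X = model.train_features.values
    for f, est in model.fold_models.items():
        va = np.flatnonzero(folds == f)
        tr = model.fold_train_indices[f]
        assert not np.intersect1d(va, tr).size, \
            f"fold {f}: validation samples present in its training set"
        covered[va] += 1
        repro = _positive_proba(est, X[va])
        assert np.allclose(repro, model.oof_probs[va], atol=atol), \
            f"fold {f}: stored OOF probabilities not reproducible"
    assert (covered == 1).all(), "folds do not partition the training split"
    return True
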