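"""Top-level modelling surface: PeptideStackingModel -> StackingResults.

This is the package's front door, organised the way statistical modelling
libraries present estimators: a model object is constructed from data plus
design choices, ``fit`` runs the whole estimation (split, encode, train the
grid with cross-validation, stack, optionally pre-filter and select members,
fit the final meta-classifier) and returns a results object carrying the
estimates — member weights, decision threshold, per-model and meta-level
metrics, the selection trace — with ``summary()`` and ``predict()``.

For scripted pipelines the underlying modules remain directly usable; this
class only orchestrates them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .base import (ModelGrid, SingleFeatureModel, default_grid, predict_single,
                   train_single)
from .data import LabeledDataset, assign_folds, read_csv_dataset, read_fasta, \
    stratified_split
from .encoders import make_encoder
from .metrics import MetricsReport, evaluate_probabilities
from .selection import SelectionTrace, filter_by_accuracy, \
    majority_class_baseline, saauc, sawc, sdiwc
from .stacking import MetaModel, ProbabilityMatrix, build_probability_matrix, \
    extract_awclr, fit_meta, predict_meta

__all__ = ["PeptideStackingModel", "StackingResults"]


class PeptideStackingModel:
    """Stacked-generalisation classifier for labeled peptide datasets.

    Parameters
    ----------
    dataset : LabeledDataset
        Labeled peptides. If no train/test split is present one is made at
        ``fit`` time (stratified, ``test_fraction`` to the test side).
    grid : ModelGrid, optional
        (classifier, encoding) cells to train; defaults to the full
        168-cell grid. Small custom grids are the practical choice for
        exploratory runs.
    meta_name : str
        Meta-classifier; 'LR' enables the weight-based selection methods.
    selection : str or None
        None, 'saauc', 'sawc' or 'sdiwc'.
    acc_prefilter : bool
        Drop members below the majority-class baseline accuracy before
        selection.
    """

    def __init__(self, dataset: LabeledDataset, grid: ModelGrid | None = None,
                 meta_name: str = "LR", selection: str | None = None,
                 acc_prefilter: bool = False, test_fraction: float = 0.2,
                 n_folds: int = 5, plm_dim: int = 64,
                 plm_provider: str = "stub"):
        self.dataset = dataset
        self.grid = grid if grid is not None else default_grid()
        self.meta_name = meta_name
        self.selection = selection
        self.acc_prefilter = acc_prefilter
        self.test_fraction = test_fraction
        self.n_folds = n_folds
        self.plm_dim = plm_dim
        self.plm_provider = plm_provider

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs):
        return cls(LabeledDataset(df.copy()), **kwargs)

    @classmethod
    def from_fasta(cls, path, **kwargs):
        return cls(read_fasta(path), **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs):
        return cls(read_csv_dataset(path), **kwargs)

    # -- estimation ------------------------------------------------------
    def fit(self, seed: int = 0, verbose: bool = False) -> "StackingResults":
        ds = self.dataset
        if not (ds.table["split"] == "test").any():
            ds = stratified_split(ds, self.test_fraction, seed=seed)
        if (ds.train().folds < 0).any():
            ds = assign_folds(ds, n_folds=self.n_folds, seed=seed)
        train = ds.train()

        # one fitted encoder (and feature matrix) per encoding, shared by
        # every classifier paired with it
        encodings = sorted({e for _, e in self.grid})
        encoders, feats = {}, {}
        for name in encodings:
            kwargs = {}
            if name == "ESM2":
                kwargs = {"provider": self.plm_provider, "dim": self.plm_dim}
            enc = make_encoder(name, seed=seed, **kwargs)
            enc.fit(train.sequences)
            encoders[name] = enc
            feats[name] = enc.transform(train.sequences)
            if verbose:
                print(f"encoded {name}: {feats[name].n_features} features")

        models = []
        for clf, enc_name in self.grid:
            m = train_single(ds, enc_name, clf, seed=seed,
                             encoder=encoders[enc_name],
                             features=feats[enc_name])
            if verbose:
                print(f"trained {m.model_key}: CV AUC {m.cv_auc:.3f}")
            models.append(m)

        pm = build_probability_matrix(models, train.labels)

        candidates = models
        if self.acc_prefilter:
            candidates = filter_by_accuracy(models, train.labels)
        trace = None
        if self.selection is not None:
            algo = {"saauc": saauc, "sawc": sawc, "sdiwc": sdiwc}[
                self.selection.lower()]
            if self.selection.lower() == "saauc":
                trace = algo(candidates, pm, meta_name=self.meta_name,
                             seed=seed)
            else:
                trace = algo(candidates, pm, seed=seed)
            member_keys = trace.best_members
        else:
            member_keys = [m.model_key for m in candidates]

        meta = fit_meta(pm.select(member_keys), meta_name=self.meta_name,
                        seed=seed)

        test = ds.test()
        test_metrics = None
        if len(test) and not np.isnan(test.labels).any():
            probs, _ = predict_meta(meta, models, test)
            test_metrics = evaluate_probabilities(
                test.labels, probs, threshold=meta.threshold)

        return StackingResults(
            model=self, dataset=ds, seed=seed, single_models=models,
            prob_matrix=pm, meta=meta, trace=trace,
            test_metrics=test_metrics)


@dataclass
class StackingResults:
    """Fitted stacking classifier: estimates, diagnostics, prediction."""

    model: PeptideStackingModel
    dataset: LabeledDataset
    seed: int
    single_models: list[SingleFeatureModel]
    prob_matrix: ProbabilityMatrix
    meta: MetaModel
    trace: SelectionTrace | None = None
    test_metrics: MetricsReport | None = None

    # -- estimates -------------------------------------------------------
    @property
    def member_keys(self) -> list[str]:
        return self.meta.model_keys

    @property
    def threshold(self) -> float:
        return self.meta.threshold

    def awclr(self) -> dict[str, float]:
        return extract_awclr(self.meta)

    def model_table(self) -> pd.DataFrame:
        """Per-cell CV metrics of every trained single-feature model."""
        rows = []
        for m in self.single_models:
            r = {"model_key": m.model_key, "encoding": m.encoding,
                 "classifier": m.classifier}
            r.update({k: v for k, v in m.cv_metrics.as_dict().items()
                      if k in ("SEN", "SPE", "PRE", "ACC", "MCC", "AUC",
                               "AUPRC", "threshold")})
            rows.append(r)
        return pd.DataFrame(rows).sort_values(
            "AUC", ascending=False, ignore_index=True)

    # -- prediction ------------------------------------------------------
    def predict(self, data) -> pd.DataFrame:
        """Per-peptide probability and binary call at the stored threshold.

        ``data`` may be a LabeledDataset, a list of sequences, or a FASTA
        path.
        """
        if isinstance(data, (str, Path)) and Path(str(data)).exists():
            data = read_fasta(data)
        probs, calls = predict_meta(self.meta, self.single_models, data)
        ids = data.ids if isinstance(data, LabeledDataset) else \
            [f"s{i}" for i in range(len(probs))]
        return pd.DataFrame({"id": ids, "probability": probs, "call": calls})

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        train = self.dataset.train()
        n_pos, n_neg = train.class_counts()
        lines = [
            "Stacked peptide activity classifier",
            "=" * 60,
            f"training samples:     {len(train)} ({n_pos} pos / {n_neg} neg)",
            f"baseline accuracy:    {majority_class_baseline(train.labels):.4f}",
            f"grid cells trained:   {len(self.single_models)}",
            f"meta-classifier:      {self.meta.meta_name}",
            f"selection:            {self.trace.method if self.trace else 'none'}",
            f"members stacked:      {len(self.member_keys)}",
            f"decision threshold:   {self.threshold:.4f}",
            "",
            "meta-level CV metrics (out-of-fold):",
        ]
        cv = self.meta.cv_metrics
        fmt = ("  SEN {SEN:.3f}  SPE {SPE:.3f}  PRE {PRE:.3f}  ACC {ACC:.3f}"
               "  MCC {MCC:.3f}  AUC {AUC:.3f}  AUPRC {AUPRC:.3f}")
        lines.append(fmt.format(**cv.as_dict()))
        if self.test_metrics is not None:
            lines.append("held-out test metrics:")
            lines.append(fmt.format(**self.test_metrics.as_dict()))
        if self.meta.meta_name == "LR":
            lines += ["", "member weights (AWCLR ranking):",
                      f"  {'model':<24}{'beta':>10}{'AWCLR':>10}"]
            awclr = self.awclr()
            betas = dict(zip(self.meta.model_keys, self.meta.weights[1:]))
            for k in sorted(awclr, key=lambda k: -awclr[k]):
                lines.append(f"  {k:<24}{betas[k]:>10.4f}{awclr[k]:>10.4f}")
            lines.append(f"  {'(intercept)':<24}{self.meta.weights[0]:>10.4f}")
        if self.trace is not None:
            lines += ["", f"selection trace: best X = {self.trace.best_X}, "
                          f"plateau X = {self.trace.plateau_X()}"]
        return "\n".join(lines)

    def save_manifest(self, path) -> None:
        """Persist a JSON manifest of the run (grid, members, weights,
        threshold, metrics)."""
        manifest = {
            "version": __version__,
            "seed": self.seed,
            "grid": [list(p) for p in self.model.grid],
            "meta_name": self.meta.meta_name,
            "members": self.member_keys,
            "threshold": self.threshold,
            "weights": None if self.meta.weights is None
            else list(map(float, self.meta.weights)),
            "cv_metrics": self.meta.cv_metrics.as_dict(),
            "test_metrics": None if self.test_metrics is None
            else self.test_metrics.as_dict(),
        }
        Path(path).write_text(json.dumps(manifest, indent=2))
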