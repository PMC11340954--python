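"""Model-subset selection: SAAUC, SAWC, SDIWC and the accuracy pre-filter.

Three algorithms choose which single-feature models the final
meta-classifier should stack:

* **SAAUC** — sequential addition by AUC rank: members are added one at a
  time in descending order of their cross-validation AUC.
* **SAWC** — sequential addition by AWCLR rank: a logistic-regression
  meta-classifier over *all* members is fitted once, members are ranked by
  the absolute value of their weight coefficient, and added in that fixed
  order.
* **SDIWC** — sequential deletion with iterative AWCLR re-ranking: starting
  from all members, the meta-classifier is refitted at every step, the
  member with the smallest AWCLR is deleted, and the ranking is recomputed,
  until one member remains. Because the weights change with the member
  subset, this adapts the ranking as the subset shrinks.

Each algorithm emits a :class:`SelectionTrace` with one step per subset
size X, carrying the member keys and the meta-level out-of-fold AUC/MCC at
that size. The best subset is the argmax-AUC step (smallest X on ties); a
plateau detector additionally reports the smallest X whose AUC stays
within a tolerance of the maximum for several consecutive sizes.

An optional pre-filter drops members whose CV accuracy falls below the
majority-class baseline N_neg / (N_neg + N_pos) computed from the training
labels — under heavy imbalance a model below that line is worse than the
constant all-negative rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .base import SingleFeatureModel, rank_models_by_auc
from .stacking import MetaModel, ProbabilityMatrix, extract_awclr, fit_meta

__all__ = ["SelectionStep", "SelectionTrace", "saauc", "sawc", "sdiwc",
           "filter_by_accuracy", "majority_class_baseline", "select_best"]


@dataclass
class SelectionStep:
    X: int
    members: list[str]
    auc: float
    mcc: float
    awclr: dict[str, float] | None = None


@dataclass
class SelectionTrace:
    method: str
    steps: list[SelectionStep] = field(default_factory=list)
    plateau_eps: float = 0.002
    plateau_run: int = 3

    @property
    def best_X(self) -> int:
        return self.best_step().X

    @property
    def best_members(self) -> list[str]:
        return self.best_step().members

    def best_step(self) -> SelectionStep:
        if not self.steps:
            raise ValueError("empty selection trace")
        best = max(s.auc for s in self.steps)
        return min((s for s in self.steps if s.auc == best), key=lambda s: s.X)

    def plateau_X(self) -> int | None:
        """Smallest X opening a run of >= ``plateau_run`` consecutive sizes
        whose AUC is within ``plateau_eps`` of the trace maximum."""
        steps = sorted(self.steps, key=lambda s: s.X)
        best = max(s.auc for s in steps)
        near = [s.auc >= best - self.plateau_eps for s in steps]
        run = 0
        for i, ok in enumerate(near):
            run = run + 1 if ok else 0
            if run >= self.plateau_run:
                return steps[i - self.plateau_run + 1].X
        return None

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(
            [{"method": self.method, "X": s.X, "AUC": s.auc, "MCC": s.mcc,
              "members": ";".join(s.members)} for s in self.steps])


def _step(pm: ProbabilityMatrix, keys: list[str], meta_name: str,
          seed: int, with_awclr: bool = False) -> tuple[SelectionStep, MetaModel]:
    meta = fit_meta(pm.select(keys), meta_name=meta_name, seed=seed)
    awclr = extract_awclr(meta) if with_awclr and meta.meta_name == "LR" else None
    step = SelectionStep(len(keys), list(keys), meta.cv_metrics.AUC,
                         meta.cv_metrics.MCC, awclr)
    return step, meta


def saauc(models: list[SingleFeatureModel], pm: ProbabilityMatrix,
          meta_name: str = "LR", seed: int = 0) -> SelectionTrace:
    """Sequential addition in descending CV-AUC order (ranking fixed)."""
    ranked = [m.model_key for m in rank_models_by_auc(models)]
    trace = SelectionTrace("SAAUC")
    for X in range(1, len(ranked) + 1):
        step, _ = _step(pm, ranked[:X], meta_name, seed)
        trace.steps.append(step)
    return trace


def _awclr_ranking(awclr: dict[str, float]) -> list[str]:
    # descending weight; equal weights rank lexicographically earlier first
    return sorted(awclr, key=lambda k: (-awclr[k], k))


def sawc(models: list[SingleFeatureModel], pm: ProbabilityMatrix,
         seed: int = 0) -> SelectionTrace:
    """Sequential addition in descending AWCLR order.

    The ranking comes from a single LR meta-classifier fitted on all
    members and is never updated, so subsets are nested.
    """
    keys = [m.model_key for m in models]
    full = fit_meta(pm.select(keys), meta_name="LR", seed=seed)
    ranked = _awclr_ranking(extract_awclr(full))
    trace = SelectionTrace("SAWC")
    for X in range(1, len(ranked) + 1):
        step, _ = _step(pm, ranked[:X], "LR", seed)
        trace.steps.append(step)
    return trace


def sdiwc(models: list[SingleFeatureModel] | list[str], pm: ProbabilityMatrix,
          seed: int = 0) -> SelectionTrace:
    """Sequential deletion with iterative AWCLR re-ranking.

    At each size X the LR meta-classifier is refitted on the remaining
    members, their AWCLR recomputed, and the minimum-AWCLR member deleted
    (ties delete the lexicographically last key); one step is recorded per
    size from X = n down to 1.
    """
    current = [getattr(m, "model_key", m) for m in models]
    if len(current) < 2:
        raise ValueError("SDIWC needs at least 2 models")
    trace = SelectionTrace("SDIWC")
    while current:
        step, meta = _step(pm, current, "LR", seed, with_awclr=True)
        trace.steps.append(step)
        if len(current) == 1:
            break
        awclr = step.awclr
        low = min(awclr.values())
        victim = max(k for k, v in awclr.items() if v == low)
        current = [k for k in current if k != victim]
    return trace


def majority_class_baseline(labels) -> float:
    """Accuracy of the constant all-negative rule: N_neg / (N_neg + N_pos)."""
    y = np.asarray(labels, dtype=float)
    return float(np.sum(y == 0) / y.size)


def filter_by_accuracy(models: list[SingleFeatureModel],
                       labels) -> list[SingleFeatureModel]:
    """Keep models whose CV accuracy meets the majority-class baseline
    computed from the training labels (never a hard-coded constant)."""
    baseline = majority_class_baseline(labels)
    kept = [m for m in models if m.cv_metrics.ACC >= baseline]
    if not kept:
        warnings.warn(
            f"no model reaches the baseline accuracy {baseline:.4f}",
            stacklevel=2)
    return kept


def select_best(trace: SelectionTrace) -> list[str]:
    """Member keys of the argmax-AUC step (smallest X on ties)."""
    return trace.best_members
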