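"""Synthetic peptide datasets with controllable, known signal.

Negatives are drawn i.i.d. from a background residue distribution
(uniform by default; a Swiss-Prot-like frequency preset is bundled).
Positives are drawn from the same background and then receive implanted
motif substrings and/or a per-class composition shift, so the strength and
the *kind* of class signal (compositional vs. positional/order) are fully
under test control. Class sizes mirror the heavy imbalance typical of
curated activity datasets (a few hundred positives against thousands of
negatives), under which the all-negative baseline accuracy already exceeds
0.9 — the regime the thresholding and selection machinery is built for.

Generation is fully reproducible: one seed determines every sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import LabeledDataset
from .tables import ALPHABET

__all__ = ["SyntheticSpec", "generate", "make_complementary_signals",
           "SWISSPROT_FREQS"]

#: Approximate Swiss-Prot residue frequencies (fractions, alphabetical order).
SWISSPROT_FREQS = {
    "A": 0.0825, "C": 0.0138, "D": 0.0545, "E": 0.0672, "F": 0.0386,
    "G": 0.0707, "H": 0.0227, "I": 0.0591, "K": 0.0580, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0474, "Q": 0.0393, "R": 0.0553,
    "S": 0.0665, "T": 0.0536, "V": 0.0685, "W": 0.0110, "Y": 0.0292,
}


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic dataset.

    ``motifs`` is a list of ``(pattern, implant_probability)`` pairs; each
    positive receives each motif independently with its probability, at a
    uniformly random position. ``composition_bias`` optionally mixes the
    positive-class background towards given residue frequencies with the
    stated weight.
    """

    n_pos: int = 313
    n_neg: int = 2908
    length_range: tuple[int, int] = (9, 25)
    motifs: list[tuple[str, float]] = field(
        default_factory=lambda: [("WHKYW", 0.9)])
    background: dict[str, float] | None = None  # None = uniform 1/20
    composition_bias: tuple[dict[str, float], float] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be >= 1")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid length range")
        for pattern, p in self.motifs:
            if len(pattern) > lo:
                raise ValueError(
                    f"motif {pattern!r} longer than minimum length {lo}")
            if not 0.0 <= p <= 1.0:
                raise ValueError("implant probability must be in [0, 1]")


def _freq_vector(freqs: dict[str, float] | None) -> np.ndarray:
    if freqs is None:
        return np.full(20, 1 / 20)
    v = np.array([freqs[aa] for aa in ALPHABET], dtype=float)
    return v / v.sum()


def _draw_sequence(rng, length: int, p: np.ndarray) -> str:
    return "".join(rng.choice(list(ALPHABET), size=length, p=p))


def generate(spec: SyntheticSpec) -> LabeledDataset:
    """Generate a labeled dataset according to ``spec`` (see class doc)."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    bg = _freq_vector(spec.background)
    pos_bg = bg
    if spec.composition_bias is not None:
        target, weight = spec.composition_bias
        pos_bg = (1 - weight) * bg + weight * _freq_vector(target)
        pos_bg = pos_bg / pos_bg.sum()

    rows = []
    for i in range(spec.n_pos):
        L = int(rng.integers(lo, hi + 1))
        seq = list(_draw_sequence(rng, L, pos_bg))
        for pattern, p in spec.motifs:
            if rng.random() < p:
                start = int(rng.integers(0, L - len(pattern) + 1))
                seq[start:start + len(pattern)] = pattern
        rows.append({"id": f"pos{i}", "sequence": "".join(seq), "label": 1.0})
    for i in range(spec.n_neg):
        L = int(rng.integers(lo, hi + 1))
        rows.append({"id": f"neg{i}", "sequence": _draw_sequence(rng, L, bg),
                     "label": 0.0})
    return LabeledDataset.from_records(rows)


def make_complementary_signals(seed: int = 0, n_pos: int = 200,
                               n_neg: int = 800,
                               motif_a: str = "WHWKH",
                               motif_b: str = "CMCPC") -> LabeledDataset:
    """Dataset whose positive class splits into two disjoint subpopulations.

    Half of the positives carry only motif A, half only motif B (always
    implanted), negatives neither. A detector tuned to one motif is
    informative on only half the positives, so stacking two such detectors
    should clearly beat either alone — the property this fixture exists to
    probe.
    """
    rng = np.random.default_rng(seed)
    half = n_pos // 2
    a = generate(SyntheticSpec(n_pos=half, n_neg=1, motifs=[(motif_a, 1.0)],
                               seed=int(rng.integers(2 ** 31))))
    b = generate(SyntheticSpec(n_pos=n_pos - half, n_neg=n_neg,
                               motifs=[(motif_b, 1.0)],
                               seed=int(rng.integers(2 ** 31))))
    import pandas as pd

    ta = a.table[a.table["label"] == 1.0].copy()
    ta["id"] = [f"posA{i}" for i in range(len(ta))]
    tb = b.table.copy()
    tb.loc[tb["label"] == 1.0, "id"] = [
        f"posB{i}" for i in range(int((tb["label"] == 1.0).sum()))]
    return LabeledDataset(pd.concat([ta, tb], ignore_index=True))
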