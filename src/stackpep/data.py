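"""Peptide dataset container, FASTA/CSV I/O, stratified splitting and folds.

A :class:`LabeledDataset` is a thin wrapper around a pandas DataFrame with
one row per peptide (``id``, ``sequence``, ``label``, ``split``, ``fold``).
Splitting is stratified per class at a configurable test fraction (default
1:4 test:train), and cross-validation folds are assigned stratified within
the training split only — the test split never enters fold training. No
resampling is ever applied: class counts are preserved end to end.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .tables import ALPHABET

_VALID = set(ALPHABET)

TRAIN, TEST = "train", "test"


class DataError(ValueError):
    """Raised for malformed or invalid input data."""


@dataclass(frozen=True)
class Peptide:
    """A single validated peptide sequence."""

    id: str
    sequence: str

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise DataError(f"peptide {self.id!r}: empty sequence")
        bad = set(self.sequence) - _VALID
        if bad:
            raise DataError(
                f"peptide {self.id!r}: non-standard residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _validate_sequences(df: pd.DataFrame, nonstandard: str) -> pd.DataFrame:
    """Upper-case sequences, then reject or drop records with residues
    outside the 20-letter alphabet (``nonstandard`` in {'reject','drop'})."""
    df = df.copy()
    df["sequence"] = df["sequence"].astype(str).str.upper()
    bad = df["sequence"].map(lambda s: bool(set(s) - _VALID) or len(s) == 0)
    if bad.any():
        offenders = df.loc[bad, "id"].tolist()
        if nonstandard == "reject":
            raise DataError(
                f"records with non-standard or empty sequences: {offenders}"
            )
        warnings.warn(f"dropping {len(offenders)} records with non-standard "
                      f"residues: {offenders}", stacklevel=3)
        df = df.loc[~bad].reset_index(drop=True)
    if df.empty:
        raise DataError("no valid records")
    return df


@dataclass
class LabeledDataset:
    """Peptides with binary labels and split/fold bookkeeping.

    ``label`` is 1 for the positive (activity-inducing) class, 0 otherwise,
    and may be NaN for unlabeled prediction inputs. ``split`` is 'train' or
    'test' (empty before splitting); ``fold`` is an integer fold id for
    train records and -1 elsewhere.
    """

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("id", "sequence")

    def __post_init__(self):
        df = self.table
        for col in self.REQUIRED:
            if col not in df.columns:
                raise DataError(f"missing column {col!r}")
        if "label" not in df.columns:
            df["label"] = np.nan
        if "split" not in df.columns:
            df["split"] = ""
        if "fold" not in df.columns:
            df["fold"] = -1
        self.table = df.reset_index(drop=True)

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.table)

    @property
    def sequences(self) -> list[str]:
        return self.table["sequence"].tolist()

    @property
    def ids(self) -> list[str]:
        return self.table["id"].tolist()

    @property
    def labels(self) -> np.ndarray:
        return self.table["label"].to_numpy(dtype=float)

    @property
    def folds(self) -> np.ndarray:
        return self.table["fold"].to_numpy(dtype=int)

    def peptides(self) -> list[Peptide]:
        return [Peptide(i, s) for i, s in zip(self.ids, self.sequences)]

    def subset(self, mask: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(self.table.loc[np.asarray(mask)].copy())

    def train(self) -> "LabeledDataset":
        return self.subset((self.table["split"] == TRAIN).to_numpy())

    def test(self) -> "LabeledDataset":
        return self.subset((self.table["split"] == TEST).to_numpy())

    def class_counts(self) -> tuple[int, int]:
        """(n_positive, n_negative) over labeled records."""
        y = self.labels
        return int(np.nansum(y == 1)), int(np.nansum(y == 0))

    # -- I/O -------------------------------------------------------------
    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for _, row in self.table.iterrows():
                header = row["id"]
                if not pd.isna(row["label"]):
                    header = f"{header}|label={int(row['label'])}"
                fh.write(f">{header}\n{row['sequence']}\n")

    @classmethod
    def from_records(cls, records, nonstandard: str = "reject"):
        df = pd.DataFrame(records)
        return cls(_validate_sequences(df, nonstandard))


def read_fasta(path, nonstandard: str = "reject") -> LabeledDataset:
    """Read a multi-record FASTA file into a dataset.

    Labels are taken from ``|label=0/1`` header tags when present and left
    missing otherwise. Records containing residues outside the standard
    alphabet are rejected with an error by default, or silently dropped with
    ``nonstandard='drop'``.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    text = path.read_text()
    if not text.strip():
        raise DataError(f"empty FASTA file: {path}")
    if not text.lstrip().startswith(">"):
        raise DataError(f"malformed FASTA (no '>' header) in {path}")
    rows = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        rid, label = rec.id, np.nan
        if "|label=" in rec.description:
            tag = rec.description.split("|label=", 1)[1].split()[0]
            if tag not in {"0", "1"}:
                raise DataError(f"record {rid!r}: label {tag!r} not in {{0,1}}")
            label = int(tag)
            rid = rid.split("|label=", 1)[0]
        if len(rec.seq) == 0:
            raise DataError(f"record {rid!r}: empty sequence")
        rows.append({"id": rid, "sequence": str(rec.seq), "label": label})
    if not rows:
        raise DataError(f"no FASTA records parsed from {path}")
    return LabeledDataset.from_records(rows, nonstandard=nonstandard)


def read_csv_dataset(path, nonstandard: str = "reject") -> LabeledDataset:
    """Read a ``sequence,label[,id,split,fold]`` CSV into a dataset.

    Labels must be exactly 0 or 1; duplicate sequences are kept with a
    warning so class counts stay faithful to the input.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    df = pd.read_csv(path)
    if "sequence" not in df.columns:
        raise DataError("CSV must have a 'sequence' column")
    if "label" in df.columns:
        for i, v in enumerate(df["label"]):
            if pd.isna(v):
                raise DataError(f"row {i}: missing label")
            if float(v) not in (0.0, 1.0):
                raise DataError(f"row {i}: label {v!r} not in {{0,1}}")
        df["label"] = df["label"].astype(float)
    if "id" not in df.columns:
        df["id"] = [f"p{i}" for i in range(len(df))]
    dup = df["sequence"].duplicated()
    if dup.any():
        warnings.warn(f"{int(dup.sum())} duplicate sequences kept", stacklevel=2)
    return LabeledDataset(_validate_sequences(df, nonstandard))


def stratified_split(ds: LabeledDataset, test_fraction: float = 0.2,
                     seed: int = 0) -> LabeledDataset:
    """Assign train/test split tags, stratified per class.

    Per class, ``floor(n_class * test_fraction)`` records go to test and the
    remainder to train, so class counts are deterministic for a given input
    and only the membership depends on the seed.
    """
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must be in (0, 1)")
    y = ds.labels
    if np.isnan(y).any():
        raise DataError("cannot split: unlabeled records present")
    rng = np.random.default_rng(seed)
    split = np.full(len(ds), TRAIN, dtype=object)
    for cls in (0.0, 1.0):
        idx = np.flatnonzero(y == cls)
        if len(idx) < 2:
            raise DataError(f"class {int(cls)} has fewer than 2 members")
        n_test = int(np.floor(len(idx) * test_fraction))
        split[rng.permutation(idx)[:n_test]] = TEST
    out = ds.table.copy()
    out["split"] = split
    out["fold"] = -1
    return LabeledDataset(out)


def assign_folds(ds: LabeledDataset, n_folds: int = 5,
                 seed: int = 0) -> LabeledDataset:
    """Assign stratified CV folds to the training split.

    Within each class, shuffled train records are dealt round-robin into
    ``n_folds`` folds, so per-fold class counts differ by at most one.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    out = ds.table.copy()
    if (out["split"] == "").all():
        out["split"] = TRAIN
    train_mask = (out["split"] == TRAIN).to_numpy()
    y = out["label"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    fold = np.full(len(out), -1, dtype=int)
    for cls in (0.0, 1.0):
        idx = np.flatnonzero(train_mask & (y == cls))
        if len(idx) < n_folds:
            raise DataError(
                f"class {int(cls)} has {len(idx)} train members "
                f"< {n_folds} folds")
        perm = rng.permutation(idx)
        fold[perm] = np.arange(len(perm)) % n_folds
    out["fold"] = fold
    return LabeledDataset(out)
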