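"""Sequence encoders: fixed-width numeric features from peptide sequences.

Two layers:

* pure per-sequence functions (``encode_kmer``, ``encode_cksaap``, ...) that
  map one sequence string to one numeric vector, and
* :class:`Encoder` objects that wrap them for whole datasets, learning any
  dataset-level state (maximum padded length, k-mer embedding model,
  language-model provider) from the training sequences via ``fit`` before
  ``transform`` produces a :class:`FeatureMatrix`.

Composition encoders (k-mer, grouped k-mer, conjoint triad, CKSAAP blocks)
are normalised frequency vectors; position encoders (one-hot, BLOSUM62 rows,
z-scales, sliding-window composition) are per-residue vectors flattened and
zero-padded to a fixed length; property encoders pool residue scales;
embedding encoders mean-pool learned token vectors.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import tables
from .tables import ALPHABET, AA_INDEX

__all__ = [
    "EncodingSpec", "FeatureMatrix", "Encoder", "make_encoder",
    "encoder_names", "encoding_dimensions",
    "encode_kmer", "encode_cksaap", "encode_gaac_family", "encode_ctriad",
    "encode_ctd", "encode_paac", "encode_binary", "encode_eaac",
    "encode_aaindex", "encode_blosum62", "encode_zscale",
    "encode_index_sequence",
]


class EncodingError(ValueError):
    """Raised when a sequence cannot be encoded under a scheme's params."""


@dataclass(frozen=True)
class EncodingSpec:
    """Name + parameters of one encoding scheme.

    ``shape_kind`` distinguishes schemes whose width is intrinsic
    ('fixed') from per-residue schemes whose width scales with the padded
    length ('per-residue').
    """

    name: str
    params: tuple = ()
    shape_kind: str = "fixed"

    def __str__(self) -> str:
        return self.name


@dataclass
class FeatureMatrix:
    """Numeric features for one encoding, rows aligned to a dataset."""

    encoding: str
    values: np.ndarray
    feature_names: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length mismatch")
        if not np.isfinite(self.values).all():
            raise EncodingError(
                f"{self.encoding}: non-finite values after encoding")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# composition-based encoders
# ---------------------------------------------------------------------------

def _kmer_index(k: int) -> dict[str, int]:
    return {"".join(t): i
            for i, t in enumerate(itertools.product(ALPHABET, repeat=k))}


def kmer_feature_names(k: int, alphabet: str = ALPHABET) -> list[str]:
    return ["".join(t) for t in itertools.product(alphabet, repeat=k)]


def encode_kmer(seq: str, k: int) -> np.ndarray:
    """Overlapping k-mer frequencies: count(q) / (L - k + 1), length 20^k.

    k=1 is amino-acid composition (AAC), k=2 di-peptide (DPC), k=3
    tri-peptide composition (TPC).
    """
    if not 1 <= k <= 3:
        raise ValueError("k must be in 1..3")
    L = len(seq)
    if L < k:
        raise EncodingError(f"sequence length {L} < k={k}")
    idx = _kmer_index(k)
    v = np.zeros(20 ** k)
    for i in range(L - k + 1):
        v[idx[seq[i:i + k]]] += 1
    return v / (L - k + 1)


def encode_cksaap(seq: str, k_max: int = 5) -> np.ndarray:
    """Composition of k-spaced amino-acid pairs, gaps 0..k_max.

    Block g counts ordered pairs (a, b) at positional distance g+1,
    normalised by the number of such pairs, L - g - 1. The gap-0 block is
    numerically identical to di-peptide composition. Gaps too large for the
    sequence yield an all-zero block with a warning.
    """
    L = len(seq)
    pair_idx = _kmer_index(2)
    out = np.zeros(400 * (k_max + 1))
    for g in range(k_max + 1):
        n_pairs = L - g - 1
        if n_pairs < 1:
            warnings.warn(
                f"CKSAAP: length {L} too short for gap {g}; zero block",
                stacklevel=2)
            continue
        block = out[400 * g: 400 * (g + 1)]
        for i in range(n_pairs):
            block[pair_idx[seq[i] + seq[i + g + 1]]] += 1
        block /= n_pairs
    return out


def cksaap_feature_names(k_max: int = 5) -> list[str]:
    return [f"{a}.gap{g}.{b}"
            for g in range(k_max + 1) for a in ALPHABET for b in ALPHABET]


def encode_gaac_family(seq: str, order: int = 1) -> np.ndarray:
    """Grouped k-mer composition over the 5 physicochemical classes.

    order 1/2/3 gives 5/25/125 features (GAAC / GDPC / GTPC).
    """
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    L = len(seq)
    if L < order:
        raise EncodingError(f"sequence length {L} < order={order}")
    gmap = tables.gaac_map()
    names = sorted(tables.gaac_groups())
    gidx = {g: i for i, g in enumerate(names)}
    v = np.zeros(5 ** order)
    for i in range(L - order + 1):
        code = 0
        for aa in seq[i:i + order]:
            code = code * 5 + gidx[gmap[aa]]
        v[code] += 1
    return v / (L - order + 1)


def gaac_feature_names(order: int) -> list[str]:
    names = sorted(tables.gaac_groups())
    return ["".join(t) for t in itertools.product(names, repeat=order)]


def encode_ctriad(seq: str) -> np.ndarray:
    """Conjoint-triad frequencies: consecutive residue triples under the
    7-class alphabet, normalised by the triad count L - 2 (343 features)."""
    L = len(seq)
    if L < 3:
        raise EncodingError(f"sequence length {L} < 3 for conjoint triad")
    gmap = tables.ctriad_map()
    names = sorted(tables.ctriad_groups())
    gidx = {g: i for i, g in enumerate(names)}
    v = np.zeros(343)
    for i in range(L - 2):
        a, b, c = (gidx[gmap[x]] for x in seq[i:i + 3])
        v[a * 49 + b * 7 + c] += 1
    return v / (L - 2)


def ctriad_feature_names() -> list[str]:
    names = sorted(tables.ctriad_groups())
    return [f"{a}.{b}.{c}"
            for a in names for b in names for c in names]


def encode_ctd(seq: str, part: str) -> np.ndarray:
    """Composition / Transition / Distribution descriptors.

    For each of 13 physicochemical properties partitioned into 3 groups:

    * C: the 3 group fractions (39 features, each property summing to 1);
    * T: frequencies of adjacent-residue transitions between distinct
      groups (3 unordered pairs), normalised by L - 1 (39 features);
    * D: for each group, positions (as percent of L) of the first, 25%,
      50%, 75% and last occurrence; 0 for absent groups (195 features).
    """
    if part not in ("C", "T", "D"):
        raise ValueError("part must be 'C', 'T' or 'D'")
    L = len(seq)
    if L < 1 or (part == "T" and L < 2):
        raise EncodingError(f"sequence length {L} too short for CTD-{part}")
    props = tables.ctd_properties()
    out = []
    for prop, groups in props.items():
        gmap = {aa: gi for gi, residues in enumerate(groups) for aa in residues}
        codes = np.array([gmap[aa] for aa in seq])
        if part == "C":
            out.extend(np.bincount(codes, minlength=3) / L)
        elif part == "T":
            pairs = list(zip(codes[:-1], codes[1:]))
            for a, b in ((0, 1), (0, 2), (1, 2)):
                n = sum(1 for x, y in pairs
                        if (x, y) == (a, b) or (x, y) == (b, a))
                out.append(n / (L - 1))
        else:
            for gi in range(3):
                pos = np.flatnonzero(codes == gi) + 1  # 1-based positions
                if len(pos) == 0:
                    out.extend([0.0] * 5)
                    continue
                n = len(pos)
                marks = [0, int(np.floor(0.25 * n)) - 1,
                         int(np.floor(0.50 * n)) - 1,
                         int(np.floor(0.75 * n)) - 1, n - 1]
                marks = [max(m, 0) for m in marks]
                out.extend(pos[m] * 100.0 / L for m in marks)
    return np.asarray(out)


def ctd_feature_names(part: str) -> list[str]:
    props = list(tables.ctd_properties())
    if part == "C":
        return [f"{p}.g{g}" for p in props for g in (1, 2, 3)]
    if part == "T":
        return [f"{p}.tr{a}{b}" for p in props for a, b in ((1, 2), (1, 3), (2, 3))]
    return [f"{p}.g{g}.d{d}" for p in props for g in (1, 2, 3)
            for d in (0, 25, 50, 75, 100)]


def encode_paac(seq: str, lam: int = 5, w: float = 0.05) -> np.ndarray:
    """Pseudo-amino-acid composition: 20 + lam features.

    The first 20 components are residue frequencies and the last ``lam``
    are rank-d sequence-order correlation factors theta_d, d = 1..lam, with

        theta_d = mean over i of Theta(R_i, R_{i+d}),
        Theta(a, b) = mean over the 3 standardised property scales of
                      (H(b) - H(a))^2,

    all normalised by 1 + w * sum(theta) so the full vector is a proper
    composition in Chou's sense.
    """
    L = len(seq)
    if L <= lam:
        raise EncodingError(f"sequence length {L} must exceed lambda={lam}")
    props = tables.paac_properties().to_numpy()  # 20 x 3
    props = (props - props.mean(axis=0)) / props.std(axis=0)
    codes = np.array([AA_INDEX[aa] for aa in seq])
    theta = np.empty(lam)
    for d in range(1, lam + 1):
        diffs = props[codes[d:]] - props[codes[:-d]]
        theta[d - 1] = np.mean(diffs ** 2)
    freqs = np.bincount(codes, minlength=20) / L
    denom = 1.0 + w * theta.sum()
    return np.concatenate([freqs / denom, w * theta / denom])


def paac_feature_names(lam: int = 5) -> list[str]:
    return list(ALPHABET) + [f"theta{d}" for d in range(1, lam + 1)]


# ---------------------------------------------------------------------------
# position-based encoders (fixed padded length)
# ---------------------------------------------------------------------------

def _check_length(seq: str, L_max: int) -> None:
    if len(seq) > L_max:
        raise EncodingError(
            f"sequence length {len(seq)} exceeds padded length {L_max}")


def encode_binary(seq: str, L_max: int) -> np.ndarray:
    """One-hot encoding, 20 positions per residue, zero-padded to L_max."""
    _check_length(seq, L_max)
    v = np.zeros(20 * L_max)
    for i, aa in enumerate(seq):
        v[20 * i + AA_INDEX[aa]] = 1.0
    return v


def encode_blosum62(seq: str, L_max: int) -> np.ndarray:
    """Per-residue BLOSUM62 substitution-score rows, zero-padded."""
    _check_length(seq, L_max)
    m = tables.blosum62()
    v = np.zeros(20 * L_max)
    for i, aa in enumerate(seq):
        v[20 * i: 20 * (i + 1)] = m.loc[aa].to_numpy()
    return v


def encode_zscale(seq: str, L_max: int) -> np.ndarray:
    """Per-residue 5-component z-scale descriptors, zero-padded."""
    _check_length(seq, L_max)
    z = tables.zscales()
    v = np.zeros(5 * L_max)
    for i, aa in enumerate(seq):
        v[5 * i: 5 * (i + 1)] = z[aa]
    return v


def encode_index_sequence(seq: str, L_max: int) -> np.ndarray:
    """Ordinal residue indices (1..20), zero-padded: the fixed-vector form
    consumed by fallback learners in place of a learned residue embedding."""
    _check_length(seq, L_max)
    v = np.zeros(L_max)
    for i, aa in enumerate(seq):
        v[i] = AA_INDEX[aa] + 1
    return v


def encode_eaac(seq: str, window: int = 5, L_max: int | None = None) -> np.ndarray:
    """Sliding-window amino-acid composition (enhanced AAC).

    Window j (starting at residue j) contributes 20 components
    count(aa in window)/window; windows beyond the real sequence are
    zero-padded up to L_max - window + 1 windows.
    """
    L = len(seq)
    if L < window:
        raise EncodingError(f"sequence length {L} < window {window}")
    if L_max is None:
        L_max = L
    _check_length(seq, L_max)
    n_windows = L_max - window + 1
    v = np.zeros(20 * n_windows)
    for j in range(L - window + 1):
        block = v[20 * j: 20 * (j + 1)]
        for aa in seq[j: j + window]:
            block[AA_INDEX[aa]] += 1
        block /= window
    return v


# ---------------------------------------------------------------------------
# property-pooling encoders
# ---------------------------------------------------------------------------

def encode_aaindex(seq: str, table=None) -> np.ndarray:
    """Mean over residues of each amino-acid index scale in the table."""
    if table is None:
        table = tables.aaindex_snapshot()
    cols = list(table.columns)
    missing = set(seq) - set(cols)
    if missing:
        raise EncodingError(f"residues absent from index table: {missing}")
    mat = table[[aa for aa in seq]].to_numpy()
    return mat.mean(axis=1)


# ---------------------------------------------------------------------------
# dataset-level Encoder objects
# ---------------------------------------------------------------------------

class Encoder:
    """Dataset-level wrapper: ``fit`` learns state from training sequences,
    ``transform`` maps sequences to a :class:`FeatureMatrix`."""

    name: str

    def fit(self, sequences: list[str]) -> "Encoder":
        return self

    def transform(self, sequences: list[str]) -> FeatureMatrix:
        raise NotImplementedError

    def fit_transform(self, sequences: list[str]) -> FeatureMatrix:
        return self.fit(sequences).transform(sequences)


class _FunctionEncoder(Encoder):
    def __init__(self, name: str, fn: Callable[[str], np.ndarray],
                 feature_names: list[str]):
        self.name = name
        self._fn = fn
        self._feature_names = feature_names

    def transform(self, sequences):
        rows = [self._fn(s) for s in sequences]
        return FeatureMatrix(self.name, np.vstack(rows), self._feature_names)


class _PaddedEncoder(Encoder):
    """Per-residue encoder padded to the longest training sequence."""

    def __init__(self, name: str, fn_factory, width_per_pos: int,
                 L_max: int | None = None):
        self.name = name
        self._factory = fn_factory
        self._width = width_per_pos
        self.L_max = L_max

    def fit(self, sequences):
        if self.L_max is None:
            self.L_max = max(len(s) for s in sequences)
        return self

    def transform(self, sequences):
        if self.L_max is None:
            raise RuntimeError(f"{self.name}: call fit before transform")
        fn, names = self._factory(self.L_max)
        rows = [fn(s) for s in sequences]
        return FeatureMatrix(self.name, np.vstack(rows), names)


class W2VEncoder(Encoder):
    """Mean-pooled skip-gram k-mer embeddings (see :mod:`stackpep.w2v`)."""

    def __init__(self, k: int, dim: int = 128, window: int = 40,
                 epochs: int = 100, seed: int = 0, corpus=None):
        self.name = f"W2V_{k}"
        self.k, self.dim = k, dim
        self.window, self.epochs, self.seed = window, epochs, seed
        self.corpus = corpus
        self.model = None

    def fit(self, sequences):
        from .w2v import train_w2v
        corpus = self.corpus if self.corpus is not None else sequences
        self.model = train_w2v(corpus, k=self.k, dim=self.dim,
                               window=self.window, epochs=self.epochs,
                               seed=self.seed)
        return self

    def transform(self, sequences):
        from .w2v import encode_w2v
        if self.model is None:
            raise RuntimeError(f"{self.name}: call fit before transform")
        rows = [encode_w2v(s, self.model, self.k) for s in sequences]
        names = [f"w2v{self.k}_{i}" for i in range(self.dim)]
        return FeatureMatrix(self.name, np.vstack(rows), names)


class PLMEncoder(Encoder):
    """Mean-pooled protein-language-model embeddings via a provider."""

    name = "ESM2"

    def __init__(self, provider: str = "stub", **kwargs):
        self.provider = provider
        self.kwargs = kwargs

    def transform(self, sequences):
        from .plm import embed_sequences
        values = embed_sequences(sequences, provider=self.provider,
                                 **self.kwargs)
        names = [f"plm_{i}" for i in range(values.shape[1])]
        return FeatureMatrix(self.name, values, names)


# -- registry ---------------------------------------------------------------

#: Intrinsic dimensions of the fixed-width composition/property encoders.
FIXED_DIMS = {
    "AAC": 20, "DPC": 400, "TPC": 8000, "PAAC": 25, "CKSAAP": 2400,
    "GAAC": 5, "GDPC": 25, "GTPC": 125, "CTriad": 343,
    "CTDC": 39, "CTDT": 39, "CTDD": 195,
}

#: Encodings only consumable after padding to a fixed maximum length.
PER_RESIDUE = ("BE", "NN", "EAAC", "BLOSUM62", "ZSCALE")


def make_encoder(name: str, seed: int = 0, L_max: int | None = None,
                 **params) -> Encoder:
    """Build an encoder by registry name.

    ``L_max`` fixes the padded length for per-residue schemes (default:
    longest training sequence seen in ``fit``); ``seed`` controls embedding
    training; other keyword params are scheme-specific.
    """
    if name == "AAC":
        return _FunctionEncoder(name, lambda s: encode_kmer(s, 1),
                                kmer_feature_names(1))
    if name == "DPC":
        return _FunctionEncoder(name, lambda s: encode_kmer(s, 2),
                                kmer_feature_names(2))
    if name == "TPC":
        return _FunctionEncoder(name, lambda s: encode_kmer(s, 3),
                                kmer_feature_names(3))
    if name == "CKSAAP":
        k_max = params.get("k_max", 5)
        return _FunctionEncoder(name, lambda s: encode_cksaap(s, k_max),
                                cksaap_feature_names(k_max))
    if name in ("GAAC", "GDPC", "GTPC"):
        order = {"GAAC": 1, "GDPC": 2, "GTPC": 3}[name]
        return _FunctionEncoder(name, lambda s: encode_gaac_family(s, order),
                                gaac_feature_names(order))
    if name == "CTriad":
        return _FunctionEncoder(name, encode_ctriad, ctriad_feature_names())
    if name in ("CTDC", "CTDT", "CTDD"):
        part = name[-1]
        return _FunctionEncoder(name, lambda s: encode_ctd(s, part),
                                ctd_feature_names(part))
    if name == "PAAC":
        lam, w = params.get("lam", 5), params.get("w", 0.05)
        return _FunctionEncoder(name, lambda s: encode_paac(s, lam, w),
                                paac_feature_names(lam))
    if name == "AAINDEX":
        table = params.get("table")
        enc = _FunctionEncoder(name, lambda s: encode_aaindex(s, table),
                               list((table if table is not None
                                     else tables.aaindex_snapshot()).index))
        return enc
    if name == "BE":
        return _PaddedEncoder(name, lambda L: (
            lambda s: encode_binary(s, L),
            [f"pos{i}_{aa}" for i in range(L) for aa in ALPHABET]), 20, L_max)
    if name == "BLOSUM62":
        return _PaddedEncoder(name, lambda L: (
            lambda s: encode_blosum62(s, L),
            [f"pos{i}_b{aa}" for i in range(L) for aa in ALPHABET]), 20, L_max)
    if name == "ZSCALE":
        return _PaddedEncoder(name, lambda L: (
            lambda s: encode_zscale(s, L),
            [f"pos{i}_z{j}" for i in range(L) for j in range(1, 6)]), 5, L_max)
    if name == "NN":
        return _PaddedEncoder(name, lambda L: (
            lambda s: encode_index_sequence(s, L),
            [f"pos{i}_idx" for i in range(L)]), 1, L_max)
    if name == "EAAC":
        window = params.get("window", 5)
        return _PaddedEncoder(name, lambda L: (
            lambda s: encode_eaac(s, window, L),
            [f"win{j}_{aa}" for j in range(L - window + 1)
             for aa in ALPHABET]), 20, L_max)
    if name.startswith("W2V_"):
        k = int(name.split("_")[1])
        return W2VEncoder(k, seed=seed, **params)
    if name == "ESM2":
        return PLMEncoder(**params)
    raise ValueError(f"unknown encoding {name!r}")


def encoder_names(include_per_residue: bool = True) -> list[str]:
    names = list(FIXED_DIMS) + ["EAAC", "AAINDEX", "BLOSUM62", "ZSCALE",
                                "ESM2", "W2V_1", "W2V_2", "W2V_3", "W2V_4"]
    if include_per_residue:
        return names
    return [n for n in names if n not in PER_RESIDUE]


def encoding_dimensions(sample: str = "ACDEFGHIKLMNPQRSTVWYAC") -> dict[str, int]:
    """Actual output widths of the intrinsic-width encoders, measured by
    encoding a sample sequence (not read from a lookup table)."""
    dims = {}
    for name in FIXED_DIMS:
        enc = make_encoder(name)
        dims[name] = enc.fit_transform([sample]).n_features
    return dims
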