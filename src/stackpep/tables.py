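"""Bundled physicochemical property tables.

All residue-level constants used by the encoders live here: the 5-class
physicochemical grouping of the 20 amino acids, the conjoint-triad 7-class
grouping, thirteen 3-way property partitions for composition/transition/
distribution descriptors, the 5 Sandberg z-scales, the pseudo-amino-acid
composition property triple (hydrophobicity, hydrophilicity, side-chain
mass), and a reduced snapshot of published amino-acid index scales.

Tables are shipped as plain TSV files next to this module; BLOSUM62 is taken
from Biopython's published substitution matrices rather than re-bundled.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

#: Canonical alphabetical ordering of the 20 standard amino acids.
#: All feature vectors index residues in this order.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

#: Residues outside the standard alphabet that appear in real data.
NONSTANDARD = set("BJOUXZ")


def _table_path(name: str):
    return resources.files("stackpep").joinpath("tables", name)


@lru_cache(maxsize=None)
def _read_tsv(name: str) -> pd.DataFrame:
    with resources.as_file(_table_path(name)) as p:
        return pd.read_csv(p, sep="\t")


@lru_cache(maxsize=None)
def gaac_groups() -> dict[str, str]:
    """5-class physicochemical grouping, group name -> residue string."""
    df = _read_tsv("gaac_groups.tsv")
    groups = dict(zip(df["group"], df["residues"]))
    assert sorted("".join(groups.values())) == sorted(ALPHABET)
    return groups


@lru_cache(maxsize=None)
def ctriad_groups() -> dict[str, str]:
    """Conjoint-triad 7-class grouping by side-chain dipole and volume."""
    df = _read_tsv("ctriad_groups.tsv")
    groups = dict(zip(df["group"], df["residues"]))
    assert sorted("".join(groups.values())) == sorted(ALPHABET)
    return groups


def _group_map(groups: dict[str, str]) -> dict[str, str]:
    return {aa: g for g, residues in groups.items() for aa in residues}


@lru_cache(maxsize=None)
def gaac_map() -> dict[str, str]:
    return _group_map(gaac_groups())


@lru_cache(maxsize=None)
def ctriad_map() -> dict[str, str]:
    return _group_map(ctriad_groups())


@lru_cache(maxsize=None)
def ctd_properties() -> dict[str, tuple[str, str, str]]:
    """Thirteen 3-way residue partitions (Dubchak-style convention).

    Returns property name -> (group1, group2, group3) residue strings.
    Each triple partitions the 20-letter alphabet.
    """
    df = _read_tsv("ctd_groups.tsv")
    out: dict[str, tuple[str, str, str]] = {}
    for _, row in df.iterrows():
        triple = (row["g1"], row["g2"], row["g3"])
        assert sorted("".join(triple)) == sorted(ALPHABET), row["property"]
        out[row["property"]] = triple
    return out


@lru_cache(maxsize=None)
def zscales() -> dict[str, np.ndarray]:
    """Sandberg's 5 z-scale descriptors per amino acid."""
    df = _read_tsv("zscale.tsv").set_index("aa")
    return {aa: df.loc[aa].to_numpy(dtype=float) for aa in ALPHABET}


@lru_cache(maxsize=None)
def paac_properties() -> pd.DataFrame:
    """Hydrophobicity / hydrophilicity / side-chain mass, indexed by residue.

    Values are the standard tables of Chou's pseudo-amino-acid composition;
    the encoder standardises each column over the 20 residues before use.
    """
    return _read_tsv("paac_properties.tsv").set_index("aa").loc[list(ALPHABET)]


@lru_cache(maxsize=None)
def aaindex_snapshot() -> pd.DataFrame:
    """Reduced snapshot of published amino-acid index scales.

    Rows are index identifiers, columns the 20 residues. The full public
    index collection holds several hundred scales; this curated subset keeps
    the encoder exercisable offline, and the encoder's dimension follows the
    table rather than being hard-coded.
    """
    df = _read_tsv("aaindex_snapshot.tsv").set_index("index")
    assert list(df.columns) == list(ALPHABET)
    assert not df.isna().any().any()
    return df


@lru_cache(maxsize=None)
def blosum62() -> pd.DataFrame:
    """The published BLOSUM62 matrix restricted to the 20 standard residues."""
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("BLOSUM62")
    data = {a: [float(m[a, b]) for b in ALPHABET] for a in ALPHABET}
    return pd.DataFrame(data, index=list(ALPHABET)).T
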