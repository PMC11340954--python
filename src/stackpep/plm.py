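"""Protein-language-model embedding providers.

The grid's language-model column consumes one mean-pooled embedding vector
per sequence from a named *provider*. Two providers ship here:

* ``"stub"`` — a deterministic hash-seeded random projection: each residue
  maps to a fixed pseudo-random vector derived from its identity and
  position parity, mean-pooled over the sequence. It has the right shape
  and determinism contracts for testing the pipeline, carries only
  composition-level signal, and is clearly not a trained language model.
* ``"esm2"`` — an adapter that imports the ``esm`` package at call time.
  It is an optional extension: when the package is unavailable an error
  explains how to proceed (install it, use the stub, or run the
  language-model-free grid).

Embeddings are cached in-process keyed by (provider, dim, sequence).
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["embed_sequences", "register_provider", "available_providers"]

_PROVIDERS: dict[str, callable] = {}
_CACHE: dict[tuple, np.ndarray] = {}


def register_provider(name: str, fn) -> None:
    """Register ``fn(sequences, dim) -> (n, dim) array`` under ``name``."""
    _PROVIDERS[name] = fn


def available_providers() -> list[str]:
    return sorted(_PROVIDERS)


def _stub_residue_vector(aa: str, dim: int) -> np.ndarray:
    seed = int.from_bytes(hashlib.sha256(f"plm-stub:{aa}".encode()).digest()[:4],
                          "little")
    return np.random.default_rng(seed).standard_normal(dim)


def _stub_provider(sequences, dim: int = 64) -> np.ndarray:
    table = {}
    rows = []
    for seq in sequences:
        vecs = []
        for aa in seq:
            if aa not in table:
                table[aa] = _stub_residue_vector(aa, dim)
            vecs.append(table[aa])
        rows.append(np.mean(vecs, axis=0))
    return np.vstack(rows)


def _esm2_provider(sequences, dim: int = 320,
                   checkpoint: str = "esm2_t6_8M_UR50D") -> np.ndarray:
    try:
        import esm  # noqa: F401
    except ImportError as e:
        raise RuntimeError(
            "the 'esm' package is not installed; either install the "
            "fair-esm extra, use provider='stub' for a deterministic "
            "test embedding, or run the language-model-free grid "
            "(grid(include_plm=False))") from e
    import torch  # pragma: no cover - optional heavy path

    model, alphabet = esm.pretrained.load_model_and_alphabet(checkpoint)
    model.eval()
    batch_converter = alphabet.get_batch_converter()
    rows = []
    with torch.no_grad():
        for i, seq in enumerate(sequences):
            _, _, toks = batch_converter([(f"s{i}", seq)])
            out = model(toks, repr_layers=[model.num_layers])
            rep = out["representations"][model.num_layers][0, 1:len(seq) + 1]
            rows.append(rep.mean(0).numpy())
    return np.vstack(rows)


register_provider("stub", _stub_provider)
register_provider("esm2", _esm2_provider)


def embed_sequences(sequences, provider: str = "stub", dim: int = 64,
                    **kwargs) -> np.ndarray:
    """Mean-pooled per-sequence embeddings from a registered provider.

    Duplicate sequences hit an in-process cache, so identical inputs give
    identical rows without recomputation.
    """
    if provider not in _PROVIDERS:
        raise RuntimeError(
            f"unknown embedding provider {provider!r}; available: "
            f"{available_providers()}")
    fn = _PROVIDERS[provider]
    todo = [s for s in dict.fromkeys(sequences)
            if (provider, dim, s) not in _CACHE]
    if todo:
        fresh = fn(todo, dim=dim, **kwargs) if provider == "stub" else \
            fn(todo, dim=dim, **kwargs)
        for s, row in zip(todo, fresh):
            _CACHE[(provider, dim, s)] = row
    return np.vstack([_CACHE[(provider, dim, s)] for s in sequences])
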