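"""Biomedical-text representations of drugs and side effects.

A pluggable sentence-embedding provider turns each entity's free-text
description into a fixed-length vector; a linear projection into the shared
embedding space is learned jointly with the rest of the model.  Two
providers ship with the package:

* :class:`HashedBagOfWordsEncoder` -- a deterministic feature-hashing
  encoder (each lowercased token hashed to one of f signed buckets, counts
  accumulated, L2-normalized).  It carries lexical-overlap signal and needs
  no pretrained weights, which keeps the whole pipeline self-contained.
* :class:`PrecomputedTableProvider` -- reads entity_id -> vector rows from
  a TSV, the adapter route for any external language model whose sentence
  embeddings were exported beforehand.

A leakage filter removes description sentences that mention both a corpus
drug and a corpus side-effect term, so the text modality cannot smuggle in
the associations the model is asked to predict.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol

import numpy as np

__all__ = [
    "TextEmbeddingProvider",
    "HashedBagOfWordsEncoder",
    "PrecomputedTableProvider",
    "SemanticTable",
    "embed_corpus_texts",
    "sanitize_description",
]

_TOKEN_RE = re.compile(r"[a-z0-9]+")
_SENTENCE_RE = re.compile(r"[^.!?]*[.!?]?\s*")


class TextEmbeddingProvider(Protocol):
    name: str
    output_dim: int

    def embed(self, text: str) -> np.ndarray: ...


@dataclass
class HashedBagOfWordsEncoder:
    """Deterministic hashed bag-of-words sentence encoder.

    Each token is mapped by a stable hash (md5, independent of process
    state) to a bucket in [0, f) with a +/-1 sign; token counts accumulate
    and the result is L2-normalized.  Empty text gives the zero vector.
    """

    output_dim: int = 64
    name: str = "hashed-bow"

    def embed(self, text: str) -> np.ndarray:
        vec = np.zeros(self.output_dim)
        for token in _TOKEN_RE.findall(text.lower()):
            digest = hashlib.md5(token.encode()).digest()
            bucket = int.from_bytes(digest[:4], "little") % self.output_dim
            sign = 1.0 if digest[4] % 2 == 0 else -1.0
            vec[bucket] += sign
        norm = np.linalg.norm(vec)
        return vec / norm if norm > 0 else vec


@dataclass
class PrecomputedTableProvider:
    """Embeddings looked up from a TSV of entity_id + f floats."""

    table: dict[str, np.ndarray]
    output_dim: int
    name: str = "precomputed"

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PrecomputedTableProvider":
        table: dict[str, np.ndarray] = {}
        dim = None
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 2:
                    continue
                vec = np.array([float(x) for x in parts[1:]])
                if dim is None:
                    dim = vec.size
                elif vec.size != dim:
                    raise ValueError(f"embedding dimension drift at {parts[0]!r}")
                table[parts[0]] = vec
        if dim is None:
            raise ValueError("empty embedding table")
        return cls(table, dim)

    def embed(self, text: str) -> np.ndarray:  # keyed by id, not text
        raise NotImplementedError("PrecomputedTableProvider is looked up by entity id")

    def lookup(self, entity_id: str) -> np.ndarray:
        return self.table.get(entity_id, np.zeros(self.output_dim))


@dataclass
class SemanticTable:
    """Per-entity embedding matrix, row-indexed by id list order."""

    ids: list[str]
    vectors: np.ndarray  # (n_entities, f)
    provider_name: str = "hashed-bow"
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        if self.vectors.shape[0] != len(self.ids):
            raise ValueError("one vector per entity required")
        self.index = {e: i for i, e in enumerate(self.ids)}


def embed_corpus_texts(
    ids: list[str], texts: list[str], provider: TextEmbeddingProvider
) -> SemanticTable:
    """Embed each entity's description; empty text maps to the zero vector."""
    if len(ids) != len(texts):
        raise ValueError("ids and texts must align")
    if isinstance(provider, PrecomputedTableProvider):
        rows = [provider.lookup(e) for e in ids]
    else:
        rows = []
        for text in texts:
            v = provider.embed(text) if text.strip() else np.zeros(provider.output_dim)
            if v.shape != (provider.output_dim,):
                raise ValueError(
                    f"provider {provider.name!r} returned dimension {v.shape}, expected {provider.output_dim}"
                )
            rows.append(v)
    return SemanticTable(list(ids), np.array(rows), provider.name)


def sanitize_description(text: str, drug_terms: list[str], se_terms: list[str]) -> str:
    """Drop sentences that mention both a corpus drug and a side-effect term.

    The filter is a plain substring test per sentence (case-insensitive),
    sentences split naively on '.', '!', '?'.  It never lengthens the text.
    """
    if not text:
        return text
    drugs = [t.lower() for t in drug_terms if t]
    ses = [t.lower() for t in se_terms if t]
    kept: list[str] = []
    for sentence in _SENTENCE_RE.findall(text):
        if not sentence:
            continue
        low = sentence.lower()
        if any(d in low for d in drugs) and any(s in low for s in ses):
            continue
        kept.append(sentence)
    return "".join(kept).strip()
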