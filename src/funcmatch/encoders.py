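"""Frozen-encoder abstraction.

The matching model treats its sequence and text encoders as frozen black
boxes producing fixed-length vectors.  Heavy pretrained encoders are only
ever integrated through precomputed embedding tables (``table_lookup``);
for everything exercisable on a laptop there are two deterministic toy
encoders:

``toy_sequence``
    k-mer count features hashed into ``dim`` buckets, L2-normalized.
``toy_text``
    lowercased token (whitespace/punctuation split) count features hashed
    into ``dim`` buckets, L2-normalized — texts sharing tokens therefore
    have positive cosine similarity, the compositionality that zero-shot
    transfer through descriptions relies on.

Both are pure functions of (input, spec): repeated calls agree bit-for-bit.
"""

from __future__ import annotations

import hashlib
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Any, Iterable

import numpy as np
from scipy import sparse

from .data_io import EmbeddingTable

_TOKEN_RE = re.compile(r"[a-z0-9]+")


class MissingEmbeddingError(KeyError):
    pass


@dataclass
class EncoderSpec:
    """Configuration of one frozen encoder.

    kind: ``toy_sequence`` | ``toy_text`` | ``table_lookup``
    dim: output vector length
    params: named settings — ``k`` (k-mer size, toy_sequence only, default 3),
        ``seed`` (hash seed, default 0), ``table`` (EmbeddingTable, lookup only).
    """

    kind: str
    dim: int
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in {"toy_sequence", "toy_text", "table_lookup"}:
            raise ValueError(f"unknown encoder kind {self.kind!r}")
        if self.dim <= 0:
            raise ValueError("encoder dim must be positive")


def stable_bucket(token: str, dim: int, seed: int) -> int:
    """Map a token to a bucket with a platform-stable keyed hash."""
    digest = hashlib.blake2b(
        token.encode("utf-8"), digest_size=8, key=str(seed).encode()
    ).digest()
    return int.from_bytes(digest, "big") % dim


def _bucket_counts(tokens: Iterable[str], dim: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """L2-normalized hashed counts as (bucket indices, values)."""
    counts = Counter(stable_bucket(tok, dim, seed) for tok in tokens)
    idx = np.fromiter(counts.keys(), dtype=np.int64, count=len(counts))
    val = np.fromiter(counts.values(), dtype=np.float64, count=len(counts))
    norm = np.sqrt((val * val).sum())
    if norm > 0:
        val /= norm
    return idx, val


def _hashed_counts(tokens: Iterable[str], dim: int, seed: int) -> np.ndarray:
    idx, val = _bucket_counts(tokens, dim, seed)
    vec = np.zeros(dim, dtype=np.float64)
    vec[idx] = val
    return vec


def _sequence_kmers(sequence: str, spec: EncoderSpec) -> Iterable[str]:
    if not sequence:
        raise ValueError("cannot encode an empty sequence")
    k = int(spec.params.get("k", 3))
    if len(sequence) < k:
        return [sequence]
    return (sequence[i : i + k] for i in range(len(sequence) - k + 1))


def sequence_buckets(sequence: str, spec: EncoderSpec) -> tuple[np.ndarray, np.ndarray]:
    """Sparse form of :func:`encode_sequence` for the toy k-mer encoder:
    (bucket indices, L2-normalized counts).  Identical values to the dense
    encoding, which is ~98% zeros at the default dimensionality."""
    if spec.kind != "toy_sequence":
        raise ValueError(f"{spec.kind} has no sparse bucket form")
    seed = int(spec.params.get("seed", 0))
    return _bucket_counts(_sequence_kmers(sequence, spec), spec.dim, seed)


def rows_to_csr(rows: list[tuple[np.ndarray, np.ndarray]], dim: int) -> sparse.csr_matrix:
    """Stack (indices, values) rows into a CSR matrix."""
    indptr = np.zeros(len(rows) + 1, dtype=np.int64)
    np.cumsum([len(idx) for idx, _ in rows], out=indptr[1:])
    if rows:
        indices = np.concatenate([idx for idx, _ in rows])
        data = np.concatenate([val for _, val in rows])
    else:
        indices = np.empty(0, dtype=np.int64)
        data = np.empty(0)
    return sparse.csr_matrix((data, indices, indptr), shape=(len(rows), dim))


def encode_sequence_batch(sequences: Iterable[str], spec: EncoderSpec):
    """Encode many sequences: CSR for the toy k-mer encoder, dense otherwise."""
    if spec.kind == "toy_sequence":
        return rows_to_csr([sequence_buckets(s, spec) for s in sequences], spec.dim)
    return np.asarray([encode_sequence(s, spec) for s in sequences])


def encode_sequence(sequence: str, spec: EncoderSpec) -> np.ndarray:
    """Encode an amino-acid sequence into a length-``spec.dim`` vector."""
    if not sequence:
        raise ValueError("cannot encode an empty sequence")
    if spec.kind == "table_lookup":
        return _lookup(sequence, spec)
    if spec.kind != "toy_sequence":
        raise ValueError(f"{spec.kind} is not a sequence encoder")
    seed = int(spec.params.get("seed", 0))
    return _hashed_counts(_sequence_kmers(sequence, spec), spec.dim, seed)


def tokenize(text: str) -> list[str]:
    return _TOKEN_RE.findall(text.lower())


def encode_text(text: str, spec: EncoderSpec) -> np.ndarray:
    """Encode a free-text function description into a length-``spec.dim`` vector."""
    if not text:
        raise ValueError("cannot encode empty text")
    if spec.kind == "table_lookup":
        return _lookup(text, spec)
    if spec.kind != "toy_text":
        raise ValueError(f"{spec.kind} is not a text encoder")
    seed = int(spec.params.get("seed", 0))
    tokens = tokenize(text)
    if not tokens:
        raise ValueError(f"text {text!r} contains no tokens")
    return _hashed_counts(tokens, spec.dim, seed)


def _lookup(key: str, spec: EncoderSpec) -> np.ndarray:
    table = spec.params.get("table")
    if not isinstance(table, EmbeddingTable):
        raise ValueError("table_lookup spec needs params['table'] = EmbeddingTable")
    try:
        vec = table[key]
    except KeyError as exc:
        raise MissingEmbeddingError(str(exc)) from None
    if vec.size != spec.dim:
        raise ValueError(f"table dim {vec.size} != spec dim {spec.dim}")
    return vec
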