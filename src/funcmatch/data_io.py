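"""Domain types and on-disk formats.

The framework moves four kinds of files around: FASTA sequence files,
two-column annotation TSVs (seq_id, term_id), term catalogs (either a
five-column TSV or an OBO subset), and two-column embedding tables
(id, comma-joined floats).  Everything is UTF-8 with Unix newlines.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import obonet

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residues accepted in input sequences; X passes through uncorrupted downstream
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")

NAMESPACES = frozenset(
    {"biological_process", "cellular_component", "molecular_function", "ec_class"}
)

DEFAULT_MAX_LEN = 10_000


class ParseError(ValueError):
    """Malformed on-disk input."""


class ConsistencyError(ValueError):
    """Cross-reference violation (unknown parent, annotation to unknown term...)."""


@dataclass
class ProteinRecord:
    """One protein: identifier, amino-acid sequence, annotated term ids."""

    seq_id: str
    sequence: str
    annotations: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.seq_id}: empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ParseError(
                f"{self.seq_id}: non-standard residues {sorted(bad)} "
                "(only the 20 standard amino acids plus X are accepted)"
            )


@dataclass
class FunctionTerm:
    """One function label: id, namespace, short/long text descriptions, parents.

    ``long_desc`` falls back to ``short_desc`` when empty, so both are always
    non-empty after construction.
    """

    term_id: str
    namespace: str
    short_desc: str
    long_desc: str = ""
    parents: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.namespace not in NAMESPACES:
            raise ValueError(
                f"{self.term_id}: unknown namespace {self.namespace!r}; "
                f"expected one of {sorted(NAMESPACES)}"
            )
        if not self.short_desc:
            raise ValueError(f"{self.term_id}: short_desc must be non-empty")
        if not self.long_desc:
            self.long_desc = self.short_desc
        if self.term_id in self.parents:
            raise ConsistencyError(f"{self.term_id}: term lists itself as parent")


@dataclass
class AnnotationDataset:
    """An ordered protein collection plus the term catalog it annotates against."""

    proteins: list[ProteinRecord]
    terms: dict[str, FunctionTerm]
    split_tag: str = "train"

    def __post_init__(self) -> None:
        if self.split_tag not in {"train", "val", "test", "zero_shot"}:
            raise ValueError(f"unknown split_tag {self.split_tag!r}")

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def validate(self) -> None:
        """Check every annotation references a catalog term."""
        for rec in self.proteins:
            missing = rec.annotations - self.terms.keys()
            if missing:
                raise ConsistencyError(
                    f"{rec.seq_id}: annotations {sorted(missing)} not in term catalog"
                )

    def annotation_map(self) -> dict[str, set[str]]:
        return {rec.seq_id: set(rec.annotations) for rec in self.proteins}


@dataclass
class EmbeddingTable:
    """Precomputed id -> vector map standing in for a frozen encoder's outputs."""

    id_to_vector: dict[str, np.ndarray]
    dim: int

    def __post_init__(self) -> None:
        for key, vec in self.id_to_vector.items():
            if vec.shape != (self.dim,):
                raise ValueError(
                    f"embedding for {key!r} has length {vec.shape}, expected ({self.dim},)"
                )

    def __getitem__(self, key: str) -> np.ndarray:
        try:
            return self.id_to_vector[key]
        except KeyError:
            raise KeyError(f"no embedding stored for identifier {key!r}") from None


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into an ordered list of (seq_id, sequence).

    Headers are split at the first whitespace.  A sequence line appearing
    before any header is a parse error naming the line.
    """
    records: list[tuple[str, str]] = []
    seq_id: str | None = None
    chunks: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if seq_id is not None:
                    records.append((seq_id, "".join(chunks)))
                seq_id = line[1:].split()[0] if line[1:].split() else ""
                if not seq_id:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
                chunks = []
            else:
                if seq_id is None:
                    raise ParseError(
                        f"{path}:{lineno}: sequence data before any '>' header"
                    )
                chunks.append(line.upper())
    if seq_id is not None:
        records.append((seq_id, "".join(chunks)))
    for sid, seq in records:
        bad = set(seq) - VALID_RESIDUES
        if bad:
            raise ParseError(f"{path}: record {sid}: non-standard residues {sorted(bad)}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for seq_id, seq in records:
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Annotations


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column (seq_id, term_id) TSV into seq_id -> term-id set."""
    out: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row:
                continue
            if len(row) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(row)}"
                )
            seq_id, term_id = row
            out.setdefault(seq_id, set()).add(term_id)
    return out


def write_annotations(annotations: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for seq_id in annotations:
            for term_id in sorted(annotations[seq_id]):
                writer.writerow([seq_id, term_id])


# ---------------------------------------------------------------------------
# Term catalogs


def _validate_catalog(terms: dict[str, FunctionTerm]) -> None:
    offenders = {
        (tid, p) for tid, t in terms.items() for p in t.parents if p not in terms
    }
    if offenders:
        raise ConsistencyError(
            "parent ids absent from catalog: "
            + ", ".join(f"{t}->{p}" for t, p in sorted(offenders))
        )
    graph = nx.DiGraph()
    graph.add_nodes_from(terms)
    graph.add_edges_from((tid, p) for tid, t in terms.items() for p in t.parents)
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise ConsistencyError(f"term hierarchy contains a cycle: {cycle}")


def _read_term_tsv(path: str | Path) -> dict[str, FunctionTerm]:
    terms: dict[str, FunctionTerm] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row:
                continue
            if len(row) != 5:
                raise ParseError(
                    f"{path}:{lineno}: expected 5 tab-separated columns, got {len(row)}"
                )
            term_id, namespace, short_desc, long_desc, parents_str = row
            parents = {p for p in parents_str.split(",") if p}
            terms[term_id] = FunctionTerm(term_id, namespace, short_desc, long_desc, parents)
    return terms


def _read_term_obo(path: str | Path) -> dict[str, FunctionTerm]:
    # obonet parses the OBO stanza structure; only id/namespace/name/def/is_a
    # are consumed here.
    graph = obonet.read_obo(path, ignore_obsolete=True)
    terms: dict[str, FunctionTerm] = {}
    for term_id, data in graph.nodes(data=True):
        short = data.get("name", "")
        long_desc = data.get("def", "")
        if long_desc.startswith('"'):
            # OBO def lines look like: "text" [xrefs]
            long_desc = long_desc.split('"')[1]
        parents = set(data.get("is_a", []))
        terms[term_id] = FunctionTerm(
            term_id, data.get("namespace", "molecular_function"), short, long_desc, parents
        )
    return terms


def read_term_catalog(path: str | Path) -> dict[str, FunctionTerm]:
    """Read a term catalog from a five-column TSV or an OBO subset file.

    Missing long descriptions fall back to the short description; parent
    references are validated and the hierarchy must be acyclic.
    """
    with open(path, encoding="utf-8") as fh:
        head = fh.read(2048)
    is_obo = "[Term]" in head or head.startswith("format-version")
    terms = _read_term_obo(path) if is_obo else _read_term_tsv(path)
    _validate_catalog(terms)
    return terms


def write_term_catalog(terms: Mapping[str, FunctionTerm], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for term_id in terms:
            t = terms[term_id]
            writer.writerow(
                [t.term_id, t.namespace, t.short_desc, t.long_desc, ",".join(sorted(t.parents))]
            )


# ---------------------------------------------------------------------------
# Cleaning


def clean_dataset(ds: AnnotationDataset, max_len: int = DEFAULT_MAX_LEN) -> AnnotationDataset:
    """Drop exact duplicate sequences (keeping the first) and over-length sequences.

    Idempotent; removal counts are logged.
    """
    if max_len <= 0:
        raise ValueError("max_len must be positive")
    seen: set[str] = set()
    kept: list[ProteinRecord] = []
    n_dup = n_long = 0
    for rec in ds.proteins:
        if len(rec.sequence) > max_len:
            n_long += 1
            continue
        if rec.sequence in seen:
            n_dup += 1
            continue
        seen.add(rec.sequence)
        kept.append(replace(rec, annotations=set(rec.annotations)))
    logger.info(
        "clean_dataset: removed %d duplicate and %d over-length sequences (%d kept)",
        n_dup, n_long, len(kept),
    )
    return AnnotationDataset(kept, dict(ds.terms), ds.split_tag)


# ---------------------------------------------------------------------------
# Embedding tables


def read_embedding_table(path: str | Path) -> EmbeddingTable:
    """Read a two-column TSV (identifier, comma-joined floats)."""
    vectors: dict[str, np.ndarray] = {}
    dim: int | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row:
                continue
            if len(row) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(row)}"
                )
            key, vec_str = row
            if key in vectors:
                raise ParseError(f"{path}:{lineno}: duplicate identifier {key!r}")
            vec = np.array([float(x) for x in vec_str.split(",")], dtype=np.float64)
            if dim is None:
                dim = vec.size
            elif vec.size != dim:
                raise ParseError(
                    f"{path}:{lineno}: vector for {key!r} has length {vec.size}, "
                    f"expected {dim}"
                )
            vectors[key] = vec
    if dim is None:
        raise ParseError(f"{path}: empty embedding table (dimension undefined)")
    return EmbeddingTable(vectors, dim)


def write_embedding_table(table: EmbeddingTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for key, vec in table.id_to_vector.items():
            fh.write(key + "\t" + ",".join(repr(float(x)) for x in vec) + "\n")
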