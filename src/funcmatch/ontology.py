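"""DAG reasoning over the function-term catalog.

Annotations are trained ancestor-inclusively: a protein annotated with a
specific term is implicitly annotated with every ancestor of that term, so
annotation sets are closed under upward propagation before frequencies,
sampling weights, or losses ever see them.  This module also partitions the
vocabulary for zero-shot evaluation: terms absent from the training label
set are *out-of-vocabulary* and scoring them is zero-shot prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import networkx as nx

from .data_io import AnnotationDataset, FunctionTerm, ProteinRecord


class UnknownTermError(KeyError):
    pass


class OntologyGraph:
    """Directed acyclic child -> parent graph over a term catalog."""

    def __init__(self, terms: Mapping[str, FunctionTerm]):
        g = nx.DiGraph()
        g.add_nodes_from(terms)
        for term in terms.values():
            for parent in term.parents:
                if parent not in terms:
                    raise UnknownTermError(
                        f"{term.term_id} lists unknown parent {parent!r}"
                    )
                g.add_edge(term.term_id, parent)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError(f"term hierarchy is cyclic: {nx.find_cycle(g)}")
        self._g = g

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def ancestors(self, term_id: str) -> set[str]:
        """All terms reachable from ``term_id`` via parent edges (exclusive)."""
        if term_id not in self._g:
            raise UnknownTermError(term_id)
        # edges point child -> parent, so graph-descendants are ontology-ancestors
        return nx.descendants(self._g, term_id)

    def children(self, term_id: str) -> set[str]:
        if term_id not in self._g:
            raise UnknownTermError(term_id)
        return set(self._g.predecessors(term_id))

    def term_ids(self) -> set[str]:
        return set(self._g.nodes)


@dataclass
class TermFrequencyTable:
    """Training-set term counts f_j over propagated annotations."""

    freq: dict[str, int]
    n_sequences: int

    def __post_init__(self) -> None:
        if self.n_sequences <= 0:
            raise ValueError("n_sequences must be positive")
        bad = {t: c for t, c in self.freq.items() if c < 1 or c > self.n_sequences}
        if bad:
            raise ValueError(f"counts out of [1, n_sequences] range: {bad}")

    def get(self, term_id: str) -> int:
        """Count for ``term_id``; unseen terms are assigned frequency 1 so a
        sampling weight can still be formed without dividing by zero."""
        return self.freq.get(term_id, 1)


@dataclass
class VocabularyPartition:
    """Disjoint split of term ids into in-vocabulary and out-of-vocabulary."""

    in_vocab: set[str]
    out_of_vocab: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = self.in_vocab & self.out_of_vocab
        if overlap:
            raise ValueError(f"vocabulary partition overlaps: {sorted(overlap)}")


def propagate_annotations(annotations: Iterable[str], graph: OntologyGraph) -> set[str]:
    """Close an annotation set under ancestor propagation.

    Returns the union of the input terms and every ancestor reachable via
    parent edges; always a superset of the input.
    """
    result: set[str] = set()
    for term_id in annotations:
        if term_id not in graph:
            raise UnknownTermError(term_id)
        result.add(term_id)
        result |= graph.ancestors(term_id)
    return result


def propagate_dataset(ds: AnnotationDataset, graph: OntologyGraph | None = None) -> AnnotationDataset:
    """Return a copy of ``ds`` with every protein's annotations propagated."""
    graph = graph if graph is not None else OntologyGraph(ds.terms)
    proteins = [
        replace(rec, annotations=propagate_annotations(rec.annotations, graph))
        for rec in ds.proteins
    ]
    return AnnotationDataset(proteins, dict(ds.terms), ds.split_tag)


def compute_frequencies(train: AnnotationDataset) -> TermFrequencyTable:
    """Count, per term, how many training proteins carry it (post-propagation).

    Terms never observed in the training set are absent from the table.
    """
    if train.n_proteins == 0:
        raise ValueError("cannot compute term frequencies on an empty dataset")
    freq: dict[str, int] = {}
    for rec in train.proteins:
        for term_id in rec.annotations:
            freq[term_id] = freq.get(term_id, 0) + 1
    return TermFrequencyTable(freq, train.n_proteins)


def classify_nodes(terms: Iterable[str], graph: OntologyGraph) -> dict[str, str]:
    """Label each term ``leaf`` (no children in the catalog) or ``inferred``."""
    return {
        t: ("leaf" if not graph.children(t) else "inferred") for t in terms
    }


def build_zero_shot_split(
    new_release: AnnotationDataset,
    old_vocab: set[str],
    old_seq_ids: set[str],
    strict_sequences: bool = False,
    old_sequences: set[str] | None = None,
) -> AnnotationDataset:
    """Carve the zero-shot test set out of a newer annotation release.

    Keeps only proteins new to the release (seq_id not previously seen; with
    ``strict_sequences`` also requires an unseen sequence string) and, within
    those, only out-of-vocabulary annotations.  Proteins left without any
    annotation are dropped.  Expects ``new_release`` cleaned and propagated.
    """
    if strict_sequences and old_sequences is None:
        raise ValueError("strict_sequences=True requires old_sequences")
    kept: list[ProteinRecord] = []
    for rec in new_release.proteins:
        if rec.seq_id in old_seq_ids:
            continue
        if strict_sequences and rec.sequence in old_sequences:  # type: ignore[operator]
            continue
        novel = rec.annotations - old_vocab
        if not novel:
            continue
        kept.append(replace(rec, annotations=novel))
    return AnnotationDataset(kept, dict(new_release.terms), "zero_shot")
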