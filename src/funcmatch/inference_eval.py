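"""Inference, baselines, and evaluation.

Inference ensembles the two description variants of a term: the pair is
scored once with the short and once with the long description and the two
probabilities are averaged (a single pass when the descriptions coincide,
as for EC numbers whose one description is the comma-joined concatenation
of the four level descriptions).

Evaluation is threshold-free: per-term average precision (the non-
interpolated AUPRC estimator) aggregated as macro mAP (terms weighted
equally; the model-selection metric) and micro mAP (all pairs pooled, hence
prevalence-weighted).  The zero-shot similarity baseline maps each
out-of-vocabulary term to its most text-similar in-vocabulary term and
reuses that term's scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .data_io import AnnotationDataset, FunctionTerm, ProteinRecord
from .encoders import EncoderSpec, encode_sequence, encode_sequence_batch, encode_text
from .model_core import PairScorer


@dataclass
class EvalReport:
    """Macro/micro mAP with per-term and per-group breakdowns."""

    map_macro: float
    map_micro: float
    per_term_ap: dict[str, float]
    per_group: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_terms_skipped: int = 0


@dataclass
class ECNumber:
    """Four-level dotted enzyme classification with per-level descriptions."""

    code: str
    level_descs: list[str]

    def __post_init__(self) -> None:
        if len(self.code.split(".")) != 4:
            raise ValueError(f"EC code {self.code!r} must have four dotted levels")
        if len(self.level_descs) != 4 or any(not d for d in self.level_descs):
            raise ValueError(
                f"EC {self.code}: exactly 4 non-empty level descriptions required"
            )

    @property
    def top_class(self) -> str:
        return self.code.split(".")[0]


def ec_description(ec: ECNumber) -> str:
    """Single textual description: the four level descriptions joined by ', '."""
    return ", ".join(ec.level_descs)


def ec_to_term(ec: ECNumber) -> FunctionTerm:
    """Wrap an EC number as a FunctionTerm with one description (no ensembling)."""
    desc = ec_description(ec)
    return FunctionTerm(ec.code, "ec_class", desc, desc)


# ---------------------------------------------------------------------------
# Prediction


def predict_pair(
    model: PairScorer,
    sequence: str,
    term: FunctionTerm,
    seq_spec: EncoderSpec,
    text_spec: EncoderSpec,
) -> float:
    """Ensembled probability for one (sequence, term) pair.

    Mean of the short- and long-description scores; a single forward pass
    when the two descriptions are identical.
    """
    seq_emb = encode_sequence(sequence, seq_spec)
    p_short = float(model.score_batch(seq_emb, encode_text(term.short_desc, text_spec))[0])
    if term.long_desc == term.short_desc:
        return p_short
    p_long = float(model.score_batch(seq_emb, encode_text(term.long_desc, text_spec))[0])
    return 0.5 * (p_short + p_long)


def predict_scores(
    model: PairScorer,
    proteins: Sequence[ProteinRecord],
    terms: Mapping[str, FunctionTerm],
    seq_spec: EncoderSpec,
    text_spec: EncoderSpec,
    batch_pairs: int = 8192,
) -> dict[tuple[str, str], float]:
    """Ensembled scores for the full protein x term grid, batched."""
    term_ids = sorted(terms)
    seq_embs = encode_sequence_batch([rec.sequence for rec in proteins], seq_spec)
    short_embs = np.asarray([encode_text(terms[t].short_desc, text_spec) for t in term_ids])
    long_embs = np.asarray([encode_text(terms[t].long_desc, text_spec) for t in term_ids])
    n_seq, n_term = len(proteins), len(term_ids)
    row_order = np.repeat(np.arange(n_seq), n_term)

    def grid_scores(text_embs: np.ndarray) -> np.ndarray:
        seq_rows = seq_embs[row_order]
        text_rows = np.tile(text_embs, (n_seq, 1))
        out = np.empty(n_seq * n_term)
        for start in range(0, out.size, batch_pairs):
            stop = min(start + batch_pairs, out.size)
            out[start:stop] = model.score_batch(
                seq_rows[start:stop], text_rows[start:stop], training=False
            )
        return out

    p = grid_scores(short_embs)
    if any(terms[t].long_desc != terms[t].short_desc for t in term_ids):
        p = 0.5 * (p + grid_scores(long_embs))
    scores: dict[tuple[str, str], float] = {}
    k = 0
    for rec in proteins:
        for t in term_ids:
            scores[(rec.seq_id, t)] = float(p[k])
            k += 1
    return scores


# ---------------------------------------------------------------------------
# Zero-shot similarity baseline


def similarity_baseline(
    oov_terms: Mapping[str, FunctionTerm],
    iv_terms: Mapping[str, FunctionTerm],
    iv_scores: Mapping[tuple[str, str], float],
    text_spec: EncoderSpec,
) -> dict[tuple[str, str], float]:
    """Description-similarity zero-shot baseline.

    Each out-of-vocabulary term is mapped to the in-vocabulary term whose
    description embedding is most cosine-similar (ties broken by the
    lexicographically smallest in-vocabulary id), and inherits that term's
    score for every sequence.  Term description embeddings average the short
    and long variants.
    """
    if not iv_terms:
        raise ValueError("in-vocabulary catalog is empty")

    def term_embedding(term: FunctionTerm) -> np.ndarray:
        emb = encode_text(term.short_desc, text_spec)
        if term.long_desc != term.short_desc:
            emb = 0.5 * (emb + encode_text(term.long_desc, text_spec))
        return emb

    iv_ids = sorted(iv_terms)
    iv_mat = np.asarray([term_embedding(iv_terms[t]) for t in iv_ids])
    iv_norms = np.linalg.norm(iv_mat, axis=1)
    seq_ids = sorted({sid for sid, _ in iv_scores})

    out: dict[tuple[str, str], float] = {}
    for oov_id in sorted(oov_terms):
        emb = term_embedding(oov_terms[oov_id])
        denom = iv_norms * np.linalg.norm(emb)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosines = np.where(denom > 0, iv_mat @ emb / denom, 0.0)
        best = iv_ids[int(np.argmax(cosines))]  # argmax takes the first (smallest id) on ties
        for sid in seq_ids:
            out[(sid, oov_id)] = iv_scores[(sid, best)]
    return out


# ---------------------------------------------------------------------------
# Metrics


def average_precision(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Non-interpolated average precision.

    Pairs are sorted by descending score with a stable sort (ties keep input
    order); AP is the mean, over positives, of the precision at each
    positive's rank.  Undefined without at least one positive.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    if not labels.any():
        raise ValueError("average precision is undefined without positives")
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    cum_pos = np.cumsum(y)
    ranks = np.arange(1, y.size + 1)
    return float((cum_pos[y] / ranks[y]).mean())


def evaluate(
    scores: Mapping[tuple[str, str], float],
    truth: AnnotationDataset,
    grouping: Mapping[str, str] | None = None,
) -> EvalReport:
    """Score a prediction grid against a ground-truth dataset.

    macro mAP: mean per-term AP over terms with at least one positive (the
    rest are counted in ``n_terms_skipped``); micro mAP: AP over the
    flattened list of all (sequence, term) pairs.  ``grouping`` (term ->
    group label, e.g. namespace or top-level EC class) adds per-group
    macro/micro entries.
    """
    term_ids = sorted(truth.terms)
    seq_order = [rec.seq_id for rec in truth.proteins]
    annot = truth.annotation_map()
    missing = [
        (sid, t) for sid in seq_order for t in term_ids if (sid, t) not in scores
    ]
    if missing:
        raise ValueError(
            f"scores missing for {len(missing)} (sequence, term) pairs, "
            f"e.g. {missing[:5]}"
        )

    per_term_ap: dict[str, float] = {}
    skipped = 0
    flat_scores: list[float] = []
    flat_labels: list[int] = []
    term_flat: dict[str, tuple[list[float], list[int]]] = {}
    for t in term_ids:
        s = [scores[(sid, t)] for sid in seq_order]
        y = [int(t in annot[sid]) for sid in seq_order]
        term_flat[t] = (s, y)
        flat_scores.extend(s)
        flat_labels.extend(y)
        if any(y):
            per_term_ap[t] = average_precision(s, y)
        else:
            skipped += 1

    if not per_term_ap:
        raise ValueError("no term has a positive example; nothing to evaluate")
    map_macro = float(np.mean(list(per_term_ap.values())))
    map_micro = average_precision(flat_scores, flat_labels)

    per_group: dict[str, tuple[float, float]] = {}
    if grouping is not None:
        for group in sorted(set(grouping.values())):
            members = [t for t in term_ids if grouping.get(t) == group]
            aps = [per_term_ap[t] for t in members if t in per_term_ap]
            g_scores = [x for t in members for x in term_flat[t][0]]
            g_labels = [x for t in members for x in term_flat[t][1]]
            if aps and any(g_labels):
                per_group[group] = (
                    float(np.mean(aps)),
                    average_precision(g_scores, g_labels),
                )
    return EvalReport(map_macro, map_micro, per_term_ap, per_group, skipped)


def prevalence_baseline_ap(truth: AnnotationDataset) -> float:
    """Mean positive prevalence over terms with >= 1 positive.

    The expected AP of an uninformative scorer on a term equals the term's
    positive prevalence, so this is the chance floor for macro mAP.
    """
    annot = truth.annotation_map()
    n = truth.n_proteins
    prevalences = []
    for t in sorted(truth.terms):
        k = sum(1 for sid in annot if t in annot[sid])
        if k:
            prevalences.append(k / n)
    if not prevalences:
        raise ValueError("no term has a positive example")
    return float(np.mean(prevalences))


# ---------------------------------------------------------------------------
# Embedding / annotation concordance


def concordance(
    seq_embeddings: Mapping[str, np.ndarray],
    annotations: Mapping[str, Iterable[str]],
) -> tuple[np.ndarray, np.ndarray, float]:
    """Pairwise embedding-cosine vs annotation-Jaccard concordance.

    For every unordered pair of sequences, computes the cosine similarity of
    their projection-head embeddings and the Jaccard similarity of their
    annotation sets, and returns both vectors plus their Pearson r.
    """
    ids = sorted(seq_embeddings)
    if len(ids) < 2:
        raise ValueError("concordance needs at least two sequences")
    ann = {sid: set(annotations[sid]) for sid in ids}
    if any(not ann[sid] for sid in ids):
        raise ValueError("all annotation sets must be non-empty")
    mat = np.asarray([seq_embeddings[sid] for sid in ids], dtype=np.float64)
    norms = np.linalg.norm(mat, axis=1)
    if (norms == 0).any():
        raise ValueError("zero-norm embedding encountered")
    unit = mat / norms[:, None]
    cos_mat = unit @ unit.T
    cosines, jaccards = [], []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            cosines.append(cos_mat[i, j])
            inter = len(ann[ids[i]] & ann[ids[j]])
            union = len(ann[ids[i]] | ann[ids[j]])
            jaccards.append(inter / union)
    cosines = np.asarray(cosines)
    jaccards = np.asarray(jaccards)
    if len(cosines) < 2 or np.std(cosines) == 0 or np.std(jaccards) == 0:
        r = float("nan")  # correlation undefined for a single or constant pair list
    else:
        r = float(stats.pearsonr(cosines, jaccards).statistic)
    return cosines, jaccards, r
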