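"""Training procedure for the pair-scoring network.

Class imbalance over function terms is extreme in real annotation corpora,
so two mechanisms work together: the focal loss (:mod:`funcmatch.model_core`)
down-weights easy pairs, and sequences are sampled with probability
proportional to the inverse square-root frequency of their annotations,

    w_i = sum over annotated terms j of 1 / sqrt(f_j),

so that carriers of rare terms are seen more often.  Three augmentations
regularize training: conservative residue substitution driven by BLOSUM62,
random choice between a term's short and long description, and Gaussian
noise injected into the text embedding before the projection head.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from Bio.Align import substitution_matrices

from .data_io import AMINO_ACIDS, AnnotationDataset, FunctionTerm, ProteinRecord
from .encoders import (
    EncoderSpec,
    encode_sequence,
    encode_text,
    rows_to_csr,
    sequence_buckets,
)
from .model_core import (
    ModelConfig,
    PairScorer,
    build_model,
    focal_loss,
    focal_loss_grad_logit,
)
from .ontology import TermFrequencyTable, compute_frequencies

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimization and augmentation settings.

    lr / clip_norm follow the published recipe (Adam at 3e-4, global-norm
    gradient clipping at 1).  ``batch_size`` counts drawn sequences per step;
    every drawn sequence contributes its positive pairs plus
    ``negatives_per_sequence`` negative pairs ("all" pairs it with every
    non-annotated catalog term).
    """

    lr: float = 3e-4
    clip_norm: float = 1.0
    batch_size: int = 32
    epochs: int = 30
    corruption_rate: float = 0.1
    noise_sigma: float = 0.1
    negatives_per_sequence: int | str = "all"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0 or self.clip_norm <= 0:
            raise ValueError("lr and clip_norm must be positive")
        if not 0 <= self.corruption_rate <= 1:
            raise ValueError("corruption_rate must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.epochs < 0 or self.batch_size <= 0:
            raise ValueError("epochs must be >= 0 and batch_size positive")
        if self.negatives_per_sequence != "all" and int(self.negatives_per_sequence) < 0:
            raise ValueError("negatives_per_sequence must be 'all' or a non-negative int")


@dataclass
class SamplingWeights:
    weights: dict[str, float]

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.weights.items() if v <= 0}
        if bad:
            raise ValueError(f"sampling weights must be positive: {bad}")


# ---------------------------------------------------------------------------
# Sampling


def sampling_weight(annotations: Iterable[str], freq: TermFrequencyTable) -> float:
    """Inverse square-root-frequency weight of one sequence."""
    annotations = set(annotations)
    if not annotations:
        raise ValueError(
            "sequence has no annotations; it should have been dropped upstream"
        )
    return float(sum(1.0 / np.sqrt(freq.get(t)) for t in annotations))


def compute_sampling_weights(ds: AnnotationDataset, freq: TermFrequencyTable) -> SamplingWeights:
    return SamplingWeights(
        {rec.seq_id: sampling_weight(rec.annotations, freq) for rec in ds.proteins}
    )


def draw_batch(
    ds: AnnotationDataset,
    weights: SamplingWeights,
    cfg: TrainConfig,
    rng: np.random.Generator,
) -> list[tuple[ProteinRecord, FunctionTerm, bool]]:
    """Draw one batch of (protein, term, is_positive) pairs.

    Sequences are drawn with replacement, probability proportional to their
    sampling weight.  Each drawn sequence is paired positively with all its
    (propagated) annotations and negatively with terms outside its annotation
    set — all of them when ``negatives_per_sequence == "all"``, otherwise a
    uniform subsample.  Triples for one drawn sequence are contiguous.
    """
    missing = {rec.seq_id for rec in ds.proteins} - weights.weights.keys()
    if missing:
        raise ValueError(f"weights missing for sequences: {sorted(missing)}")
    w = np.array([weights.weights[rec.seq_id] for rec in ds.proteins])
    probs = w / w.sum()
    idx = rng.choice(len(ds.proteins), size=cfg.batch_size, replace=True, p=probs)
    all_terms = sorted(ds.terms)
    triples: list[tuple[ProteinRecord, FunctionTerm, bool]] = []
    for i in idx:
        rec = ds.proteins[i]
        for term_id in sorted(rec.annotations):
            triples.append((rec, ds.terms[term_id], True))
        negatives = [t for t in all_terms if t not in rec.annotations]
        if cfg.negatives_per_sequence != "all":
            k = int(cfg.negatives_per_sequence)
            if k > len(negatives):
                logger.warning(
                    "negatives_per_sequence=%d exceeds the %d available negatives; clamping",
                    k, len(negatives),
                )
                k = len(negatives)
            sel = rng.choice(len(negatives), size=k, replace=False) if k else []
            negatives = [negatives[j] for j in sorted(sel)]
        for term_id in negatives:
            triples.append((rec, ds.terms[term_id], False))
    return triples


# ---------------------------------------------------------------------------
# Augmentations


_POSITIVE_PARTNERS: dict[str, str] | None = None


def _blosum_partners() -> dict[str, str]:
    """aa -> string of non-identical residues with BLOSUM62 score > 0."""
    global _POSITIVE_PARTNERS
    if _POSITIVE_PARTNERS is None:
        mat = substitution_matrices.load("BLOSUM62")
        _POSITIVE_PARTNERS = {
            a: "".join(b for b in AMINO_ACIDS if b != a and mat[a, b] > 0)
            for a in AMINO_ACIDS
        }
    return _POSITIVE_PARTNERS


def corrupt_sequence(sequence: str, rate: float, rng: np.random.Generator) -> str:
    """Conservative-substitution augmentation.

    Each residue is independently selected with probability ``rate``; a
    selected residue is replaced by a uniform draw from its non-identical
    BLOSUM62-positive partners.  Residues with no positive partner, and X,
    are left unchanged.  Length is always preserved.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must lie in [0, 1]")
    if rate == 0 or not sequence:
        return sequence
    partners = _blosum_partners()
    hit = rng.random(len(sequence)) < rate
    if not hit.any():
        return sequence
    out = list(sequence)
    for i in np.flatnonzero(hit):
        options = partners.get(out[i], "")
        if options:
            out[i] = options[rng.integers(len(options))]
    return "".join(out)


def pick_description(term: FunctionTerm, rng: np.random.Generator) -> str:
    """Sample the short or long description with probability 1/2 each."""
    if term.short_desc == term.long_desc:
        return term.short_desc
    return term.short_desc if rng.integers(2) == 0 else term.long_desc


def add_label_noise(text_embedding: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian(0, sigma^2) i.i.d. noise on the text embedding (training only)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return text_embedding
    return text_embedding + rng.normal(0.0, sigma, size=text_embedding.shape)


# ---------------------------------------------------------------------------
# Optimizer


class Adam:
    """Adam with global-norm gradient clipping, updating model params in place."""

    def __init__(self, model: PairScorer, lr: float, clip_norm: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr, self.clip_norm = lr, clip_norm
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self) -> None:
        params = list(self.model.params())
        total = np.sqrt(sum(float((g * g).sum()) for _, _, g in params))
        scale = self.clip_norm / total if total > self.clip_norm else 1.0
        self.t += 1
        bc1 = 1.0 - self.beta1 ** self.t
        bc2 = 1.0 - self.beta2 ** self.t
        for name, p, g in params:
            g = g * scale
            m = self.m.setdefault(name, np.zeros_like(p))
            v = self.v.setdefault(name, np.zeros_like(p))
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


# ---------------------------------------------------------------------------
# Training loop


class _TextCache:
    """Per-(term, variant) text-embedding cache; descriptions never change mid-run."""

    def __init__(self, spec: EncoderSpec):
        self.spec = spec
        self._store: dict[tuple[str, str], np.ndarray] = {}

    def get(self, term: FunctionTerm, text: str) -> np.ndarray:
        variant = "short" if text == term.short_desc else "long"
        key = (term.term_id, variant)
        if key not in self._store:
            self._store[key] = encode_text(text, self.spec)
        return self._store[key]


def train(
    train_ds: AnnotationDataset,
    val_ds: AnnotationDataset | None,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    seq_spec: EncoderSpec,
    text_spec: EncoderSpec,
) -> tuple[PairScorer, list[dict]]:
    """Run the full optimization loop and return (best checkpoint, log).

    Expects ``train_ds`` (and ``val_ds``) cleaned and ancestor-propagated.
    Per epoch: stream weighted batches with all three augmentations applied,
    minimize the mean focal loss with Adam under global-norm clipping, then
    score the validation set (ensembled inference) with macro mAP.  The
    returned model carries the parameters of the best-validation epoch; with
    no validation set, the final epoch.  ``epochs == 0`` returns the freshly
    initialized model and an empty log.
    """
    from .inference_eval import evaluate, predict_scores  # local: avoids cycle

    model = build_model(model_cfg, seq_spec.dim, text_spec.dim)
    log: list[dict] = []
    if train_cfg.epochs == 0:
        return model, log

    freq = compute_frequencies(train_ds)
    weights = compute_sampling_weights(train_ds, freq)
    rng = np.random.default_rng(train_cfg.seed)
    optimizer = Adam(model, train_cfg.lr, train_cfg.clip_norm)
    text_cache = _TextCache(text_spec)
    steps_per_epoch = max(1, int(np.ceil(train_ds.n_proteins / train_cfg.batch_size)))

    best_map = -np.inf
    best_params = None
    for epoch in range(train_cfg.epochs):
        epoch_losses = []
        for step in range(steps_per_epoch):
            triples = draw_batch(train_ds, weights, train_cfg, rng)
            seq_sparse = seq_spec.kind == "toy_sequence"
            seq_rows, text_rows, labels = [], [], []
            current_rec = None
            current_emb = None
            for rec, term, is_pos in triples:
                if rec is not current_rec:
                    corrupted = corrupt_sequence(rec.sequence, train_cfg.corruption_rate, rng)
                    current_emb = (
                        sequence_buckets(corrupted, seq_spec)
                        if seq_sparse
                        else encode_sequence(corrupted, seq_spec)
                    )
                    current_rec = rec
                seq_rows.append(current_emb)
                emb = text_cache.get(term, pick_description(term, rng))
                text_rows.append(add_label_noise(emb, train_cfg.noise_sigma, rng))
                labels.append(is_pos)
            seq_arr = (
                rows_to_csr(seq_rows, seq_spec.dim) if seq_sparse else np.asarray(seq_rows)
            )
            text_arr = np.asarray(text_rows)
            y = np.asarray(labels, dtype=bool)
            p = model.score_batch(seq_arr, text_arr, training=True)
            loss = float(np.mean(focal_loss(p, y, model_cfg.gamma)))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, step {step}"
                )
            model.backward(focal_loss_grad_logit(p, y, model_cfg.gamma) / len(y))
            optimizer.step()
            epoch_losses.append(loss)

        record = {"epoch": epoch, "train_loss": float(np.mean(epoch_losses))}
        if val_ds is not None and val_ds.n_proteins > 0:
            scores = predict_scores(model, val_ds.proteins, val_ds.terms, seq_spec, text_spec)
            report = evaluate(scores, val_ds)
            record["val_map_macro"] = report.map_macro
            record["val_map_micro"] = report.map_micro
            if report.map_macro > best_map:
                best_map = report.map_macro
                best_params = model.get_param_dict()
        log.append(record)
        logger.info("epoch %d: %s", epoch, record)

    if best_params is not None:
        model.set_param_dict(best_params)
    return model, log
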