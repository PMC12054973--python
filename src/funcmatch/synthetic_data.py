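"""Synthetic sequence-function worlds.

The generator emulates the statistical structure the matching model relies
on, at desk scale:

* **Motif-determined function.**  Each function term is a conjunction of
  1-3 short sequence motifs; a term is positive for a sequence iff all of
  its motifs occur as substrings.  Sequences are background residues with
  the motifs of their intended terms implanted at non-overlapping
  positions.
* **Compositional descriptions.**  A term's short and long descriptions
  name its motifs in a shared vocabulary, so descriptions of held-out terms
  share tokens with training terms — the property that makes zero-shot
  transfer through a text encoder possible at all.
* **Skewed label frequencies.**  Term prevalence follows a Zipf-like law
  with exponent ``label_skew``.
* **A term DAG.**  Parent edges run only to terms whose motif set is a
  proper subset of the child's, so the motif semantics and ancestor
  propagation agree and every emitted annotation set is closed under
  propagation.
* **An in-/out-of-vocabulary split.**  A fraction of terms is held out
  entirely: they never appear in the train/val/test vocabularies and only
  annotate the dedicated zero-shot test sequences, mimicking terms first
  described after a training release.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .data_io import AMINO_ACIDS, AnnotationDataset, FunctionTerm, ProteinRecord

logger = logging.getLogger(__name__)

_GO_NAMESPACES = ("molecular_function", "biological_process", "cellular_component")
_MAX_RETRIES = 1000


class GenerationError(RuntimeError):
    pass


@dataclass
class WorldConfig:
    """Parameters of one synthetic world.

    Defaults give 200 training sequences over 20 in-vocabulary terms plus 6
    zero-shot terms (``frac_zero_shot_terms`` of 26), sequence lengths
    100-200, built from 8 motifs of length 10 — the span of a short
    functional sequence motif, long enough that a k-mer encoder sees several
    correlated features per motif.
    """

    n_motifs: int = 8
    motif_length: int = 10
    n_terms: int = 26
    terms_per_motif_combo: tuple[int, int] = (1, 3)
    n_sequences: int = 200
    n_val_sequences: int = 50
    n_test_sequences: int = 50
    n_zero_shot_sequences: int = 60
    seq_length_range: tuple[int, int] = (100, 200)
    background_composition: dict[str, float] | None = None
    label_skew: float = 1.0
    frac_zero_shot_terms: float = 0.23
    parent_edges_per_term: float = 1.0
    seed: int = 7

    def __post_init__(self) -> None:
        if not 0 < self.frac_zero_shot_terms <= 0.5:
            raise ValueError("frac_zero_shot_terms must lie in (0, 0.5]")
        for name in ("n_motifs", "motif_length", "n_terms", "n_sequences",
                     "n_val_sequences", "n_test_sequences", "n_zero_shot_sequences"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.terms_per_motif_combo
        if not 1 <= lo <= hi <= 3:
            raise ValueError("terms_per_motif_combo must satisfy 1 <= lo <= hi <= 3")
        if self.seq_length_range[0] > self.seq_length_range[1]:
            raise ValueError("seq_length_range must be (min, max) with min <= max")
        if self.label_skew < 0:
            raise ValueError("label_skew must be >= 0")


# ---------------------------------------------------------------------------
# Pieces


def _background_probs(cfg: WorldConfig) -> np.ndarray:
    if cfg.background_composition is None:
        return np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
    p = np.array([cfg.background_composition.get(a, 0.0) for a in AMINO_ACIDS])
    if p.sum() <= 0:
        raise ValueError("background_composition has no mass on the 20 residues")
    return p / p.sum()


def _draw_motifs(cfg: WorldConfig, rng: np.random.Generator) -> list[str]:
    probs = _background_probs(cfg)
    letters = np.array(list(AMINO_ACIDS))
    motifs: list[str] = []
    for _ in range(_MAX_RETRIES):
        m = "".join(rng.choice(letters, size=cfg.motif_length, p=probs))
        if m not in motifs:
            motifs.append(m)
        if len(motifs) == cfg.n_motifs:
            return motifs
    raise GenerationError("could not draw distinct motifs within the retry budget")


def _draw_combos(
    cfg: WorldConfig, rng: np.random.Generator, n_in_vocab: int, n_zero_shot: int
) -> tuple[list[frozenset[int]], list[frozenset[int]]]:
    """Motif-index combinations per term; zero-shot combos reuse the motif
    pool (never introducing a motif unseen in vocabulary terms) but are new
    combinations, and carry >= 2 motifs so a strict compositional transfer is
    required."""
    lo, hi = cfg.terms_per_motif_combo
    taken: set[frozenset[int]] = set()
    in_vocab: list[frozenset[int]] = []
    for i in range(n_in_vocab):
        for _ in range(_MAX_RETRIES):
            size = int(rng.integers(lo, hi + 1))
            if i < cfg.n_motifs:
                # guarantee every motif appears in some in-vocabulary term
                others = [j for j in range(cfg.n_motifs) if j != i]
                extra = rng.choice(others, size=size - 1, replace=False).tolist() if size > 1 else []
                combo_f = frozenset([i, *extra])
            else:
                combo_f = frozenset(rng.choice(cfg.n_motifs, size=size, replace=False).tolist())
            if combo_f not in taken:
                taken.add(combo_f)
                in_vocab.append(combo_f)
                break
        else:
            raise GenerationError("could not draw a fresh in-vocabulary motif combo")
    zs_lo = max(2, lo)
    zero_shot: list[frozenset[int]] = []
    for _ in range(n_zero_shot):
        for _ in range(_MAX_RETRIES):
            size = int(rng.integers(zs_lo, hi + 1))
            combo_f = frozenset(rng.choice(cfg.n_motifs, size=size, replace=False).tolist())
            if combo_f not in taken:
                taken.add(combo_f)
                zero_shot.append(combo_f)
                break
        else:
            raise GenerationError("could not draw a fresh zero-shot motif combo")
    return in_vocab, zero_shot


def _describe(combo: frozenset[int]) -> tuple[str, str]:
    names = [f"motif-{i + 1}" for i in sorted(combo)]
    short = " and ".join(names) + " dependent activity"
    long = (
        "protein function that requires the joint presence of "
        + " and ".join(f"sequence element {n}" for n in names)
        + " within the amino acid chain"
    )
    return short, long


def _build_terms(
    combos: list[frozenset[int]],
    ids: list[str],
    rng: np.random.Generator,
    parent_rate: float,
) -> dict[str, FunctionTerm]:
    """Terms over the given combos with subset-consistent parent edges."""
    terms: dict[str, FunctionTerm] = {}
    for idx, (tid, combo) in enumerate(zip(ids, combos)):
        short, long = _describe(combo)
        candidates = [
            ids[j] for j, other in enumerate(combos) if other < combo
        ]
        parents: set[str] = set()
        if candidates:
            keep = min(1.0, parent_rate / len(candidates))
            parents = {c for c in candidates if rng.random() < keep}
        terms[tid] = FunctionTerm(
            tid, _GO_NAMESPACES[idx % 3], short, long, parents
        )
    return terms


def _implant(
    length: int,
    motifs: list[str],
    probs: np.ndarray,
    rng: np.random.Generator,
) -> str:
    total = sum(len(m) for m in motifs)
    if total > length:
        raise GenerationError(
            f"sequence of length {length} too short for {len(motifs)} motifs"
        )
    letters = np.array(list(AMINO_ACIDS))
    seq = list(rng.choice(letters, size=length, p=probs))
    placed: list[tuple[int, int]] = []
    for motif in motifs:
        for _ in range(_MAX_RETRIES):
            start = int(rng.integers(0, length - len(motif) + 1))
            stop = start + len(motif)
            if all(stop <= a or start >= b for a, b in placed):
                placed.append((start, stop))
                seq[start:stop] = list(motif)
                break
        else:
            raise GenerationError("could not place motifs without overlap")
    return "".join(seq)


def _zipf_probs(n: int, skew: float) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1) ** skew
    return w / w.sum()


def term_is_positive(sequence: str, motifs: frozenset[str]) -> bool:
    """Ground-truth labeling rule: all of the term's motifs occur as substrings."""
    return all(m in sequence for m in motifs)


# ---------------------------------------------------------------------------
# The generator


def generate_world(
    cfg: WorldConfig,
) -> tuple[AnnotationDataset, AnnotationDataset, AnnotationDataset, AnnotationDataset,
           dict[str, frozenset[str]]]:
    """Generate (train, val, supervised_test, zero_shot_test, ground_truth).

    ``ground_truth`` maps every term id to its defining motif strings.  The
    first three datasets share the in-vocabulary catalog; the zero-shot set
    uses only the held-out terms and freshly drawn sequences.  Byte-identical
    output is guaranteed for a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    probs = _background_probs(cfg)
    motifs = _draw_motifs(cfg, rng)

    n_zero_shot = max(1, round(cfg.frac_zero_shot_terms * cfg.n_terms))
    n_in_vocab = cfg.n_terms - n_zero_shot
    if n_in_vocab < cfg.n_motifs:
        raise GenerationError(
            "need at least as many in-vocabulary terms as motifs to cover the pool"
        )
    iv_combos, zs_combos = _draw_combos(cfg, rng, n_in_vocab, n_zero_shot)
    width = len(str(cfg.n_terms))
    iv_ids = [f"T{i + 1:0{width}d}" for i in range(n_in_vocab)]
    zs_ids = [f"Z{i + 1:0{width}d}" for i in range(n_zero_shot)]
    iv_terms = _build_terms(iv_combos, iv_ids, rng, cfg.parent_edges_per_term)
    zs_terms = _build_terms(zs_combos, zs_ids, rng, cfg.parent_edges_per_term)

    ground_truth: dict[str, frozenset[str]] = {}
    for tid, combo in zip(iv_ids + zs_ids, iv_combos + zs_combos):
        ground_truth[tid] = frozenset(motifs[i] for i in combo)

    iv_probs = _zipf_probs(n_in_vocab, cfg.label_skew)
    n_collisions = 0
    n_positive_pairs = 0

    def make_split(prefix: str, n_seq: int, zero_shot: bool) -> AnnotationDataset:
        nonlocal n_collisions, n_positive_pairs
        proteins: list[ProteinRecord] = []
        catalog = zs_terms if zero_shot else iv_terms
        counter = itertools.count(1)
        while len(proteins) < n_seq:
            seq_id = f"{prefix}_{next(counter):04d}"
            if zero_shot:
                # real zero-shot releases carry a median of one new label per
                # sequence; mimic that (mostly 1, occasionally 2)
                k = 1 + int(rng.random() < 0.2)
                intended = [zs_ids[j] for j in rng.choice(n_zero_shot, size=min(k, n_zero_shot), replace=False)]
                # distractor in-vocabulary motifs keep zero-shot sequences from
                # being trivially recognizable by motif count
                if rng.random() < 0.5:
                    intended.append(iv_ids[int(rng.choice(n_in_vocab, p=iv_probs))])
            else:
                k = 1 + int(np.searchsorted([0.5, 0.8], rng.random()))
                sel = rng.choice(n_in_vocab, size=k, replace=False, p=iv_probs)
                intended = [iv_ids[j] for j in sel]
            motif_set = sorted({m for t in intended for m in ground_truth[t]})
            length = int(rng.integers(cfg.seq_length_range[0], cfg.seq_length_range[1] + 1))
            sequence = _implant(length, motif_set, probs, rng)
            positives = {
                tid for tid in catalog if term_is_positive(sequence, ground_truth[tid])
            }
            if not positives:
                continue
            extra = positives - {t for t in intended if t in catalog}
            implied = {
                tid for tid in extra
                if ground_truth[tid] <= {m for t in intended for m in ground_truth[t]}
            }
            n_collisions += len(extra - implied)
            n_positive_pairs += len(positives)
            proteins.append(ProteinRecord(seq_id, sequence, positives))
        tag = "zero_shot" if zero_shot else ("train" if prefix == "train" else prefix)
        ds = AnnotationDataset(proteins, dict(catalog), tag)
        ds.validate()
        return ds

    train = make_split("train", cfg.n_sequences, False)
    val = make_split("val", cfg.n_val_sequences, False)
    test = make_split("test", cfg.n_test_sequences, False)
    zero_shot_test = make_split("zs", cfg.n_zero_shot_sequences, True)
    logger.info(
        "generate_world: %d background-collision positives out of %d positive pairs",
        n_collisions, n_positive_pairs,
    )
    return train, val, test, zero_shot_test, ground_truth


def world_stats(ds: AnnotationDataset) -> dict[str, float]:
    """Summary mirroring standard dataset tables: lengths, labels/sequence,
    unique label count."""
    if ds.n_proteins == 0:
        raise ValueError("empty dataset")
    lengths = [len(rec.sequence) for rec in ds.proteins]
    labels = [len(rec.annotations) for rec in ds.proteins]
    used = set().union(*(rec.annotations for rec in ds.proteins))
    return {
        "n_sequences": ds.n_proteins,
        "median_seq_length": float(np.median(lengths)),
        "max_seq_length": float(max(lengths)),
        "median_labels_per_seq": float(np.median(labels)),
        "max_labels_per_seq": float(max(labels)),
        "n_unique_labels": len(used),
    }
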