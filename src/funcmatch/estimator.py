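"""scikit-learn-style front door to the matching model.

:class:`ProteinFunctionClassifier` bundles the encoder specs, network
config, and training loop behind the familiar ``fit`` / ``predict_proba`` /
``score`` surface (with ``get_params``/``set_params`` from
``sklearn.base.BaseEstimator``, so grid search over its hyperparameters
works out of the box).  ``X`` for ``fit`` is an
:class:`~funcmatch.data_io.AnnotationDataset` — the labels live inside the
records, so no separate ``y`` is passed.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .data_io import AnnotationDataset, FunctionTerm, ProteinRecord
from .encoders import EncoderSpec, encode_sequence_batch
from .inference_eval import evaluate, predict_pair, predict_scores
from .model_core import ModelConfig
from .training import TrainConfig, train


class ProteinFunctionClassifier(BaseEstimator):
    """Binary classifier over (protein sequence, function description) pairs.

    Parameters mirror the network and training configs; ``random_state``
    seeds parameter initialization, sampling, and all augmentations.

    Fitted attributes: ``model_`` (the trained pair scorer), ``log_``
    (per-epoch loss/metric records), ``terms_`` (training term catalog),
    ``seq_spec_`` / ``text_spec_`` (frozen encoder specs).
    """

    def __init__(
        self,
        d: int = 64,
        hidden_multiplier: int = 3,
        n_hidden: int = 3,
        gamma: float = 2.0,
        use_batch_norm: bool = True,
        lr: float = 1e-3,
        clip_norm: float = 1.0,
        batch_size: int = 8,
        epochs: int = 60,
        corruption_rate: float = 0.1,
        noise_sigma: float = 0.1,
        negatives_per_sequence: int | str = "all",
        seq_encoder_dim: int = 8192,
        seq_kmer: int = 5,
        text_encoder_dim: int = 256,
        encoder_hash_seed: int = 0,
        random_state: int = 0,
    ):
        self.d = d
        self.hidden_multiplier = hidden_multiplier
        self.n_hidden = n_hidden
        self.gamma = gamma
        self.use_batch_norm = use_batch_norm
        self.lr = lr
        self.clip_norm = clip_norm
        self.batch_size = batch_size
        self.epochs = epochs
        self.corruption_rate = corruption_rate
        self.noise_sigma = noise_sigma
        self.negatives_per_sequence = negatives_per_sequence
        self.seq_encoder_dim = seq_encoder_dim
        self.seq_kmer = seq_kmer
        self.text_encoder_dim = text_encoder_dim
        self.encoder_hash_seed = encoder_hash_seed
        self.random_state = random_state

    # ------------------------------------------------------------------

    def _make_specs(self) -> tuple[EncoderSpec, EncoderSpec]:
        seq_spec = EncoderSpec(
            "toy_sequence",
            self.seq_encoder_dim,
            {"k": self.seq_kmer, "seed": self.encoder_hash_seed},
        )
        text_spec = EncoderSpec(
            "toy_text", self.text_encoder_dim, {"seed": self.encoder_hash_seed}
        )
        return seq_spec, text_spec

    def fit(self, X: AnnotationDataset, y=None, val: AnnotationDataset | None = None):
        """Train on a cleaned, ancestor-propagated dataset.

        ``val`` enables best-epoch checkpoint selection by validation macro
        mAP; without it the final epoch is kept.
        """
        if not isinstance(X, AnnotationDataset):
            raise TypeError("X must be an AnnotationDataset")
        seq_spec, text_spec = self._make_specs()
        model_cfg = ModelConfig(
            d=self.d,
            hidden_multiplier=self.hidden_multiplier,
            n_hidden=self.n_hidden,
            gamma=self.gamma,
            use_batch_norm=self.use_batch_norm,
            seed=self.random_state,
        )
        train_cfg = TrainConfig(
            lr=self.lr,
            clip_norm=self.clip_norm,
            batch_size=self.batch_size,
            epochs=self.epochs,
            corruption_rate=self.corruption_rate,
            noise_sigma=self.noise_sigma,
            negatives_per_sequence=self.negatives_per_sequence,
            seed=self.random_state,
        )
        self.model_, self.log_ = train(X, val, model_cfg, train_cfg, seq_spec, text_spec)
        self.terms_ = dict(X.terms)
        self.seq_spec_, self.text_spec_ = seq_spec, text_spec
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit() first")

    def predict_proba(
        self,
        proteins: list[ProteinRecord] | AnnotationDataset,
        terms: dict[str, FunctionTerm] | None = None,
    ) -> dict[tuple[str, str], float]:
        """Ensembled match probabilities for every (protein, term) pair.

        ``terms`` defaults to the training catalog; passing an unseen catalog
        is exactly the zero-shot setting.
        """
        self._check_fitted()
        if isinstance(proteins, AnnotationDataset):
            terms = terms if terms is not None else proteins.terms
            proteins = proteins.proteins
        if terms is None:
            terms = self.terms_
        return predict_scores(self.model_, proteins, terms, self.seq_spec_, self.text_spec_)

    def predict_pair(self, sequence: str, term: FunctionTerm) -> float:
        self._check_fitted()
        return predict_pair(self.model_, sequence, term, self.seq_spec_, self.text_spec_)

    def score(self, X: AnnotationDataset, y=None) -> float:
        """Macro mAP on a labeled dataset (the model-selection metric)."""
        self._check_fitted()
        return evaluate(self.predict_proba(X), X).map_macro

    def sequence_embeddings(self, proteins: list[ProteinRecord]) -> dict[str, np.ndarray]:
        """Sequence projection-head embeddings (the concordance-analysis input)."""
        self._check_fitted()
        raw = encode_sequence_batch([rec.sequence for rec in proteins], self.seq_spec_)
        projected = self.model_.embed_sequences(raw)
        return {rec.seq_id: projected[i] for i, rec in enumerate(proteins)}
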