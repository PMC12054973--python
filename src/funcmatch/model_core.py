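"""The trainable pair-scoring network and the focal loss.

Architecture: two independent projection heads (one for the frozen sequence
embedding, one for the frozen text embedding), each an MLP with ``n_hidden``
hidden layers of ``hidden_multiplier * d`` units and an output layer of size
``d``; their outputs are concatenated (length ``2d``) and passed through a
fusion MLP of the same hidden shape ending in a single output unit, whose
logistic transform is the probability that the (sequence, description) pair
is a true annotation.  Hidden activations are ReLU; when batch normalization
is on, linear layers carry no bias and each hidden linear map is followed by
a normalization step (linear -> normalize -> ReLU).  At inference the
normalization uses accumulated running statistics, so single-pair and
batched scoring agree.

The whole forward/backward pass is written in NumPy; parameters live in
plain arrays so the optimizer in :mod:`funcmatch.training` can update them
in place.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import sparse

_EPS = 1e-7  # probability clamp: the focal loss diverges at p_t = 0
_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass
class ModelConfig:
    """Network hyperparameters.

    d: common embedding size after the projection heads.
    hidden_multiplier: hidden width is ``hidden_multiplier * d``.
    n_hidden: hidden layers per head and in the fusion MLP.
    gamma: focal-loss exponent (0 recovers plain cross-entropy).
    use_batch_norm: normalize after each hidden linear map; disables biases.
    seed: parameter-initialization seed.
    """

    d: int = 64
    hidden_multiplier: int = 3
    n_hidden: int = 3
    gamma: float = 2.0
    use_batch_norm: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("d must be positive")
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if self.hidden_multiplier < 1:
            raise ValueError("hidden_multiplier must be >= 1")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


# ---------------------------------------------------------------------------
# Loss


def focal_loss(p, is_positive, gamma: float):
    """Focal loss FL = (1 - p_t)^gamma * (-ln p_t) for a pair probability.

    ``p_t`` is ``p`` for a true annotation and ``1 - p`` otherwise.
    Probabilities are clamped to [1e-7, 1 - 1e-7] first.  Vectorized; accepts
    scalars or arrays for ``p`` and ``is_positive``.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    p = np.clip(np.asarray(p, dtype=np.float64), _EPS, 1.0 - _EPS)
    pos = np.asarray(is_positive, dtype=bool)
    pt = np.where(pos, p, 1.0 - p)
    out = (1.0 - pt) ** gamma * (-np.log(pt))
    return out if out.ndim else float(out)


def focal_loss_grad_logit(p, is_positive, gamma: float):
    """d FL / d logit, for a probability produced by a logistic unit.

    With s = +1 for positives and -1 for negatives and p_t the matched
    probability, the derivative is s * (gamma * p_t * (1-p_t)^gamma * ln p_t
    - (1-p_t)^(gamma+1)); at gamma = 0 this reduces to the familiar
    cross-entropy gradient -(s)(1 - p_t).
    """
    p = np.clip(np.asarray(p, dtype=np.float64), _EPS, 1.0 - _EPS)
    pos = np.asarray(is_positive, dtype=bool)
    pt = np.where(pos, p, 1.0 - p)
    sign = np.where(pos, 1.0, -1.0)
    return sign * (gamma * pt * (1.0 - pt) ** gamma * np.log(pt) - (1.0 - pt) ** (gamma + 1.0))


# ---------------------------------------------------------------------------
# Layers


class _Linear:
    """Dense linear map; accepts scipy.sparse row batches (high-dimensional
    hashed k-mer inputs are ~99% zeros).  ``input_layer`` skips the input
    gradient, which no one consumes for the first map of a head."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int, bias: bool,
                 input_layer: bool = False):
        # He initialization suits the ReLU stacks
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out) if bias else None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b) if bias else None
        self.input_layer = input_layer
        self._x = None

    def forward(self, x, training: bool) -> np.ndarray:
        if training:
            self._x = x
        y = x @ self.W
        y = np.asarray(y)
        if self.b is not None:
            y = y + self.b
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray | None:
        self.dW = np.asarray(self._x.T @ dy)
        if self.b is not None:
            self.db = dy.sum(axis=0)
        if self.input_layer:
            return None
        return dy @ self.W.T

    def params(self):
        yield "W", self.W, self.dW
        if self.b is not None:
            yield "b", self.b, self.db


class _BatchNorm:
    def __init__(self, n: int):
        self.gamma = np.ones(n)
        self.beta = np.zeros(n)
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.dgamma = np.zeros(n)
        self.dbeta = np.zeros(n)
        self._xhat: np.ndarray | None = None
        self._inv_std: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (1 - _BN_MOMENTUM) * self.running_mean + _BN_MOMENTUM * mean
            self.running_var = (1 - _BN_MOMENTUM) * self.running_var + _BN_MOMENTUM * var
            inv_std = 1.0 / np.sqrt(var + _BN_EPS)
            xhat = (x - mean) * inv_std
            self._xhat, self._inv_std = xhat, inv_std
        else:
            xhat = (x - self.running_mean) / np.sqrt(self.running_var + _BN_EPS)
        return self.gamma * xhat + self.beta

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._xhat, self._inv_std
        n = dy.shape[0]
        self.dgamma = (dy * xhat).sum(axis=0)
        self.dbeta = dy.sum(axis=0)
        dxhat = dy * self.gamma
        return (inv_std / n) * (
            n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
        )

    def params(self):
        yield "gamma", self.gamma, self.dgamma
        yield "beta", self.beta, self.dbeta

    def state(self):
        yield "running_mean", self.running_mean
        yield "running_var", self.running_var


class _MLP:
    """ReLU MLP: n_hidden hidden layers of fixed width, then a linear output."""

    def __init__(
        self,
        rng: np.random.Generator,
        n_in: int,
        width: int,
        n_hidden: int,
        n_out: int,
        use_bn: bool,
        input_layer: bool = False,
    ):
        self.use_bn = use_bn
        self.hidden: list[_Linear] = []
        self.norms: list[_BatchNorm] = []
        fan_in = n_in
        for i in range(n_hidden):
            self.hidden.append(
                _Linear(rng, fan_in, width, bias=not use_bn,
                        input_layer=input_layer and i == 0)
            )
            if use_bn:
                self.norms.append(_BatchNorm(width))
            fan_in = width
        self.out = _Linear(rng, fan_in, n_out, bias=not use_bn)
        self._masks: list[np.ndarray] = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._masks = []
        for i, lin in enumerate(self.hidden):
            x = lin.forward(x, training)
            if self.use_bn:
                x = self.norms[i].forward(x, training)
            mask = x > 0
            x = x * mask
            if training:
                self._masks.append(mask)
        return self.out.forward(x, training)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = self.out.backward(dy)
        for i in range(len(self.hidden) - 1, -1, -1):
            dx = dx * self._masks[i]
            if self.use_bn:
                dx = self.norms[i].backward(dx)
            dx = self.hidden[i].backward(dx)
        return dx

    def params(self, prefix: str):
        for i, lin in enumerate(self.hidden):
            for name, p, g in lin.params():
                yield f"{prefix}.hidden{i}.{name}", p, g
            if self.use_bn:
                for name, p, g in self.norms[i].params():
                    yield f"{prefix}.norm{i}.{name}", p, g
        for name, p, g in self.out.params():
            yield f"{prefix}.out.{name}", p, g

    def state(self, prefix: str):
        if self.use_bn:
            for i, bn in enumerate(self.norms):
                for name, arr in bn.state():
                    yield f"{prefix}.norm{i}.{name}", arr


# ---------------------------------------------------------------------------
# The pair scorer


class PairScorer:
    """Two projection heads + fusion MLP mapping an embedding pair to P(match)."""

    def __init__(self, cfg: ModelConfig, seq_dim: int, text_dim: int):
        if seq_dim <= 0 or text_dim <= 0:
            raise ValueError("encoder dimensions must be positive")
        self.cfg = cfg
        self.seq_dim = seq_dim
        self.text_dim = text_dim
        rng = np.random.default_rng(cfg.seed)
        width = cfg.hidden_multiplier * cfg.d
        self.seq_head = _MLP(rng, seq_dim, width, cfg.n_hidden, cfg.d,
                             cfg.use_batch_norm, input_layer=True)
        self.text_head = _MLP(rng, text_dim, width, cfg.n_hidden, cfg.d,
                              cfg.use_batch_norm, input_layer=True)
        self.fusion = _MLP(rng, 2 * cfg.d, width, cfg.n_hidden, 1, cfg.use_batch_norm)

    # -- forward / backward over a batch of pairs -------------------------

    @staticmethod
    def _as_batch(x):
        if sparse.issparse(x):
            return x
        return np.atleast_2d(np.asarray(x, dtype=np.float64))

    def score_batch(self, seq_emb, text_emb, training: bool = False) -> np.ndarray:
        """Probabilities for a batch of embedding pairs; rows may be dense
        arrays or scipy.sparse matrices (hashed k-mer inputs are sparse)."""
        seq_emb = self._as_batch(seq_emb)
        text_emb = self._as_batch(text_emb)
        if seq_emb.shape[1] != self.seq_dim or text_emb.shape[1] != self.text_dim:
            raise ValueError(
                f"embedding dims {seq_emb.shape[1]}/{text_emb.shape[1]} do not match "
                f"model dims {self.seq_dim}/{self.text_dim}"
            )
        if seq_emb.shape[0] != text_emb.shape[0]:
            raise ValueError("sequence and text batches differ in length")
        zs = self.seq_head.forward(seq_emb, training)
        zt = self.text_head.forward(text_emb, training)
        logits = self.fusion.forward(np.hstack([zs, zt]), training)[:, 0]
        return 1.0 / (1.0 + np.exp(-logits))

    def backward(self, dlogit: np.ndarray) -> None:
        dcat = self.fusion.backward(np.asarray(dlogit, dtype=np.float64)[:, None])
        d = self.cfg.d
        self.seq_head.backward(dcat[:, :d])
        self.text_head.backward(dcat[:, d:])

    def embed_sequences(self, seq_emb) -> np.ndarray:
        """Sequence projection-head output (inference mode)."""
        return self.seq_head.forward(self._as_batch(seq_emb), False)

    # -- parameter access --------------------------------------------------

    def params(self):
        yield from self.seq_head.params("seq_head")
        yield from self.text_head.params("text_head")
        yield from self.fusion.params("fusion")

    def state(self):
        yield from self.seq_head.state("seq_head")
        yield from self.text_head.state("text_head")
        yield from self.fusion.state("fusion")

    def get_param_dict(self) -> dict[str, np.ndarray]:
        out = {name: p.copy() for name, p, _ in self.params()}
        out.update({name: arr.copy() for name, arr in self.state()})
        return out

    def set_param_dict(self, values: dict[str, np.ndarray]) -> None:
        for name, p, _ in self.params():
            p[...] = values[name]
        for name, arr in self.state():
            arr[...] = values[name]


def build_model(cfg: ModelConfig, seq_dim: int, text_dim: int) -> PairScorer:
    """Construct a seeded, untrained pair scorer."""
    return PairScorer(cfg, seq_dim, text_dim)


def forward(model: PairScorer, seq_embedding: np.ndarray, text_embedding: np.ndarray) -> float:
    """Score one (sequence embedding, text embedding) pair in inference mode."""
    return float(model.score_batch(seq_embedding, text_embedding, training=False)[0])


# ---------------------------------------------------------------------------
# Checkpoints: a single .npz archive of key -> tensor plus embedded JSON config


def save_checkpoint(model: PairScorer, path: str | Path, extra_meta: dict | None = None) -> None:
    meta = {
        "config": asdict(model.cfg),
        "seq_dim": model.seq_dim,
        "text_dim": model.text_dim,
        "extra": extra_meta or {},
    }
    arrays = model.get_param_dict()
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode("utf-8"), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> PairScorer:
    """Restore a PairScorer; any extra metadata lands on ``model.extra_meta``."""
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode("utf-8"))
        model = PairScorer(ModelConfig(**meta["config"]), meta["seq_dim"], meta["text_dim"])
        model.set_param_dict({k: archive[k] for k in archive.files if k != "__meta__"})
    model.extra_meta = meta.get("extra", {})
    return model
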