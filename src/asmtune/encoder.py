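"""Permutation-invariant set encoder trained by contrastive regression.

Each sample enters as a set of z-normalized (hash, count) pairs.  The
encoder is a DeepSets composition

    Enc(X) = g( mean_i h(x_i) ),

where ``h`` (widths 2-128-128-128-128 by default) embeds each element and
``g`` (widths 128-256-256-256-64) maps the pooled representation to a
64-dimensional embedding.  Every layer but the last of each subnet is
followed by batch normalization and a ReLU.  Mean pooling makes the output
independent of element order; in evaluation mode batch normalization uses
running statistics, so inference is deterministic and exactly permutation
invariant (elements are additionally sorted canonically before pooling so
the floating-point summation order is fixed).

Training minimizes the cosine-similarity mean-squared-error contrastive
loss over batches of embeddings z_i with pairwise similarity labels S:

    L = (1 / N^2) * sum_ij ( cos(z_i, z_j) - S_ij )^2,

including the i = j terms.  The network and its Adam optimizer are
implemented directly on numpy arrays (forward and backward passes are
hand-written), keeping the package dependency-light and deterministic.

Data augmentation subsamples a sample's reads at the seven ratios
0.65 ... 0.95 (per-read Bernoulli keep); augmented samples inherit their
parents' pairwise similarity labels, and members of the same family get
label 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "EncoderConfig",
    "TrainConfig",
    "AugmentedSample",
    "SetEncoder",
    "contrastive_loss",
    "cosine_matrix",
    "augment",
    "extend_labels",
    "train",
    "DEFAULT_RATIOS",
]

DEFAULT_RATIOS = (0.65, 0.7, 0.75, 0.8, 0.85, 0.9, 0.95)


@dataclass
class EncoderConfig:
    h_layers: tuple[int, ...] = (2, 128, 128, 128, 128)
    g_layers: tuple[int, ...] = (128, 256, 256, 256, 64)
    bn_momentum: float = 0.1
    bn_eps: float = 1e-5

    def __post_init__(self) -> None:
        if self.h_layers[-1] != self.g_layers[0]:
            raise ValueError("h output width must equal g input width")

    @property
    def embedding_dim(self) -> int:
        return self.g_layers[-1]


@dataclass
class TrainConfig:
    batch_size: int = 128
    epochs: int = 400
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.batch_size, self.epochs) < 1 or self.learning_rate <= 0:
            raise ValueError("training configuration must be positive")


@dataclass
class AugmentedSample:
    parent_id: str
    ratio: float
    reads: list[str]


# ---------------------------------------------------------------------------
# layers


class _Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        # He initialization suits the ReLU subnets
        self.W = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x if train else None
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.gW = self._x.T @ grad
        self.gb = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]


class _BatchNorm:
    def __init__(self, n: int, momentum: float, eps: float):
        self.gamma = np.ones(n)
        self.beta = np.zeros(n)
        self.run_mean = np.zeros(n)
        self.run_var = np.ones(n)
        self.momentum = momentum
        self.eps = eps
        self.ggamma = np.zeros(n)
        self.gbeta = np.zeros(n)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.run_mean = (1 - self.momentum) * self.run_mean + self.momentum * mean
            self.run_var = (1 - self.momentum) * self.run_var + self.momentum * var
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if train:
            self._xhat, self._inv = xhat, inv
        return self.gamma * xhat + self.beta

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        n = grad.shape[0]
        self.ggamma = (grad * xhat).sum(axis=0)
        self.gbeta = grad.sum(axis=0)
        gx = (
            self.gamma
            * inv
            / n
            * (n * grad - grad.sum(axis=0) - xhat * (grad * xhat).sum(axis=0))
        )
        return gx

    def params(self):
        return [(self.gamma, self.ggamma), (self.beta, self.gbeta)]


class _ReLU:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0 if train else None
        return np.maximum(x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask

    def params(self):
        return []


def _mlp(widths: tuple[int, ...], cfg: EncoderConfig, rng) -> list:
    layers: list = []
    n_pairs = len(widths) - 1
    for i in range(n_pairs):
        layers.append(_Linear(widths[i], widths[i + 1], rng))
        if i < n_pairs - 1:
            layers.append(_BatchNorm(widths[i + 1], cfg.bn_momentum, cfg.bn_eps))
            layers.append(_ReLU())
    return layers


def _forward(layers: list, x: np.ndarray, train: bool) -> np.ndarray:
    for layer in layers:
        x = layer.forward(x, train)
    return x


def _backward(layers: list, grad: np.ndarray) -> np.ndarray:
    for layer in reversed(layers):
        grad = layer.backward(grad)
    return grad


class _Adam:
    def __init__(self, params, lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]

    def step(self, params) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for i, (p, g) in enumerate(params):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)


# ---------------------------------------------------------------------------
# encoder


class SetEncoder:
    """DeepSets encoder g(mean h(x)) with hand-written backprop."""

    def __init__(self, config: EncoderConfig | None = None, seed: int = 0):
        self.config = config or EncoderConfig()
        rng = np.random.default_rng(seed)
        self.h = _mlp(self.config.h_layers, self.config, rng)
        self.g = _mlp(self.config.g_layers, self.config, rng)

    # -- parameters

    def _params(self):
        out = []
        for layer in self.h + self.g:
            out.extend(layer.params())
        return out

    # -- forward/backward over a batch of sets

    def forward_batch(
        self, sets: Sequence[np.ndarray], train: bool
    ) -> np.ndarray:
        sizes = np.array([len(x) for x in sets])
        if np.any(sizes == 0):
            raise ValueError("cannot encode an empty set")
        elements = np.concatenate(sets, axis=0)
        seg = np.repeat(np.arange(len(sets)), sizes)
        H = _forward(self.h, elements, train)
        offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]])
        pooled = np.add.reduceat(H, offsets, axis=0) / sizes[:, None]
        Z = _forward(self.g, pooled, train)
        if train:
            self._seg, self._sizes = seg, sizes
        return Z

    def backward_batch(self, dZ: np.ndarray) -> None:
        dPooled = _backward(self.g, dZ)
        dH = dPooled[self._seg] / self._sizes[self._seg][:, None]
        _backward(self.h, dH)

    def encode(self, x_set: np.ndarray) -> np.ndarray:
        """Evaluation-mode embedding of one normalized set.

        Elements are sorted canonically first, so any permutation of the
        input rows yields a bit-identical embedding.
        """
        x_set = np.asarray(x_set, dtype=float)
        if x_set.ndim != 2 or len(x_set) == 0:
            raise ValueError("expected a nonempty (n, d) element array")
        order = np.lexsort(x_set.T[::-1])
        return self.forward_batch([x_set[order]], train=False)[0]

    # -- persistence (JSON of weights; text-only artifact)

    def state_dict(self) -> dict:
        state = {"config": {
            "h_layers": list(self.config.h_layers),
            "g_layers": list(self.config.g_layers),
            "bn_momentum": self.config.bn_momentum,
            "bn_eps": self.config.bn_eps,
        }, "layers": []}
        for layer in self.h + self.g:
            if isinstance(layer, _Linear):
                state["layers"].append(
                    {"type": "linear", "W": layer.W.tolist(), "b": layer.b.tolist()}
                )
            elif isinstance(layer, _BatchNorm):
                state["layers"].append(
                    {
                        "type": "bn",
                        "gamma": layer.gamma.tolist(),
                        "beta": layer.beta.tolist(),
                        "run_mean": layer.run_mean.tolist(),
                        "run_var": layer.run_var.tolist(),
                    }
                )
            else:
                state["layers"].append({"type": "relu"})
        return state

    def load_state_dict(self, state: dict) -> None:
        stored = state["layers"]
        mine = self.h + self.g
        if len(stored) != len(mine):
            raise ValueError("encoder state does not match configuration")
        for layer, rec in zip(mine, stored):
            if isinstance(layer, _Linear):
                layer.W = np.asarray(rec["W"], dtype=float)
                layer.b = np.asarray(rec["b"], dtype=float)
            elif isinstance(layer, _BatchNorm):
                layer.gamma = np.asarray(rec["gamma"], dtype=float)
                layer.beta = np.asarray(rec["beta"], dtype=float)
                layer.run_mean = np.asarray(rec["run_mean"], dtype=float)
                layer.run_var = np.asarray(rec["run_var"], dtype=float)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.state_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "SetEncoder":
        state = json.loads(Path(path).read_text())
        cfg = EncoderConfig(
            h_layers=tuple(state["config"]["h_layers"]),
            g_layers=tuple(state["config"]["g_layers"]),
            bn_momentum=state["config"]["bn_momentum"],
            bn_eps=state["config"]["bn_eps"],
        )
        enc = cls(cfg)
        enc.load_state_dict(state)
        return enc


# ---------------------------------------------------------------------------
# loss


def cosine_matrix(Z: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(Z, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-norm embedding in batch")
    Zn = Z / norms[:, None]
    return Zn @ Zn.T


def contrastive_loss(
    embeddings: np.ndarray, labels: np.ndarray
) -> float:
    """Mean squared error between pairwise cosines and similarity labels.

    The sum runs over all ordered pairs including i = j and is divided by
    the squared batch size.
    """
    Z = np.asarray(embeddings, dtype=float)
    S = np.asarray(labels, dtype=float)
    if S.shape != (len(Z), len(Z)):
        raise ValueError("label matrix must be batch x batch")
    C = cosine_matrix(Z)
    return float(np.mean((C - S) ** 2))


def _loss_and_grad(Z: np.ndarray, S: np.ndarray) -> tuple[float, np.ndarray]:
    norms = np.linalg.norm(Z, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-norm embedding in batch")
    Zn = Z / norms[:, None]
    C = Zn @ Zn.T
    diff = C - S
    n = len(Z)
    loss = float(np.mean(diff**2))
    dC = 2.0 * diff / (n * n)
    dZn = (dC + dC.T) @ Zn
    # back through the row normalization: remove the radial component
    radial = (Zn * dZn).sum(axis=1, keepdims=True)
    dZ = (dZn - Zn * radial) / norms[:, None]
    return loss, dZ


# ---------------------------------------------------------------------------
# augmentation


def augment(
    sample_reads: Sequence[str],
    ratios: Sequence[float] = DEFAULT_RATIOS,
    seed: int = 0,
    parent_id: str = "",
) -> list[AugmentedSample]:
    """One per-read Bernoulli subsample of the reads per sampling ratio."""
    if len(sample_reads) == 0:
        raise ValueError("cannot augment an empty read set")
    out = []
    for idx, ratio in enumerate(ratios):
        rng = np.random.default_rng((seed, idx))
        if ratio >= 1.0:
            kept = list(sample_reads)
        else:
            keep = rng.random(len(sample_reads)) < ratio
            kept = [r for r, kflag in zip(sample_reads, keep) if kflag]
            if not kept:  # degenerate tiny inputs: keep one read
                kept = [sample_reads[int(rng.integers(len(sample_reads)))]]
        out.append(AugmentedSample(parent_id=parent_id, ratio=float(ratio), reads=kept))
    return out


def extend_labels(S: np.ndarray, parent_index: Sequence[int]) -> np.ndarray:
    """Similarity labels for an expanded corpus of originals + augments.

    ``parent_index[t]`` is the representative-sample row that training item
    ``t`` descends from.  Cross-parent pairs inherit the parents' label;
    same-family pairs (original with its own subsamples, or two subsamples
    of one parent) get label 1.
    """
    S = np.asarray(S, dtype=float)
    idx = np.asarray(parent_index, dtype=int)
    ext = S[np.ix_(idx, idx)].copy()
    same = idx[:, None] == idx[None, :]
    ext[same] = 1.0
    return ext


# ---------------------------------------------------------------------------
# training


def train(
    inputs: Sequence[np.ndarray],
    labels: np.ndarray,
    enc_cfg: EncoderConfig | None = None,
    train_cfg: TrainConfig | None = None,
    encoder: SetEncoder | None = None,
) -> tuple[SetEncoder, list[float]]:
    """Minimize the contrastive loss by Adam; returns (encoder, loss history).

    ``inputs`` are normalized element sets (one per training item) and
    ``labels`` the full item-by-item similarity matrix.  Batches are drawn
    without replacement each epoch; the recorded history is the mean batch
    loss per epoch.
    """
    labels = np.asarray(labels, dtype=float)
    n = len(inputs)
    if labels.shape != (n, n):
        raise ValueError("label matrix must be n x n for n inputs")
    train_cfg = train_cfg or TrainConfig()
    encoder = encoder or SetEncoder(enc_cfg, seed=train_cfg.seed)
    opt = _Adam(encoder._params(), train_cfg.learning_rate)
    rng = np.random.default_rng(train_cfg.seed)
    history = []
    for _epoch in range(train_cfg.epochs):
        perm = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, train_cfg.batch_size):
            idx = perm[start : start + train_cfg.batch_size]
            if len(idx) < 2:
                continue
            Z = encoder.forward_batch([inputs[i] for i in idx], train=True)
            loss, dZ = _loss_and_grad(Z, labels[np.ix_(idx, idx)])
            encoder.backward_batch(dZ)
            opt.step(encoder._params())
            batch_losses.append(loss)
        history.append(float(np.mean(batch_losses)) if batch_losses else np.nan)
    return encoder, history
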