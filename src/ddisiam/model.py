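"""Siamese twin CNN for drug-pair event classification.

Two weight-sharing one-dimensional CNN branches encode the two drugs'
similarity-profile matrices (``n_drugs x 3``, the 3 modalities as input
channels); the branch embeddings are fused by element-wise addition and
classified by an MLP head.  Additive fusion plus full weight sharing
makes the network exactly symmetric in drug order at evaluation time.

The backbone is five length-preserving convolutions (kernel 3, stride 1)
with rectifier activations; the rectified output of conv layer 2 is
added to the rectified output of conv layer 4 (a residual connection, so
layers 3-4 learn a correction term), then conv layer 5, batch
normalization and pooling produce the embedding.

All layers are implemented directly on NumPy arrays with explicit
backward passes, keeping the package dependency-light and every
gradient auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "ModelConfig",
    "SiameseCNN",
    "softmax",
    "save_checkpoint",
    "load_checkpoint",
]


class ConfigurationError(ValueError):
    """Raised when an architecture configuration is internally inconsistent."""


@dataclass(frozen=True)
class ModelConfig:
    """Architecture constants.

    Defaults follow the published architecture: five convolutional
    layers with 64/128/128/128/256 kernels of size 3x1, a residual
    connection from conv layer 2 to the input of conv layer 5, batch
    normalization after the last convolution, and an MLP head with
    hidden widths 2048 and 256 over 65 event classes.

    ``pooling`` maps the final ``channels x n_drugs`` feature map to the
    embedding: ``global_average`` (default; roster-size-agnostic
    embedding of length 256) or ``flatten``.

    ``siamese=False`` gives the single-branch ablation: the two input
    matrices are summed and passed through one CNN.
    """

    conv_channels: tuple[int, ...] = (64, 128, 128, 128, 256)
    kernel_length: int = 3
    n_modalities: int = 3
    mlp_hidden: tuple[int, ...] = (2048, 256)
    n_classes: int = 65
    pooling: str = "global_average"
    residual: bool = True
    siamese: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "conv_channels", tuple(self.conv_channels))
        object.__setattr__(self, "mlp_hidden", tuple(self.mlp_hidden))
        if len(self.conv_channels) != 5:
            raise ConfigurationError(
                f"backbone expects 5 conv layers, got {len(self.conv_channels)}"
            )
        if self.residual and self.conv_channels[1] != self.conv_channels[3]:
            raise ConfigurationError(
                "residual connection requires equal channel counts at conv "
                f"layers 2 and 4, got {self.conv_channels[1]} and "
                f"{self.conv_channels[3]}"
            )
        if self.kernel_length < 1 or self.kernel_length % 2 == 0:
            raise ConfigurationError(
                f"kernel_length must be odd for length-preserving padding, "
                f"got {self.kernel_length}"
            )
        if self.n_classes < 2:
            raise ConfigurationError("n_classes must be >= 2")
        if self.pooling not in ("global_average", "flatten"):
            raise ConfigurationError(f"unknown pooling mode {self.pooling!r}")
        if len(self.mlp_hidden) != 2:
            raise ConfigurationError("mlp_hidden must list two hidden widths")


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise normalized exponential; numerically stabilized."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# Layers (forward caches what backward needs; grads accumulate in .g*)
# ---------------------------------------------------------------------------

class _Conv1d:
    """Same-padded 1D convolution, stride 1, over (N, C_in, L) arrays."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        bound = np.sqrt(1.0 / (c_in * k))
        self.w = rng.uniform(-bound, bound, size=(c_out, c_in, k))
        self.b = np.zeros(c_out)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self.k = k

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, length = x.shape
        p = (self.k - 1) // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        # (N, C, L, k) sliding windows -> (N*L, C*k)
        win = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=2)
        cols = win.transpose(0, 2, 1, 3).reshape(n * length, c * self.k)
        self._cols, self._shape = cols, (n, c, length)
        out = cols @ self.w.reshape(self.w.shape[0], -1).T + self.b
        return out.reshape(n, length, -1).transpose(0, 2, 1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, length = self._shape
        c_out = self.w.shape[0]
        gflat = grad.transpose(0, 2, 1).reshape(n * length, c_out)
        self.gw += (gflat.T @ self._cols).reshape(self.w.shape)
        self.gb += gflat.sum(axis=0)
        gcols = gflat @ self.w.reshape(c_out, -1)  # (N*L, C*k)
        gcols = gcols.reshape(n, length, c, self.k)
        p = (self.k - 1) // 2
        gxp = np.zeros((n, c, length + 2 * p))
        for j in range(self.k):
            gxp[:, :, j : j + length] += gcols[:, :, :, j].transpose(0, 2, 1)
        return gxp[:, :, p : p + length]

    def params(self):
        return [("w", self), ("b", self)]


class _BatchNorm1d:
    """Per-channel batch normalization over (N, C, L).

    Batch statistics in training; exponential running averages
    (momentum 0.1) in evaluation.
    """

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        self._cache = (xhat, inv, train, x.shape)
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv, train, shape = self._cache
        self.ggamma += (grad * xhat).sum(axis=(0, 2))
        self.gbeta += grad.sum(axis=(0, 2))
        gxhat = grad * self.gamma[None, :, None]
        if not train:
            return gxhat * inv[None, :, None]
        m = shape[0] * shape[2]
        s1 = gxhat.sum(axis=(0, 2))[None, :, None]
        s2 = (gxhat * xhat).sum(axis=(0, 2))[None, :, None]
        return (inv[None, :, None] / m) * (m * gxhat - s1 - xhat * s2)


class _Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        bound = np.sqrt(1.0 / d_in)
        self.w = rng.uniform(-bound, bound, size=(d_out, d_in))
        self.b = np.zeros(d_out)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.gw += grad.T @ self._x
        self.gb += grad.sum(axis=0)
        return grad @ self.w


class _ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0)


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------

class SiameseCNN:
    """Weight-sharing twin CNN + additive fusion + MLP head.

    Parameters are initialized with fan-in-scaled uniform draws and zero
    biases from a seeded generator, so construction is reproducible.

    ``n_drugs`` fixes the profile length the network was built for (and,
    under ``flatten`` pooling, the head's input width).
    """

    def __init__(self, config: ModelConfig, n_drugs: int, seed: int = 0):
        self.config = config
        self.n_drugs = int(n_drugs)
        rng = np.random.default_rng(seed)
        ch = config.conv_channels
        k = config.kernel_length
        self.convs = [
            _Conv1d(config.n_modalities, ch[0], k, rng),
            _Conv1d(ch[0], ch[1], k, rng),
            _Conv1d(ch[1], ch[2], k, rng),
            _Conv1d(ch[2], ch[3], k, rng),
            _Conv1d(ch[3], ch[4], k, rng),
        ]
        self.bn = _BatchNorm1d(ch[4])
        self.embedding_dim = (
            ch[4] if config.pooling == "global_average" else ch[4] * self.n_drugs
        )
        h1, h2 = config.mlp_hidden
        self.head = [
            _Linear(self.embedding_dim, h1, rng),
            _Linear(h1, h2, rng),
            _Linear(h2, config.n_classes, rng),
        ]
        self._relus = [_ReLU() for _ in range(6)]  # conv1-4, head hidden x2

    # -- parameter bookkeeping -------------------------------------------

    def _param_layers(self):
        for i, c in enumerate(self.convs):
            yield f"conv{i + 1}", c
        yield "bn", self.bn
        for i, l in enumerate(self.head):
            yield f"fc{i + 1}", l

    def parameters(self) -> dict[str, np.ndarray]:
        """Flat name -> array view of every trainable parameter."""
        out: dict[str, np.ndarray] = {}
        for name, layer in self._param_layers():
            if isinstance(layer, _BatchNorm1d):
                out[f"{name}.gamma"] = layer.gamma
                out[f"{name}.beta"] = layer.beta
            else:
                out[f"{name}.w"] = layer.w
                out[f"{name}.b"] = layer.b
        return out

    def gradients(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, layer in self._param_layers():
            if isinstance(layer, _BatchNorm1d):
                out[f"{name}.gamma"] = layer.ggamma
                out[f"{name}.beta"] = layer.gbeta
            else:
                out[f"{name}.w"] = layer.gw
                out[f"{name}.b"] = layer.gb
        return out

    def set_parameters(self, values: dict[str, np.ndarray]) -> None:
        current = self.parameters()
        for name, arr in values.items():
            current[name][...] = arr

    def zero_grad(self) -> None:
        for g in self.gradients().values():
            g[...] = 0.0

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters().values())

    # -- forward / backward ----------------------------------------------

    def backbone_forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Encode profile matrices (N, n_drugs, 3) -> embeddings (N, d)."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1] != self.n_drugs or x.shape[2] != self.config.n_modalities:
            raise ConfigurationError(
                f"input shape {x.shape[1:]} does not match "
                f"({self.n_drugs}, {self.config.n_modalities})"
            )
        h = x.transpose(0, 2, 1)  # modalities become conv channels
        h = self._relus[0].forward(self.convs[0].forward(h))
        h2 = self._relus[1].forward(self.convs[1].forward(h))
        h = self._relus[2].forward(self.convs[2].forward(h2))
        h = self._relus[3].forward(self.convs[3].forward(h))
        pre5 = h + h2 if self.config.residual else h
        h = self.bn.forward(self.convs[4].forward(pre5), train)
        self._pooled_shape = h.shape
        if self.config.pooling == "global_average":
            return h.mean(axis=2)
        return h.reshape(h.shape[0], -1)

    def _backbone_backward(self, gemb: np.ndarray) -> None:
        n, c, length = self._pooled_shape
        if self.config.pooling == "global_average":
            g = np.broadcast_to(gemb[:, :, None] / length, (n, c, length)).copy()
        else:
            g = gemb.reshape(n, c, length)
        g = self.convs[4].backward(self.bn.backward(g))
        gskip = g if self.config.residual else 0.0
        g = self.convs[3].backward(self._relus[3].backward(g))
        g = self.convs[2].backward(self._relus[2].backward(g))
        g = g + gskip
        g = self.convs[1].backward(self._relus[1].backward(g))
        self.convs[0].backward(self._relus[0].backward(g))

    def head_forward(self, fused: np.ndarray) -> np.ndarray:
        """MLP head: fused embedding (N, d) -> logits (N, n_classes)."""
        h = self._relus[4].forward(self.head[0].forward(fused))
        h = self._relus[5].forward(self.head[1].forward(h))
        return self.head[2].forward(h)

    def _head_backward(self, glogits: np.ndarray) -> np.ndarray:
        g = self.head[2].backward(glogits)
        g = self.head[1].backward(self._relus[5].backward(g))
        return self.head[0].backward(self._relus[4].backward(g))

    @staticmethod
    def fuse(ea: np.ndarray, eb: np.ndarray) -> np.ndarray:
        """Element-wise additive fusion of the two branch embeddings."""
        ea, eb = np.asarray(ea, float), np.asarray(eb, float)
        if ea.shape != eb.shape:
            raise ConfigurationError(
                f"embedding shape mismatch: {ea.shape} vs {eb.shape}"
            )
        return ea + eb

    def forward(
        self, xa: np.ndarray, xb: np.ndarray, train: bool = False
    ) -> np.ndarray:
        """Logits for a batch of ordered drug pairs.

        Both branches run through the same parameters; the two inputs
        are concatenated into one backbone batch so batch-norm sees a
        drug-order-invariant batch.
        """
        xa = np.asarray(xa, float)
        xb = np.asarray(xb, float)
        if xa.ndim == 2:
            xa = xa[None]
        if xb.ndim == 2:
            xb = xb[None]
        n = xa.shape[0]
        if not self.config.siamese:
            emb = self.backbone_forward(xa + xb, train)
            self._n_pairs = None
            return self.head_forward(emb)
        emb = self.backbone_forward(np.concatenate([xa, xb], axis=0), train)
        self._n_pairs = n
        fused = self.fuse(emb[:n], emb[n:])
        return self.head_forward(fused)

    def backward(self, grad_logits: np.ndarray) -> None:
        """Backpropagate d(loss)/d(logits); accumulates into gradients()."""
        gfused = self._head_backward(np.asarray(grad_logits, float))
        if self._n_pairs is None:
            self._backbone_backward(gfused)
        else:
            self._backbone_backward(np.concatenate([gfused, gfused], axis=0))

    def predict_proba(self, xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
        """Evaluation-mode class probabilities for ordered pairs."""
        return softmax(self.forward(xa, xb, train=False))


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

CHECKPOINT_SCHEMA = 1


def save_checkpoint(
    model: SiameseCNN, path: str | Path, drug_ids: tuple[str, ...] | None = None
) -> None:
    """Write config echo, all parameter/normalization arrays and the
    roster drug-id order (needed to featurize future queries) to one
    ``.npz`` archive with a versioned schema field."""
    meta = {
        "schema": CHECKPOINT_SCHEMA,
        "config": asdict(model.config),
        "n_drugs": model.n_drugs,
        "drug_ids": list(drug_ids) if drug_ids is not None else None,
    }
    arrays = {f"param/{k}": v for k, v in model.parameters().items()}
    arrays["state/bn.running_mean"] = model.bn.running_mean
    arrays["state/bn.running_var"] = model.bn.running_var
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path: str | Path) -> tuple[SiameseCNN, list[str] | None]:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        if meta["schema"] != CHECKPOINT_SCHEMA:
            raise ConfigurationError(
                f"unsupported checkpoint schema {meta['schema']}"
            )
        cfg = ModelConfig(**meta["config"])
        model = SiameseCNN(cfg, n_drugs=meta["n_drugs"], seed=0)
        model.set_parameters(
            {k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")}
        )
        model.bn.running_mean = data["state/bn.running_mean"].copy()
        model.bn.running_var = data["state/bn.running_var"].copy()
    return model, meta["drug_ids"]
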