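"""The Conv1D-augmented transformer classifier for prominent bowel sounds.

Architecture, following the published configuration:

- Conv1D stem over the MFCC frame axis (13 input channels -> 64 filters,
  kernel 3, stride 1, same padding), layer normalization, ReLU, then a
  learned 64 -> 128 projection bridging the stem width to the transformer
  embedding dimension, plus fixed sinusoidal positional encoding (the
  projection and positional code are this package's reading of the
  64-filter stem feeding a 128-wide encoder; a switch disables the
  positional code).
- 4 post-norm transformer encoder blocks: 8-head self-attention
  (d_k = 128/8 = 16) -> dropout -> residual -> layer norm -> feed-forward
  128 -> 256 -> 128 with ReLU -> dropout -> residual -> layer norm.
- Global average pooling over frames, dense 128 -> 64 with ReLU, dense
  64 -> 1 with sigmoid.

Weights initialize from a uniform fan-in scheme with a seeded generator,
so a config plus seed fully determines the network.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn

__all__ = ["ModelConfig", "TransformerBlock", "BowelSoundClassifier",
           "count_parameters", "load_checkpoint"]


@dataclass(frozen=True)
class ModelConfig:
    conv_kernel: int = 3
    conv_filters: int = 64
    n_blocks: int = 4
    n_heads: int = 8
    d_model: int = 128
    ffn_dim: int = 256
    dropout: float = 0.1
    dense_hidden: int = 64
    input_shape: tuple[int, int] = (31, 13)  # (frames, n_coeffs)
    positional_encoding: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    @staticmethod
    def reduced(seed: int = 0, input_shape: tuple[int, int] = (31, 13)) -> "ModelConfig":
        """A narrow variant for single-CPU experiments; same topology."""
        return ModelConfig(conv_filters=24, n_blocks=2, n_heads=4, d_model=32,
                           ffn_dim=64, dense_hidden=16, seed=seed,
                           input_shape=input_shape)


class TransformerBlock(nn.Layer):
    """Post-norm encoder block: attention and feed-forward sub-layers,
    each followed by dropout, a residual connection, and layer norm."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.attn = nn.MultiHeadSelfAttention(cfg.d_model, cfg.n_heads, rng)
        self.drop1 = nn.Dropout(cfg.dropout, rng)
        self.norm1 = nn.LayerNorm(cfg.d_model)
        self.ffn1 = nn.Dense(cfg.d_model, cfg.ffn_dim, rng)
        self.ffn_relu = nn.ReLU()
        self.ffn2 = nn.Dense(cfg.ffn_dim, cfg.d_model, rng)
        self.drop2 = nn.Dropout(cfg.dropout, rng)
        self.norm2 = nn.LayerNorm(cfg.d_model)
        self.sublayers = [self.attn, self.drop1, self.norm1, self.ffn1,
                          self.ffn_relu, self.ffn2, self.drop2, self.norm2]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        a = self.drop1.forward(self.attn.forward(x, training), training)
        h = self.norm1.forward(x + a, training)
        f = self.ffn2.forward(
            self.ffn_relu.forward(self.ffn1.forward(h, training), training), training
        )
        f = self.drop2.forward(f, training)
        return self.norm2.forward(h + f, training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.norm2.backward(grad)
        gf = self.ffn1.backward(
            self.ffn_relu.backward(self.ffn2.backward(self.drop2.backward(g)))
        )
        gh = self.norm1.backward(g + gf)
        gx = self.attn.backward(self.drop1.backward(gh))
        return gh + gx


class BowelSoundClassifier:
    """Binary segment classifier: (batch, frames, 13) -> probability."""

    def __init__(self, cfg: ModelConfig = ModelConfig()):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        frames, n_coeffs = cfg.input_shape
        self.conv = nn.Conv1DSame(n_coeffs, cfg.conv_filters, cfg.conv_kernel, rng)
        self.conv_norm = nn.LayerNorm(cfg.conv_filters)
        self.conv_relu = nn.ReLU()
        self.proj = nn.Dense(cfg.conv_filters, cfg.d_model, rng)
        self.pos = nn.PositionalEncoding(frames, cfg.d_model)
        self.blocks = [TransformerBlock(cfg, rng) for _ in range(cfg.n_blocks)]
        self.pool = nn.GlobalAveragePool()
        self.head1 = nn.Dense(cfg.d_model, cfg.dense_hidden, rng)
        self.head_relu = nn.ReLU()
        self.head2 = nn.Dense(cfg.dense_hidden, 1, rng)

    # ---- layer plumbing -------------------------------------------------

    def _named_layers(self) -> list[tuple[str, nn.Layer]]:
        pairs: list[tuple[str, nn.Layer]] = [
            ("conv", self.conv), ("conv_norm", self.conv_norm), ("proj", self.proj)
        ]
        sublayer_names = ("attn", "drop1", "norm1", "ffn1", "ffn_relu", "ffn2",
                          "drop2", "norm2")
        for i, block in enumerate(self.blocks):
            pairs.extend(
                (f"block{i}.{s}", layer)
                for s, layer in zip(sublayer_names, block.sublayers)
            )
        pairs.extend([("head1", self.head1), ("head2", self.head2)])
        return pairs

    def named_parameters(self) -> dict[str, np.ndarray]:
        return {
            f"{prefix}.{pname}": value
            for prefix, layer in self._named_layers()
            for pname, value in layer.params.items()
        }

    def named_grads(self) -> dict[str, np.ndarray]:
        return {
            f"{prefix}.{pname}": value
            for prefix, layer in self._named_layers()
            for pname, value in layer.grads.items()
        }

    def zero_grad(self) -> None:
        for _, layer in self._named_layers():
            layer.zero_grad()

    def n_parameters(self) -> int:
        """Introspected learned-scalar count (sum of parameter sizes)."""
        return sum(layer.n_params() for _, layer in self._named_layers())

    # ---- forward / backward --------------------------------------------

    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        squeeze = x.ndim == 2
        if squeeze:
            x = x[None]
        h = self.conv.forward(x, training)
        h = self.conv_relu.forward(self.conv_norm.forward(h, training), training)
        h = self.proj.forward(h, training)
        if self.cfg.positional_encoding:
            h = self.pos.forward(h, training)
        for block in self.blocks:
            h = block.forward(h, training)
        h = self.pool.forward(h, training)
        h = self.head_relu.forward(self.head1.forward(h, training), training)
        z = self.head2.forward(h, training)[:, 0]
        return z[0:1] if squeeze else z

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Per-segment probability of the prominent class, in (0, 1)."""
        return nn.sigmoid(self.forward_logits(x, training=False))

    def backward_from_logits(self, dlogits: np.ndarray) -> None:
        g = self.head2.backward(dlogits[:, None])
        g = self.head1.backward(self.head_relu.backward(g))
        g = self.pool.backward(g)
        for block in reversed(self.blocks):
            g = block.backward(g)
        if self.cfg.positional_encoding:
            g = self.pos.backward(g)
        g = self.proj.backward(g)
        g = self.conv_norm.backward(self.conv_relu.backward(g))
        self.conv.backward(g)

    def loss_and_grad_step(self, x: np.ndarray, y: np.ndarray,
                           training: bool = True) -> float:
        """One forward/backward pass; leaves gradients in the layers."""
        self.zero_grad()
        z = self.forward_logits(x, training=training)
        loss, dz = nn.bce_with_logits(z, y)
        self.backward_from_logits(dz)
        return loss

    # ---- weights I/O ----------------------------------------------------

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.named_parameters().items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        if set(params) != set(weights):
            raise ValueError("weight names do not match this architecture")
        for name, value in weights.items():
            if params[name].shape != value.shape:
                raise ValueError(f"shape mismatch for {name}")
            params[name][...] = value

    def save_checkpoint(self, path: str | Path) -> Path:
        """Serialize config + weights to one .npz checkpoint."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        cfg_json = json.dumps(asdict(self.cfg))
        np.savez(path, __config__=np.frombuffer(cfg_json.encode(), dtype=np.uint8),
                 **self.named_parameters())
        return path


def load_checkpoint(path: str | Path) -> BowelSoundClassifier:
    with np.load(path) as data:
        cfg_dict = json.loads(bytes(data["__config__"]).decode())
        cfg_dict["input_shape"] = tuple(cfg_dict["input_shape"])
        model = BowelSoundClassifier(ModelConfig(**cfg_dict))
        model.set_weights({k: data[k] for k in data.files if k != "__config__"})
    return model


def count_parameters(cfg: ModelConfig) -> int:
    """Closed-form learned-scalar count for a config.

    The head count h never appears: head splitting is a reshape of the
    same projection matrices.
    """
    k, f, d = cfg.conv_kernel, cfg.conv_filters, cfg.d_model
    frames, c_in = cfg.input_shape
    conv = k * c_in * f + f
    conv_norm = 2 * f
    proj = f * d + d
    attn = 4 * (d * d + d)
    ffn = d * cfg.ffn_dim + cfg.ffn_dim + cfg.ffn_dim * d + d
    block = attn + 2 * d + ffn + 2 * d  # two layer norms
    head = d * cfg.dense_hidden + cfg.dense_hidden + cfg.dense_hidden * 1 + 1
    return conv + conv_norm + proj + cfg.n_blocks * block + head
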