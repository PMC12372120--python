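"""Primary and secondary classification networks.

The primary classifier is an MLP with a 4-head self-attention block on its
64-d hidden representation:

    fc1 (in -> 64) -> ReLU -> dropout 0.3 -> fc2 (64 -> 64)
        -> multi-head self-attention (d_model=64, h=4, d_k=d_v=16)
        -> dropout 0.3 -> [embedding, 64-d] -> classifier (64 -> C)

The secondary correction network is deliberately lighter:

    fc1 (64 -> 32) -> ReLU -> dropout 0.5
        -> multi-head self-attention (d_model=32, h=4, d_k=d_v=8)
        -> dropout 0.5 -> classifier (32 -> C)

Attention operates on the hidden vector either as one token (``single_token``,
default: the softmax over a single key is degenerate, so the block is a
composition of the head projections — faithful to the stated geometry) or
reshaped into ``h`` feature tokens (``feature_tokens``). Projections carry no
bias terms. No residual connections or layer norm. Dropout is inverted
dropout, active only in training mode.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .autodiff import Tensor, concat

__all__ = [
    "NetworkSpec",
    "Linear",
    "MultiHeadSelfAttention",
    "PrimaryNet",
    "SecondaryNet",
    "scaled_dot_attention",
    "save_state",
    "load_state",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture description for either network."""

    in_dim: int
    hidden_dims: tuple = (64, 64)
    dropout_rates: tuple = (0.3, 0.3)
    n_heads: int = 4
    d_model: int = 64
    d_k: int = 16
    d_v: int = 16
    out_dim: int = 3
    token_layout: str = "single_token"  # or "feature_tokens"
    use_attention: bool = True

    def __post_init__(self):
        if self.use_attention and self.d_model != self.n_heads * self.d_k:
            raise ValueError(
                f"d_model ({self.d_model}) must equal h*d_k "
                f"({self.n_heads}*{self.d_k})"
            )
        if any(not 0 <= r < 1 for r in self.dropout_rates):
            raise ValueError("dropout rates must lie in [0, 1)")
        if self.token_layout not in ("single_token", "feature_tokens"):
            raise ValueError(f"unknown token_layout {self.token_layout!r}")


def scaled_dot_attention(Q, K, V) -> np.ndarray:
    """softmax(Q K^T / sqrt(d_k)) V on plain arrays (single head)."""
    Q, K, V = (np.asarray(m, dtype=np.float64) for m in (Q, K, V))
    if Q.shape[-1] != K.shape[-1]:
        raise ValueError("Q and K widths differ")
    if K.shape[-2] != V.shape[-2]:
        raise ValueError("K and V token counts differ")
    scores = Q @ np.swapaxes(K, -1, -2) / np.sqrt(Q.shape[-1])
    scores -= scores.max(axis=-1, keepdims=True)
    w = np.exp(scores)
    w /= w.sum(axis=-1, keepdims=True)
    return w @ V


class Linear:
    """Dense layer with seeded uniform fan-in initialization."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(in_dim)
        self.W = Tensor(rng.uniform(-bound, bound, (in_dim, out_dim)),
                        requires_grad=True)
        self.b = Tensor(rng.uniform(-bound, bound, out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def params(self) -> list[Tensor]:
        return [self.W, self.b]


class MultiHeadSelfAttention:
    """h parallel scaled-dot-product heads on Q = K = V = x, concatenated
    and projected by W_O. Bias-free projections."""

    def __init__(self, d_model: int, n_heads: int, d_k: int, d_v: int,
                 rng: np.random.Generator):
        if n_heads * d_v != d_model:
            raise ValueError("h * d_v must equal d_model for the concat width")
        self.d_model, self.h, self.d_k, self.d_v = d_model, n_heads, d_k, d_v
        bound = 1.0 / np.sqrt(d_model)

        def mk(shape):
            return Tensor(rng.uniform(-bound, bound, shape), requires_grad=True)

        self.Wq = mk((d_model, n_heads * d_k))
        self.Wk = mk((d_model, n_heads * d_k))
        self.Wv = mk((d_model, n_heads * d_v))
        self.Wo = mk((n_heads * d_v, d_model))

    def __call__(self, x: Tensor) -> Tensor:
        """x: (B, T, d_model) -> (B, T, d_model)."""
        B, T, _ = x.shape
        h, d_k, d_v = self.h, self.d_k, self.d_v

        def split_heads(t: Tensor, width: int) -> Tensor:
            # (B, T, h*width) -> (B, h, T, width)
            return t.reshape(B, T, h, width).swapaxes(1, 2)

        Q = split_heads(x @ self.Wq, d_k)
        K = split_heads(x @ self.Wk, d_k)
        V = split_heads(x @ self.Wv, d_v)
        scores = (Q @ K.swapaxes(2, 3)) / np.sqrt(d_k)
        attn = scores.softmax(axis=-1)
        heads = attn @ V  # (B, h, T, d_v)
        merged = heads.swapaxes(1, 2).reshape(B, T, h * d_v)
        return merged @ self.Wo

    def params(self) -> list[Tensor]:
        return [self.Wq, self.Wk, self.Wv, self.Wo]


def _dropout(x: Tensor, rate: float, training: bool,
             rng: np.random.Generator | None) -> Tensor:
    if not training or rate == 0.0:
        return x
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)


class _AttentionMLP:
    """Shared skeleton: fc stack, optional attention block, classifier."""

    def __init__(self, spec: NetworkSpec, seed: int):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.fcs = []
        prev = spec.in_dim
        for width in spec.hidden_dims:
            self.fcs.append(Linear(prev, width, rng))
            prev = width
        self.attn = None
        if spec.use_attention:
            if spec.token_layout == "feature_tokens":
                tok = spec.d_model // spec.n_heads
                self.attn = MultiHeadSelfAttention(
                    tok, spec.n_heads, tok // spec.n_heads or 1,
                    tok // spec.n_heads or 1, rng)
            else:
                self.attn = MultiHeadSelfAttention(
                    spec.d_model, spec.n_heads, spec.d_k, spec.d_v, rng)
        self.classifier = Linear(prev, spec.out_dim, rng)

    def params(self) -> list[Tensor]:
        out: list[Tensor] = []
        for fc in self.fcs:
            out.extend(fc.params())
        if self.attn is not None:
            out.extend(self.attn.params())
        out.extend(self.classifier.params())
        return out

    def n_params(self) -> int:
        return sum(p.data.size for p in self.params())

    def _apply_attention(self, x: Tensor) -> Tensor:
        B, d = x.shape
        if self.spec.token_layout == "feature_tokens":
            tok = self.spec.d_model // self.spec.n_heads
            t = x.reshape(B, self.spec.n_heads, tok)
            return self.attn(t).reshape(B, d)
        return self.attn(x.reshape(B, 1, d)).reshape(B, d)


class PrimaryNet(_AttentionMLP):
    """Primary classifier; forward returns logits and the 64-d embedding."""

    def __init__(self, spec: NetworkSpec, seed: int):
        super().__init__(spec, seed)

    def forward(self, features: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None
                ) -> tuple[Tensor, Tensor]:
        x = np.atleast_2d(np.asarray(features, dtype=np.float64))
        if x.shape[1] != self.spec.in_dim:
            raise ValueError(
                f"expected {self.spec.in_dim} input features, got {x.shape[1]}"
            )
        t = Tensor(x)
        t = self.fcs[0](t).relu()
        t = _dropout(t, self.spec.dropout_rates[0], training, rng)
        t = self.fcs[1](t)
        if self.attn is not None:
            t = self._apply_attention(t)
        t = _dropout(t, self.spec.dropout_rates[1], training, rng)
        embedding = t
        logits = self.classifier(t)
        return logits, embedding

    def predict(self, features: np.ndarray) -> np.ndarray:
        logits, _ = self.forward(features, training=False)
        return logits.data.argmax(axis=1)

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        logits, _ = self.forward(features, training=False)
        return logits.softmax(axis=-1).data

    def embed(self, features: np.ndarray) -> np.ndarray:
        _, emb = self.forward(features, training=False)
        return emb.data


class SecondaryNet(_AttentionMLP):
    """Lighter correction network consuming the primary's 64-d embeddings
    (or raw features behind an input projection)."""

    def __init__(self, spec: NetworkSpec, seed: int):
        super().__init__(spec, seed)

    @staticmethod
    def default_spec(in_dim: int = 64, out_dim: int = 3) -> NetworkSpec:
        return NetworkSpec(
            in_dim=in_dim, hidden_dims=(32,), dropout_rates=(0.5, 0.5),
            n_heads=4, d_model=32, d_k=8, d_v=8, out_dim=out_dim)

    @staticmethod
    def raw_feature_spec(in_dim: int, out_dim: int = 3) -> NetworkSpec:
        """Fallback mode: raw features behind an in_dim -> 64 projection."""
        return NetworkSpec(
            in_dim=in_dim, hidden_dims=(64, 32), dropout_rates=(0.5, 0.5),
            n_heads=4, d_model=32, d_k=8, d_v=8, out_dim=out_dim)

    def forward(self, features: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None
                ) -> tuple[Tensor, Tensor]:
        x = np.atleast_2d(np.asarray(features, dtype=np.float64))
        if x.shape[1] != self.spec.in_dim:
            raise ValueError(
                f"expected {self.spec.in_dim} input features, got {x.shape[1]}"
            )
        t = Tensor(x)
        for fc in self.fcs:  # one fc by default; raw-feature mode prepends 8->64
            t = fc(t).relu()
        t = _dropout(t, self.spec.dropout_rates[0], training, rng)
        if self.attn is not None:
            t = self._apply_attention(t)
        t = _dropout(t, self.spec.dropout_rates[1], training, rng)
        logits = self.classifier(t)
        return logits, t

    predict = PrimaryNet.predict
    predict_proba = PrimaryNet.predict_proba


def save_state(net: _AttentionMLP, path) -> None:
    """Checkpoint: parameters in an .npz plus a JSON sidecar of the spec."""
    arrays = {f"p{i}": p.data for i, p in enumerate(net.params())}
    np.savez(path, **arrays)
    sidecar = str(path) + ".json"
    with open(sidecar, "w") as fh:
        json.dump(
            {"spec": asdict(net.spec), "seed": net.seed,
             "kind": type(net).__name__},
            fh, indent=2)


def load_state(path) -> _AttentionMLP:
    sidecar = str(path) + ".json"
    with open(sidecar) as fh:
        meta = json.load(fh)
    spec_dict = meta["spec"]
    spec_dict["hidden_dims"] = tuple(spec_dict["hidden_dims"])
    spec_dict["dropout_rates"] = tuple(spec_dict["dropout_rates"])
    spec = NetworkSpec(**spec_dict)
    cls = {"PrimaryNet": PrimaryNet, "SecondaryNet": SecondaryNet}[meta["kind"]]
    net = cls(spec, meta["seed"])
    with np.load(path if str(path).endswith(".npz") else str(path) + ".npz") as data:
        for i, p in enumerate(net.params()):
            p.data = data[f"p{i}"].copy()
    return net
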