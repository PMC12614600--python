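"""Token-sequence transformer encoder.

Used for the amino-acid sequence, the discrete structure-token string and
the keyword-text modality. The layer follows the printed form exactly:
learned token embedding plus learned positional table, then per layer
multi-head scaled dot-product attention (softmax over valid key
positions only), head concatenation through ``W_O``, and a position-wise
feed-forward network ``max(0, hW1 + b1)W2 + b2``. With ``n_layers=0``
the output is ``E(x) + P(x)``.

A masked-language-model head and loss are provided for pretraining the
text encoder. Any weight matrix can be wrapped with low-rank adapters
(``lora_rank``), in which case the ``lora`` training policy updates only
the factors.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ..autodiff import Tensor, astensor, concat
from .lora import LoraAdapter

_NEG_INF = -1e30


@dataclasses.dataclass(frozen=True)
class TransformerConfig:
    vocab_size: int
    d_model: int = 32
    n_layers: int = 1
    n_heads: int = 4
    d_ff: int = 64
    max_len: int = 128

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        for field in ("vocab_size", "d_model", "n_heads", "d_ff", "max_len"):
            if getattr(self, field) < 1:
                raise ValueError(f"{field} must be >= 1")
        if self.n_layers < 0:
            raise ValueError("n_layers must be >= 0")

    @property
    def d_head(self) -> int:
        return self.d_model // self.n_heads


class _MaybeLora:
    """A weight matrix, optionally carrying low-rank adapter factors."""

    def __init__(self, data: np.ndarray, lora_rank: int | None,
                 lora_alpha: float, rng: np.random.Generator):
        self.base = Tensor(data, requires_grad=True)
        self.adapter: LoraAdapter | None = None
        if lora_rank is not None and lora_rank < min(data.shape):
            self.adapter = LoraAdapter(
                data, rank=lora_rank, alpha=lora_alpha,
                seed=int(rng.integers(2 ** 31)))
            # share storage so "frozen W" and base view agree
            self.adapter.W = self.base

    def matmul(self, x: Tensor) -> Tensor:
        if self.adapter is not None:
            return self.adapter.forward(x)
        return x @ self.base


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


class Transformer:
    """Seedable transformer encoder state plus forward pass."""

    def __init__(self, config: TransformerConfig, seed: int = 0,
                 lora_rank: int | None = None, lora_alpha: float = 1.0):
        self.config = config
        rng = np.random.default_rng(seed)
        d, ff = config.d_model, config.d_ff
        s = 1.0 / np.sqrt(d)
        self.embedding = Tensor(rng.normal(scale=s, size=(config.vocab_size, d)),
                                requires_grad=True)
        self.positional = Tensor(rng.normal(scale=s, size=(config.max_len, d)),
                                 requires_grad=True)
        self.layers: list[dict] = []
        for _ in range(config.n_layers):
            layer = {
                "Wq": _MaybeLora(rng.normal(scale=s, size=(d, d)), lora_rank,
                                 lora_alpha, rng),
                "Wk": _MaybeLora(rng.normal(scale=s, size=(d, d)), lora_rank,
                                 lora_alpha, rng),
                "Wv": _MaybeLora(rng.normal(scale=s, size=(d, d)), lora_rank,
                                 lora_alpha, rng),
                "Wo": _MaybeLora(rng.normal(scale=s, size=(d, d)), lora_rank,
                                 lora_alpha, rng),
                "W1": _MaybeLora(rng.normal(scale=s, size=(d, ff)), lora_rank,
                                 lora_alpha, rng),
                "b1": Tensor(np.zeros(ff), requires_grad=True),
                "W2": _MaybeLora(rng.normal(scale=1.0 / np.sqrt(ff), size=(ff, d)),
                                 lora_rank, lora_alpha, rng),
                "b2": Tensor(np.zeros(d), requires_grad=True),
            }
            self.layers.append(layer)

    # -- parameter access ----------------------------------------------------
    def _base_parameters(self) -> list[Tensor]:
        params = [self.embedding, self.positional]
        for layer in self.layers:
            for v in layer.values():
                params.append(v.base if isinstance(v, _MaybeLora) else v)
        return params

    def _lora_parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for layer in self.layers:
            for v in layer.values():
                if isinstance(v, _MaybeLora) and v.adapter is not None:
                    params.extend(v.adapter.trainable_parameters())
        return params

    def trainable_parameters(self, policy: str = "full") -> list[Tensor]:
        if policy == "freeze":
            return []
        if policy == "full":
            return self._base_parameters() + self._lora_parameters()
        if policy == "lora":
            return self._lora_parameters()
        raise ValueError(f"unknown training policy '{policy}'")

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {"embedding": self.embedding.data, "positional": self.positional.data}
        for i, layer in enumerate(self.layers):
            for k, v in layer.items():
                out[f"layer{i}.{k}"] = (v.base.data if isinstance(v, _MaybeLora)
                                        else v.data)
                if isinstance(v, _MaybeLora) and v.adapter is not None:
                    out[f"layer{i}.{k}.lora_A"] = v.adapter.A.data
                    out[f"layer{i}.{k}.lora_B"] = v.adapter.B.data
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        self.embedding.data = np.array(state["embedding"])
        self.positional.data = np.array(state["positional"])
        for i, layer in enumerate(self.layers):
            for k, v in layer.items():
                data = np.array(state[f"layer{i}.{k}"])
                if isinstance(v, _MaybeLora):
                    v.base.data = data
                    if v.adapter is not None:
                        v.adapter.A.data = np.array(state[f"layer{i}.{k}.lora_A"])
                        v.adapter.B.data = np.array(state[f"layer{i}.{k}.lora_B"])
                else:
                    v.data = data

    def checksum(self) -> float:
        return float(sum(np.abs(p).sum() for p in self.state_dict().values()))

    # -- forward -------------------------------------------------------------
    def forward(self, tokens: np.ndarray, mask: np.ndarray | None = None) -> Tensor:
        """Encode ``tokens`` (B, L) ints with a validity ``mask`` (B, L).

        Returns per-position features of shape (B, L, d). Padded key
        positions are excluded from every attention softmax, so outputs
        at valid positions are independent of padded content.
        """
        tokens = np.asarray(tokens)
        if tokens.ndim == 1:
            tokens = tokens[None, :]
            if mask is not None:
                mask = np.asarray(mask)[None, :]
        B, L = tokens.shape
        cfg = self.config
        if L > cfg.max_len:
            raise ValueError(f"length {L} exceeds maximum {cfg.max_len}")
        if tokens.min() < 0 or tokens.max() >= cfg.vocab_size:
            raise ValueError("token id out of range")
        if mask is None:
            mask = np.ones((B, L), dtype=bool)
        mask = np.asarray(mask, dtype=bool)

        h = self.embedding[tokens] + self.positional[slice(0, L)]
        key_bias = np.where(mask, 0.0, _NEG_INF)[:, None, None, :]  # (B,1,1,L)

        p, dk = cfg.n_heads, cfg.d_head
        for layer in self.layers:
            q = layer["Wq"].matmul(h)
            k = layer["Wk"].matmul(h)
            v = layer["Wv"].matmul(h)

            def heads(t: Tensor) -> Tensor:
                return t.reshape(B, L, p, dk).transpose(0, 2, 1, 3)

            qh, kh, vh = heads(q), heads(k), heads(v)
            scores = (qh @ kh.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dk))
            scores = scores + Tensor(np.broadcast_to(
                key_bias, scores.shape).copy())
            attn = softmax(scores, axis=-1)
            ctx = attn @ vh  # (B,p,L,dk)
            ctx = ctx.transpose(0, 2, 1, 3).reshape(B, L, p * dk)
            h = layer["Wo"].matmul(ctx)
            h = layer["W1"].matmul(h) + layer["b1"]
            h = h.relu()
            h = layer["W2"].matmul(h) + layer["b2"]
        return h


def transformer_encode(tokens, state: Transformer,
                       mask: np.ndarray | None = None) -> np.ndarray:
    """Functional forward pass returning (L, d) or (B, L, d) arrays."""
    tokens = np.asarray(tokens)
    out = state.forward(tokens, mask).data
    return out[0] if tokens.ndim == 1 else out


# ---------------------------------------------------------------------------
# Masked-language-model objective
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MLMBatch:
    tokens: np.ndarray            # (L,) ints, with masked slots replaced
    masked_positions: np.ndarray  # indices into tokens
    original_tokens: np.ndarray   # true ids at the masked positions

    def __post_init__(self) -> None:
        self.tokens = np.asarray(self.tokens)
        self.masked_positions = np.asarray(self.masked_positions, dtype=int)
        self.original_tokens = np.asarray(self.original_tokens, dtype=int)
        if self.masked_positions.size and (
                self.masked_positions.min() < 0
                or self.masked_positions.max() >= len(self.tokens)):
            raise ValueError("masked position out of bounds")


def mlm_loss(predicted, batch: MLMBatch, reduction: str = "sum"):
    """Negative log-likelihood of the true tokens at masked positions.

    ``predicted`` is an (L, V) array (or Tensor) of normalized
    distributions. Default reduction is the printed sum; ``"mean"``
    divides by ``|masked|``.
    """
    if batch.masked_positions.size == 0:
        raise ValueError("masked position set is empty")
    pred = astensor(predicted)
    picked = pred[(batch.masked_positions, batch.original_tokens)]
    loss = -(picked.log().sum())
    if reduction == "mean":
        loss = loss * (1.0 / batch.masked_positions.size)
    elif reduction != "sum":
        raise ValueError("reduction must be 'sum' or 'mean'")
    return loss.data.item() if not isinstance(predicted, Tensor) else loss


def make_mlm_batch(tokens: np.ndarray, mask_fraction: float,
                   mask_token_id: int, rng: np.random.Generator) -> MLMBatch:
    """Mask a random nonempty subset of positions for MLM training."""
    tokens = np.asarray(tokens)
    n_mask = max(1, int(round(mask_fraction * len(tokens))))
    positions = rng.choice(len(tokens), size=n_mask, replace=False)
    corrupted = tokens.copy()
    originals = tokens[positions].copy()
    corrupted[positions] = mask_token_id
    return MLMBatch(tokens=corrupted, masked_positions=positions,
                    original_tokens=originals)
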