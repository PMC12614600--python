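"""Pooling and projection heads mapping encoder outputs onto the unit sphere.

The 1D convolution implements ``y[t, j] = sum_i sum_k w[j, i, k] *
x[t + k, i]`` over valid positions only (cross-correlation; an input of
length L and kernel K yields L - K + 1 positions). The masked variant
multiplies the input by a binary mask first and reduces to the plain
convolution when the mask is all ones. The attention pooler scores each
position with a masked convolution, softmaxes over valid positions only
(invalid positions get exactly zero weight) and returns the weighted sum
of features.

Every function accepts plain arrays or autodiff tensors and returns the
matching type, so the same code path serves inference and training.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .autodiff import Tensor, astensor, concat

_NEG_INF = -1e30


def _wrap(x) -> tuple[Tensor, bool]:
    if isinstance(x, Tensor):
        return x, True
    return Tensor(np.asarray(x, dtype=np.float64)), False


def _unwrap(t: Tensor, keep: bool):
    return t if keep else t.data


# ---------------------------------------------------------------------------
# Convolutions
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ConvParams:
    """Filter tensor of shape (C_out, C_in, K)."""

    weight: Tensor

    def __init__(self, weight):
        w = weight if isinstance(weight, Tensor) else Tensor(
            np.asarray(weight, dtype=np.float64))
        if w.ndim != 3:
            raise ValueError("filter must have shape (C_out, C_in, K)")
        self.weight = w

    @property
    def kernel_size(self) -> int:
        return self.weight.shape[2]


def _as_conv_params(params) -> ConvParams:
    if isinstance(params, ConvParams):
        return params
    return ConvParams(params)


def conv1d(x, params):
    """Valid cross-correlation of (L, C_in) input with (C_out, C_in, K) filter."""
    params = _as_conv_params(params)
    xt, keep = _wrap(x)
    if xt.ndim == 1:
        xt = xt.reshape(-1, 1)
    L = xt.shape[0]
    K = params.kernel_size
    if L < K:
        raise ValueError(f"input length {L} shorter than kernel {K}")
    w = params.weight
    out = None
    for k in range(K):
        term = xt[slice(k, L - K + 1 + k)] @ w[(slice(None), slice(None), k)].T
        out = term if out is None else out + term
    return _unwrap(out, keep)


def masked_conv1d(x, mask, params):
    """Conv1d of the mask-zeroed input; mask must be binary, length L."""
    xt, keep = _wrap(x)
    if xt.ndim == 1:
        xt = xt.reshape(-1, 1)
    mask = np.asarray(mask, dtype=np.float64).reshape(-1)
    if mask.shape[0] != xt.shape[0]:
        raise ValueError("mask length must equal input length")
    if not np.all((mask == 0.0) | (mask == 1.0)):
        raise ValueError("mask must be binary")
    masked = xt * Tensor(mask[:, None])
    out = conv1d(masked, params)
    return _unwrap(astensor(out), keep)


# ---------------------------------------------------------------------------
# Pooling
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AttentionPoolParams:
    """Score head: a masked K=1 convolution producing scalar scores."""

    score: ConvParams

    @classmethod
    def init(cls, d: int, seed: int = 0) -> "AttentionPoolParams":
        rng = np.random.default_rng(seed)
        w = Tensor(rng.normal(scale=1.0 / np.sqrt(d), size=(1, d, 1)),
                   requires_grad=True)
        return cls(score=ConvParams(w))

    def trainable_parameters(self) -> list[Tensor]:
        return [self.score.weight]


def attention1d_pool(features, mask, params: AttentionPoolParams):
    """Score-weighted sum of features over valid positions."""
    ft, keep = _wrap(features)
    mask = np.asarray(mask, dtype=np.float64).reshape(-1)
    if mask.sum() < 1:
        raise ValueError("at least one valid position required")
    scores = astensor(masked_conv1d(ft, mask, params.score))  # (L, 1)
    logits = scores.reshape(-1) + Tensor(np.where(mask > 0, 0.0, _NEG_INF))
    shifted = logits - Tensor(logits.data.max())
    e = shifted.exp()
    weights = e / e.sum()
    out = weights @ ft
    return _unwrap(out, keep)


def mean_pool(features, mask=None):
    """Arithmetic mean over valid positions."""
    ft, keep = _wrap(features)
    if mask is None:
        mask = np.ones(ft.shape[0])
    mask = np.asarray(mask, dtype=np.float64).reshape(-1)
    total = mask.sum()
    if total < 1:
        raise ValueError("at least one valid position required")
    out = (Tensor(mask / total) @ ft)
    return _unwrap(out, keep)


def cls_pool(features):
    """First-position feature vector."""
    ft, keep = _wrap(features)
    if ft.shape[0] < 1:
        raise ValueError("empty feature matrix")
    return _unwrap(ft[0], keep)


# ---------------------------------------------------------------------------
# Projection + normalization
# ---------------------------------------------------------------------------

class ProjectionParams:
    """Linear (vW + b) or one-hidden-layer MLP map into the shared space."""

    def __init__(self, in_dim: int, out_dim: int, kind: str = "linear",
                 hidden: int | None = None, seed: int = 0):
        if kind not in ("linear", "mlp"):
            raise ValueError("kind must be 'linear' or 'mlp'")
        self.kind = kind
        self.out_dim = out_dim
        rng = np.random.default_rng(seed)
        if kind == "linear":
            self.W = Tensor(rng.normal(scale=1.0 / np.sqrt(in_dim),
                                       size=(in_dim, out_dim)),
                            requires_grad=True)
            self.b = Tensor(np.zeros(out_dim), requires_grad=True)
        else:
            h = hidden or out_dim
            self.W1 = Tensor(rng.normal(scale=1.0 / np.sqrt(in_dim),
                                        size=(in_dim, h)), requires_grad=True)
            self.b1 = Tensor(np.zeros(h), requires_grad=True)
            self.W2 = Tensor(rng.normal(scale=1.0 / np.sqrt(h),
                                        size=(h, out_dim)), requires_grad=True)
            self.b2 = Tensor(np.zeros(out_dim), requires_grad=True)

    def trainable_parameters(self) -> list[Tensor]:
        if self.kind == "linear":
            return [self.W, self.b]
        return [self.W1, self.b1, self.W2, self.b2]


def project(v, params: ProjectionParams):
    vt, keep = _wrap(v)
    if params.kind == "linear":
        out = vt @ params.W + params.b
    else:
        out = (vt @ params.W1 + params.b1).relu() @ params.W2 + params.b2
    return _unwrap(out, keep)


def l2_normalize(v, axis: int = -1, eps: float = 0.0):
    """Scale to unit Euclidean norm; zero vectors are an error."""
    vt, keep = _wrap(v)
    sq = (vt * vt).sum(axis=axis, keepdims=True)
    if np.any(sq.data <= eps):
        raise ValueError("cannot normalize a zero vector")
    out = vt * sq ** -0.5
    if vt.ndim == 1:
        out = out.reshape(-1)
    return _unwrap(out, keep)
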