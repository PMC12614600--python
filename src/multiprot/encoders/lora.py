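"""Low-rank adaptation of frozen weight matrices: W' = W + (α/r)·A·B."""

from __future__ import annotations

import numpy as np

from ..autodiff import Tensor, astensor


class LoraAdapter:
    """A frozen base matrix with trainable low-rank factors.

    The effective weight is ``W + (alpha / r) * A @ B``; only ``A`` and
    ``B`` receive gradients, ``W`` is never modified by training.
    """

    def __init__(self, W: np.ndarray, rank: int, alpha: float = 1.0,
                 seed: int | None = None, init_scale: float = 0.01):
        W = np.asarray(W, dtype=np.float64)
        if W.ndim != 2:
            raise ValueError("W must be a matrix")
        n, m = W.shape
        if not 1 <= rank < min(n, m):
            raise ValueError(f"rank must satisfy 1 <= r < min(n, m)={min(n, m)}")
        rng = np.random.default_rng(seed)
        self.W = Tensor(W)  # frozen: requires_grad stays False
        self.A = Tensor(rng.normal(scale=init_scale, size=(n, rank)),
                        requires_grad=True)
        self.B = Tensor(np.zeros((rank, m)), requires_grad=True)
        self.rank = rank
        self.alpha = float(alpha)

    @property
    def scale(self) -> float:
        return self.alpha / self.rank

    def effective_weight(self) -> Tensor:
        return self.W + self.scale * (self.A @ self.B)

    def forward(self, x) -> Tensor:
        """``x @ W + (alpha/r) * x @ A @ B`` (factored evaluation)."""
        x = astensor(x)
        return x @ self.W + self.scale * ((x @ self.A) @ self.B)

    def trainable_parameters(self) -> list[Tensor]:
        return [self.A, self.B]


def lora_forward(adapter: LoraAdapter, x) -> np.ndarray:
    """Functional evaluation returning a plain array."""
    return adapter.forward(x).data
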