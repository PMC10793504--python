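"""Parameter containers and the layers the network is assembled from."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .tensor import Tensor, layer_norm, matmul

__all__ = ["Parameter", "Module", "Linear", "LayerNorm", "trunc_normal_"]


class Parameter(Tensor):
    """A tensor that is updated by the optimiser."""

    def __init__(self, data: np.ndarray):
        super().__init__(np.ascontiguousarray(data, dtype=np.float32), requires_grad=True)


def trunc_normal_(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal draws truncated to two standard deviations (resampled)."""
    x = rng.standard_normal(shape) * std
    bad = np.abs(x) > 2 * std
    while bad.any():
        x[bad] = rng.standard_normal(bad.sum()) * std
        bad = np.abs(x) > 2 * std
    return x.astype(np.float32)


class Module:
    """Minimal container with named-parameter traversal, torch-style."""

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, val in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            yield from _walk(val, full)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)} unexpected={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def _walk(val, prefix: str) -> Iterator[tuple[str, Parameter]]:
    if isinstance(val, Parameter):
        yield prefix, val
    elif isinstance(val, Module):
        yield from val.named_parameters(prefix)
    elif isinstance(val, (list, tuple)):
        for i, item in enumerate(val):
            yield from _walk(item, f"{prefix}.{i}")


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True, *, rng: np.random.Generator):
        self.weight = Parameter(trunc_normal_(rng, (in_features, out_features)))
        if bias:
            self.bias = Parameter(np.zeros(out_features, dtype=np.float32))
        else:
            self.bias = None

    def __call__(self, x: Tensor) -> Tensor:
        y = matmul(x, self.weight)
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.weight = Parameter(np.ones(dim, dtype=np.float32))
        self.bias = Parameter(np.zeros(dim, dtype=np.float32))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.weight, self.bias, self.eps)
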