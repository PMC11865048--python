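"""Minimal reverse-mode neural-network core on numpy.

Every layer is a :class:`Module` with an explicit ``forward``/``backward``
pair; ``forward`` caches whatever the gradient computation needs and
``backward`` consumes the cache, returns the gradient with respect to the
layer input and accumulates gradients on its :class:`Param` objects.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

__all__ = ["Param", "Module", "Sequential"]


class Param:
    """A learnable array together with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Module:
    """Base class: a differentiable operation with named parameters."""

    training: bool = True

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    # -- parameter plumbing -------------------------------------------------
    def named_params(self, prefix: str = "") -> Iterator[tuple[str, Param]]:
        for name, attr in vars(self).items():
            if isinstance(attr, Param):
                yield f"{prefix}{name}", attr
            elif isinstance(attr, Module):
                yield from attr.named_params(f"{prefix}{name}.")
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        yield from item.named_params(f"{prefix}{name}.{i}.")

    def params(self) -> Iterator[Param]:
        for _, p in self.named_params():
            yield p

    def modules(self) -> Iterator["Module"]:
        yield self
        for attr in vars(self).values():
            if isinstance(attr, Module):
                yield from attr.modules()
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        yield from item.modules()

    def param_count(self) -> int:
        return sum(p.size for p in self.params())

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def set_training(self, mode: bool) -> None:
        for m in self.modules():
            m.training = mode

    # -- (de)serialisation --------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.value.copy() for name, p in self.named_params()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_params())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in own.items():
            if p.value.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.value[...] = state[name]


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out
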