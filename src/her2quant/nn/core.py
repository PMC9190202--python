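"""Minimal NumPy module system: parameters, buffers, state dicts.

Every layer caches what its backward pass needs during a ``forward(...,
train=True)`` call; ``backward`` consumes the cache and accumulates gradients
into ``Parameter.grad``. Inference (``train=False``) caches nothing.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from ..errors import ShapeError


class Parameter:
    """A learnable array with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover
        return f"Parameter(shape={self.data.shape}, dtype={self.data.dtype})"


class Module:
    """Base class; subclasses declare children, parameters and buffers.

    ``_params()``   -> list of (name, Parameter)      — learnable
    ``_buffers()``  -> list of attribute names (str)  — persistent, not learnable
    ``_children()`` -> list of (name, Module)
    """

    def _params(self) -> list[tuple[str, Parameter]]:
        return []

    def _buffers(self) -> list[str]:
        return []

    def _children(self) -> list[tuple[str, "Module"]]:
        return []

    # -- traversal -------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params():
            yield prefix + name, p
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, "Module", str]]:
        for attr in self._buffers():
            yield prefix + attr, self, attr
        for cname, child in self._children():
            yield from child.named_buffers(prefix + cname + ".")

    def modules(self) -> Iterator["Module"]:
        yield self
        for _, child in self._children():
            yield from child.modules()

    # -- state -----------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, owner, attr in self.named_buffers():
            state[name] = np.asarray(getattr(owner, attr)).copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        expected = {name for name, _ in self.named_parameters()}
        expected |= {name for name, _, _ in self.named_buffers()}
        missing = expected - set(state)
        extra = set(state) - expected
        if missing or extra:
            raise ShapeError(
                f"state dict mismatch: missing={sorted(missing)} extra={sorted(extra)}"
            )
        for name, p in self.named_parameters():
            arr = np.asarray(state[name])
            if arr.shape != p.data.shape:
                raise ShapeError(f"{name}: shape {arr.shape} != {p.data.shape}")
            p.data = arr.astype(p.data.dtype, copy=True)
            p.grad = np.zeros_like(p.data)
        for name, owner, attr in self.named_buffers():
            cur = np.asarray(getattr(owner, attr))
            arr = np.asarray(state[name])
            if arr.shape != cur.shape:
                raise ShapeError(f"{name}: shape {arr.shape} != {cur.shape}")
            setattr(owner, attr, arr.astype(cur.dtype, copy=True))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def astype(self, dtype) -> "Module":
        """In-place dtype conversion of all parameters and buffers."""
        for _, p in self.named_parameters():
            p.data = p.data.astype(dtype)
            p.grad = p.grad.astype(dtype)
        for _, owner, attr in self.named_buffers():
            setattr(owner, attr, np.asarray(getattr(owner, attr)).astype(dtype))
        return self

    # -- computation ------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train)
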