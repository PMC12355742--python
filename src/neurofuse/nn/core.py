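"""Minimal layer library with explicit reverse-mode gradients.

Every layer caches what its backward pass needs during ``forward`` and
releases the gradient of its input from ``backward``.  Parameters carry a
``frozen`` flag honoured by the optimizers, which is how transfer-learning
regimes freeze whole parameter groups.  All arrays are float64 and all
initialization is driven by an explicit ``numpy.random.Generator``, so two
builds from the same seed are bit-identical.
"""

from __future__ import annotations

import numpy as np


class Parameter:
    """A learnable array with an accumulated gradient and a freeze flag."""

    __slots__ = ("data", "grad", "frozen")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)
        self.frozen = False

    @property
    def size(self) -> int:
        return self.data.size


class Module:
    """Base class: tracks named parameters and child modules recursively."""

    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._children: dict[str, Module] = {}

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield (prefix + name if not prefix else f"{prefix}.{name}"), p
        for cname, child in self._children.items():
            sub = cname if not prefix else f"{prefix}.{cname}"
            yield from child.named_parameters(sub)

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    def freeze(self, frozen: bool = True):
        for p in self.parameters():
            p.frozen = frozen
        return self

    def forward(self, x, train: bool = False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x, train: bool = False):
        return self.forward(x, train=train)


def state_arrays(module: Module, prefix: str = "") -> dict[str, np.ndarray]:
    """All persistent arrays (parameters + running statistics) by name."""
    out = {}
    for name, p in module.named_parameters():
        out[name] = p.data
    for name, buf in _named_buffers(module, prefix):
        out[name] = buf
    return out


def _named_buffers(module: Module, prefix: str = ""):
    for attr in ("running_mean", "running_var"):
        buf = getattr(module, attr, None)
        if isinstance(buf, np.ndarray):
            yield (attr if not prefix else f"{prefix}.{attr}"), buf
    for cname, child in module._children.items():
        sub = cname if not prefix else f"{prefix}.{cname}"
        yield from _named_buffers(child, sub)


def load_state(module: Module, state: dict[str, np.ndarray]):
    own = {name: p for name, p in module.named_parameters()}
    for name, arr in state.items():
        if name in own:
            own[name].data[...] = arr
    for name, buf in _named_buffers(module):
        if name in state:
            buf[...] = state[name]


def parameter_hash(module: Module) -> str:
    """Deterministic digest of all parameter values (order-stable)."""
    import hashlib

    h = hashlib.sha256()
    for name, p in sorted(module.named_parameters()):
        h.update(name.encode())
        h.update(np.ascontiguousarray(p.data).tobytes())
    return h.hexdigest()
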