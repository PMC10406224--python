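"""Module tree with dotted parameter names, plus checkpoint containers."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

from .layers import Layer

__all__ = ["Module", "Sequential", "Checkpoint"]


class Module:
    """A tree of :class:`Layer` leaves addressable by dotted names.

    Sub-modules and layers are discovered from instance attributes (and
    lists of them), in attribute insertion order, which makes parameter
    naming deterministic for a given architecture.
    """

    def _children(self) -> Iterator[tuple[str, object]]:
        for name, val in vars(self).items():
            if isinstance(val, (Layer, Module)):
                yield name, val
            elif isinstance(val, list) and val and all(
                isinstance(v, (Layer, Module)) for v in val
            ):
                for i, v in enumerate(val):
                    yield f"{name}.{i}", v

    def named_layers(self, prefix: str = "") -> Iterator[tuple[str, Layer]]:
        for name, child in self._children():
            full = f"{prefix}{name}"
            if isinstance(child, Layer):
                yield full, child
            else:
                yield from child.named_layers(prefix=full + ".")

    def named_parameters(self) -> dict[str, np.ndarray]:
        return {
            f"{lname}.{pname}": arr
            for lname, layer in self.named_layers()
            for pname, arr in layer.params.items()
        }

    def named_gradients(self) -> dict[str, np.ndarray]:
        return {
            f"{lname}.{pname}": arr
            for lname, layer in self.named_layers()
            for pname, arr in layer.grads.items()
        }

    def named_buffers(self) -> dict[str, np.ndarray]:
        """Non-trainable state (batch-norm running statistics)."""
        out = {}
        for lname, layer in self.named_layers():
            for bname in ("running_mean", "running_var"):
                if hasattr(layer, bname):
                    out[f"{lname}.{bname}"] = getattr(layer, bname)
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {**self.named_parameters(), **self.named_buffers()}

    def load_state_dict(self, state: dict[str, np.ndarray], strict: bool = True) -> None:
        own_params = {
            f"{lname}.{pname}": (layer, pname)
            for lname, layer in self.named_layers()
            for pname in layer.params
        }
        own_buffers = {
            f"{lname}.{bname}": (layer, bname)
            for lname, layer in self.named_layers()
            for bname in ("running_mean", "running_var")
            if hasattr(layer, bname)
        }
        for key, arr in state.items():
            if key in own_params:
                layer, pname = own_params[key]
                if layer.params[pname].shape != arr.shape:
                    raise ValueError(
                        f"shape mismatch for '{key}': "
                        f"{layer.params[pname].shape} vs {arr.shape}"
                    )
                layer.params[pname] = arr.astype(np.float32).copy()
            elif key in own_buffers:
                layer, bname = own_buffers[key]
                setattr(layer, bname, arr.astype(np.float32).copy())
            elif strict:
                raise KeyError(f"unknown tensor '{key}'")

    def n_parameters(self) -> int:
        return sum(int(np.prod(a.shape)) for a in self.named_parameters().values())

    def zero_grad(self) -> None:
        for _, layer in self.named_layers():
            layer.grads = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.forward(x, training=training)


class Sequential(Module):
    def __init__(self, *steps: Layer | Module):
        self.steps = list(steps)

    def forward(self, x, training=False):
        for step in self.steps:
            x = step(x, training=training)
        return x

    def backward(self, dout):
        for step in reversed(self.steps):
            dout = step.backward(dout)
        return dout


def recalibrate_batchnorm(module: Module, batches, forward=None) -> None:
    """Replace batch-norm running statistics with precise dataset statistics.

    With short training schedules the momentum-averaged running statistics
    lag the final weights, which skews evaluation-mode predictions.  This
    runs forward passes in training mode over ``batches`` (an iterable of
    network inputs), collects each batch-norm layer's per-batch moments, and
    sets the running statistics to their averages ("precise BN").
    """
    fwd = forward if forward is not None else (lambda x: module(x, training=True))
    sums: dict[str, list] = {}
    bn_layers = {
        name: layer for name, layer in module.named_layers() if hasattr(layer, "running_mean")
    }
    n = 0
    for x in batches:
        fwd(x)
        for name, layer in bn_layers.items():
            if hasattr(layer, "last_batch_mean"):
                m, v = sums.setdefault(name, [0.0, 0.0])
                sums[name] = [m + layer.last_batch_mean, v + layer.last_batch_var]
        n += 1
    if n == 0:
        return
    for name, layer in bn_layers.items():
        if name in sums:
            layer.running_mean = (sums[name][0] / n).astype(np.float32)
            layer.running_var = (sums[name][1] / n).astype(np.float32)


@dataclass
class Checkpoint:
    """Named tensors plus metadata; round-trips bitwise through .npz + .json."""

    state: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path.with_suffix(".npz"), **self.state)
        path.with_suffix(".json").write_text(json.dumps(self.meta, indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        path = Path(path)
        with np.load(path.with_suffix(".npz")) as npz:
            state = {k: npz[k].copy() for k in npz.files}
        meta_path = path.with_suffix(".json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(state=state, meta=meta)
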