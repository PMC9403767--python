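"""A small static computation graph over :mod:`hepaseg.nn.layers`.

Networks are directed acyclic graphs of named nodes added in topological
order.  Each node has a *scope* (dot-separated sub-network name used for
freezing and parameter accounting, e.g. ``"2d.encoder"``) and an optional
*scale* (spatial downsampling factor, used to describe dense connectivity).
"""

from __future__ import annotations

import dataclasses
import hashlib
from typing import Iterable

import numpy as np

from .layers import Layer, Param


@dataclasses.dataclass
class Node:
    name: str
    layer: Layer
    inputs: list[str]
    scope: str = ""
    scale: int | None = None


class Network:
    """Ordered DAG of layers with forward/backward, freezing and (de)serialization."""

    def __init__(self):
        self.nodes: dict[str, Node] = {}
        self.order: list[str] = []
        self.feeds: set[str] = set()

    # ------------------------------------------------------------- building
    def feed(self, name: str) -> str:
        self.feeds.add(name)
        return name

    def add(self, name: str, layer: Layer, inputs: str | Iterable[str],
            scope: str = "", scale: int | None = None) -> str:
        if name in self.nodes or name in self.feeds:
            raise ValueError(f"duplicate node name {name!r}")
        if isinstance(inputs, str):
            inputs = [inputs]
        inputs = list(inputs)
        for i in inputs:
            if i not in self.nodes and i not in self.feeds:
                raise ValueError(f"node {name!r} references unknown input {i!r}")
        self.nodes[name] = Node(name, layer, inputs, scope, scale)
        self.order.append(name)
        return name

    # ------------------------------------------------------------- running
    def forward(self, feeds: dict[str, np.ndarray], outputs: Iterable[str],
                training: bool = False) -> dict[str, np.ndarray]:
        cache: dict[str, np.ndarray] = dict(feeds)
        wanted = set(outputs)
        needed = self._needed(wanted)
        for name in self.order:
            if name not in needed:
                continue
            node = self.nodes[name]
            xs = [cache[i] for i in node.inputs]
            cache[name] = node.layer.forward(*xs, training=training)
        self._last_needed = needed
        return {k: cache[k] for k in wanted}

    def _needed(self, wanted: set[str]) -> set[str]:
        needed = set(wanted)
        for name in reversed(self.order):
            if name in needed:
                needed.update(self.nodes[name].inputs)
        return needed

    def backward(self, grads: dict[str, np.ndarray]) -> None:
        """Backpropagate from output gradients; accumulates into Param.grad."""
        acc: dict[str, np.ndarray] = dict(grads)
        for name in reversed(self.order):
            if name not in acc or name not in self._last_needed:
                continue
            node = self.nodes[name]
            gxs = node.layer.backward(acc.pop(name))
            for inp, gx in zip(node.inputs, gxs):
                if inp in self.feeds:
                    continue
                if inp in acc:
                    acc[inp] = acc[inp] + gx
                else:
                    acc[inp] = gx

    # ---------------------------------------------------------- parameters
    def parameters(self) -> list[Param]:
        out = []
        for name in self.order:
            out.extend(self.nodes[name].layer.params())
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def scopes(self) -> set[str]:
        return {n.scope for n in self.nodes.values() if n.scope}

    def set_frozen(self, scopes: Iterable[str]) -> None:
        """Freeze every parameter whose node scope equals or sits under a given scope."""
        scopes = list(scopes)
        known = self.scopes()
        for s in scopes:
            if not any(k == s or k.startswith(s + ".") for k in known):
                from ..errors import ConfigError
                raise ConfigError(f"unknown freeze scope {s!r}; scopes are {sorted(known)}")
        for node in self.nodes.values():
            frozen = any(node.scope == s or node.scope.startswith(s + ".") for s in scopes)
            for p in node.layer.params():
                p.frozen = frozen

    def count_parameters(self) -> tuple[int, int, int]:
        """(total, trainable, non_trainable); BN running stats and frozen weights are non-trainable."""
        tr = nt = 0
        for node in self.nodes.values():
            t, n = node.layer.param_counts()
            tr += t
            nt += n
        return tr + nt, tr, nt

    # -------------------------------------------------------------- state
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for name in self.order:
            for p in self.nodes[name].layer.params():
                state[f"{name}:{p.name}"] = p.value.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name in self.order:
            for p in self.nodes[name].layer.params():
                key = f"{name}:{p.name}"
                if key not in state:
                    raise KeyError(f"missing weight {key}")
                p.value = np.array(state[key], dtype=np.float32)

    def scope_digest(self, scope: str) -> str:
        """SHA-256 over all weights (running stats included) in a scope subtree."""
        h = hashlib.sha256()
        for name in self.order:
            node = self.nodes[name]
            if node.scope == scope or node.scope.startswith(scope + "."):
                for p in node.layer.params():
                    h.update(p.name.encode())
                    h.update(np.ascontiguousarray(p.value).tobytes())
        return h.hexdigest()

    # ---------------------------------------------------------- description
    def describe(self) -> list[dict]:
        records = []
        for name in self.order:
            node = self.nodes[name]
            layer = node.layer
            tr, nt = layer.param_counts()
            records.append({
                "name": name,
                "kind": layer.kind,
                "kernel": getattr(layer, "kernel", None),
                "in_channels": getattr(layer, "cin", None),
                "out_channels": getattr(layer, "cout", None),
                "params_trainable": tr,
                "params_non_trainable": nt,
                "scope": node.scope,
                "scale": node.scale,
                "inputs": list(node.inputs),
            })
        return records
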