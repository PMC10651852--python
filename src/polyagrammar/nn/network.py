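"""Network containers, the training loop, and weight (de)serialization."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .layers import Dense, Layer, sigmoid
from .losses import binary_cross_entropy, kl_divergence, mean_squared_error

F32 = np.float32


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class _BaseNet:
    """Shared plumbing: parameter flattening, batched inference, save/load."""

    trunk: Sequential
    config: dict

    def _param_layers(self) -> list[Layer]:
        raise NotImplementedError

    def parameters(self) -> list[np.ndarray]:
        out = []
        for layer in self._param_layers():
            for name in sorted(layer.params):
                out.append(layer.params[name])
        return out

    def gradients(self) -> list[np.ndarray]:
        out = []
        for layer in self._param_layers():
            for name in sorted(layer.params):
                out.append(layer.grads[name])
        return out

    def set_parameters(self, values: list[np.ndarray]) -> None:
        for current, new in zip(self.parameters(), values):
            current[...] = new

    def get_parameters(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    @staticmethod
    def _as_nlc(x: np.ndarray) -> np.ndarray:
        """Accept (N, 4, 240) one-hot batches; convert to (N, 240, 4)."""
        x = np.asarray(x, dtype=F32)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1] == 4 and x.shape[2] != 4:
            x = x.transpose(0, 2, 1)
        return np.ascontiguousarray(x)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"p{i}": p for i, p in enumerate(self.parameters())}
        np.savez(path, config=json.dumps(self.config), **arrays)

    @classmethod
    def load(cls, path: str | Path):
        from ..nnmodels import ModelConfig, build_polyaid, build_polyastrength

        with np.load(Path(path) if str(path).endswith(".npz") else f"{path}", allow_pickle=False) as data:
            config = json.loads(str(data["config"]))
            kind = config.pop("kind")
            model = (build_polyaid if kind == "polyaid" else build_polyastrength)(
                ModelConfig(**config))
            values = [data[f"p{i}"] for i in range(len(model.parameters()))]
        model.set_parameters(values)
        return model


class DualHeadNet(_BaseNet):
    """Shared conv+BiLSTM trunk with a sigmoid classification head and a
    softmax (simplex) cleavage head of length 50."""

    def __init__(self, trunk: Sequential, head_class: Dense, head_cleavage: Dense,
                 config: dict):
        self.trunk = trunk
        self.head_class = head_class
        self.head_cleavage = head_cleavage
        self.config = config

    def _param_layers(self) -> list[Layer]:
        return [*self.trunk.layers, self.head_class, self.head_cleavage]

    def _forward(self, x: np.ndarray, train: bool = False):
        feats = self.trunk.forward(x, train=train)
        p = sigmoid(self.head_class.forward(feats)).ravel()
        q = softmax(self.head_cleavage.forward(feats))
        return p, q

    def predict(self, x: np.ndarray, batch_size: int = 1024):
        """Return (p_class, cleavage) for a batch of one-hot windows."""
        x = self._as_nlc(x)
        ps, qs = [], []
        for start in range(0, len(x), batch_size):
            p, q = self._forward(x[start:start + batch_size])
            ps.append(p)
            qs.append(q)
        return np.concatenate(ps), np.concatenate(qs)

    def train_batch(self, x, y, cleavage, optimizer) -> float:
        x = self._as_nlc(x)
        n = len(x)
        p, q = self._forward(x, train=True)
        loss = binary_cross_entropy(y, p) + kl_divergence(cleavage, q)
        # gradients w.r.t. the pre-activation logits of each head
        dz_cls = ((p - y) / n).astype(F32)[:, None]
        dz_clv = ((q - cleavage) / n).astype(F32)
        dfeat = self.head_class.backward(dz_cls) + self.head_cleavage.backward(dz_clv)
        self.trunk.backward(dfeat)
        optimizer.step(self.gradients())
        return loss

    def evaluate(self, x, y, cleavage, batch_size: int = 1024) -> float:
        p, q = self.predict(x, batch_size=batch_size)
        return binary_cross_entropy(y, p) + kl_divergence(cleavage, q)


class RegressionNet(_BaseNet):
    """Conv+BiLSTM trunk with a single linear output (site-strength score)."""

    def __init__(self, trunk: Sequential, head: Dense, config: dict):
        self.trunk = trunk
        self.head = head
        self.config = config

    def _param_layers(self) -> list[Layer]:
        return [*self.trunk.layers, self.head]

    def predict(self, x: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        x = self._as_nlc(x)
        outs = []
        for start in range(0, len(x), batch_size):
            feats = self.trunk.forward(x[start:start + batch_size])
            outs.append(self.head.forward(feats).ravel())
        return np.concatenate(outs)

    def train_batch(self, x, target, optimizer) -> float:
        x = self._as_nlc(x)
        n = len(x)
        feats = self.trunk.forward(x, train=True)
        v = self.head.forward(feats).ravel()
        loss = mean_squared_error(target, v)
        dz = (2.0 * (v - target) / n).astype(F32)[:, None]
        self.trunk.backward(self.head.backward(dz))
        optimizer.step(self.gradients())
        return loss

    def evaluate(self, x, target, batch_size: int = 1024) -> float:
        return mean_squared_error(target, self.predict(x, batch_size=batch_size))
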