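"""A small fully connected regression network implemented on numpy.

Voxel-wise density/RSP regression needs only a tabular k-input multilayer
perceptron, so the network is implemented directly: hidden blocks of
``linear -> layer normalization -> ReLU`` (nine blocks of 80 nodes by
default), a linear output head, mean-squared-error loss, and mini-batch Adam.
Training is fully deterministic given the seed: weight initialization (a
uniform fan-in scheme), batch shuffling and the optimizer state all flow
from one ``numpy.random.Generator``.

The default configuration trains for ``max_epochs`` while snapshotting the
parameters at ``epochs_used``; predictions use the snapshot, which guards
against late-epoch overfitting without early stopping.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

__all__ = ["FCNNConfig", "FCNN"]


@dataclass(frozen=True)
class FCNNConfig:
    """Hyperparameters of the voxel-wise regressor."""

    hidden_layers: int = 9
    width: int = 80
    learning_rate: float = 1e-3
    batch_size: int = 1000
    max_epochs: int = 500
    epochs_used: int = 300
    layer_norm: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_layers < 1:
            raise ValueError("hidden_layers must be >= 1")
        if self.width < 1:
            raise ValueError("width must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs_used > self.max_epochs:
            raise ValueError(
                f"epochs_used ({self.epochs_used}) exceeds max_epochs ({self.max_epochs})"
            )


_EPS = 1e-5  # layer-norm variance floor


class FCNN:
    """Fully connected voxel-wise regressor with layer normalization.

    Parameters
    ----------
    n_inputs : int
        Number of input channels k.
    n_outputs : int
        Number of regression targets (1 for separate density / RSP models,
        2 for the joint variant).
    config : FCNNConfig
    """

    def __init__(self, n_inputs: int, n_outputs: int = 1, config: FCNNConfig | None = None):
        self.config = config or FCNNConfig()
        self.n_inputs = int(n_inputs)
        self.n_outputs = int(n_outputs)
        rng = np.random.default_rng(self.config.seed)
        dims = [self.n_inputs] + [self.config.width] * self.config.hidden_layers + [self.n_outputs]
        self.W, self.b, self.g, self.beta = [], [], [], []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            bound = 1.0 / np.sqrt(fan_in)
            self.W.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
            self.b.append(rng.uniform(-bound, bound, size=fan_out))
        for _ in range(self.config.hidden_layers):
            self.g.append(np.ones(self.config.width))
            self.beta.append(np.zeros(self.config.width))
        self._rng = rng
        self._snapshot = None
        self.history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}

    # ---- forward / backward -------------------------------------------------

    def _forward(self, X: np.ndarray, cache: list | None = None):
        a = X
        for layer in range(self.config.hidden_layers):
            h = a @ self.W[layer] + self.b[layer]
            if self.config.layer_norm:
                mu = h.mean(axis=1, keepdims=True)
                xc = h - mu
                var = (xc**2).mean(axis=1, keepdims=True)
                inv = 1.0 / np.sqrt(var + _EPS)
                xhat = xc * inv
                z = xhat * self.g[layer] + self.beta[layer]
            else:
                xhat = inv = None
                z = h
            out = np.maximum(z, 0.0)
            if cache is not None:
                cache.append((a, xhat, inv, z, out))
            a = out
        y = a @ self.W[-1] + self.b[-1]
        if cache is not None:
            cache.append((a, y))
        return y

    def _backward(self, cache, dy, grads_W, grads_b, grads_g, grads_beta):
        a_last, _ = cache[-1]
        grads_W[-1] += a_last.T @ dy
        grads_b[-1] += dy.sum(axis=0)
        da = dy @ self.W[-1].T
        for layer in range(self.config.hidden_layers - 1, -1, -1):
            a, xhat, inv, z, _ = cache[layer]
            dz = da * (z > 0.0)
            if self.config.layer_norm:
                grads_g[layer] += (dz * xhat).sum(axis=0)
                grads_beta[layer] += dz.sum(axis=0)
                dxhat = dz * self.g[layer]
                # standard layer-norm backward over the feature axis
                m = xhat.shape[1]
                dh = (
                    dxhat
                    - dxhat.mean(axis=1, keepdims=True)
                    - xhat * (dxhat * xhat).mean(axis=1, keepdims=True)
                ) * inv
                del m
            else:
                dh = dz
            grads_W[layer] += a.T @ dh
            grads_b[layer] += dh.sum(axis=0)
            if layer > 0:
                da = dh @ self.W[layer].T
        return None

    # ---- training -----------------------------------------------------------

    def _params(self):
        return self.W + self.b + self.g + self.beta

    def loss(self, X: np.ndarray, y: np.ndarray) -> float:
        pred = self._forward(np.asarray(X, dtype=np.float64))
        return float(np.mean((pred - y.reshape(pred.shape)) ** 2))

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
        epochs: int | None = None,
    ) -> dict[str, list[float]]:
        """Mini-batch Adam on the MSE loss; returns the loss history.

        The validation set is used for monitoring only — it never influences
        the parameter updates or the stopping point.
        """
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).reshape(len(X), self.n_outputs)
        if X.shape[1] != self.n_inputs:
            raise ValueError(f"expected {self.n_inputs} input channels, got {X.shape[1]}")
        if len(X) == 0:
            raise ValueError("empty training set")
        n_epochs = epochs if epochs is not None else self.config.max_epochs
        params = self._params()
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        lr = self.config.learning_rate
        step = 0
        for epoch in range(1, n_epochs + 1):
            order = self._rng.permutation(len(X))
            epoch_loss = 0.0
            for start in range(0, len(X), self.config.batch_size):
                idx = order[start : start + self.config.batch_size]
                xb, yb = X[idx], y[idx]
                cache: list = []
                pred = self._forward(xb, cache)
                err = pred - yb
                batch_loss = float(np.mean(err**2))
                if not np.isfinite(batch_loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch} "
                        f"(lr={lr}, batch={self.config.batch_size})"
                    )
                epoch_loss += batch_loss * len(xb)
                dy = 2.0 * err / err.size
                gW = [np.zeros_like(w) for w in self.W]
                gb = [np.zeros_like(bb) for bb in self.b]
                gg = [np.zeros_like(gg_) for gg_ in self.g]
                gbeta = [np.zeros_like(bb) for bb in self.beta]
                self._backward(cache, dy, gW, gb, gg, gbeta)
                grads = gW + gb + gg + gbeta
                step += 1
                c1 = 1.0 - beta1**step
                c2 = 1.0 - beta2**step
                for p, gr, mi, vi in zip(params, grads, m, v):
                    mi *= beta1
                    mi += (1 - beta1) * gr
                    vi *= beta2
                    vi += (1 - beta2) * gr**2
                    p -= lr * (mi / c1) / (np.sqrt(vi / c2) + eps)
            self.history["train_loss"].append(epoch_loss / len(X))
            if X_val is not None and len(X_val):
                self.history["val_loss"].append(self.loss(X_val, y_val))
            if epoch == min(self.config.epochs_used, n_epochs):
                self._snapshot = [p.copy() for p in params]
        if self._snapshot is None:
            self._snapshot = [p.copy() for p in params]
        return self.history

    # ---- inference & persistence -------------------------------------------

    def _with_snapshot(self):
        nh = self.config.hidden_layers
        W = self._snapshot[: nh + 1]
        b = self._snapshot[nh + 1 : 2 * (nh + 1)]
        g = self._snapshot[2 * (nh + 1) : 2 * (nh + 1) + nh]
        beta = self._snapshot[2 * (nh + 1) + nh :]
        return W, b, g, beta

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict with the ``epochs_used`` parameter snapshot."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_inputs:
            raise ValueError(
                f"expected an (N, {self.n_inputs}) channel matrix, got shape {X.shape}"
            )
        if self._snapshot is None:
            raise RuntimeError("model has not been trained")
        live = self.W, self.b, self.g, self.beta
        self.W, self.b, self.g, self.beta = self._with_snapshot()
        try:
            out = self._forward(X)
        finally:
            self.W, self.b, self.g, self.beta = live
        return out[:, 0] if self.n_outputs == 1 else out

    def save(self, path: str | Path) -> None:
        """Serialize snapshot weights (npz) plus a JSON config sidecar."""
        path = Path(path)
        W, b, g, beta = self._with_snapshot()
        arrays = {}
        for i, w in enumerate(W):
            arrays[f"W{i}"] = w
        for i, bb in enumerate(b):
            arrays[f"b{i}"] = bb
        for i, gg in enumerate(g):
            arrays[f"g{i}"] = gg
        for i, bb in enumerate(beta):
            arrays[f"beta{i}"] = bb
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {
            "n_inputs": self.n_inputs,
            "n_outputs": self.n_outputs,
            "config": asdict(self.config),
            "history": self.history,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "FCNN":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(meta["n_inputs"], meta["n_outputs"], FCNNConfig(**meta["config"]))
        data = np.load(path.with_suffix(".npz"))
        nh = model.config.hidden_layers
        model.W = [data[f"W{i}"] for i in range(nh + 1)]
        model.b = [data[f"b{i}"] for i in range(nh + 1)]
        model.g = [data[f"g{i}"] for i in range(nh)]
        model.beta = [data[f"beta{i}"] for i in range(nh)]
        model._snapshot = model._params()
        model.history = meta["history"]
        return model
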