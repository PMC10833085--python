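"""Multi-task feed-forward network with residual blocks (pure numpy).

Architecture: input block (affine → batch normalization → ReLU), a stack of
residual blocks (affine → batchnorm → ReLU → dropout, identity skip), an
embedding block (affine), and two single-layer task heads reading the shared
embedding: class logits and protein predictions.

Forward and backward passes are implemented by hand so that per-task
gradients with respect to the shared embedding weights — needed by the
gradient-balancing objective — are available exactly, without an autodiff
dependency.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


class ConfigError(ValueError):
    pass


@dataclasses.dataclass
class NetworkConfig:
    input_dim: int
    n_classes: int
    n_proteins: int
    hidden_dim: int = 512
    n_resnet_blocks: int = 4
    embedding_dim: int = 128
    dropout_rate: float = 0.1
    activation: str = "relu"
    seed: int = 0

    def validate(self) -> None:
        bad = []
        for f in ("input_dim", "n_classes", "n_proteins", "hidden_dim", "embedding_dim"):
            if getattr(self, f) < 1:
                bad.append(f)
        if self.n_resnet_blocks < 0:
            bad.append("n_resnet_blocks")
        if not (0.0 <= self.dropout_rate < 1.0):
            bad.append("dropout_rate")
        if self.activation != "relu":
            bad.append("activation")
        if bad:
            raise ConfigError(f"invalid network config fields: {bad}")


def _init_linear(rng, fan_in, fan_out):
    w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
    return w, np.zeros(fan_out)


class MultiTaskModel:
    """Parameters + forward/backward for the shared-trunk two-head network."""

    def __init__(self, config: NetworkConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config
        p = {}
        p["in.W"], p["in.b"] = _init_linear(rng, c.input_dim, c.hidden_dim)
        p["in.gamma"], p["in.beta"] = np.ones(c.hidden_dim), np.zeros(c.hidden_dim)
        for i in range(c.n_resnet_blocks):
            p[f"res{i}.W"], p[f"res{i}.b"] = _init_linear(rng, c.hidden_dim, c.hidden_dim)
            p[f"res{i}.gamma"], p[f"res{i}.beta"] = np.ones(c.hidden_dim), np.zeros(c.hidden_dim)
        p["emb.W"], p["emb.b"] = _init_linear(rng, c.hidden_dim, c.embedding_dim)
        p["type.W"], p["type.b"] = _init_linear(rng, c.embedding_dim, c.n_classes)
        p["prot.W"], p["prot.b"] = _init_linear(rng, c.embedding_dim, c.n_proteins)
        self.params = p
        # batchnorm running statistics (not trainable)
        self.running = {}
        for name in ["in"] + [f"res{i}" for i in range(c.n_resnet_blocks)]:
            self.running[f"{name}.mean"] = np.zeros(c.hidden_dim)
            self.running[f"{name}.var"] = np.ones(c.hidden_dim)
        self._dropout_rng = np.random.default_rng(config.seed + 1)
        self._cache = None

    # -- building blocks ----------------------------------------------------

    def _bn_forward(self, name, z, train):
        g, b = self.params[f"{name}.gamma"], self.params[f"{name}.beta"]
        if train:
            mu = z.mean(axis=0)
            var = z.var(axis=0)
            self.running[f"{name}.mean"] = (
                (1 - _BN_MOMENTUM) * self.running[f"{name}.mean"] + _BN_MOMENTUM * mu
            )
            n = z.shape[0]
            unbiased = var * n / max(n - 1, 1)
            self.running[f"{name}.var"] = (
                (1 - _BN_MOMENTUM) * self.running[f"{name}.var"] + _BN_MOMENTUM * unbiased
            )
        else:
            mu = self.running[f"{name}.mean"]
            var = self.running[f"{name}.var"]
        inv = 1.0 / np.sqrt(var + _BN_EPS)
        zhat = (z - mu) * inv
        cache = (zhat, inv, train)
        return g * zhat + b, cache

    def _bn_backward(self, name, grad, cache, grads):
        zhat, inv, train = cache
        g = self.params[f"{name}.gamma"]
        grads[f"{name}.gamma"] = (grad * zhat).sum(axis=0)
        grads[f"{name}.beta"] = grad.sum(axis=0)
        gz = grad * g
        if not train:
            return gz * inv
        n = zhat.shape[0]
        return (inv / n) * (n * gz - gz.sum(axis=0) - zhat * (gz * zhat).sum(axis=0))

    # -- forward ------------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False):
        """Return ``(embedding, type_logits, protein_pred)``.

        In eval mode the pass is deterministic (no dropout, running batchnorm
        statistics).  In train mode intermediate activations are cached for
        :meth:`backward`.
        """
        x = np.asarray(x, dtype=float)
        if x.shape[1] != self.config.input_dim:
            raise ValueError(
                f"feature width {x.shape[1]} != input_dim {self.config.input_dim}"
            )
        cache = {"x": x, "train": train}

        z = x @ self.params["in.W"] + self.params["in.b"]
        h, cache["in.bn"] = self._bn_forward("in", z, train)
        cache["in.pre_relu"] = h
        h = np.maximum(h, 0.0)

        for i in range(self.config.n_resnet_blocks):
            name = f"res{i}"
            cache[f"{name}.x"] = h
            z = h @ self.params[f"{name}.W"] + self.params[f"{name}.b"]
            a, cache[f"{name}.bn"] = self._bn_forward(name, z, train)
            cache[f"{name}.pre_relu"] = a
            a = np.maximum(a, 0.0)
            if train and self.config.dropout_rate > 0:
                keep = 1.0 - self.config.dropout_rate
                mask = (self._dropout_rng.random(a.shape) < keep) / keep
                cache[f"{name}.drop"] = mask
                a = a * mask
            h = h + a

        cache["emb.x"] = h
        emb = h @ self.params["emb.W"] + self.params["emb.b"]
        cache["emb"] = emb
        logits = emb @ self.params["type.W"] + self.params["type.b"]
        prot = emb @ self.params["prot.W"] + self.params["prot.b"]
        if train:
            self._cache = cache
        return emb, logits, prot

    # -- backward -----------------------------------------------------------

    def backward(self, d_logits: np.ndarray, d_prot: np.ndarray):
        """Backpropagate head-output gradients; return (grads dict, d_input)."""
        if self._cache is None:
            raise RuntimeError("backward requires a preceding train-mode forward")
        c, p = self._cache, self.params
        grads = {}

        emb = c["emb"]
        grads["type.W"] = emb.T @ d_logits
        grads["type.b"] = d_logits.sum(axis=0)
        grads["prot.W"] = emb.T @ d_prot
        grads["prot.b"] = d_prot.sum(axis=0)

        g_emb = d_logits @ p["type.W"].T + d_prot @ p["prot.W"].T
        grads["emb.W"] = c["emb.x"].T @ g_emb
        grads["emb.b"] = g_emb.sum(axis=0)
        g = g_emb @ p["emb.W"].T

        for i in reversed(range(self.config.n_resnet_blocks)):
            name = f"res{i}"
            ga = g.copy()
            if f"{name}.drop" in c:
                ga = ga * c[f"{name}.drop"]
            ga = ga * (c[f"{name}.pre_relu"] > 0)
            gz = self._bn_backward(name, ga, c[f"{name}.bn"], grads)
            grads[f"{name}.W"] = c[f"{name}.x"].T @ gz
            grads[f"{name}.b"] = gz.sum(axis=0)
            g = g + gz @ p[f"{name}.W"].T

        g = g * (c["in.pre_relu"] > 0)
        gz = self._bn_backward("in", g, c["in.bn"], grads)
        grads["in.W"] = c["x"].T @ gz
        grads["in.b"] = gz.sum(axis=0)
        d_input = gz @ p["in.W"].T
        return grads, d_input

    def embedding_weight_grad(self, d_logits: np.ndarray, d_prot: np.ndarray) -> np.ndarray:
        """Gradient of a loss wrt the embedding block's weight matrix.

        This is the shared-parameter gradient used for gradient balancing;
        pass zeros for the head not involved in the task.
        """
        if self._cache is None:
            raise RuntimeError("requires a preceding train-mode forward")
        g_emb = d_logits @ self.params["type.W"].T + d_prot @ self.params["prot.W"].T
        return self._cache["emb.x"].T @ g_emb

    # -- bookkeeping --------------------------------------------------------

    def parameter_count(self) -> int:
        return sum(v.size for v in self.params.values())

    def state_dict(self) -> dict:
        return {
            "params": {k: v.copy() for k, v in self.params.items()},
            "running": {k: v.copy() for k, v in self.running.items()},
        }

    def load_state_dict(self, state: dict) -> None:
        for k, v in state["params"].items():
            self.params[k] = np.asarray(v, dtype=float)
        for k, v in state["running"].items():
            self.running[k] = np.asarray(v, dtype=float)

    def save(self, path: str | Path) -> None:
        arrays = {f"p::{k}": v for k, v in self.params.items()}
        arrays.update({f"r::{k}": v for k, v in self.running.items()})
        arrays["config_json"] = np.frombuffer(
            json.dumps(dataclasses.asdict(self.config)).encode(), dtype=np.uint8
        )
        np.savez(Path(path), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "MultiTaskModel":
        data = np.load(Path(path))
        cfg = NetworkConfig(**json.loads(bytes(data["config_json"]).decode()))
        model = cls(cfg)
        for k in data.files:
            if k.startswith("p::"):
                model.params[k[3:]] = data[k]
            elif k.startswith("r::"):
                model.running[k[3:]] = data[k]
        return model


def build_model(config: NetworkConfig) -> MultiTaskModel:
    return MultiTaskModel(config)


def parameter_count_formula(c: NetworkConfig) -> int:
    """Closed-form parameter count (affine shapes + batchnorm scale/shift)."""
    n = c.input_dim * c.hidden_dim + c.hidden_dim + 2 * c.hidden_dim
    n += c.n_resnet_blocks * (c.hidden_dim * c.hidden_dim + c.hidden_dim + 2 * c.hidden_dim)
    n += c.hidden_dim * c.embedding_dim + c.embedding_dim
    n += c.embedding_dim * c.n_classes + c.n_classes
    n += c.embedding_dim * c.n_proteins + c.n_proteins
    return n
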