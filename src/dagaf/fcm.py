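"""Functional-causal-model networks: per-node generator, PNL inverse net, critic.

The generator follows the NOTEARS-MLP architecture: a shared structure
layer L0 of d blocks (one h×d block per modelled variable, whose column
norms implicitly define the weighted adjacency) feeding locally connected
hidden layers that realise each mechanism f_j. The diagonal of every L0
block is masked at each forward pass so X̃_j never depends on X_j.

Assumptions:
  * LINGAM — linear mechanisms (the structure layer is used without a
    nonlinearity and the readout is linear), non-Gaussian noise;
  * ANM    — nonlinear mechanisms with additive Gaussian noise;
  * PNL    — ANM followed by an invertible post-nonlinearity g; training
    learns g⁻¹ with a dedicated MLP.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .graphs import WeightedAdjacency, ridge_norm_adjacency


class Assumption(str, Enum):
    LINGAM = "lingam"
    ANM = "anm"
    PNL = "pnl"


def _act(name: str):
    return {
        "sigmoid": ad.sigmoid,
        "tanh": ad.tanh,
        "relu": ad.relu,
        "identity": lambda t: t,
    }[name]


class Module:
    """Base container: anything exposing ``parameters()`` for an optimizer."""

    def parameters(self) -> list[Tensor]:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data for i, p in enumerate(self.parameters())}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            src = arrays[f"p{i}"]
            if src.shape != p.data.shape:
                raise ValueError(
                    f"parameter {i}: shape mismatch {src.shape} vs {p.data.shape}"
                )
            p.data = src.astype(np.float64).copy()


class FcmGenerator(Module):
    """Per-node generator: structure layer + local mechanisms.

    Parameters are stored stacked across nodes: ``W1`` has shape
    (d, d, h) — for node j, ``W1[j]`` maps the d inputs to h latent
    units (the transpose of the h×d block of the adjacency extraction);
    hidden layers (optional, h→h) and the readout ``W2`` (d, h, 1) are
    local to each node.
    """

    def __init__(
        self,
        d: int,
        h: int = 10,
        depth: int = 1,
        assumption: "Assumption | str" = Assumption.ANM,
        activation: str = "sigmoid",
        seed: int = 0,
        init_scale: float = 0.1,
    ):
        if d < 1 or h < 1 or depth < 1:
            raise ValueError("d, h and depth must be positive")
        self.d, self.h, self.depth = d, h, depth
        self.assumption = Assumption(assumption)
        self.activation = "identity" if self.assumption is Assumption.LINGAM else activation
        self.seed = seed
        rng = np.random.default_rng(seed)
        s = init_scale
        self.W1 = Tensor(rng.uniform(-s, s, size=(d, d, h)), requires_grad=True)
        self.b1 = Tensor(np.zeros((d, 1, h)), requires_grad=True)
        self.hidden = []
        for _ in range(depth - 1):
            W = Tensor(rng.uniform(-s, s, size=(d, h, h)), requires_grad=True)
            b = Tensor(np.zeros((d, 1, h)), requires_grad=True)
            self.hidden.append((W, b))
        self.W2 = Tensor(rng.uniform(-s, s, size=(d, h, 1)), requires_grad=True)
        self.b2 = Tensor(np.zeros((d, 1, 1)), requires_grad=True)
        mask = np.ones((d, d, 1))
        for j in range(d):
            mask[j, j, 0] = 0.0  # no self-influence
        self._mask = Tensor(mask)

    def parameters(self) -> list[Tensor]:
        ps = [self.W1, self.b1]
        for W, b in self.hidden:
            ps += [W, b]
        ps += [self.W2, self.b2]
        return ps

    def structure_parameters(self) -> list[Tensor]:
        return [self.W1]

    def mechanism_parameters(self) -> list[Tensor]:
        return [p for p in self.parameters() if p is not self.W1]

    def forward(self, X: "Tensor | np.ndarray", noise: "Tensor | np.ndarray | None" = None) -> Tensor:
        """Evaluate all mechanisms: column j of the output is f_j(X).

        ``noise`` (n×d), when given, is added to the mechanism output —
        the additive-noise placement shared by LiNGAM/ANM; under PNL the
        post-nonlinearity g is applied outside this module (the noise
        here is then pre-g by construction).
        """
        X = ad.astensor(X)
        if X.ndim != 2 or X.shape[1] != self.d:
            raise ValueError(f"expected input of shape (n, {self.d}), got {X.shape}")
        act = _act(self.activation)
        W1m = self.W1 * self._mask  # (d, d, h), diagonal rows zeroed
        H = act(ad.matmul(X, W1m) + self.b1)  # (d, n, h)
        for W, b in self.hidden:
            H = act(ad.matmul(H, W) + b)
        out = ad.matmul(H, self.W2) + self.b2  # (d, n, 1)
        n = X.shape[0]
        out = ad.swapaxes(ad.reshape(out, (self.d, n)), 0, 1)  # (n, d)
        if noise is not None:
            noise = ad.astensor(noise)
            if noise.shape != out.shape:
                raise ValueError(f"noise shape {noise.shape} != output {out.shape}")
            out = out + noise
        return out

    __call__ = forward

    def first_layer_blocks(self) -> list[np.ndarray]:
        """The d h×d blocks W⁽¹⁾_j (latent units × input variables)."""
        W = self.W1.data * self._mask.data
        return [W[j].T.copy() for j in range(self.d)]

    def adjacency(self) -> WeightedAdjacency:
        return ridge_norm_adjacency(self.first_layer_blocks())

    def squared_adjacency_tensor(self) -> Tensor:
        """Differentiable d×d matrix of squared L0 column norms."""
        W1m = self.W1 * self._mask
        return ad.sum_(ad.square(W1m), axis=2)  # (d_child, d_parent)

    def config(self) -> dict:
        return {
            "kind": "FcmGenerator",
            "d": self.d,
            "h": self.h,
            "depth": self.depth,
            "assumption": self.assumption.value,
            "activation": self.activation,
            "seed": self.seed,
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "FcmGenerator":
        return cls(
            d=cfg["d"], h=cfg["h"], depth=cfg["depth"],
            assumption=cfg["assumption"], activation=cfg["activation"],
            seed=cfg["seed"],
        )


class InverseNet(Module):
    """MLP approximating g⁻¹ for the PNL case: widths [d, 10d, 10d, 10d, d].

    Initialized near-identity (skip connection plus small last layer) so
    early training behaves like the ANM branch.
    """

    def __init__(self, d: int, width_factor: int = 10, seed: int = 0):
        self.d = d
        self.width_factor = width_factor
        self.seed = seed
        rng = np.random.default_rng(seed)
        w = width_factor * d
        dims = [d, w, w, w, d]
        self.weights: list[Tensor] = []
        self.biases: list[Tensor] = []
        for i, (m, n) in enumerate(zip(dims[:-1], dims[1:])):
            scale = np.sqrt(2.0 / m)
            W = rng.normal(0.0, scale, size=(m, n))
            if i == len(dims) - 2:
                W = W * 0.01  # near-zero readout; identity comes from the skip
            self.weights.append(Tensor(W, requires_grad=True))
            self.biases.append(Tensor(np.zeros(n), requires_grad=True))

    def parameters(self) -> list[Tensor]:
        return [*self.weights, *self.biases]

    def forward(self, X: "Tensor | np.ndarray") -> Tensor:
        X = ad.astensor(X)
        if X.ndim != 2 or X.shape[1] != self.d:
            raise ValueError(f"expected input of shape (n, {self.d}), got {X.shape}")
        H = X
        last = len(self.weights) - 1
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            H = ad.matmul(H, W) + b
            if i < last:
                H = ad.relu(H)
        return H + X  # skip connection

    __call__ = forward

    def config(self) -> dict:
        return {"kind": "InverseNet", "d": self.d,
                "width_factor": self.width_factor, "seed": self.seed}

    @classmethod
    def from_config(cls, cfg: dict) -> "InverseNet":
        return cls(d=cfg["d"], width_factor=cfg["width_factor"], seed=cfg["seed"])


class Critic(Module):
    """WGAN critic ℝ^d → ℝ: d→64→64→1 with LeakyReLU(0.2), no batch norm."""

    def __init__(self, d: int, hidden: int = 64, seed: int = 0):
        self.d, self.hidden_size, self.seed = d, hidden, seed
        rng = np.random.default_rng(seed)
        dims = [d, hidden, hidden, 1]
        self.weights, self.biases = [], []
        for m, n in zip(dims[:-1], dims[1:]):
            self.weights.append(
                Tensor(rng.normal(0.0, np.sqrt(2.0 / m), size=(m, n)), requires_grad=True)
            )
            self.biases.append(Tensor(np.zeros(n), requires_grad=True))

    def parameters(self) -> list[Tensor]:
        return [*self.weights, *self.biases]

    def forward(self, X: "Tensor | np.ndarray") -> Tensor:
        X = ad.astensor(X)
        if X.ndim != 2 or X.shape[1] != self.d:
            raise ValueError(f"expected input of shape (n, {self.d}), got {X.shape}")
        H = X
        last = len(self.weights) - 1
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            H = ad.matmul(H, W) + b
            if i < last:
                H = ad.leaky_relu(H, 0.2)
        return ad.reshape(H, (X.shape[0],))

    __call__ = forward

    def config(self) -> dict:
        return {"kind": "Critic", "d": self.d, "hidden": self.hidden_size,
                "seed": self.seed}

    @classmethod
    def from_config(cls, cfg: dict) -> "Critic":
        return cls(d=cfg["d"], hidden=cfg["hidden"], seed=cfg["seed"])


_REGISTRY = {"FcmGenerator": FcmGenerator, "InverseNet": InverseNet, "Critic": Critic}

CHECKPOINT_VERSION = 1


def save_checkpoint(path: "str | Path", modules: dict[str, Module],
                    extra: "dict | None" = None) -> None:
    """Serialize named modules (+ JSON metadata) into a single .zip archive."""
    path = Path(path)
    meta = {
        "version": CHECKPOINT_VERSION,
        "modules": {name: m.config() for name, m in modules.items()},
        "extra": extra or {},
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta, indent=2))
        for name, m in modules.items():
            import io

            buf = io.BytesIO()
            np.savez(buf, **m.state_arrays())
            zf.writestr(f"{name}.npz", buf.getvalue())


def load_checkpoint(path: "str | Path") -> tuple[dict[str, Module], dict]:
    path = Path(path)
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
        modules: dict[str, Module] = {}
        for name, cfg in meta["modules"].items():
            cls = _REGISTRY[cfg["kind"]]
            m = cls.from_config(cfg)
            import io

            with np.load(io.BytesIO(zf.read(f"{name}.npz"))) as arrs:
                m.load_state_arrays(dict(arrs))
            modules[name] = m
    return modules, meta["extra"]
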