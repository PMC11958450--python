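"""Benchmark generation: random ER ground-truth DAGs and the five
structural-equation families used throughout the experiments.

Families (A is the weighted ground-truth adjacency, Z exogenous noise,
all applied column-by-column in topological order):

  linear      X_j = Σ_k A[j,k]·X_k + Z_j                       (LiNGAM)
  nonlinear1  X_j = Σ_k A[j,k]·cos(X_k + 1) + Z_j              (ANM)
  nonlinear2  X_j = 2·sin(s_j) + s_j + Z_j,  s_j = Σ_k A[j,k](X_k + 0.5)
  pnl1        X_j = sinh(Σ_k A[j,k]·cos(X_k + 1) + Z_j)        (PNL)
  pnl2        X_j = tanh(2·sin(s_j) + s_j + Z_j)               (PNL)

The linear family takes non-Gaussian noise (uniform by default, as
LiNGAM identifiability requires); the others take standard Gaussian
noise. Adjacency convention: entry [j, k] is the weight of edge k→j.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .graphs import BinaryDag

FAMILIES = ("linear", "nonlinear1", "nonlinear2", "pnl1", "pnl2")

#: the FCM assumption under which each family is identifiable
FAMILY_ASSUMPTION = {
    "linear": "lingam",
    "nonlinear1": "anm",
    "nonlinear2": "anm",
    "pnl1": "pnl",
    "pnl2": "pnl",
}

NOISE_LAWS = ("uniform", "gaussian", "exponential", "laplace", "gumbel")


def _default_noise(family: str) -> str:
    return "uniform" if family == "linear" else "gaussian"


@dataclass
class SemSpec:
    """One simulation benchmark instance: DAG + SEM family + noise law."""

    weights: np.ndarray           # weighted ground-truth adjacency (row=child)
    family: str = "linear"
    noise: "str | None" = None    # law name; default depends on family
    noise_scale: float = 1.0
    n: int = 5000
    seed: int = 0

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; one of {FAMILIES}")
        if self.noise is None:
            self.noise = _default_noise(self.family)
        if self.noise not in NOISE_LAWS:
            raise ValueError(f"unknown noise law {self.noise!r}")
        if self.family == "linear" and self.noise == "gaussian":
            raise ValueError("the linear/LiNGAM family requires non-Gaussian noise")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        # validates acyclicity and zero diagonal
        self.dag = BinaryDag((self.weights != 0).astype(int))

    @property
    def d(self) -> int:
        return self.weights.shape[0]


def sample_er_dag(
    d: int,
    expected_degree: float = 3.0,
    weight_range: tuple[float, float] = (0.5, 2.0),
    seed: int = 0,
) -> np.ndarray:
    """Random Erdős–Rényi DAG with edge weights, as a weighted adjacency.

    Edges are included independently with p = expected_degree/(d−1)
    below the diagonal of a uniformly random variable ordering, which
    guarantees acyclicity; weights are drawn uniformly from
    ±[weight_range], the sign itself uniform, keeping every edge clear
    of zero so it remains detectable after thresholding.
    """
    if d < 2:
        raise ValueError("d must be >= 2")
    if expected_degree < 0:
        raise ValueError("expected_degree must be nonnegative")
    if expected_degree >= d:
        raise ValueError(f"expected_degree={expected_degree} must be < d={d}")
    lo, hi = weight_range
    if not (0 < lo <= hi):
        raise ValueError("weight_range must satisfy 0 < lo <= hi")
    rng = np.random.default_rng(seed)
    p = expected_degree / (d - 1)
    perm = rng.permutation(d)
    W = np.zeros((d, d))
    for a in range(d):
        for b in range(a + 1, d):
            if rng.uniform() < p:
                # edge perm[a] -> perm[b]; row = child
                w = rng.uniform(lo, hi) * (1 if rng.uniform() < 0.5 else -1)
                W[perm[b], perm[a]] = w
    return W


def _draw_noise(law: str, scale: float, size, rng: np.random.Generator) -> np.ndarray:
    if law == "uniform":
        return rng.uniform(-scale, scale, size=size)
    if law == "gaussian":
        return rng.normal(0.0, scale, size=size)
    if law == "exponential":
        return rng.exponential(scale, size=size) - scale  # centered
    if law == "laplace":
        return rng.laplace(0.0, scale, size=size)
    if law == "gumbel":
        g = rng.gumbel(0.0, scale, size=size)
        return g - scale * np.euler_gamma  # centered
    raise ValueError(f"unknown noise law {law!r}")


def simulate_sem(spec: SemSpec) -> np.ndarray:
    """Draw n samples from the SEM, generating columns in topological order."""
    W = spec.weights
    d, n = spec.d, spec.n
    rng = np.random.default_rng(spec.seed)
    Z = _draw_noise(spec.noise, spec.noise_scale, (n, d), rng)
    X = np.zeros((n, d))
    for j in spec.dag.topological_order():
        w = W[j]  # weights of all parents of j
        z = Z[:, j]
        if spec.family == "linear":
            X[:, j] = X @ w + z
        elif spec.family == "nonlinear1":
            X[:, j] = np.cos(X + 1.0) @ w + z
        elif spec.family == "nonlinear2":
            s = (X + 0.5) @ w
            X[:, j] = 2.0 * np.sin(s) + s + z
        elif spec.family == "pnl1":
            X[:, j] = np.sinh(np.cos(X + 1.0) @ w + z)
        elif spec.family == "pnl2":
            s = (X + 0.5) @ w
            X[:, j] = np.tanh(2.0 * np.sin(s) + s + z)
    return X


def load_tabular(path: "str | Path") -> pd.DataFrame:
    """Read a numeric CSV dataset (header row of variable names required)."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty file")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as err:
        raise ValueError(f"{path}: malformed CSV ({err})") from err
    for col in df.columns:
        if len(df) and not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][~df[col].apply(lambda v: isinstance(v, (int, float)))]
            loc = bad.index[0] + 2 if len(bad) else "?"
            raise ValueError(f"{path}: non-numeric cell in column {col!r}, line {loc}")
    return df


def save_tabular(data, path: "str | Path", names=None) -> None:
    """Write an n×d matrix (or DataFrame) as CSV with a header row."""
    if isinstance(data, pd.DataFrame):
        df = data
    else:
        arr = np.asarray(data)
        names = list(names) if names is not None else [f"X{i}" for i in range(arr.shape[1])]
        df = pd.DataFrame(arr, columns=names)
    # shortest exactly round-trippable float formatting
    df.to_csv(Path(path), index=False, float_format=lambda v: repr(float(v)))
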