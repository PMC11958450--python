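"""DAG representations, implicit adjacency extraction, acyclicity, and I/O.

Convention used throughout the package: adjacency entry ``[j, k]`` is the
influence of variable ``k`` (parent, column) on variable ``j`` (child,
row), 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.linalg


@dataclass(frozen=True)
class WeightedAdjacency:
    """Nonnegative d×d matrix of edge strengths (row = child, col = parent)."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"adjacency must be square, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("adjacency contains non-finite entries")
        if np.any(v < 0):
            raise ValueError("adjacency entries must be nonnegative")
        v = v.copy()
        np.fill_diagonal(v, 0.0)
        object.__setattr__(self, "values", v)

    @property
    def d(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class BinaryDag:
    """0/1 adjacency of a directed acyclic graph (edge k→j stored at [j, k])."""

    edges: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.edges)
        if e.ndim != 2 or e.shape[0] != e.shape[1]:
            raise ValueError(f"adjacency must be square, got shape {e.shape}")
        if not np.all(np.isin(e, [0, 1])):
            raise ValueError("binary adjacency must contain only 0/1")
        e = e.astype(np.int64).copy()
        if np.any(np.diag(e) != 0):
            raise ValueError("self-loops are not allowed")
        if has_cycle(e):
            raise ValueError("graph contains a cycle; not a DAG")
        object.__setattr__(self, "edges", e)

    @property
    def d(self) -> int:
        return self.edges.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.edges.sum())

    def to_networkx(self) -> nx.DiGraph:
        # edges[j, k] == 1 means k -> j
        return nx.from_numpy_array(self.edges.T, create_using=nx.DiGraph)

    def topological_order(self) -> list[int]:
        return list(nx.topological_sort(self.to_networkx()))

    def parents(self, j: int) -> np.ndarray:
        return np.flatnonzero(self.edges[j])


def has_cycle(adj: np.ndarray) -> bool:
    """Cycle test on the support of ``adj`` (any nonzero entry is an edge)."""
    g = nx.from_numpy_array((np.asarray(adj) != 0).T.astype(int), create_using=nx.DiGraph)
    return not nx.is_directed_acyclic_graph(g)


def ridge_norm_adjacency(first_layer_weights: Sequence[np.ndarray]) -> WeightedAdjacency:
    """Extract the implicit weighted adjacency from structure-layer weights.

    ``first_layer_weights[j]`` is the h×d weight block of the network
    modelling variable j; entry ``A[j, k]`` is the L2 norm of the column
    of weights connecting input variable k to all h latent units, i.e.
    the ridge-regression norm that measures how strongly X_k enters the
    mechanism of X_j.
    """
    blocks = [np.asarray(w, dtype=np.float64) for w in first_layer_weights]
    d = len(blocks)
    for j, w in enumerate(blocks):
        if w.ndim != 2 or w.shape[1] != d:
            raise ValueError(
                f"block {j}: expected shape (h, {d}), got {w.shape}"
            )
        if not np.all(np.isfinite(w)):
            raise ValueError(f"block {j} contains non-finite weights")
    A = np.stack([np.sqrt((w ** 2).sum(axis=0)) for w in blocks])
    np.fill_diagonal(A, 0.0)
    return WeightedAdjacency(A)


def acyclicity_value(A: "WeightedAdjacency | np.ndarray") -> float:
    """NOTEARS acyclicity functional h(A) = tr(exp(A∘A)) − d.

    Zero iff the support of A is acyclic, strictly positive otherwise;
    smooth in A so it can serve as an equality constraint.
    """
    M = A.values if isinstance(A, WeightedAdjacency) else np.asarray(A, dtype=np.float64)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.all(np.isfinite(M)):
        raise ValueError("adjacency contains non-finite entries")
    with np.errstate(over="raise"):
        try:
            E = scipy.linalg.expm(M * M)
        except FloatingPointError as err:
            raise OverflowError(
                "matrix exponential overflowed; rescale the adjacency"
            ) from err
    if not np.all(np.isfinite(E)):
        raise OverflowError("matrix exponential overflowed; rescale the adjacency")
    return float(np.trace(E) - M.shape[0])


def postprocess_structure(
    A_sq: np.ndarray,
    tau: float = 0.3,
    enforce_acyclic: bool = False,
) -> tuple[WeightedAdjacency, "np.ndarray | BinaryDag"]:
    """Recover edge weights (entrywise sqrt) and threshold into a graph.

    An edge is kept iff its weight is strictly greater than ``tau``; a
    boundary value drops, erring toward fewer false discoveries. The
    thresholded graph is not guaranteed acyclic; with
    ``enforce_acyclic=True`` the weakest edge of any residual cycle is
    removed greedily until a DAG remains.
    """
    A_sq = np.asarray(A_sq, dtype=np.float64)
    if np.any(A_sq < 0):
        raise ValueError("squared-weight matrix must be entrywise nonnegative")
    if tau < 0:
        raise ValueError("threshold must be nonnegative")
    weighted = WeightedAdjacency(np.sqrt(A_sq))
    mask = (weighted.values > tau).astype(np.int64)
    if enforce_acyclic or not has_cycle(mask):
        w = weighted.values.copy()
        w[mask == 0] = 0.0
        while has_cycle(mask):
            g = nx.from_numpy_array(mask.T.astype(int), create_using=nx.DiGraph)
            cycle = nx.find_cycle(g)
            weakest = min(cycle, key=lambda e: w[e[1], e[0]])
            mask[weakest[1], weakest[0]] = 0
            w[weakest[1], weakest[0]] = 0.0
        return weighted, BinaryDag(mask)
    return weighted, mask


def read_ground_truth(path: "str | Path") -> BinaryDag:
    """Read a DAG from edge-list text ("src<TAB>dst" per line) or dense CSV.

    Dense CSV is detected by a header row; edge lists are two integer
    columns, whitespace- or tab-separated, 0-based.
    """
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        # an empty edge list is a graph with no edges (and unknown size)
        return BinaryDag(np.zeros((0, 0), dtype=int))
    first = text.splitlines()[0]
    if any(c.isalpha() for c in first) or first.count(",") >= 1:
        df = pd.read_csv(path, index_col=None)
        mat = df.to_numpy()
        if mat.shape[0] != mat.shape[1]:
            raise ValueError(f"{path}: dense adjacency must be square, got {mat.shape}")
        return BinaryDag((mat != 0).astype(int))
    pairs = []
    d = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'src dst', got {line!r}")
        try:
            src, dst = int(parts[0]), int(parts[1])
        except ValueError as err:
            raise ValueError(f"{path}:{lineno}: non-integer node index") from err
        if src < 0 or dst < 0:
            raise ValueError(f"{path}:{lineno}: negative node index")
        if src == dst:
            raise ValueError(f"{path}:{lineno}: self-loop {src}->{dst} rejected")
        pairs.append((src, dst))
        d = max(d, src + 1, dst + 1)
    mat = np.zeros((d, d), dtype=int)
    for src, dst in pairs:
        mat[dst, src] = 1  # row = child
    return BinaryDag(mat)


def write_dag(
    dag: BinaryDag,
    path: "str | Path",
    names: "Sequence[str] | None" = None,
    fmt: str = "auto",
) -> None:
    """Write a DAG as edge-list text (.edges/.txt) or dense CSV (.csv)."""
    path = Path(path)
    if fmt == "auto":
        fmt = "csv" if path.suffix.lower() == ".csv" else "edges"
    if fmt == "csv":
        names = list(names) if names is not None else [f"X{i}" for i in range(dag.d)]
        pd.DataFrame(dag.edges, columns=names).to_csv(path, index=False)
    elif fmt == "edges":
        lines = [
            f"{k}\t{j}" for j in range(dag.d) for k in range(dag.d) if dag.edges[j, k]
        ]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def write_weighted(
    A: WeightedAdjacency, path: "str | Path", names: "Sequence[str] | None" = None
) -> None:
    names = list(names) if names is not None else [f"X{i}" for i in range(A.d)]
    pd.DataFrame(A.values, columns=names).to_csv(Path(path), index=False)
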