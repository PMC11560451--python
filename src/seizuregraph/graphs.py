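"""Adjacency construction for the three GCN branches.

Three views of inter-channel structure feed the model:

* a spatial-distance graph — Gaussian kernel of normalized Euclidean
  distance between bipolar-derivation midpoints, sparsified at ``R1``;
* a functional-connectivity graph — Pearson correlation between channel
  feature vectors, mapped to [0, 1] and sparsified at ``R2``;
* an adaptive graph — a free n x n parameter constrained by whole-matrix
  standardization and ReLU, learned by backpropagation (the trainable raw
  matrix lives in the model; the constraint transform is here).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .montage import ElectrodeLayout

ADJACENCY_KINDS = ("distance", "connectivity", "adaptive")


@dataclass
class Adjacency:
    """A weighted graph over EEG channels (nonnegative, zero diagonal)."""

    matrix: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        n, m = self.matrix.shape
        if n != m:
            raise ValueError("adjacency must be square")
        if self.kind not in ADJACENCY_KINDS:
            raise ValueError(f"unknown adjacency kind {self.kind!r}")
        if not np.isfinite(self.matrix).all() or (self.matrix < 0).any():
            raise ValueError("adjacency weights must be finite and nonnegative")
        if self.kind in ("distance", "connectivity") and not np.allclose(
            self.matrix, self.matrix.T
        ):
            raise ValueError(f"{self.kind} adjacency must be symmetric")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def edge_count(self) -> int:
        """Number of retained undirected edges (upper triangle, no diagonal)."""
        return int(np.count_nonzero(np.triu(self.matrix, k=1)))

    def mean_weight(self) -> float:
        """Mean weight over retained upper-triangle edges (0 if no edges)."""
        w = np.triu(self.matrix, k=1)
        nz = w[w > 0]
        return float(nz.mean()) if nz.size else 0.0

    def to_frame(self, names: list[str] | None = None) -> pd.DataFrame:
        names = names or [f"ch{i}" for i in range(self.n)]
        return pd.DataFrame(self.matrix, index=names, columns=names)

    def to_csv(self, path, names: list[str] | None = None) -> None:
        self.to_frame(names).to_csv(path)

    @staticmethod
    def from_csv(path, kind: str) -> "Adjacency":
        df = pd.read_csv(path, index_col=0)
        return Adjacency(df.to_numpy(), kind)


def build_distance_adjacency(
    layout: ElectrodeLayout, r1: float = 0.4, two_delta_sq: bool = True
) -> Adjacency:
    """Gaussian-kernel spatial graph, sparsified at threshold ``r1``.

    Pairwise Euclidean distances between derivation midpoints are normalized
    by the maximum distance to [0, 1]; the kernel bandwidth ``delta`` is the
    population standard deviation of the normalized unique-pair distances.
    Edges with normalized distance above ``r1`` are dropped; the diagonal is
    zero (self-loops are added once by the GCN normalizer).

    ``two_delta_sq`` selects ``exp(-d^2 / (2 delta^2))`` (heat-kernel
    convention, default) versus ``exp(-d^2 / delta^2)``.
    """
    coords = layout.coords
    n = len(layout)
    if n < 2:
        raise ValueError("layout needs at least 2 nodes")
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    dmax = dist.max()
    if dmax <= 0:
        raise ValueError("all nodes coincide; distance graph undefined")
    dist = dist / dmax
    iu = np.triu_indices(n, k=1)
    delta = float(dist[iu].std())  # population std over unique pairs
    denom = (2.0 if two_delta_sq else 1.0) * max(delta, 1e-12) ** 2
    a = np.exp(-(dist**2) / denom)
    a[dist > r1] = 0.0
    np.fill_diagonal(a, 0.0)
    return Adjacency(a, "distance")


def build_correlation_adjacency(
    segment: np.ndarray, r2: float = 0.25, mode: str = "shifted"
) -> Adjacency:
    """Pearson functional-connectivity graph, sparsified at threshold ``r2``.

    Correlations are mapped to [0, 1] either by the affine shift
    ``(rho + 1) / 2`` (default) or by ``|rho|``; values below ``r2`` are
    dropped and the diagonal is zeroed.
    """
    x = np.asarray(segment, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("segment must be (channels, samples>=2)")
    var = x.var(axis=1)
    dead = np.flatnonzero(var == 0)
    if dead.size:
        raise ValueError(f"zero-variance channel(s): {dead.tolist()}")
    rho = np.corrcoef(x)
    if mode == "shifted":
        rho01 = (rho + 1.0) / 2.0
    elif mode == "abs":
        rho01 = np.abs(rho)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    a = np.where(rho01 >= r2, rho01, 0.0)
    np.fill_diagonal(a, 0.0)
    a = (a + a.T) / 2.0  # enforce exact symmetry against fp noise
    return Adjacency(a, "connectivity")


def constrain_adaptive_adjacency(
    raw: np.ndarray, gamma: float = 1.0, beta: float = 0.0, eps: float = 1e-5
) -> Adjacency:
    """Constraint transform for the trainable adjacency: standardize + ReLU.

    The raw matrix is standardized over all its entries (population std with
    ``eps`` guard), passed through a learnable scalar affine (identity at
    init), then ReLU — guaranteeing a nonnegative, well-defined adjacency
    even for a constant raw matrix.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if raw.ndim != 2 or raw.shape[0] != raw.shape[1]:
        raise ValueError("raw adjacency must be square")
    if not np.isfinite(raw).all():
        raise ValueError("raw adjacency must be finite")
    z = (raw - raw.mean()) / (raw.std() + eps)
    return Adjacency(np.maximum(gamma * z + beta, 0.0), "adaptive")


def normalize_adjacency(a: np.ndarray) -> np.ndarray:
    """Symmetric GCN propagation operator ``D^-1/2 (A + I) D^-1/2``.

    ``D`` is the diagonal row-sum of ``A + I``; adding the identity
    introduces the single self-loop per node and guarantees positive degree.
    Accepts a single matrix or a stack of them.
    """
    a = np.asarray(a, dtype=np.float64)
    n = a.shape[-1]
    at = a + np.eye(n)
    d = at.sum(axis=-1)
    dinv = 1.0 / np.sqrt(d)
    return at * dinv[..., :, None] * dinv[..., None, :]


def threshold_sweep(
    builder: str,
    grid: list[float],
    layout: ElectrodeLayout | None = None,
    segment: np.ndarray | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Sparsity diagnostics over a threshold grid for either static builder.

    Returns a table of (threshold, edge_count, mean_weight). For the
    distance graph edge count is non-decreasing in the threshold; for the
    connectivity graph it is non-increasing.
    """
    if not grid or list(grid) != sorted(grid):
        raise ValueError("grid must be nonempty and ascending")
    rows = []
    for t in grid:
        if builder == "distance":
            if layout is None:
                raise ValueError("distance sweep needs a layout")
            adj = build_distance_adjacency(layout, r1=t, **kwargs)
        elif builder == "connectivity":
            if segment is None:
                raise ValueError("connectivity sweep needs a segment")
            adj = build_correlation_adjacency(segment, r2=t, **kwargs)
        else:
            raise ValueError(f"unknown builder {builder!r}")
        rows.append(
            {
                "threshold": t,
                "edge_count": adj.edge_count(),
                "mean_weight": adj.mean_weight(),
            }
        )
    return pd.DataFrame(rows)
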