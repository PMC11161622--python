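"""Functional-connectivity matrices, edge vectorization, and the atlas.

Connectivity between two atlas nodes is the Fisher z-transformed Pearson
correlation of their (pre-cleaned) time series.  The pipeline operates on
vectorized upper-triangle edges in a canonical row-major order that is
held fixed — masks, matrices and atlases must all agree on the node count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._utils import DegenerateDataError, IntegrityError

__all__ = [
    "Atlas",
    "YEO7_NETWORKS",
    "EdgeIndex",
    "fc_matrix",
    "edge_vector",
    "edge_matrix",
    "block_fc",
]

#: the 7-network cortical parcellation vocabulary
YEO7_NETWORKS = ("VIS", "SMN", "DAN", "SAL", "LIM", "FPCN", "DMN")

#: clip |r| here before arctanh so duplicated signals stay finite
R_CLIP = 1.0 - 1e-7


@dataclass
class Atlas:
    """Node -> network lookup (1-based node ids in files, 0-based in code).

    ``network_labels[i]`` is the network of node ``i`` (0-based).  The
    default vocabulary is the 7-network scheme but any label set is
    accepted.
    """

    network_labels: list[str]
    name: str = "atlas"
    n_nodes: int = field(init=False)

    def __post_init__(self):
        if not self.network_labels:
            raise ValueError("atlas needs at least one node")
        self.network_labels = [str(x) for x in self.network_labels]
        self.n_nodes = len(self.network_labels)

    @property
    def networks(self) -> list[str]:
        """Distinct labels; 7-network names in canonical order first."""
        present = set(self.network_labels)
        ordered = [n for n in YEO7_NETWORKS if n in present]
        ordered += sorted(present - set(YEO7_NETWORKS))
        return ordered

    def network_of(self, node: int) -> str:
        if not 0 <= node < self.n_nodes:
            raise IntegrityError(f"node {node} outside atlas of {self.n_nodes} nodes")
        return self.network_labels[node]


class EdgeIndex:
    """Canonical ordering of the N(N-1)/2 unordered node pairs (i < j),
    row-major over the upper triangle.  Serialized alongside masks so a
    mask can never silently be applied against a different atlas size."""

    def __init__(self, n_nodes: int):
        if n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        self.n_nodes = int(n_nodes)
        self._iu = np.triu_indices(self.n_nodes, k=1)

    @property
    def n_edges(self) -> int:
        return self.n_nodes * (self.n_nodes - 1) // 2

    def pairs(self) -> np.ndarray:
        """(n_edges, 2) array of 0-based (i, j) with i < j."""
        return np.column_stack(self._iu)

    def edge_id(self, i: int, j: int) -> int:
        if i == j:
            raise ValueError("no self-edges")
        i, j = (i, j) if i < j else (j, i)
        if not 0 <= i < j < self.n_nodes:
            raise ValueError(f"pair ({i}, {j}) outside {self.n_nodes} nodes")
        # edges before row i, plus offset within row i
        return i * (2 * self.n_nodes - i - 1) // 2 + (j - i - 1)

    def __eq__(self, other) -> bool:
        return isinstance(other, EdgeIndex) and other.n_nodes == self.n_nodes

    def __len__(self) -> int:
        return self.n_edges


def fc_matrix(timeseries: np.ndarray) -> np.ndarray:
    """Fisher-z functional-connectivity matrix from a T x N time-series
    array (T timepoints, N nodes).

    Pearson correlations are clipped to |r| <= 1 - 1e-7 before arctanh so
    perfectly correlated signals give a large finite value instead of
    infinity.  The diagonal is zeroed (self-connectivity is excluded from
    all analyses).
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 3:
        raise ValueError("need a T x N array with T >= 3")
    sds = ts.std(axis=0)
    dead = np.flatnonzero(sds == 0)
    if dead.size:
        raise DegenerateDataError(
            f"constant time series at node(s) {dead.tolist()} (0-based)"
        )
    r = np.corrcoef(ts, rowvar=False)
    r = np.clip(r, -R_CLIP, R_CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return (z + z.T) / 2.0


def edge_vector(matrix: np.ndarray, atol: float = 1e-10) -> np.ndarray:
    """Vectorize a symmetric N x N matrix into canonical edge order."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.allclose(m, m.T, atol=atol):
        raise IntegrityError("matrix is not symmetric within tolerance")
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu].copy()


def edge_matrix(edges: np.ndarray, n_nodes: int) -> np.ndarray:
    """Inverse of :func:`edge_vector`: rebuild the symmetric matrix
    (zero diagonal)."""
    edges = np.asarray(edges, dtype=float).ravel()
    index = EdgeIndex(n_nodes)
    if edges.size != index.n_edges:
        raise IntegrityError(
            f"expected {index.n_edges} edges for {n_nodes} nodes, got {edges.size}"
        )
    m = np.zeros((n_nodes, n_nodes))
    iu = np.triu_indices(n_nodes, k=1)
    m[iu] = edges
    return m + m.T


def block_fc(
    trial_windows: list[np.ndarray], block_assignment: list
) -> dict:
    """Per-block connectivity: per-trial :func:`fc_matrix`, then the
    element-wise mean of the trial matrices within each block.

    ``trial_windows[k]`` is the T_k x N series of trial k and
    ``block_assignment[k]`` its block label.  Returns {block: N x N matrix}.
    """
    if len(trial_windows) != len(block_assignment):
        raise ValueError("one block label per trial window required")
    if len(trial_windows) == 0:
        raise ValueError("no trial windows given")
    blocks: dict = {}
    for win, block in zip(trial_windows, block_assignment):
        blocks.setdefault(block, []).append(fc_matrix(win))
    return {b: np.mean(mats, axis=0) for b, mats in blocks.items()}
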