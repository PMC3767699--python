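"""Channel-space functional connectivity networks.

Pearson correlation matrices per subject/session/signal, binarized across a
sparsity sweep: at sparsity ``S`` the ``round(S * n(n-1)/2)`` strongest
edges (by signed correlation, optionally absolute) are retained. The edge
ranking is computed once per matrix, so the resulting networks are nested
across the sweep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConnectivityMatrix",
    "BinaryNetwork",
    "SparsityGrid",
    "correlation_matrix",
    "edge_ranking",
    "threshold_by_sparsity",
    "sparsity_sweep",
    "n_pairs",
    "round_half_away",
    "write_matrix_tsv",
    "read_matrix_tsv",
]


def n_pairs(n: int) -> int:
    """Maximum possible number of undirected connections, n(n-1)/2."""
    return n * (n - 1) // 2


def round_half_away(x: float) -> int:
    """Round half away from zero (platform-independent edge counts)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class ConnectivityMatrix:
    """Symmetric channel x channel Pearson correlation matrix."""

    values: np.ndarray
    channel_ids: list[str] | None = None
    subject: int | None = None
    session: int | None = None
    signal: str | None = None

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def upper_values(self) -> np.ndarray:
        """Unique off-diagonal entries in (row, col) lexicographic order."""
        iu = np.triu_indices(self.n_channels, k=1)
        return self.values[iu]


@dataclass
class BinaryNetwork:
    """Undirected, unweighted adjacency at one sparsity level."""

    adjacency: np.ndarray
    sparsity: float

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass(frozen=True)
class SparsityGrid:
    """Ordered sparsity thresholds, default 0.01 … 0.99 step 0.01."""

    values: tuple[float, ...] = field(
        default_factory=lambda: tuple(np.round(np.arange(1, 100) * 0.01, 2)))

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if len(v) == 0:
            raise ValueError("empty sparsity grid")
        if np.any(v <= 0.0) or np.any(v >= 1.0):
            raise ValueError("sparsity values must lie strictly in (0, 1)")
        if np.any(np.diff(v) <= 0):
            raise ValueError("sparsity grid must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)


def correlation_matrix(ts: np.ndarray, channel_ids: list[str] | None = None,
                       subject: int | None = None, session: int | None = None,
                       signal: str | None = None) -> ConnectivityMatrix:
    """Pearson correlation between every pair of channel time series.

    Raises ``ValueError`` naming the offending channels if any channel is
    constant (its correlations are undefined).
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[1] < 3:
        raise ValueError("need a channels x samples matrix with >= 3 samples")
    constant = np.flatnonzero(np.ptp(ts, axis=1) == 0)
    if constant.size:
        raise ValueError("constant channel(s) make Pearson correlation "
                         f"undefined: indices {constant.tolist()}")
    values = np.corrcoef(ts)
    values = np.clip((values + values.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return ConnectivityMatrix(values, channel_ids, subject, session, signal)


def edge_ranking(cm: ConnectivityMatrix, absolute: bool = False) -> np.ndarray:
    """Edge index pairs sorted strongest-first.

    Ranks by signed correlation by default (positive edges enter first);
    with ``absolute=True`` by |r|. Ties are broken by (row, col)
    lexicographic order, making the ranking — and hence every thresholded
    network — deterministic.
    """
    n = cm.n_channels
    iu, ju = np.triu_indices(n, k=1)
    vals = cm.values[iu, ju]
    key = np.abs(vals) if absolute else vals
    order = np.lexsort((ju, iu, -key))
    return np.column_stack([iu[order], ju[order]])


def threshold_by_sparsity(cm: ConnectivityMatrix, sparsity: float,
                          absolute: bool = False,
                          ranking: np.ndarray | None = None) -> BinaryNetwork:
    """Binarize: keep the K = round(S * n(n-1)/2) strongest edges."""
    if not 0.0 < sparsity < 1.0:
        raise ValueError("sparsity must lie strictly in (0, 1)")
    n = cm.n_channels
    k = round_half_away(sparsity * n_pairs(n))
    if k == 0:
        raise ValueError(f"sparsity {sparsity} yields an edgeless network "
                         f"for n = {n}")
    if ranking is None:
        ranking = edge_ranking(cm, absolute=absolute)
    adjacency = np.zeros((n, n), dtype=np.uint8)
    top = ranking[:k]
    adjacency[top[:, 0], top[:, 1]] = 1
    adjacency[top[:, 1], top[:, 0]] = 1
    return BinaryNetwork(adjacency, float(sparsity))


def sparsity_sweep(cm: ConnectivityMatrix,
                   grid: SparsityGrid | None = None,
                   absolute: bool = False) -> list[BinaryNetwork]:
    """One BinaryNetwork per grid value; edge sets are nested across the
    sweep because a single deterministic ranking is reused."""
    grid = grid or SparsityGrid()
    ranking = edge_ranking(cm, absolute=absolute)
    return [threshold_by_sparsity(cm, s, ranking=ranking) for s in grid]


def write_matrix_tsv(cm: ConnectivityMatrix, path) -> None:
    ids = cm.channel_ids or [f"CH{i + 1:02d}" for i in range(cm.n_channels)]
    df = pd.DataFrame(cm.values, index=ids, columns=ids)
    df.to_csv(path, sep="\t", float_format="%.8g", index_label="channel")


def read_matrix_tsv(path) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ConnectivityMatrix(df.to_numpy(dtype=float),
                              channel_ids=list(df.columns))
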