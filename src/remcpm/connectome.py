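"""Fisher-z functional connectivity and the edge/network algebra.

A connectome here is a symmetric node x node matrix of Fisher-z transformed
Pearson correlations between regional time series, with the diagonal stored
as zero and excluded from every computation.  The canonical vector form is
the upper triangle (i < j) in row-major order; for the default 227-node
parcellation that is 227*226/2 = 25651 edges.

Nodes carry one of ten large-scale network labels (DMN, VIS, FPN, DAN, VAN,
SAN, CON, AUD, SMN, SUB); an edge inherits the unordered pair of its
endpoint labels, giving 55 possible network pairs (10 within + 45 between).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import (
    EdgeVectorError,
    MatrixFormatError,
    ParcellationError,
    ZeroVarianceNodeError,
)

#: Canonical large-scale network labels, in fixed display order.
NETWORKS: Tuple[str, ...] = (
    "DMN", "VIS", "FPN", "DAN", "VAN", "SAN", "CON", "AUD", "SMN", "SUB",
)

_NET_INDEX: Dict[str, int] = {n: i for i, n in enumerate(NETWORKS)}

#: Correlations are clipped to +/- this value before atanh so z stays finite.
R_CLIP = 0.999999


@dataclass(frozen=True)
class Parcellation:
    """Node -> network assignment over the ten canonical networks."""

    labels: np.ndarray
    node_names: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype="U4")
        object.__setattr__(self, "labels", labels)
        if labels.size == 0:
            raise ParcellationError("parcellation has no nodes")
        bad = ~np.isin(labels, NETWORKS)
        if bad.any():
            idx = int(np.flatnonzero(bad)[0])
            raise ParcellationError(
                f"node {idx} labeled {labels[idx]!r}, not one of {NETWORKS}"
            )
        if self.node_names is not None and len(self.node_names) != labels.size:
            raise ParcellationError("node_names length mismatch")

    @property
    def n_nodes(self) -> int:
        return int(self.labels.size)

    @property
    def n_edges(self) -> int:
        n = self.n_nodes
        return n * (n - 1) // 2

    def network_sizes(self) -> Dict[str, int]:
        return {n: int((self.labels == n).sum()) for n in NETWORKS}


def parcellation_from_sizes(network_sizes: Dict[str, int]) -> Parcellation:
    """Build a parcellation with contiguous node blocks per network."""
    unknown = set(network_sizes) - set(NETWORKS)
    if unknown:
        raise ParcellationError(f"unknown network labels: {sorted(unknown)}")
    labels: List[str] = []
    for net in NETWORKS:
        labels.extend([net] * int(network_sizes.get(net, 0)))
    return Parcellation(labels=np.asarray(labels))


def triu_pairs(n: int) -> Tuple[np.ndarray, np.ndarray]:
    """Node index pairs (i, j), i < j, in canonical row-major edge order."""
    return np.triu_indices(n, k=1)


def n_edges_for(n_nodes: int) -> int:
    return n_nodes * (n_nodes - 1) // 2


def _check_square_symmetric(z: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if z.ndim != 2 or z.shape[0] != z.shape[1]:
        raise MatrixFormatError(f"expected square matrix, got shape {z.shape}")
    if not np.isfinite(z).all():
        raise MatrixFormatError("matrix contains non-finite values")
    if np.abs(z - z.T).max(initial=0.0) > tol:
        raise MatrixFormatError("matrix is not symmetric")
    return z


def compute_fc(ts: np.ndarray) -> np.ndarray:
    """Fisher-z connectivity from a nodes x timepoints series matrix.

    z[i, j] = atanh(clip(pearson(ts_i, ts_j), +/-R_CLIP)); symmetric, zero
    diagonal.  A node with zero temporal variance is rejected by name.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[1] < 2:
        raise MatrixFormatError("time series must be nodes x timepoints with >=2 timepoints")
    dead = np.flatnonzero(ts.max(axis=1) - ts.min(axis=1) == 0)
    if dead.size:
        raise ZeroVarianceNodeError(f"node {int(dead[0])} has zero variance")
    r = np.corrcoef(ts)
    r = np.clip(r, -R_CLIP, R_CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return (z + z.T) / 2.0


def vectorize(cm: np.ndarray) -> np.ndarray:
    """Upper-triangle (i < j, row-major) edge vector of a symmetric matrix."""
    z = _check_square_symmetric(cm)
    iu, ju = triu_pairs(z.shape[0])
    return z[iu, ju].copy()


def devectorize(ev: np.ndarray) -> np.ndarray:
    """Inverse of :func:`vectorize`; rejects non-triangular lengths."""
    ev = np.asarray(ev, dtype=float)
    if ev.ndim != 1:
        raise EdgeVectorError("edge vector must be one-dimensional")
    m = ev.size
    n = int((1 + np.sqrt(1 + 8 * m)) / 2)
    if n * (n - 1) // 2 != m:
        raise EdgeVectorError(f"length {m} is not a triangular number")
    z = np.zeros((n, n), dtype=float)
    iu, ju = triu_pairs(n)
    z[iu, ju] = ev
    z[ju, iu] = ev
    return z


def edge_network_pair(edge_index: int, p: Parcellation) -> Tuple[str, str]:
    """Unordered network-label pair of an edge's endpoints.

    The pair is canonicalized to the fixed :data:`NETWORKS` order, so
    DMN<->VIS and VIS<->DMN both map to ("DMN", "VIS").
    """
    m = p.n_edges
    if not (0 <= edge_index < m):
        raise IndexError(f"edge index {edge_index} out of range [0, {m})")
    iu, ju = triu_pairs(p.n_nodes)
    a = p.labels[iu[edge_index]]
    b = p.labels[ju[edge_index]]
    return canonical_pair(a, b)


def canonical_pair(a: str, b: str) -> Tuple[str, str]:
    if _NET_INDEX[a] <= _NET_INDEX[b]:
        return (str(a), str(b))
    return (str(b), str(a))


def pair_label(pair: Tuple[str, str]) -> str:
    return f"{pair[0]}-{pair[1]}"


def all_network_pairs() -> List[Tuple[str, str]]:
    """All 55 unordered network pairs in canonical order."""
    pairs = []
    for i, a in enumerate(NETWORKS):
        for b in NETWORKS[i:]:
            pairs.append((a, b))
    return pairs


def edge_pair_codes(p: Parcellation) -> np.ndarray:
    """Integer pair code per edge, vectorized over all edges.

    Code = min_idx * 10 + max_idx over the endpoint network indices; use
    :func:`pair_code_of` for the code of a named pair.
    """
    idx = np.array([_NET_INDEX[l] for l in p.labels])
    iu, ju = triu_pairs(p.n_nodes)
    a = idx[iu]
    b = idx[ju]
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    return lo * len(NETWORKS) + hi


def pair_code_of(pair: Tuple[str, str]) -> int:
    a, b = canonical_pair(*pair)
    return _NET_INDEX[a] * len(NETWORKS) + _NET_INDEX[b]
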