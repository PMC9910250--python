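"""The five topological features of a functional brain network.

For a weighted network W (entries in [0, 1], zero diagonal):

* degree / strength  D_i = sum_j W_ij, summarized by the node mean D;
* clustering coefficient C_i — geometric-mean-of-triangle-weights form,
  C_i = sum_{jk} (ŵ_ij ŵ_ik ŵ_jk)^{1/3} / (k_i (k_i - 1)) with ŵ = W / max(W)
  and k_i the number of nonzero neighbours; nodes with k_i < 2 get 0;
* characteristic path length L — shortest paths on edge lengths 1/W_ij
  (∞ for absent edges), averaged over ordered node pairs with finite
  distance; the unreachable-pair fraction is reported alongside;
* global efficiency E — mean of 1/d over ordered pairs, with 1/∞ = 0;
* brain network energy BNE — spectral graph energy, the sum of absolute
  eigenvalues of W.

On the binary complete graph these give D = n-1, C = 1, L = 1, E = 1 and
BNE = 2(n-1); all are invariant under node relabelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .errors import UndefinedPathLengthError
from .network import FunctionalBrainNetwork


@dataclass
class NetworkMetrics:
    """Summary metrics of one network plus per-node diagnostics."""

    D: float
    C: float
    L: float
    E: float
    BNE: float
    unreachable_pair_fraction: float = 0.0
    per_node_degree: np.ndarray | None = None
    per_node_clustering: np.ndarray | None = None
    subject_id: str = ""
    timepoint: str = ""

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "timepoint": self.timepoint,
            "D": self.D,
            "C": self.C,
            "L": self.L,
            "E": self.E,
            "BNE": self.BNE,
            "unreachable_pair_fraction": self.unreachable_pair_fraction,
        }


def degree(net: FunctionalBrainNetwork):
    """Per-node strength (row sums) and their mean D."""
    per_node = net.weights.sum(axis=1)
    return per_node, float(per_node.mean())


def clustering_coefficient(net: FunctionalBrainNetwork):
    """Per-node weighted clustering (geometric-mean form) and mean C."""
    w = net.weights
    w_max = w.max()
    if w_max == 0:
        per_node = np.zeros(net.n_nodes)
        return per_node, 0.0
    w_hat = w / w_max
    cube = np.cbrt(w_hat)
    # diagonal of cube^3 counts ordered (j, k) pairs closing a triangle at i
    triangles = np.diag(cube @ cube @ cube)
    k = (w > 0).sum(axis=1)
    denom = k * (k - 1)
    per_node = np.where(denom > 0, triangles / np.where(denom > 0, denom, 1), 0.0)
    return per_node, float(per_node.mean())


def _distance_matrix(net: FunctionalBrainNetwork) -> np.ndarray:
    """All-pairs shortest-path distances on edge lengths 1/weight."""
    with np.errstate(divide="ignore"):
        lengths = np.where(net.weights > 0, 1.0 / net.weights, 0.0)
    return shortest_path(lengths, method="D", directed=False)


def characteristic_path_length(net: FunctionalBrainNetwork):
    """Mean shortest-path distance over reachable ordered pairs.

    Returns ``(L, unreachable_pair_fraction)``.  Raises
    :class:`UndefinedPathLengthError` when no ordered pair is reachable
    (fully disconnected network).
    """
    d = _distance_matrix(net)
    n = net.n_nodes
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    n_pairs = int(off.sum())
    if not finite.any():
        raise UndefinedPathLengthError("no reachable node pair: path length undefined")
    unreachable = 1.0 - finite.sum() / n_pairs
    return float(d[finite].mean()), float(unreachable)


def global_efficiency(net: FunctionalBrainNetwork) -> float:
    """Mean inverse shortest-path distance over ordered pairs (1/∞ = 0)."""
    d = _distance_matrix(net)
    n = net.n_nodes
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1), 0.0)
    return float(inv[off].mean())


def brain_network_energy(net: FunctionalBrainNetwork) -> float:
    """Graph energy: sum of absolute eigenvalues of the weight matrix.

    Zero iff the network has no edges.  (The symmetric-matrix invariant is
    enforced by :class:`FunctionalBrainNetwork` itself.)
    """
    return float(np.abs(np.linalg.eigvalsh(net.weights)).sum())


def network_metrics(net: FunctionalBrainNetwork) -> NetworkMetrics:
    """All five summary metrics of one network.

    On a fully disconnected (empty) network L is undefined; it is reported
    as ``nan`` with unreachable fraction 1 so metric tables stay rectangular,
    while :func:`characteristic_path_length` itself raises.
    """
    per_d, d_mean = degree(net)
    per_c, c_mean = clustering_coefficient(net)
    try:
        L, unreachable = characteristic_path_length(net)
    except UndefinedPathLengthError:
        L, unreachable = float("nan"), 1.0
    return NetworkMetrics(
        D=d_mean,
        C=c_mean,
        L=L,
        E=global_efficiency(net),
        BNE=brain_network_energy(net),
        unreachable_pair_fraction=unreachable,
        per_node_degree=per_d,
        per_node_clustering=per_c,
        subject_id=net.subject_id,
        timepoint=net.timepoint,
    )
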