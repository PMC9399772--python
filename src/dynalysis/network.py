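"""Correlated-motion analysis and dynamic residue networks.

Two correlation flavors over Calpha fluctuations:

* DCCM — the normalized covariance of displacement vectors,
  C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2><|dr_j|^2>), in [-1, 1].  Sensitive
  to the relative orientation of motions (orthogonal correlated motions
  score 0).
* Generalized correlation — GC_ij = sqrt(1 - exp(-2 MI_ij / 3)) where MI is
  the mutual information between the two atoms' 3-D fluctuation vectors,
  estimated with the Kraskov-Stoegbauer-Grassberger k-nearest-neighbor
  estimator.  In [0, 1]; equals |r| for jointly Gaussian motions, and picks
  up nonlinear or orthogonal coupling that DCCM misses.

The dynamic network places one node per residue (its Calpha) and draws an
edge when the inter-residue heavy-atom minimum distance stays within a
cutoff (default 4.5 A) for at least an occupancy fraction (default 75%) of
frames; edge weights are -ln|C_ij|, so strong correlation means short
network distance.  Communities come from Girvan-Newman edge-betweenness
division at maximum modularity; signalling routes are minimum-weight
(Dijkstra) paths.
"""
from __future__ import annotations

import heapq
import itertools
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma

from .io import Ensemble, Selection

__all__ = [
    "CorrelationMatrix",
    "CommunityPartition",
    "dccm",
    "mutual_information",
    "generalized_correlation",
    "build_network",
    "communities",
    "optimal_path",
    "path_physical_length",
]


@dataclass
class CorrelationMatrix:
    values: np.ndarray            # (N, N), symmetric
    flavor: str                   # "dccm" | "generalized"
    residue_labels: list

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if not np.allclose(v, v.T, atol=1e-10, equal_nan=True):
            raise ValueError("correlation matrix must be symmetric")
        self.values = v

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame(self.values, index=self.residue_labels,
                            columns=self.residue_labels)


@dataclass
class CommunityPartition:
    community_of: dict            # node -> community id
    modularity: float
    sizes: list


# ---------------------------------------------------------------------------
# correlation matrices
# ---------------------------------------------------------------------------

def dccm(ensemble: Ensemble, selection: Selection) -> CorrelationMatrix:
    """Dynamic cross-correlation matrix of displacement vectors.

    Rows/columns of atoms with zero positional variance are set to NaN (the
    correlation is undefined there); the diagonal is exactly 1 elsewhere.
    """
    if ensemble.n_frames < 2:
        raise ValueError("need >= 2 frames for a correlation matrix")
    sub = ensemble.subset(selection)
    d = sub - sub.mean(axis=0, keepdims=True)
    # <dr_i . dr_j> averaged over frames
    inner = np.einsum("fic,fjc->ij", d, d) / ensemble.n_frames
    var = np.diag(inner).copy()
    zero = var <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        C = inner / np.sqrt(np.outer(var, var))
    C[zero, :] = np.nan
    C[:, zero] = np.nan
    if zero.any():
        warnings.warn(f"{zero.sum()} zero-variance atoms; their correlations "
                      "are undefined (NaN)")
    ok = np.arange(len(var))[~zero]
    C[ok, ok] = 1.0
    top = ensemble.topology
    labels = [top.residue_label(i) for i in selection.indices]
    return CorrelationMatrix(C, "dccm", labels)


def mutual_information(x: np.ndarray, y: np.ndarray, k_neighbors: int = 6,
                       rng: Optional[np.random.Generator] = None) -> float:
    """KSG (algorithm 1) k-NN mutual information between two vector samples.

    ``x`` and ``y`` are (n, d) arrays of paired samples.  Uses the Chebyshev
    metric; exact duplicate points are jittered by 1e-10 with a warning.
    Returns a nonnegative estimate in nats.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[0] != y.shape[0]:
        raise ValueError("x and y must have the same number of samples")
    n = x.shape[0]
    if n < max(100, k_neighbors + 1):
        raise ValueError("need at least 100 paired samples")
    z = np.hstack([x, y])
    dist, _ = cKDTree(z).query(z, k=k_neighbors + 1, p=np.inf)
    eps = dist[:, -1]
    if np.any(eps == 0):
        warnings.warn("duplicate sample points; applying 1e-10 jitter")
        rng = rng or np.random.default_rng(0)
        jitter = 1e-10 * rng.standard_normal(z.shape)
        x = x + jitter[:, :x.shape[1]]
        y = y + jitter[:, x.shape[1]:]
        z = np.hstack([x, y])
        dist, _ = cKDTree(z).query(z, k=k_neighbors + 1, p=np.inf)
        eps = dist[:, -1]
    # strictly-less-than count, per KSG
    r = np.nextafter(eps, 0.0)
    nx_ = cKDTree(x).query_ball_point(x, r, p=np.inf, return_length=True) - 1
    ny_ = cKDTree(y).query_ball_point(y, r, p=np.inf, return_length=True) - 1
    mi = (digamma(k_neighbors) + digamma(n)
          - np.mean(digamma(nx_ + 1) + digamma(ny_ + 1)))
    return max(float(mi), 0.0)


def generalized_correlation(ensemble: Ensemble, selection: Selection,
                            k_neighbors: int = 6,
                            max_frames: int = 20000,
                            dimensionality: int = 3) -> CorrelationMatrix:
    """Mutual-information generalized correlation matrix.

    GC_ij = sqrt(1 - exp(-2 MI_ij / d)) with d = 3 for atomic fluctuation
    vectors; the diagonal is set to 1.  Frames beyond ``max_frames`` are
    subsampled uniformly (the KSG estimator cost grows with n log n per
    pair).
    """
    sub = ensemble.subset(selection)
    nf = sub.shape[0]
    if nf > max_frames:
        stride = int(np.ceil(nf / max_frames))
        sub = sub[::stride]
    d = sub - sub.mean(axis=0, keepdims=True)
    k = d.shape[1]
    G = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            mi = mutual_information(d[:, i, :], d[:, j, :], k_neighbors)
            G[i, j] = G[j, i] = np.sqrt(
                1.0 - np.exp(-2.0 * mi / dimensionality))
    top = ensemble.topology
    labels = [top.residue_label(i) for i in selection.indices]
    return CorrelationMatrix(G, "generalized", labels)


# ---------------------------------------------------------------------------
# dynamic network
# ---------------------------------------------------------------------------

def _residue_atoms(ensemble: Ensemble, heavy_only: bool = True) -> dict:
    """Map (chain, resid) -> atom indices, optionally heavy atoms only."""
    top = ensemble.topology
    out: dict = {}
    for i in range(top.n_atoms):
        if heavy_only and str(top.elements[i]).upper() == "H":
            continue
        out.setdefault((top.chainids[i], int(top.resids[i])), []).append(i)
    return out


def build_network(ensemble: Ensemble, corr: CorrelationMatrix,
                  node_selection: Selection,
                  contact_cutoff: float = 4.5, occupancy: float = 0.75,
                  exclude_adjacent: bool = True,
                  contact_mode: str = "heavy") -> nx.Graph:
    """Residue interaction network with -ln|C| edge weights.

    Nodes are the residues of ``node_selection`` (one atom per residue,
    typically Calpha), labeled by residue label.  An edge joins residues
    whose minimum heavy-atom distance (``contact_mode="heavy"``; or
    node-atom distance for ``"ca"``) is within ``contact_cutoff`` in at
    least ``occupancy`` of frames (boundary inclusive).  Qualifying pairs
    with |C| = 0 are dropped (infinite distance) with a warning; sequence
    neighbors (i, i+-1 on the same chain) are excluded by default.
    """
    idx = list(node_selection.indices)
    n = len(idx)
    if corr.values.shape != (n, n):
        raise ValueError("correlation matrix size does not match selection")
    top = ensemble.topology
    node_res = [(top.chainids[i], int(top.resids[i])) for i in idx]
    if contact_mode == "heavy":
        res_atoms = _residue_atoms(ensemble, heavy_only=True)
        atom_groups = [res_atoms.get(r, [i]) for r, i in zip(node_res, idx)]
    elif contact_mode == "ca":
        atom_groups = [[i] for i in idx]
    else:
        raise ValueError(f"unknown contact_mode {contact_mode!r}")

    contact_counts = np.zeros((n, n))
    group_of = {}
    flat = []
    for g, atoms in enumerate(atom_groups):
        for a in atoms:
            group_of[len(flat)] = g
            flat.append(a)
    flat = np.array(flat)
    for f in range(ensemble.n_frames):
        pos = ensemble.coordinates[f][flat]
        tree = cKDTree(pos)
        pairs = tree.query_pairs(contact_cutoff + 1e-9, output_type="ndarray")
        if len(pairs):
            gi = np.vectorize(group_of.get)(pairs[:, 0])
            gj = np.vectorize(group_of.get)(pairs[:, 1])
            mask = gi != gj
            seen = set(zip(np.minimum(gi[mask], gj[mask]).tolist(),
                           np.maximum(gi[mask], gj[mask]).tolist()))
            for a, b in seen:
                contact_counts[a, b] += 1
    G = nx.Graph()
    labels = corr.residue_labels
    mean_pos = ensemble.coordinates[:, idx, :].mean(axis=0)
    for a in range(n):
        G.add_node(labels[a], resid=node_res[a][1], chain=str(node_res[a][0]),
                   px=float(mean_pos[a][0]), py=float(mean_pos[a][1]),
                   pz=float(mean_pos[a][2]))
    nf = ensemble.n_frames
    for a in range(n):
        for b in range(a + 1, n):
            occ = contact_counts[a, b] / nf
            if occ + 1e-12 < occupancy:
                continue
            if exclude_adjacent and node_res[a][0] == node_res[b][0] \
                    and abs(node_res[a][1] - node_res[b][1]) == 1:
                continue
            c = abs(corr.values[a, b])
            if not np.isfinite(c) or c == 0.0:
                warnings.warn(f"edge {labels[a]}-{labels[b]} has |C|=0 or "
                              "undefined correlation; dropped")
                continue
            G.add_edge(labels[a], labels[b], weight=float(-np.log(c)),
                       occupancy=float(occ), correlation=float(corr.values[a, b]))
    return G


def communities(network: nx.Graph) -> CommunityPartition:
    """Girvan-Newman divisive community detection at maximum modularity.

    Iteratively removes the highest-edge-betweenness edge and returns the
    partition along the dendrogram (including the trivial one-community
    partition) that maximizes weighted modularity.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    base = [frozenset(c) for c in nx.connected_components(network)]
    best = base
    best_q = nx.community.modularity(network, base, weight="weight") \
        if network.number_of_edges() else 0.0
    def _heaviest_betweenness_edge(g):
        bet = nx.edge_betweenness_centrality(g, weight="weight")
        return max(bet, key=bet.get)

    if network.number_of_edges():
        for part in nx.community.girvan_newman(
                network, most_valuable_edge=_heaviest_betweenness_edge):
            q = nx.community.modularity(network, part, weight="weight")
            if q > best_q + 1e-12:
                best_q, best = q, [frozenset(c) for c in part]
    community_of = {}
    ordered = sorted(best, key=lambda c: (-len(c), sorted(map(str, c))))
    for cid, comm in enumerate(ordered):
        for node in comm:
            community_of[node] = cid
    return CommunityPartition(community_of, float(best_q),
                              [len(c) for c in ordered])


def optimal_path(network: nx.Graph, source, target):
    """Minimum-total-weight path between two residues (Dijkstra).

    Ties are broken by fewer hops, then lexicographic node order.  Returns
    ``(path_nodes, total_weight)``; a disconnected pair yields
    ``(None, inf)``.
    """
    if source not in network or target not in network:
        raise KeyError("source or target not in network")
    if source == target:
        return [source], 0.0
    # Dijkstra with lexicographic (weight, hops, path) priority; node labels
    # must be orderable (strings here), which makes the tie-break total
    heap = [(0.0, 0, (source,))]
    settled = set()
    while heap:
        w, hops, path = heapq.heappop(heap)
        node = path[-1]
        if node == target:
            return list(path), w
        if node in settled:
            continue
        settled.add(node)
        for nbr, attrs in network[node].items():
            if nbr not in settled:
                heapq.heappush(heap, (w + attrs["weight"], hops + 1,
                                      path + (nbr,)))
    return None, float("inf")


def path_physical_length(network: nx.Graph, path: Sequence) -> float:
    """Sum of mean Calpha-Calpha distances (A) along consecutive path nodes."""
    if path is None or len(path) < 2:
        return 0.0
    total = 0.0
    for a, b in zip(path[:-1], path[1:]):
        pa = np.array([network.nodes[a][k] for k in ("px", "py", "pz")])
        pb = np.array([network.nodes[b][k] for k in ("px", "py", "pz")])
        total += float(np.linalg.norm(pa - pb))
    return total
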