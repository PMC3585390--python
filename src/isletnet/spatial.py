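"""Distance-resolved analyses of functional networks.

Relates pairwise Euclidean distances between ROI centroids (µm) to pairwise
correlations and to network structure: 2-D (distance, correlation)
histograms, distance-binned average correlation, mean link lengths of hub
cells, and mean incident-link length as a function of local clustering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .graphmetrics import clustering_coefficients
from .network import CorrelationMatrix, FunctionalNetwork
from .traces import CellMap

__all__ = [
    "DistanceMatrix",
    "pairwise_distances",
    "hist2d_distance_correlation",
    "distance_binned_avg_correlation",
    "hub_link_lengths",
    "clustering_vs_link_length",
]

#: spec'd display defaults: 10-µm distance bins, 0.05-wide R bins, 0.1-wide C bins
DEFAULT_D_BIN_UM = 10.0
DEFAULT_R_BIN = 0.05
DEFAULT_C_BIN = 0.1


@dataclass
class DistanceMatrix:
    """Symmetric Euclidean distance matrix (µm) between ROI centroids."""

    l: np.ndarray
    cell_ids: list[int]

    def __post_init__(self) -> None:
        self.l = np.asarray(self.l, dtype=float)
        n = len(self.cell_ids)
        if self.l.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.l.shape} != ({n}, {n})")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def offdiag_values(self) -> np.ndarray:
        iu = np.triu_indices(self.n_cells, k=1)
        return self.l[iu]


def pairwise_distances(cells: CellMap, cell_ids=None) -> DistanceMatrix:
    """Euclidean distances ``l_ij`` between centroids, in µm."""
    ids = list(cell_ids) if cell_ids is not None else cells.cell_ids
    xy = cells.positions(ids)
    return DistanceMatrix(l=squareform(pdist(xy)), cell_ids=ids)


def _paired(dist: DistanceMatrix, corr: CorrelationMatrix) -> tuple[np.ndarray, np.ndarray]:
    if dist.cell_ids != corr.cell_ids:
        raise ValueError("distance and correlation matrices index different cells")
    return dist.offdiag_values(), corr.offdiag_values()


def hist2d_distance_correlation(
    dist: DistanceMatrix,
    corr: CorrelationMatrix,
    d_edges: np.ndarray | None = None,
    r_edges: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """2-D histogram of unordered cell pairs over (distance, correlation).

    Returns ``(counts, d_edges, r_edges, n_overflow)``; counts of in-range
    pairs plus the overflow count always total ``N(N-1)/2``.
    """
    l, r = _paired(dist, corr)
    if d_edges is None:
        top = max(l.max(), DEFAULT_D_BIN_UM)
        d_edges = np.arange(0.0, top + DEFAULT_D_BIN_UM, DEFAULT_D_BIN_UM)
    if r_edges is None:
        r_edges = np.arange(-1.0, 1.0 + DEFAULT_R_BIN / 2, DEFAULT_R_BIN)
    d_edges = np.asarray(d_edges, dtype=float)
    r_edges = np.asarray(r_edges, dtype=float)
    for e, name in ((d_edges, "d_edges"), (r_edges, "r_edges")):
        if np.any(np.diff(e) <= 0):
            raise ValueError(f"{name} must be strictly increasing")
    counts, _, _ = np.histogram2d(l, r, bins=(d_edges, r_edges))
    # pairs outside the binned range: conservation means counts + overflow
    # always totals N(N-1)/2
    n_overflow = int(l.size - counts.sum())
    return counts, d_edges, r_edges, n_overflow


def distance_binned_avg_correlation(
    dist: DistanceMatrix,
    corr: CorrelationMatrix,
    d_edges: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean ``R_ij`` of cell pairs per Euclidean-distance bin.

    Returns a DataFrame ``bin_center, mean_r, n_pairs``; bins with no pairs
    report ``mean_r = NaN`` (missing, not zero).
    """
    l, r = _paired(dist, corr)
    if d_edges is None:
        top = max(l.max(), DEFAULT_D_BIN_UM)
        d_edges = np.arange(0.0, top + DEFAULT_D_BIN_UM, DEFAULT_D_BIN_UM)
    d_edges = np.asarray(d_edges, dtype=float)
    idx = np.digitize(l, d_edges) - 1
    rows = []
    for b in range(d_edges.size - 1):
        mask = idx == b
        rows.append(
            {
                "bin_center": 0.5 * (d_edges[b] + d_edges[b + 1]),
                "mean_r": float(r[mask].mean()) if mask.any() else np.nan,
                "n_pairs": int(mask.sum()),
            }
        )
    return pd.DataFrame(rows)


def hub_link_lengths(
    net: FunctionalNetwork,
    dist: DistanceMatrix,
    top_fraction: float = 0.2,
) -> float:
    """Mean length of links incident to the most-connected cells.

    Hubs are the ``ceil(top_fraction * N)`` nodes of highest degree (ties
    broken by ascending cell id for determinism); the mean runs over edges
    with at least one hub endpoint, each edge counted once.  Returns NaN on
    an edgeless network.
    """
    if net.cell_ids != dist.cell_ids:
        raise ValueError("network and distance matrix index different cells")
    if net.n_edges == 0:
        return float("nan")
    n_hubs = math.ceil(top_fraction * net.n_nodes)
    deg = dict(net.graph.degree())
    order = sorted(net.cell_ids, key=lambda c: (-deg[c], c))
    hubs = set(order[:n_hubs])
    pos = {c: i for i, c in enumerate(dist.cell_ids)}
    lengths = [
        dist.l[pos[u], pos[v]]
        for u, v in net.graph.edges()
        if u in hubs or v in hubs
    ]
    return float(np.mean(lengths)) if lengths else float("nan")


def mean_link_length(net: FunctionalNetwork, dist: DistanceMatrix) -> float:
    """Mean Euclidean length over all links; NaN when edgeless."""
    if net.cell_ids != dist.cell_ids:
        raise ValueError("network and distance matrix index different cells")
    if net.n_edges == 0:
        return float("nan")
    pos = {c: i for i, c in enumerate(dist.cell_ids)}
    return float(np.mean([dist.l[pos[u], pos[v]] for u, v in net.graph.edges()]))


def clustering_vs_link_length(
    net: FunctionalNetwork,
    dist: DistanceMatrix,
    c_edges: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean incident-link length of cells grouped by local clustering.

    Per node of degree >= 1, the mean length of its incident links is
    computed; nodes are then binned by their clustering coefficient ``C_i``
    and the per-bin mean of node values reported.  Degree-0 nodes are
    excluded.  Returns ``bin_center, mean_link_length_um, n_cells``.
    """
    if net.cell_ids != dist.cell_ids:
        raise ValueError("network and distance matrix index different cells")
    if net.n_edges == 0:
        raise ValueError("network has no links")
    if c_edges is None:
        c_edges = np.arange(0.0, 1.0 + DEFAULT_C_BIN / 2, DEFAULT_C_BIN)
    c_edges = np.asarray(c_edges, dtype=float)
    ci, _ = clustering_coefficients(net)
    pos = {c: i for i, c in enumerate(dist.cell_ids)}
    node_c, node_len = [], []
    for u in net.cell_ids:
        nbrs = list(net.graph.neighbors(u))
        if not nbrs:
            continue
        node_c.append(ci[u])
        node_len.append(np.mean([dist.l[pos[u], pos[v]] for v in nbrs]))
    node_c = np.asarray(node_c)
    node_len = np.asarray(node_len)
    # right-closed top bin so C_i = 1 lands in the last bin
    idx = np.clip(np.digitize(node_c, c_edges) - 1, 0, c_edges.size - 2)
    rows = []
    for b in range(c_edges.size - 1):
        mask = idx == b
        rows.append(
            {
                "bin_center": 0.5 * (c_edges[b] + c_edges[b + 1]),
                "mean_link_length_um": float(node_len[mask].mean()) if mask.any() else np.nan,
                "n_cells": int(mask.sum()),
            }
        )
    return pd.DataFrame(rows)
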