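"""Correlation-threshold functional networks.

Two cells are declared functionally connected when the Pearson correlation
``R_ij`` of their fluorescence signals over a stated time window exceeds a
positive threshold ``R_th``.  The statistical significance of a given
``R_ij`` at ``n`` compared samples follows from the t statistic
``t = R*sqrt((n-2)/(1-R^2))``; inverting at the two-tailed critical t gives
the critical correlation ``R_crit = t_c/sqrt(n-2+t_c^2)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .traces import TraceSet

__all__ = [
    "CorrelationMatrix",
    "FunctionalNetwork",
    "pearson_matrix",
    "critical_r",
    "threshold_network",
    "average_correlation",
    "sliding_metrics",
]


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson matrix over one time window.

    ``constant_cells`` lists ids whose trace was constant in the window;
    their correlations are recorded as 0 rather than NaN so a single dead
    cell cannot abort an islet.
    """

    R: np.ndarray
    cell_ids: list[int]
    n_samples: int
    window: tuple[float, float] | None = None
    constant_cells: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        n = len(self.cell_ids)
        if self.R.shape != (n, n):
            raise ValueError(f"R shape {self.R.shape} does not match {n} cells")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def offdiag_values(self) -> np.ndarray:
        """R_ij over the N(N-1)/2 unordered off-diagonal pairs."""
        iu = np.triu_indices(self.n_cells, k=1)
        return self.R[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.R, index=self.cell_ids, columns=self.cell_ids)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="cell_id")


@dataclass
class FunctionalNetwork:
    """Thresholded undirected simple graph with edge weights ``R_ij``."""

    graph: nx.Graph
    r_th: float
    cell_ids: list[int]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def degrees(self) -> np.ndarray:
        """Node degrees in ``cell_ids`` order."""
        d = dict(self.graph.degree())
        return np.array([d[c] for c in self.cell_ids])

    @property
    def k_avg(self) -> float:
        return float(self.degrees.mean())

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"cell_i": u, "cell_j": v, "R_ij": w}
            for u, v, w in self.graph.edges(data="weight")
        ]
        return pd.DataFrame(rows, columns=["cell_i", "cell_j", "R_ij"])

    def to_csv(self, path) -> None:
        self.edge_table().to_csv(path, index=False)


def pearson_matrix(traces: TraceSet, window: tuple[float, float] | None = None) -> CorrelationMatrix:
    """Pearson correlation matrix of all cell pairs over the trace window.

    Requires at least 3 frames and 2 cells.  Constant traces yield
    undefined correlations, which are recorded as 0 and the cell flagged in
    ``constant_cells``.
    """
    if traces.n_frames < 3:
        raise ValueError(
            f"correlation window must span >= 3 frames, got {traces.n_frames}"
        )
    if traces.n_cells < 2:
        raise ValueError("need at least 2 cells")
    x = traces.values
    sd = x.std(axis=1)
    constant = sd == 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # corrcoef warns on zero variance
        R = np.corrcoef(x)
    R = np.where(np.isfinite(R), R, 0.0)
    if constant.any():
        R[constant, :] = 0.0
        R[:, constant] = 0.0
    np.fill_diagonal(R, 1.0)
    if window is None:
        window = (float(traces.times[0]), float(traces.times[-1]))
    return CorrelationMatrix(
        R=R,
        cell_ids=list(traces.cell_ids),
        n_samples=traces.n_frames,
        window=window,
        constant_cells=[c for c, f in zip(traces.cell_ids, constant) if f],
    )


def critical_r(n: int, p: float = 0.001) -> float:
    """Critical Pearson correlation at two-tailed significance ``p``.

    Inverts ``t = R*sqrt((n-2)/(1-R^2))`` at the critical t for ``n-2``
    degrees of freedom: ``R_crit = t_c/sqrt(n-2+t_c^2)``.  Strictly
    decreasing in ``n``.
    """
    n = int(n)
    if n < 3:
        raise ValueError("need n >= 3 samples")
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie in (0, 1)")
    t_c = stats.t.ppf(1.0 - p / 2.0, df=n - 2)
    return float(t_c / np.sqrt(n - 2 + t_c**2))


def threshold_network(
    corr: CorrelationMatrix, r_th: float, p: float = 0.001
) -> FunctionalNetwork:
    """Threshold a correlation matrix into a simple undirected graph.

    An edge joins ``(i, j)`` iff ``R_ij > r_th`` (strict); isolated nodes
    are retained.  ``r_th`` must be positive; a warning is issued when it
    falls below the significance cutoff :func:`critical_r` at level ``p``.
    """
    if r_th <= 0:
        raise ValueError("the correlation threshold must be positive")
    if corr.n_samples >= 3 and r_th < critical_r(corr.n_samples, p):
        warnings.warn(
            f"R_th={r_th:g} is below the p<{p:g} significance cutoff "
            f"{critical_r(corr.n_samples, p):.3f} at n={corr.n_samples}",
            stacklevel=2,
        )
    g = nx.Graph()
    g.add_nodes_from(corr.cell_ids)
    n = corr.n_cells
    iu, ju = np.triu_indices(n, k=1)
    keep = corr.R[iu, ju] > r_th
    g.add_weighted_edges_from(
        (corr.cell_ids[i], corr.cell_ids[j], float(corr.R[i, j]))
        for i, j in zip(iu[keep], ju[keep])
    )
    return FunctionalNetwork(graph=g, r_th=float(r_th), cell_ids=list(corr.cell_ids))


def average_correlation(corr: CorrelationMatrix) -> float:
    """Mean ``R_ij`` over all unordered off-diagonal pairs."""
    if corr.n_cells < 2:
        raise ValueError("need at least 2 cells")
    return float(corr.offdiag_values().mean())


def sliding_metrics(
    traces: TraceSet,
    window_s: float,
    step_s: float | None = None,
    r_th: float = 0.75,
    metrics: tuple[str, ...] = ("r_avg", "k_avg", "c_avg", "e_glob"),
) -> pd.DataFrame:
    """Network metrics on sliding correlation windows.

    Windows of length ``window_s`` start at multiples of ``step_s``
    (default: non-overlapping, ``step_s = window_s``) from the first frame;
    only complete windows are evaluated (no padding beyond the trace end).
    Timestamps are window centres.

    Returns a DataFrame with ``t_center`` plus one column per requested
    metric among ``r_avg`` (all-pairs mean correlation), ``k_avg``,
    ``c_avg`` and ``e_glob`` (computed on the graph thresholded at
    ``r_th``).
    """
    from . import graphmetrics

    if step_s is None:
        step_s = window_s
    min_window = 3.0 * traces.frame_interval_s
    if window_s < min_window:
        raise ValueError(
            f"window must span >= 3 frames ({min_window:g} s at this rate)"
        )
    if step_s > window_s:
        raise ValueError("step_s must not exceed window_s")
    known = {"r_avg", "k_avg", "c_avg", "e_glob"}
    unknown = set(metrics) - known
    if unknown:
        raise ValueError(f"unknown metric(s) {sorted(unknown)}; choose from {sorted(known)}")

    t0 = float(traces.times[0])
    total = traces.n_frames * traces.frame_interval_s
    n_windows = int(np.floor((total - window_s) / step_s + 1e-9)) + 1
    rows = []
    for w in range(max(n_windows, 0)):
        start = t0 + w * step_s
        sl = traces.slice_time(start, start + window_s)
        corr = pearson_matrix(sl)
        row: dict[str, float] = {"t_center": start + window_s / 2.0}
        net = None
        if {"k_avg", "c_avg", "e_glob"} & set(metrics):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                net = threshold_network(corr, r_th)
        if "r_avg" in metrics:
            row["r_avg"] = average_correlation(corr)
        if "k_avg" in metrics:
            row["k_avg"] = net.k_avg
        if "c_avg" in metrics:
            row["c_avg"] = graphmetrics.clustering_coefficients(net)[1]
        if "e_glob" in metrics:
            row["e_glob"] = graphmetrics.global_efficiency(net)
        rows.append(row)
    return pd.DataFrame(rows, columns=["t_center", *metrics])
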