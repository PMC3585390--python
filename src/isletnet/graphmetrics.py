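"""Graph-theoretic characterization of functional networks.

Segregation is measured by the average clustering coefficient ``C_avg``,
integration by the global efficiency ``E_glob`` (mean inverse shortest-path
length, Latora-Marchiori form, so disconnected pairs contribute zero).
Both are referenced against a uniform random graph with the same number of
nodes and links; the small-world-ness
``S = (C_avg/C_rand) / (E_rand/E_glob)`` exceeds 1 for networks that are
more clustered than a matched random graph at comparable integration.

Degree structure is summarised by the cumulative distribution
``G(k) = P(degree >= k)`` on degrees normalized per islet by ``k_max``,
and characterised by least-squares fits (in log space) of a power law, an
exponential decay and an exponentially truncated power law.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .network import FunctionalNetwork

__all__ = [
    "NetworkSummary",
    "DegreeDistribution",
    "DegreeFitResult",
    "clustering_coefficients",
    "global_efficiency",
    "random_reference",
    "small_worldness",
    "small_worldness_from_ratios",
    "cumulative_degree_distribution",
    "fit_degree_models",
]


def _as_graph(net: FunctionalNetwork | nx.Graph) -> nx.Graph:
    return net.graph if isinstance(net, FunctionalNetwork) else net


def clustering_coefficients(
    net: FunctionalNetwork | nx.Graph,
) -> tuple[dict, float]:
    """Per-node clustering ``C_i`` and network mean ``C_avg``.

    ``C_i`` is the number of existing links among the neighbors of node i
    divided by the number of possible ones; nodes of degree < 2 have
    ``C_i = 0`` and are included in the average, which keeps ``C_avg``
    defined on sparse low-glucose networks.
    """
    g = _as_graph(net)
    ci = nx.clustering(g)
    c_avg = float(np.mean(list(ci.values()))) if ci else 0.0
    return ci, c_avg


def global_efficiency(net: FunctionalNetwork | nx.Graph) -> float:
    """Mean inverse shortest-path length over all ordered node pairs.

    ``E_glob = (1/(N(N-1))) * sum_{i != j} 1/d_ij`` with ``1/inf = 0`` for
    disconnected pairs; equals 1 on a complete graph and 0 on an edgeless
    one.
    """
    g = _as_graph(net)
    if g.number_of_nodes() < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    return float(nx.global_efficiency(g))


def random_reference(
    n_nodes: int,
    n_edges: int,
    n_realizations: int = 100,
    seed: int | None = 0,
) -> tuple[float, float]:
    """``(C_rand, E_rand)`` of the uniform fixed-edge-count random graph.

    Averages ``C_avg`` and ``E_glob`` over ``n_realizations`` G(n, m)
    graphs with exactly ``n_nodes`` nodes and ``n_edges`` edges (same
    number of nodes, links and mean degree as the network of interest).
    Deterministic given ``seed``.
    """
    max_edges = n_nodes * (n_nodes - 1) // 2
    if not 0 <= n_edges <= max_edges:
        raise ValueError(
            f"edge count {n_edges} infeasible for {n_nodes} nodes "
            f"(max {max_edges})"
        )
    if n_realizations < 1:
        raise ValueError("need at least one realization")
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    # degenerate densities need no sampling
    if n_edges == max_edges:
        return 1.0, 1.0
    if n_edges == 0:
        return 0.0, 0.0
    rng = np.random.default_rng(seed)
    c_vals = np.empty(n_realizations)
    e_vals = np.empty(n_realizations)
    for k in range(n_realizations):
        g = nx.gnm_random_graph(n_nodes, n_edges, seed=int(rng.integers(2**31)))
        c_vals[k] = clustering_coefficients(g)[1]
        e_vals[k] = global_efficiency(g)
    return float(c_vals.mean()), float(e_vals.mean())


@dataclass
class NetworkSummary:
    """Per-regime scalar metrics of one functional network."""

    regime: str = ""
    r_avg: float = np.nan
    k_avg: float = np.nan
    c_avg: float = np.nan
    e_glob: float = np.nan
    c_rand: float = np.nan
    e_rand: float = np.nan
    clustering_ratio: float = np.nan
    efficiency_ratio: float = np.nan
    s: float = np.nan
    mean_link_length_um: float = np.nan
    hub_link_length_um: float = np.nan
    degenerate: bool = False

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def small_worldness(
    c_avg: float, e_glob: float, c_rand: float, e_rand: float
) -> NetworkSummary:
    """Small-world-ness from a network's metrics and its random reference.

    ``clustering_ratio = C_avg/C_rand``, ``efficiency_ratio =
    E_rand/E_glob`` and ``S`` is their ratio.  Zero denominators flag the
    result as degenerate (NaN ratios) instead of returning infinities.
    """
    out = NetworkSummary(
        c_avg=float(c_avg), e_glob=float(e_glob),
        c_rand=float(c_rand), e_rand=float(e_rand),
    )
    if c_rand <= 0 or e_glob <= 0:
        out.degenerate = True
        return out
    out.clustering_ratio = float(c_avg / c_rand)
    out.efficiency_ratio = float(e_rand / e_glob)
    if out.efficiency_ratio == 0:
        out.degenerate = True
        return out
    out.s = out.clustering_ratio / out.efficiency_ratio
    return out


def small_worldness_from_ratios(
    clustering_ratio: float, efficiency_ratio: float
) -> float:
    """``S`` directly from the two ratios (e.g. values read off a summary table)."""
    if efficiency_ratio == 0:
        raise ValueError("efficiency ratio must be nonzero")
    return float(clustering_ratio) / float(efficiency_ratio)


@dataclass
class DegreeDistribution:
    """Cumulative distribution ``G(x) = P(k/k_max >= x)`` on normalized degree.

    ``curves`` holds the per-islet curves on the common ``grid``; ``G`` is
    their mean when pooled (a single islet pools trivially with itself).
    """

    grid: np.ndarray
    G: np.ndarray
    curves: np.ndarray  # (n_islets, n_grid)
    pooled: bool = False
    excluded_islets: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k_over_kmax": self.grid, "G": self.G})


def _single_curve(degrees: np.ndarray, grid: np.ndarray) -> np.ndarray:
    kmax = degrees.max()
    x = degrees / kmax
    return np.array([np.mean(x >= g - 1e-12) for g in grid])


def cumulative_degree_distribution(
    nets: FunctionalNetwork | nx.Graph | list,
    grid: np.ndarray | None = None,
) -> DegreeDistribution:
    """Cumulative degree distribution, per islet or pooled over islets.

    Degrees are normalized per islet by that islet's maximal degree
    ``k_max`` before pooling; the pooled curve is the mean of the per-islet
    curves evaluated on a common normalized-degree grid (default: 20
    points evenly spaced on (0, 1]; weak inequality in ``G``).  Islets
    with an empty edge set (``k_max = 0``) are excluded with a warning.
    """
    many = isinstance(nets, (list, tuple))
    net_list = list(nets) if many else [nets]
    degree_sets: list[np.ndarray] = []
    excluded: list[int] = []
    for idx, net in enumerate(net_list):
        g = _as_graph(net)
        deg = np.array([d for _, d in g.degree()], dtype=float)
        if deg.size == 0:
            raise ValueError("network has no nodes")
        if deg.max() == 0:
            warnings.warn(f"islet {idx}: empty graph (k_max=0), excluded", stacklevel=2)
            excluded.append(idx)
            continue
        degree_sets.append(deg)
    if not degree_sets:
        raise ValueError("all networks have empty edge sets")
    if grid is None:
        grid = np.linspace(0.05, 1.0, 20)
    grid = np.asarray(grid, dtype=float)
    curves = np.vstack([_single_curve(d, grid) for d in degree_sets])
    return DegreeDistribution(
        grid=grid,
        G=curves.mean(axis=0),
        curves=curves,
        pooled=many,
        excluded_islets=excluded,
    )


@dataclass
class DegreeFitResult:
    """Least-squares fit of one decay model to a cumulative distribution."""

    model: str  # power_law | exponential | truncated_power_law
    amplitude: float
    alpha: float  # power-law exponent (0 for pure exponential)
    kappa: float  # exponential cutoff scale (inf for pure power law)
    r2: float
    best: bool = False


def fit_degree_models(dist: DegreeDistribution) -> list[DegreeFitResult]:
    """Fit power-law, exponential and truncated power-law models to ``G``.

    Models ``A*x^-alpha``, ``A*exp(-x/kappa)`` and ``A*x^-alpha*
    exp(-x/kappa)`` are fitted on points with ``G > 0`` in log-G space,
    where all three are linear in their parameters; ``r^2`` is the
    coefficient of determination on the fitted (log) scale and exactly one
    model is marked best (highest ``r^2``).
    """
    mask = dist.G > 0
    x = dist.grid[mask]
    y = np.log(dist.G[mask])
    if x.size < 5:
        raise ValueError(f"need >= 5 grid points with G > 0, got {x.size}")
    logx = np.log(x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    # a constant curve (all connected nodes at k_max) is fitted exactly by
    # any of the models; r^2 is 1 by convention rather than 0/0
    degenerate_tot = ss_tot <= 1e-10 * x.size

    designs = {
        "power_law": np.column_stack([np.ones_like(x), -logx]),
        "exponential": np.column_stack([np.ones_like(x), -x]),
        "truncated_power_law": np.column_stack([np.ones_like(x), -logx, -x]),
    }
    results: list[DegreeFitResult] = []
    for model, X in designs.items():
        try:
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ coef
            ss_res = float(np.sum(resid**2))
            r2 = 1.0 if degenerate_tot else 1.0 - ss_res / ss_tot
            amp = float(np.exp(coef[0]))
            if model == "power_law":
                alpha, kappa = float(coef[1]), np.inf
            elif model == "exponential":
                alpha, kappa = 0.0, float(1.0 / coef[1]) if coef[1] != 0 else np.inf
            else:
                alpha = float(coef[1])
                kappa = float(1.0 / coef[2]) if coef[2] != 0 else np.inf
            results.append(
                DegreeFitResult(model=model, amplitude=amp, alpha=alpha, kappa=kappa, r2=r2)
            )
        except np.linalg.LinAlgError:
            results.append(
                DegreeFitResult(model=model, amplitude=np.nan, alpha=np.nan,
                                kappa=np.nan, r2=np.nan)
            )
    finite = [r for r in results if np.isfinite(r.r2)]
    if finite:
        best = max(finite, key=lambda r: r.r2)
        best.best = True
    return results
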