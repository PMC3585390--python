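"""Model objects tying the analysis chain together.

:class:`IsletFunctionalConnectivity` is built from one islet's data (raw
traces, ROI positions, stimulation schedule); ``fit()`` conditions the
traces, classifies beta cells, and extracts the per-regime correlation
matrices, thresholded networks, graph metrics and spatial measures into an
:class:`IsletConnectivityResults`.

:class:`IsletStudy` aggregates several islets: ``fit()`` produces medians
and ranges per regime and metric, pooled cumulative degree distributions
with their three-model fits, and the paired regime-comparison statistics
(Friedman, then Wilcoxon signed-rank with Bonferroni correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import graphmetrics, network, preprocess, spatial
from .schedule import RegimeSchedule
from .simulate import SimParams, simulate_islet
from .traces import CellMap, TraceSet

__all__ = [
    "IsletFunctionalConnectivity",
    "IsletConnectivityResults",
    "IsletStudy",
    "StudyResults",
    "compare_regimes",
    "simulate_study",
]

#: regimes entering small-world analysis, degree fits and statistics; the
#: driven ON/OFF transients give near-complete graphs whose random-reference
#: ratios are degenerate
ANALYSIS_REGIMES = ("LG1", "HG", "LG2")

#: metrics compared across regimes in the study statistics
STUDY_METRICS = (
    "r_avg",
    "mean_link_length_um",
    "k_avg",
    "c_avg",
    "e_glob",
    "hub_link_length_um",
)

REGIME_PAIRS = (("LG1", "HG"), ("HG", "LG2"), ("LG1", "LG2"))


class IsletFunctionalConnectivity:
    """Functional-connectivity model of a single islet recording.

    Parameters
    ----------
    traces : TraceSet
        Raw fluorescence traces (stage ``raw``).
    cells : CellMap
        ROI centroid positions in µm.
    schedule : RegimeSchedule
        Named stimulation regimes; must contain LG1/ON/HG/OFF/LG2.
    r_th : float
        Correlation threshold for network extraction (default 0.75).
    p_level : float
        Significance level backing the threshold sanity check.
    criteria : ClassifyCriteria, optional
        Beta-cell classification thresholds.
    """

    def __init__(
        self,
        traces: TraceSet,
        cells: CellMap,
        schedule: RegimeSchedule | None = None,
        r_th: float = 0.75,
        p_level: float = 0.001,
        criteria: preprocess.ClassifyCriteria | None = None,
    ):
        self.traces = traces
        self.cells = cells
        self.schedule = schedule or RegimeSchedule.default()
        self.r_th = float(r_th)
        self.p_level = float(p_level)
        self.criteria = criteria
        missing = sorted(set(traces.cell_ids) - set(cells.cell_ids))
        if missing:
            raise ValueError(f"traced cell(s) missing from position table: {missing}")

    @classmethod
    def from_fixture(cls, path, **kwargs) -> "IsletFunctionalConnectivity":
        from .simulate import read_fixture

        traces, cells, schedule = read_fixture(path)
        return cls(traces, cells, schedule, **kwargs)

    def fit(self, n_random: int = 100, seed: int = 0) -> "IsletConnectivityResults":
        """Run the full per-islet analysis.

        ``n_random`` and ``seed`` control the random-graph reference used
        for the small-world ratios.
        """
        caught: list[str] = []
        corrected = preprocess.correct_bleaching(self.traces, self.schedule)
        normalized = preprocess.f_over_f0(corrected, self.schedule)
        labels = preprocess.classify_cells(normalized, self.schedule, self.criteria)
        beta_ids = [int(c) for c in labels.loc[labels.label == "beta", "cell_id"]]
        if len(beta_ids) < 3:
            raise ValueError(
                f"only {len(beta_ids)} beta cells classified; need at least 3"
            )
        unit = preprocess.rescale_unit(normalized.select_cells(beta_ids))
        dist = spatial.pairwise_distances(self.cells, beta_ids)

        summaries: dict[str, graphmetrics.NetworkSummary] = {}
        correlations: dict[str, network.CorrelationMatrix] = {}
        networks: dict[str, network.FunctionalNetwork] = {}
        for regime in self.schedule.names:
            sl = preprocess.segment(unit, self.schedule, regime)
            corr = network.pearson_matrix(
                sl, window=(self.schedule[regime].t_start_s, self.schedule[regime].t_end_s)
            )
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                net = network.threshold_network(corr, self.r_th, p=self.p_level)
            caught.extend(str(w.message) for w in wlist)
            correlations[regime] = corr
            networks[regime] = net

            _, c_avg = graphmetrics.clustering_coefficients(net)
            e_glob = graphmetrics.global_efficiency(net)
            if regime in ANALYSIS_REGIMES:
                c_rand, e_rand = graphmetrics.random_reference(
                    net.n_nodes, net.n_edges, n_realizations=n_random, seed=seed
                )
                summ = graphmetrics.small_worldness(c_avg, e_glob, c_rand, e_rand)
            else:
                summ = graphmetrics.NetworkSummary(c_avg=c_avg, e_glob=e_glob)
            summ.regime = regime
            summ.r_avg = network.average_correlation(corr)
            summ.k_avg = net.k_avg
            summ.mean_link_length_um = spatial.mean_link_length(net, dist)
            summ.hub_link_length_um = spatial.hub_link_lengths(net, dist)
            summaries[regime] = summ

        return IsletConnectivityResults(
            model=self,
            labels=labels,
            beta_ids=beta_ids,
            unit_traces=unit,
            distances=dist,
            correlations=correlations,
            networks=networks,
            summaries=summaries,
            warnings_=caught,
        )


@dataclass
class IsletConnectivityResults:
    """Fitted per-islet functional-connectivity results."""

    model: IsletFunctionalConnectivity
    labels: pd.DataFrame
    beta_ids: list[int]
    unit_traces: TraceSet
    distances: spatial.DistanceMatrix
    correlations: dict[str, network.CorrelationMatrix]
    networks: dict[str, network.FunctionalNetwork]
    summaries: dict[str, graphmetrics.NetworkSummary]
    warnings_: list[str] = field(default_factory=list)

    @property
    def n_beta(self) -> int:
        return len(self.beta_ids)

    def summary_frame(self) -> pd.DataFrame:
        """One row per regime with all scalar network metrics."""
        rows = [s.as_dict() for s in self.summaries.values()]
        return pd.DataFrame(rows).set_index("regime")

    def sliding_metrics(
        self,
        window_s: float = 100.0,
        step_s: float | None = None,
        metrics: tuple[str, ...] = ("r_avg", "k_avg", "c_avg", "e_glob"),
    ) -> pd.DataFrame:
        """Sliding-window evolution of the requested metrics."""
        return network.sliding_metrics(
            self.unit_traces, window_s, step_s, r_th=self.model.r_th, metrics=metrics
        )

    def degree_distribution(self, regime: str) -> graphmetrics.DegreeDistribution:
        return graphmetrics.cumulative_degree_distribution(self.networks[regime])

    def distance_binned_correlation(self, regime: str, d_edges=None) -> pd.DataFrame:
        return spatial.distance_binned_avg_correlation(
            self.distances, self.correlations[regime], d_edges
        )

    def hist2d(self, regime: str, d_edges=None, r_edges=None):
        return spatial.hist2d_distance_correlation(
            self.distances, self.correlations[regime], d_edges, r_edges
        )

    def clustering_vs_link_length(self, regime: str, c_edges=None) -> pd.DataFrame:
        return spatial.clustering_vs_link_length(
            self.networks[regime], self.distances, c_edges
        )

    def summary(self) -> str:
        df = self.summary_frame()
        lines = [
            "Islet functional connectivity",
            "=" * 64,
            f"cells traced: {self.model.traces.n_cells}   "
            f"beta: {self.n_beta}   R_th: {self.model.r_th:g}",
            "",
            df.drop(columns=["degenerate"]).round(4).to_string(),
        ]
        if self.warnings_:
            lines += ["", "warnings:"] + [f"  - {w}" for w in self.warnings_]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# multi-islet study
# ---------------------------------------------------------------------------

def compare_regimes(
    per_islet: pd.DataFrame,
    regimes: tuple[str, str, str] = ANALYSIS_REGIMES,
    alpha: float = 0.05,
    on_incomplete: str = "error",
) -> pd.DataFrame:
    """Friedman + post-hoc Wilcoxon comparison of regimes across islets.

    ``per_islet`` is a long DataFrame with columns ``metric, islet, regime,
    value`` holding one value per (metric, islet, regime); the design is
    paired, so every islet must have all three regimes.  Per metric, a
    Friedman test runs across the three regimes; the three pairwise
    Wilcoxon signed-rank tests (exact distribution at small n) are always
    computed but flagged ``posthoc_licensed`` only when the Friedman p is
    below ``alpha``.  Significance flags use the Bonferroni threshold
    ``alpha/3``.

    The design is paired; a missing (islet, regime) value raises by
    default.  With ``on_incomplete="skip"`` such a metric is reported with
    NaN p-values instead (e.g. mean link length of an islet whose
    low-glucose network has no edges).
    """
    required = {"metric", "islet", "regime", "value"}
    if missing := required - set(per_islet.columns):
        raise ValueError(f"per_islet table missing columns {sorted(missing)}")
    bonf = alpha / len(REGIME_PAIRS)
    rows = []
    for metric, grp in per_islet.groupby("metric", sort=False):
        pivot = grp.pivot(index="islet", columns="regime", values="value")
        if any(r not in pivot.columns for r in regimes) or pivot[list(regimes)].isna().any().any():
            if on_incomplete == "skip":
                for a, b in REGIME_PAIRS:
                    rows.append(
                        {
                            "metric": metric,
                            "comparison": f"{a}-{b}",
                            "friedman_p": np.nan,
                            "wilcoxon_p": np.nan,
                            "significant": False,
                            "posthoc_licensed": False,
                        }
                    )
                continue
            raise ValueError(
                f"metric {metric!r}: paired design requires a value for every "
                "islet and regime"
            )
        cols = [pivot[r].to_numpy() for r in regimes]
        if all(np.allclose(c, cols[0]) for c in cols[1:]):
            friedman_p = 1.0  # no differences anywhere
        else:
            try:
                _, friedman_p = sstats.friedmanchisquare(*cols)
            except ValueError:
                friedman_p = 1.0
        licensed = bool(friedman_p < alpha)
        for a, b in REGIME_PAIRS:
            x, y = pivot[a].to_numpy(), pivot[b].to_numpy()
            d = x - y
            if np.all(d == 0):
                p = 1.0
            else:
                method = "exact" if d.size <= 25 and not np.any(d == 0) else "auto"
                _, p = sstats.wilcoxon(x, y, alternative="two-sided", method=method)
            rows.append(
                {
                    "metric": metric,
                    "comparison": f"{a}-{b}",
                    "friedman_p": float(friedman_p),
                    "wilcoxon_p": float(p),
                    "significant": bool(p < bonf),
                    "posthoc_licensed": licensed,
                }
            )
    return pd.DataFrame(rows)


def simulate_study(
    n_islets: int = 9,
    seed: int = 0,
    n_cells_range: tuple[int, int] = (45, 80),
    **param_overrides,
) -> list[tuple[TraceSet, CellMap, RegimeSchedule]]:
    """Simulate a multi-islet study (per-islet seeds derived from ``seed``).

    Cell counts vary per islet within ``n_cells_range``, mirroring islets
    of different sizes; wave speed is drawn independently per islet.
    """
    if n_islets < 1:
        raise ValueError("need at least one islet")
    rng = np.random.default_rng([int(seed), 2])
    out = []
    for k in range(n_islets):
        n_cells = int(rng.integers(n_cells_range[0], n_cells_range[1] + 1))
        params = SimParams(
            n_cells=n_cells,
            seed=int(rng.integers(2**31 - 1)),
            **param_overrides,
        )
        traces, geom = simulate_islet(params)
        out.append((traces, geom.cells, params.schedule))
    return out


class IsletStudy:
    """Multi-islet study over a common stimulation protocol.

    Built from a list of :class:`IsletFunctionalConnectivity` models (or
    ``(traces, cells, schedule)`` tuples); requires at least 2 islets.
    """

    def __init__(self, islets, r_th: float = 0.75, **model_kwargs):
        models = []
        for item in islets:
            if isinstance(item, IsletFunctionalConnectivity):
                models.append(item)
            else:
                traces, cells, schedule = item
                models.append(
                    IsletFunctionalConnectivity(
                        traces, cells, schedule, r_th=r_th, **model_kwargs
                    )
                )
        if len(models) < 2:
            raise ValueError("a study needs at least 2 islets")
        self.models = models

    @classmethod
    def simulate(
        cls, n_islets: int = 9, seed: int = 0, r_th: float = 0.75, **param_overrides
    ) -> "IsletStudy":
        return cls(simulate_study(n_islets, seed, **param_overrides), r_th=r_th)

    def fit(self, n_random: int = 100, seed: int = 0) -> "StudyResults":
        rng = np.random.default_rng([int(seed), 3])
        islet_results = [
            m.fit(n_random=n_random, seed=int(rng.integers(2**31 - 1)))
            for m in self.models
        ]
        frames = []
        for i, res in enumerate(islet_results):
            df = res.summary_frame().reset_index()
            df.insert(0, "islet", i)
            frames.append(df)
        per_islet_wide = pd.concat(frames, ignore_index=True)

        long = per_islet_wide.melt(
            id_vars=["islet", "regime"], var_name="metric", value_name="value"
        )
        long = long[long.metric != "degenerate"]
        long = long.assign(value=long.value.astype(float))

        agg_source = long[long.regime.isin(ANALYSIS_REGIMES)].dropna(subset=["value"])
        aggregate = (
            agg_source.groupby(["metric", "regime"])["value"]
            .agg(median="median", min="min", max="max")
            .reset_index()
        )

        stats_table = compare_regimes(
            long[
                long.metric.isin(STUDY_METRICS) & long.regime.isin(ANALYSIS_REGIMES)
            ].reset_index(drop=True),
            on_incomplete="skip",
        )

        degree_distributions = {}
        degree_fits = {}
        for regime in ANALYSIS_REGIMES:
            nets = [res.networks[regime] for res in islet_results]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dist = graphmetrics.cumulative_degree_distribution(nets)
            degree_distributions[regime] = dist
            degree_fits[regime] = graphmetrics.fit_degree_models(dist)

        return StudyResults(
            study=self,
            islet_results=islet_results,
            per_islet=per_islet_wide,
            aggregate=aggregate,
            stats=stats_table,
            degree_distributions=degree_distributions,
            degree_fits=degree_fits,
        )


@dataclass
class StudyResults:
    """Aggregated multi-islet results: medians, statistics, degree fits."""

    study: IsletStudy
    islet_results: list[IsletConnectivityResults]
    per_islet: pd.DataFrame
    aggregate: pd.DataFrame
    stats: pd.DataFrame
    degree_distributions: dict[str, graphmetrics.DegreeDistribution]
    degree_fits: dict[str, list[graphmetrics.DegreeFitResult]]

    @property
    def n_islets(self) -> int:
        return len(self.islet_results)

    def median(self, metric: str, regime: str) -> float:
        sel = self.aggregate[
            (self.aggregate.metric == metric) & (self.aggregate.regime == regime)
        ]
        if sel.empty:
            raise KeyError(f"no aggregate for metric={metric!r}, regime={regime!r}")
        return float(sel["median"].iloc[0])

    def table1(self) -> pd.DataFrame:
        """Small-world summary: medians of per-islet values and ratios.

        Ratios and S are medianized over per-islet ratios (not ratios of
        medians), one row per analysis regime.  A quantity undefined in
        every islet of a regime (e.g. ratios when all its networks are
        empty) is reported as NaN.
        """
        cols = [
            "c_avg", "e_glob", "c_rand", "e_rand",
            "clustering_ratio", "efficiency_ratio", "s",
        ]
        rows = {}
        for regime in ANALYSIS_REGIMES:
            row = {}
            for c in cols:
                try:
                    row[c] = self.median(c, regime)
                except KeyError:
                    row[c] = np.nan
            rows[regime] = row
        return pd.DataFrame.from_dict(rows, orient="index")[cols]

    def degree_fits_frame(self) -> pd.DataFrame:
        rows = []
        for regime, fits in self.degree_fits.items():
            for f in fits:
                rows.append(
                    {
                        "regime": regime,
                        "model": f.model,
                        "amplitude": f.amplitude,
                        "alpha": f.alpha,
                        "kappa": f.kappa,
                        "r2": f.r2,
                        "best": f.best,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Islet functional-connectivity study ({self.n_islets} islets, "
            f"R_th={self.study.models[0].r_th:g})",
            "=" * 72,
            "",
            "Median metrics per regime (min-max across islets in aggregate table):",
            self.table1().round(3).to_string(),
            "",
            "Regime comparisons (Friedman + Wilcoxon signed-rank, "
            "Bonferroni at 0.05/3):",
            self.stats.round(4).to_string(index=False),
            "",
            "Cumulative degree-distribution fits (log-space least squares):",
            self.degree_fits_frame().round(4).to_string(index=False),
        ]
        return "\n".join(lines)

    def save(self, outdir) -> dict:
        """Write summary.csv, table1.csv, stats.csv, degree_fits.csv."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "summary": out / "summary.csv",
            "table1": out / "table1.csv",
            "stats": out / "stats.csv",
            "degree_fits": out / "degree_fits.csv",
        }
        self.per_islet.to_csv(paths["summary"], index=False)
        self.table1().to_csv(paths["table1"], index_label="regime")
        self.stats.to_csv(paths["stats"], index=False)
        self.degree_fits_frame().to_csv(paths["degree_fits"], index=False)
        return {k: str(v) for k, v in paths.items()}
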