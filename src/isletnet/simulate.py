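"""Synthetic islet geometries and calcium-fluorescence traces.

The generator emulates the statistical structure of multicellular calcium
imaging in an islet of Langerhans under a glucose step protocol:

* beta cells sit quietly at baseline in low (6 mM) glucose;
* on stimulation (12 mM) each cell rises sigmoidally to a plateau with its
  own onset delay (up to a few tens of seconds);
* during the high-glucose plateau every beta cell oscillates at a common
  frequency, with phases lagging in proportion to the distance from a wave
  source (a traveling calcium wave with a per-realization speed drawn from
  a broad distribution);
* on glucose withdrawal cells fall back to baseline, more synchronously
  than they activated;
* non-beta cells (alpha/delta-like, confined to the islet periphery)
  oscillate in low glucose instead, exercising the beta-cell classifier;
* the whole record is multiplied by a linear-plus-exponential
  photobleaching drift and carries i.i.d. Gaussian imaging noise.

Everything is deterministic given ``SimParams.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schedule import RegimeSchedule
from .traces import CellMap, TraceSet

__all__ = [
    "SimParams",
    "IsletGeometry",
    "PackingError",
    "generate_geometry",
    "simulate_traces",
    "simulate_islet",
    "write_fixture",
    "read_fixture",
]


class PackingError(RuntimeError):
    """Raised when the requested cell count cannot be packed into the islet."""


@dataclass
class SimParams:
    """Parameters of one simulated islet recording.

    Distances in µm, times in seconds, fluorescence in arbitrary units with
    the per-cell baseline near ``baseline_f``.
    """

    n_cells: int = 60
    cell_diameter_um: float = 20.0
    frame_rate_hz: float = 0.5
    schedule: RegimeSchedule = field(default_factory=RegimeSchedule.default)
    #: plateau oscillation period; ~10 cycles fit the default 400-s HG window
    osc_period_s: float = 40.0
    #: oscillation waveform: burst-like pulses (``sin^osc_pulse_shape`` of the
    #: positive half-wave, zero-mean unit-variance normalized); larger values
    #: give narrower bursts whose correlation decays faster with wave lag
    osc_pulse_shape: float = 5.0
    #: wave speed; ``None`` draws log-uniformly from ``wave_speed_range_um_s``,
    #: ``math.inf`` gives zero-lag (synchronous) oscillations
    wave_speed_um_s: float | None = None
    wave_speed_range_um_s: tuple[float, float] = (8.0, 30.0)
    n_wave_sources: int = 1
    onset_delay_max_s: float = 30.0
    baseline_f: float = 1.0
    plateau_amp: float = 1.0
    osc_amp: float = 0.25
    #: per-cell slow plateau modulation (uncorrelated between cells); keeps
    #: high-glucose correlations below the driven ON/OFF transients
    hg_wander_amp: float = 0.07
    hg_wander_period_range_s: tuple[float, float] = (150.0, 400.0)
    #: shared very-slow baseline drift with heterogeneous per-cell coupling;
    #: produces the distance-independent correlated pairs seen in low glucose
    lg_shared_sd: float = 0.06
    lg_shared_period_range_s: tuple[float, float] = (280.0, 420.0)
    lg_strong_frac: float = 0.15
    #: peripheral non-beta cells oscillate in low glucose with this amplitude
    nonbeta_frac: float = 0.1
    nonbeta_osc_amp: float = 0.5
    nonbeta_osc_period_s: float = 50.0
    noise_sd: float = 0.04
    bleach_linear: float = 5e-5  # per second
    bleach_exp_amp: float = 0.1
    bleach_exp_tau: float = 300.0  # seconds
    #: dye-loading heterogeneity: per-cell baseline ~ lognormal(sigma)
    loading_sigma: float = 0.3
    islet_radius_um: float | None = None
    packing_fraction: float = 0.55
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.osc_period_s < 2.0 / self.frame_rate_hz:
            raise ValueError(
                "osc_period_s below the Nyquist limit "
                f"(needs >= {2.0 / self.frame_rate_hz:g} s at "
                f"{self.frame_rate_hz:g} Hz)"
            )
        if self.onset_delay_max_s < 0:
            raise ValueError("onset delays must be nonnegative")
        if not 0 <= self.nonbeta_frac < 1:
            raise ValueError("nonbeta_frac must lie in [0, 1)")

    def radius_um(self) -> float:
        """Islet radius: explicit, or sized to hold n_cells at the packing fraction."""
        if self.islet_radius_um is not None:
            return float(self.islet_radius_um)
        return 0.5 * self.cell_diameter_um * math.sqrt(
            self.n_cells / self.packing_fraction
        )


@dataclass
class IsletGeometry:
    """Cell centre positions in a 2-D islet disc."""

    cells: CellMap
    islet_radius_um: float
    cell_diameter_um: float

    @property
    def n_cells(self) -> int:
        return self.cells.n_cells

    @property
    def cell_ids(self) -> list[int]:
        return self.cells.cell_ids


def _rng(seed: int, stream: int) -> np.random.Generator:
    # independent deterministic streams for geometry vs. dynamics
    return np.random.default_rng([int(seed), int(stream)])


def generate_geometry(params: SimParams) -> IsletGeometry:
    """Pack ``params.n_cells`` cell centres into a disc by dart throwing.

    Centres are drawn uniformly in the disc and accepted when at least
    ``0.8 * cell_diameter_um`` from every accepted centre.  Non-beta cells
    (fraction ``nonbeta_frac``) are assigned to the outermost positions,
    mirroring the peripheral mantle of alpha/delta cells in mouse islets.

    Raises
    ------
    PackingError
        If the disc cannot hold the requested count; the message names the
        number of cells that was achievable.
    """
    if params.n_cells < 3:
        raise ValueError("need at least 3 cells")
    rng = _rng(params.seed, 0)
    radius = params.radius_um()
    min_dist = 0.8 * params.cell_diameter_um
    placed: list[tuple[float, float]] = []
    attempts_per_cell = 2000
    for _ in range(params.n_cells):
        for _attempt in range(attempts_per_cell):
            r = radius * math.sqrt(rng.uniform())
            theta = rng.uniform(0.0, 2.0 * math.pi)
            x, y = r * math.cos(theta), r * math.sin(theta)
            if all(
                (x - px) ** 2 + (y - py) ** 2 >= min_dist**2 for px, py in placed
            ):
                placed.append((x, y))
                break
        else:
            raise PackingError(
                f"could not pack {params.n_cells} cells of diameter "
                f"{params.cell_diameter_um} µm into a disc of radius "
                f"{radius:.1f} µm; achievable maximum at this density is "
                f"{len(placed)} cells"
            )
    xy = np.array(placed)
    n_nonbeta = int(round(params.nonbeta_frac * params.n_cells))
    is_beta = np.ones(params.n_cells, dtype=bool)
    if n_nonbeta:
        radial = np.hypot(xy[:, 0], xy[:, 1])
        # outermost cells become non-beta, but only within the peripheral
        # annulus (width 1.5 cell diameters)
        annulus = radial >= radius - 1.5 * params.cell_diameter_um
        outer_order = np.argsort(-radial)
        chosen = [i for i in outer_order if annulus[i]][:n_nonbeta]
        is_beta[chosen] = False
    cells = CellMap.from_arrays(
        cell_ids=np.arange(params.n_cells), x_um=xy[:, 0], y_um=xy[:, 1], is_beta=is_beta
    )
    return IsletGeometry(
        cells=cells, islet_radius_um=radius, cell_diameter_um=params.cell_diameter_um
    )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _pulse_wave(t: np.ndarray, period_s: float, shape: float) -> np.ndarray:
    """Zero-mean, unit-variance burst train: ``max(sin, 0)**shape`` normalized.

    ``shape = 1`` gives half-wave sines; larger exponents give narrower
    calcium-burst-like pulses.
    """
    theta = 2.0 * math.pi * t / period_s
    raw = np.maximum(np.sin(theta), 0.0) ** shape
    # analytic normalisation is awkward for general exponents; use a dense
    # one-period quadrature instead (t-independent, so deterministic)
    grid = np.linspace(0.0, 2.0 * math.pi, 4096, endpoint=False)
    ref = np.maximum(np.sin(grid), 0.0) ** shape
    return (raw - ref.mean()) / ref.std()


def _bleach_curve(t: np.ndarray, params: SimParams) -> np.ndarray:
    """Multiplicative drift (1 - a t)(1 - b (1 - exp(-t/tau)))."""
    lin = 1.0 - params.bleach_linear * t
    expo = 1.0 - params.bleach_exp_amp * (1.0 - np.exp(-t / params.bleach_exp_tau))
    return lin * expo


def simulate_traces(geom: IsletGeometry, params: SimParams) -> TraceSet:
    """Simulate raw fluorescence traces for every cell in ``geom``.

    Returns a ``raw``-stage :class:`TraceSet` covering the full schedule at
    ``params.frame_rate_hz``.
    """
    schedule = params.schedule
    if len(schedule) == 0:
        raise ValueError("empty schedule")
    rng = _rng(params.seed, 1)
    duration = schedule.total_duration_s
    dt = 1.0 / params.frame_rate_hz
    n_frames = int(round(duration / dt))
    t = np.arange(n_frames) * dt

    n = geom.n_cells
    xy = geom.cells.positions()
    is_beta = geom.cells.table["is_beta"].to_numpy()

    # wave kinematics: phase lag at each cell = distance to nearest source / speed
    if params.wave_speed_um_s is None:
        lo, hi = params.wave_speed_range_um_s
        speed = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    else:
        speed = float(params.wave_speed_um_s)
    n_src = max(1, int(params.n_wave_sources))
    src_r = geom.islet_radius_um * np.sqrt(rng.uniform(size=n_src))
    src_th = rng.uniform(0.0, 2.0 * math.pi, size=n_src)
    sources = np.column_stack([src_r * np.cos(src_th), src_r * np.sin(src_th)])
    dists = np.linalg.norm(xy[:, None, :] - sources[None, :, :], axis=2).min(axis=1)
    lag_s = np.zeros(n) if math.isinf(speed) else dists / speed

    onset_delay = rng.uniform(0.0, params.onset_delay_max_s, size=n)
    # deactivation is more synchronous than activation
    offset_delay = rng.uniform(0.0, 0.5 * params.onset_delay_max_s, size=n)
    loading = np.exp(rng.normal(0.0, params.loading_sigma, size=n))

    # shared very-slow baseline drift (common mode), coupled per cell with
    # gain u_i: a minority of cells couple strongly, giving low-glucose
    # correlated pairs that are independent of distance
    lo_p, hi_p = params.lg_shared_period_range_s
    # dominant component at mid-range period: any ~300-s baseline window then
    # carries a stable fraction of the drift variance, whatever the phase
    shared = np.sin(
        2.0 * math.pi * t / rng.uniform(0.9 * lo_p + 0.1 * hi_p, 0.1 * lo_p + 0.9 * hi_p)
        + rng.uniform(0.0, 2.0 * math.pi)
    )
    for _ in range(2):
        period = rng.uniform(lo_p, hi_p)
        phase = rng.uniform(0.0, 2.0 * math.pi)
        shared += rng.uniform(0.2, 0.4) * np.sin(2.0 * math.pi * t / period + phase)
    sd = shared.std()
    shared = shared / sd if sd > 0 else shared
    strong = rng.uniform(size=n) < params.lg_strong_frac
    share_gain = rng.uniform(0.0, 0.5, size=n)
    share_gain[strong] += rng.uniform(2.0, 2.6, size=int(strong.sum()))

    # per-cell slow plateau wander (uncorrelated between cells)
    wander_period = rng.uniform(*params.hg_wander_period_range_s, size=n)
    wander_phase = rng.uniform(0.0, 2.0 * math.pi, size=n)

    t_on = schedule["ON"].t_start_s if "ON" in schedule else None
    t_off = schedule["OFF"].t_start_s if "OFF" in schedule else None

    tau_rise, rise_lead = 8.0, 25.0
    tau_fall, fall_lead = 6.0, 20.0

    values = np.empty((n, n_frames))
    for i in range(n):
        base = params.baseline_f * loading[i]
        if is_beta[i]:
            if t_on is None:
                env = np.zeros(n_frames)
            else:
                env = _sigmoid((t - (t_on + onset_delay[i] + rise_lead)) / tau_rise)
                if t_off is not None:
                    env = env * _sigmoid(
                        ((t_off + offset_delay[i] + fall_lead) - t) / tau_fall
                    )
            osc = (params.osc_amp / math.sqrt(2.0)) * _pulse_wave(
                t - lag_s[i], params.osc_period_s, params.osc_pulse_shape
            )
            wander = params.hg_wander_amp * np.sin(
                2.0 * math.pi * t / wander_period[i] + wander_phase[i]
            )
            ideal = base * (
                1.0
                + env * (params.plateau_amp + osc + wander)
                + (1.0 - env) * params.lg_shared_sd * share_gain[i] * shared
            )
        else:
            # alpha/delta-like: oscillates in low glucose, suppressed while
            # the stimulus is on
            if t_on is None or t_off is None:
                low_glucose = np.ones(n_frames)
            else:
                # active before ON and again after the OFF transient ends
                low_glucose = np.clip(
                    1.0
                    - _sigmoid((t - t_on) / 10.0)
                    + _sigmoid((t - (t_off + 120.0)) / 10.0),
                    0.0,
                    1.0,
                )
            phase = rng.uniform(0.0, 2.0 * math.pi)
            osc = params.nonbeta_osc_amp * np.sin(
                2.0 * math.pi * t / params.nonbeta_osc_period_s + phase
            )
            ideal = base * (
                1.0
                + low_glucose * osc
                + params.lg_shared_sd * share_gain[i] * shared
            )
        values[i] = ideal
    values *= _bleach_curve(t, params)[None, :]
    if params.noise_sd > 0:
        values += (
            rng.normal(0.0, params.noise_sd, size=values.shape)
            * (params.baseline_f * loading)[:, None]
        )
    return TraceSet(times=t, values=values, cell_ids=geom.cell_ids, stage="raw")


def simulate_islet(params: SimParams) -> tuple[TraceSet, IsletGeometry]:
    """Convenience: geometry + traces for one islet."""
    geom = generate_geometry(params)
    return simulate_traces(geom, params), geom


# ---------------------------------------------------------------------------
# fixture I/O
# ---------------------------------------------------------------------------

def write_fixture(
    traces: TraceSet,
    geom: IsletGeometry | CellMap,
    path,
    schedule: RegimeSchedule | None = None,
) -> dict:
    """Write a trace CSV, position CSV and schedule YAML under ``path``.

    ``path`` is a directory (created if needed).  Returns the file paths.
    The trace/position/schedule files round-trip losslessly through
    :func:`read_fixture`.  Without an explicit ``schedule`` the canonical
    five-regime protocol is written.
    """
    from pathlib import Path

    cells = geom.cells if isinstance(geom, IsletGeometry) else geom
    if set(traces.cell_ids) - set(cells.cell_ids):
        missing = sorted(set(traces.cell_ids) - set(cells.cell_ids))
        raise ValueError(f"traced cell(s) missing from position table: {missing}")
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "traces": out / "traces.csv",
        "positions": out / "positions.csv",
        "schedule": out / "schedule.yaml",
    }
    traces.to_csv(paths["traces"])
    cells.to_csv(paths["positions"])
    (schedule or RegimeSchedule.default()).to_yaml(paths["schedule"])
    return {k: str(v) for k, v in paths.items()}


def read_fixture(path) -> tuple[TraceSet, CellMap, RegimeSchedule]:
    """Read back a fixture directory written by :func:`write_fixture`."""
    from pathlib import Path

    p = Path(path)
    traces = TraceSet.from_csv(p / "traces.csv")
    cells = CellMap.from_csv(p / "positions.csv")
    schedule = RegimeSchedule.from_yaml(p / "schedule.yaml")
    missing = sorted(set(traces.cell_ids) - set(cells.cell_ids))
    if missing:
        raise ValueError(f"traced cell(s) missing from position table: {missing}")
    return traces, cells, schedule
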