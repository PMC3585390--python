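"""Conditioning of raw fluorescence traces and beta-cell classification.

The conditioning chain mirrors standard islet calcium-imaging practice:

1. :func:`correct_bleaching` -- divide out a linear-plus-exponential
   photobleaching drift fitted to the baseline (low-glucose) segments only,
   so the glucose response is not absorbed into the drift model;
2. :func:`f_over_f0` -- express each trace relative to its initial
   fluorescence F0;
3. :func:`rescale_unit` -- min-max rescale each trace to [0, 1] (Pearson
   correlations are unchanged by this affine step);
4. :func:`classify_cells` -- label each ROI beta / non_beta / unresponsive
   from its regime-specific response pattern;
5. :func:`segment` -- cut out one named regime window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .schedule import RegimeSchedule
from .traces import TraceSet

__all__ = [
    "correct_bleaching",
    "f_over_f0",
    "rescale_unit",
    "classify_cells",
    "segment",
    "ClassifyCriteria",
]


def _baseline_mask(times: np.ndarray, schedule: RegimeSchedule) -> np.ndarray:
    schedule.require("LG1", "LG2")
    mask = np.zeros(times.size, dtype=bool)
    for name in ("LG1", "LG2"):
        r = schedule[name]
        mask |= (times >= r.t_start_s) & (times < r.t_end_s)
    return mask


def _drift_model(t, c0, c1, c2, tau):
    return c0 + c1 * t + c2 * np.exp(-t / tau)


def correct_bleaching(traces: TraceSet, schedule: RegimeSchedule) -> TraceSet:
    """Remove photobleaching drift from raw traces.

    Per cell, ``d(t) = c0 + c1*t + c2*exp(-t/tau)`` is least-squares fitted
    to the concatenated LG1 + LG2 (baseline) samples and the full trace is
    divided by ``d(t)/d(0)``.  Cells whose nonlinear fit does not converge
    fall back to a linear-only fit and are flagged in
    ``flags["bleach_linear_fallback"]``.
    """
    if traces.stage != "raw":
        raise ValueError(f"bleach correction expects raw traces, got {traces.stage!r}")
    if not np.isfinite(traces.values).all():
        bad = [
            traces.cell_ids[i]
            for i in range(traces.n_cells)
            if not np.isfinite(traces.values[i]).all()
        ]
        raise ValueError(f"non-finite frames in trace(s) of cell(s) {bad}")
    mask = _baseline_mask(traces.times, schedule)
    if mask.sum() < 5:
        raise ValueError("too few baseline (LG1+LG2) frames for a drift fit")
    t_fit = traces.times[mask]
    out = traces.copy()
    fallback: list[int] = []
    duration = traces.times[-1] - traces.times[0] if traces.n_frames > 1 else 1.0
    for i, cid in enumerate(traces.cell_ids):
        y = traces.values[i, mask]
        c0_guess = float(np.median(y))
        p0 = [c0_guess, -1e-5 * c0_guess, 0.1 * c0_guess, max(duration / 6.0, 1.0)]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    _drift_model,
                    t_fit,
                    y,
                    p0=p0,
                    bounds=(
                        [-np.inf, -np.inf, -np.inf, 1.0],
                        [np.inf, np.inf, np.inf, 10.0 * duration],
                    ),
                    maxfev=10000,
                )
            drift = _drift_model(traces.times, *popt)
            if drift[0] == 0 or np.any(drift <= 0):
                raise RuntimeError("non-positive drift curve")
        except (RuntimeError, ValueError):
            coef = np.polyfit(t_fit, y, 1)
            drift = np.polyval(coef, traces.times)
            fallback.append(cid)
            if drift[0] == 0 or np.any(drift <= 0):
                # pathological baseline: leave the trace untouched
                drift = np.ones_like(traces.times)
        out.values[i] = traces.values[i] / (drift / drift[0])
    out.flags["bleach_linear_fallback"] = fallback
    return out


def f_over_f0(
    traces: TraceSet,
    schedule: RegimeSchedule | None = None,
    f0_window_s: tuple[float, float] | None = None,
) -> TraceSet:
    """Express each trace as F/F0.

    F0 is the per-cell mean over ``f0_window_s`` (default: the first 60 s of
    LG1, or of the record when no schedule is given).  The window must lie
    inside LG1 when a schedule is supplied.
    """
    if traces.stage != "raw":
        raise ValueError(f"F/F0 expects raw-stage traces, got {traces.stage!r}")
    if f0_window_s is None:
        if schedule is not None:
            lg1 = schedule["LG1"]
            f0_window_s = (lg1.t_start_s, min(lg1.t_start_s + 60.0, lg1.t_end_s))
        else:
            f0_window_s = (traces.times[0], traces.times[0] + 60.0)
    elif schedule is not None:
        lg1 = schedule["LG1"]
        if not (lg1.t_start_s <= f0_window_s[0] and f0_window_s[1] <= lg1.t_end_s):
            raise ValueError(
                f"F0 window {f0_window_s} must lie inside LG1 "
                f"[{lg1.t_start_s}, {lg1.t_end_s})"
            )
    t0, t1 = f0_window_s
    mask = (traces.times >= t0) & (traces.times < t1)
    if not mask.any():
        # degenerate single-frame window: take the nearest frame at/after t0
        idx = int(np.searchsorted(traces.times, t0))
        mask = np.zeros(traces.n_frames, dtype=bool)
        mask[min(idx, traces.n_frames - 1)] = True
    f0 = traces.values[:, mask].mean(axis=1)
    bad = [cid for cid, v in zip(traces.cell_ids, f0) if v <= 0]
    if bad:
        raise ValueError(f"non-positive F0 for cell(s) {bad}")
    out = traces.copy()
    out.values = traces.values / f0[:, None]
    out.stage = "f_over_f0"
    return out


def rescale_unit(traces: TraceSet) -> TraceSet:
    """Min-max rescale every trace to the unit interval.

    Constant traces map to all-zeros and are flagged in
    ``flags["constant_cells"]``.  Pearson correlations between cells are
    unchanged by this per-cell affine map.
    """
    if not np.isfinite(traces.values).all():
        raise ValueError("unit rescale requires finite traces")
    lo = traces.values.min(axis=1, keepdims=True)
    hi = traces.values.max(axis=1, keepdims=True)
    span = hi - lo
    constant = span[:, 0] == 0
    span[constant] = 1.0
    out = traces.copy()
    out.values = (traces.values - lo) / span
    out.values[constant] = 0.0
    out.stage = "unit"
    out.flags["constant_cells"] = [
        cid for cid, c in zip(traces.cell_ids, constant) if c
    ]
    return out


@dataclass
class ClassifyCriteria:
    """Thresholds of the regime-response beta-cell classifier.

    ``osc_m`` scales the noise SD for the LG1 threshold-crossing count,
    ``osc_max_fraction`` is the largest crossing fraction still considered
    quiescent, ``hg_rise_factor`` the minimum HG/LG1 mean ratio, and
    ``lg2_return_band`` the relative band within which the LG2 mean must
    return to the LG1 mean.
    """

    osc_m: float = 3.0
    osc_max_fraction: float = 0.1
    hg_rise_factor: float = 1.2
    lg2_return_band: float = 0.2


def _oscillation_score(y: np.ndarray, t: np.ndarray, m: float) -> float:
    """Fraction of frames beyond ±m times the noise SD, after detrending.

    The segment is linearly detrended; the noise SD is estimated from first
    differences (``std(diff)/sqrt(2)``), which tracks the imaging noise but
    not slow bounded oscillations, so oscillating cells score high.
    """
    if y.size < 8:
        return 0.0
    # cubic detrend: removes slow baseline drift (shared or photobleaching
    # residue) while leaving oscillations at tens-of-seconds periods intact
    coef = np.polyfit(t, y, 3)
    resid = y - np.polyval(coef, t)
    sigma = np.std(np.diff(resid)) / np.sqrt(2.0)
    if sigma <= 1e-12 * max(1.0, float(np.abs(y).max())):
        return 0.0  # (numerically) constant segment
    return float(np.mean(np.abs(resid) > m * sigma))


def classify_cells(
    traces: TraceSet,
    schedule: RegimeSchedule,
    criteria: ClassifyCriteria | None = None,
) -> pd.DataFrame:
    """Label each cell ``beta`` / ``non_beta`` / ``unresponsive``.

    A beta cell (i) shows no oscillations in LG1 (threshold-crossing score
    below ``osc_max_fraction``), (ii) responds to high glucose with an HG
    mean at least ``hg_rise_factor`` times the LG1 mean, and (iii) returns
    to baseline (LG2 mean within ``lg2_return_band`` of the LG1 mean).
    Cells oscillating in LG1 are ``non_beta``; the rest are
    ``unresponsive``.

    Returns a DataFrame with columns ``cell_id, label, osc_score,
    hg_ratio, lg2_ratio``.
    """
    if traces.stage not in ("f_over_f0", "unit"):
        raise ValueError(
            "classification expects f_over_f0 or unit traces, got "
            f"{traces.stage!r}"
        )
    criteria = criteria or ClassifyCriteria()
    schedule.require("LG1", "HG", "LG2")
    windows = {
        name: (traces.times >= schedule[name].t_start_s)
        & (traces.times < schedule[name].t_end_s)
        for name in ("LG1", "HG", "LG2")
    }
    rows = []
    for i, cid in enumerate(traces.cell_ids):
        y = traces.values[i]
        lg1, hg, lg2 = (y[windows[n]] for n in ("LG1", "HG", "LG2"))
        score = _oscillation_score(lg1, traces.times[windows["LG1"]], criteria.osc_m)
        lg1_mean = float(lg1.mean())
        hg_ratio = float(hg.mean() / lg1_mean) if lg1_mean != 0 else np.inf
        lg2_ratio = float(lg2.mean() / lg1_mean) if lg1_mean != 0 else np.inf
        if score >= criteria.osc_max_fraction:
            label = "non_beta"
        elif (
            hg_ratio >= criteria.hg_rise_factor
            and abs(lg2_ratio - 1.0) <= criteria.lg2_return_band
        ):
            label = "beta"
        else:
            label = "unresponsive"
        rows.append(
            {
                "cell_id": cid,
                "label": label,
                "osc_score": score,
                "hg_ratio": hg_ratio,
                "lg2_ratio": lg2_ratio,
            }
        )
    return pd.DataFrame(rows)


def segment(traces: TraceSet, schedule: RegimeSchedule, regime_name: str) -> TraceSet:
    """Frames of one named regime (half-open ``[t_start, t_end)`` window)."""
    regime = schedule[regime_name]
    return traces.slice_time(regime.t_start_s, regime.t_end_s)
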