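"""Shared fixtures: small simulated islets and a full multi-islet study.

All fixtures are generated programmatically at test time with fixed seeds,
so the suite needs no data files and is fully deterministic.
"""

import numpy as np
import pytest

import isletnet as isl


@pytest.fixture(scope="session")
def default_islet():
    """One simulated islet at default parameters (seed 1)."""
    params = isl.SimParams(n_cells=60, seed=1)
    traces, geom = isl.simulate_islet(params)
    return params, traces, geom


@pytest.fixture(scope="session")
def islet_results(default_islet):
    """Fitted single-islet results on the default simulated islet."""
    _, traces, geom = default_islet
    model = isl.IsletFunctionalConnectivity(traces, geom.cells)
    return model.fit(n_random=30, seed=0)


@pytest.fixture(scope="session")
def study_results():
    """Fitted 9-islet synthetic study (the scaled-down multi-islet design)."""
    study = isl.IsletStudy.simulate(n_islets=9, seed=1)
    return study.fit(n_random=50, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_traceset(values, dt=2.0, stage="raw", cell_ids=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n_cells, n_frames = values.shape
    return isl.TraceSet(
        times=np.arange(n_frames) * dt,
        values=values,
        cell_ids=cell_ids if cell_ids is not None else list(range(n_cells)),
        stage=stage,
    )
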