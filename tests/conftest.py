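"""Shared fixtures.

The expensive, session-scoped fixtures simulate desk-scale standard runs
(5000 DG x 200 CA3, 100k-step trajectories) once and share them between
the acceptance tests; everything else builds tiny populations on the fly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mossyinfo.analytic import AnalyticParams, analytic_channel
from mossyinfo.ca3 import CA3Params
from mossyinfo.decoding import info_vs_sample_size
from mossyinfo.dg import DGParams
from mossyinfo.simulate import SessionParams, run_session

STANDARD_SEEDS = (11, 22, 33)
DESK_SIZES = (1, 2, 5, 10, 20, 50)


def desk_params(**kw) -> SessionParams:
    dg_kw = {k: kw.pop(k) for k in list(kw) if hasattr(DGParams(), k)}
    ca3_kw = {k: kw.pop(k) for k in list(kw) if hasattr(CA3Params(), k)}
    return SessionParams(
        dg=DGParams(n_dg=5000, **dg_kw),
        ca3=CA3Params(n_ca3=200, **ca3_kw),
        n_steps=100_000,
        **kw,
    )


def desk_analytic(**kw) -> AnalyticParams:
    defaults = dict(n_configs=250, grid_points=32, seed=0)
    defaults.update(kw)
    return AnalyticParams(**defaults)


@pytest.fixture(scope="session")
def standard_runs():
    """Three standard desk sessions with their info-vs-sample-size tables."""
    runs = []
    for seed in STANDARD_SEEDS:
        sess = run_session(desk_params(), seed)
        df = info_vs_sample_size(
            sess.rates,
            sess.actual_bins,
            sess.templates,
            DESK_SIZES,
            8,
            sess.env.side_bins,
            rng_seed=seed + 1,
        )
        df["seed"] = seed
        runs.append((sess, df))
    return runs


@pytest.fixture(scope="session")
def standard_info(standard_runs) -> pd.DataFrame:
    return pd.concat([df for _, df in standard_runs], ignore_index=True)


@pytest.fixture(scope="session")
def analytic_standard():
    """Analytic channel quantities at the standard parameter set."""
    return analytic_channel(desk_analytic())


@pytest.fixture(scope="session")
def tiny_population():
    """Small synthetic population of spatially tuned noisy units.

    Gaussian-tuned rates on the 20x20 torus over a short trajectory, strong
    enough that decoding clearly works: used for decoding-layer behaviour
    tests without a full network simulation.
    """
    from mossyinfo.environment import bin_position, generate_trajectory, make_grid

    rng = np.random.default_rng(1234)
    env = make_grid(20, 20.0)
    n_units, n_steps, sigma = 30, 6000, 2.0
    centers = rng.uniform(0, 20, size=(n_units, 2))

    def rates_at(positions):
        half = 10.0
        dx = (positions[:, None, 0] - centers[None, :, 0] + half) % 20.0 - half
        dy = (positions[:, None, 1] - centers[None, :, 1] + half) % 20.0 - half
        mean = 3.0 * np.exp(-(dx * dx + dy * dy) / (2 * sigma**2))
        return mean + rng.normal(0.0, 0.5, size=mean.shape)

    traj_tpl = generate_trajectory(env, n_steps, seed=1)
    traj_dec = generate_trajectory(env, n_steps, seed=2)
    from mossyinfo.decoding import build_templates

    templates = build_templates(
        rates_at(traj_tpl.positions), bin_position(traj_tpl.positions, env), env.n_bins
    )
    return {
        "env": env,
        "templates": templates,
        "rates": rates_at(traj_dec.positions),
        "actual_bins": bin_position(traj_dec.positions, env),
    }
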