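"""End-to-end simulated sessions: trajectory, DG drive, CA3 rates, templates.

A *session* samples one quenched realization (DG field assignment and MF
connectivity), runs two independent trajectories — a template pass and a
decode pass — through the noisy threshold-linear CA3 population with the
inhibition threshold re-adjusted at every time step, and returns everything
the decoding/information layer needs, plus noise-free rate maps for field
census statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import ca3 as ca3mod
from . import dg as dgmod
from .ca3 import CA3Params, MossyProjection, thresholds_batch
from .decoding import TemplateSet, build_templates
from .dg import DGFieldSet, DGParams
from .environment import (
    EnvironmentGrid,
    Trajectory,
    bin_center,
    bin_position,
    generate_trajectory,
    make_grid,
)
from .errors import ParameterError

__all__ = ["SessionParams", "Session", "run_session", "train_projection", "field_census"]


@dataclass(frozen=True)
class SessionParams:
    """Everything needed to reproduce one simulated session bit-for-bit
    (apart from the master seed, passed separately)."""

    dg: DGParams = field(default_factory=DGParams)
    ca3: CA3Params = field(default_factory=CA3Params)
    side_bins: int = 20
    side_length: float = 20.0
    n_steps: int = 100_000
    step_length: float = 0.5
    turn_noise: float = 0.2
    threshold_mode: str = "per_step"  # or "fixed"
    fixed_theta: float = 0.0

    def env(self) -> EnvironmentGrid:
        return make_grid(self.side_bins, self.side_length)


@dataclass
class Session:
    """Results of one simulated session."""

    params: SessionParams
    seed: int
    env: EnvironmentGrid
    fields: DGFieldSet
    proj: MossyProjection
    templates: TemplateSet
    rates: np.ndarray  # (n_steps, n_ca3) decode-pass rates, float32
    actual_bins: np.ndarray  # (n_steps,)
    thetas: np.ndarray  # per-step thresholds of the decode pass
    mean_sparsity: float  # time-averaged realized sparsity, decode pass
    signal_map: np.ndarray  # (n_bins, n_ca3) noise-free drive at bin centers


def _ca3_activations(
    fields: DGFieldSet,
    proj: MossyProjection,
    positions: np.ndarray,
    env: EnvironmentGrid,
) -> np.ndarray:
    """Noise-free activations h = W beta(x) for every position: (T, n_ca3)."""
    beta, unit_ids = dgmod.dg_rate_matrix(fields, positions, env)
    w = proj.weights[:, unit_ids]
    return beta @ w.T


def _rates_with_threshold(
    h: np.ndarray, params: SessionParams, rng
) -> tuple[np.ndarray, np.ndarray, float]:
    """Add fresh noise and apply the per-step (or fixed) threshold.

    Returns (rates float32, per-step thetas, time-averaged sparsity).
    """
    noise = rng.normal(0.0, params.ca3.noise_sd, size=h.shape)
    acts = h + noise
    if params.threshold_mode == "per_step":
        thetas = thresholds_batch(acts, params.ca3.target_sparsity)
    elif params.threshold_mode == "fixed":
        thetas = np.full(h.shape[0], params.fixed_theta)
    else:
        raise ParameterError("threshold_mode must be 'per_step' or 'fixed'")
    rates = np.maximum(acts - thetas[:, None], 0.0)
    s1 = rates.mean(axis=1)
    s2 = np.einsum("ij,ij->i", rates, rates) / rates.shape[1]
    ok = s2 > 0
    mean_sparsity = float(np.mean(s1[ok] ** 2 / s2[ok])) if ok.any() else 0.0
    return rates.astype(np.float32), thetas, mean_sparsity


def run_session(
    params: SessionParams,
    seed: int,
    fields: DGFieldSet | None = None,
    proj: MossyProjection | None = None,
    decode_fields: DGFieldSet | None = None,
) -> Session:
    """Run a full session: quenched sampling, template pass, decode pass.

    Pre-sampled ``fields`` / ``proj`` (e.g. after plasticity training) can
    be injected; ``decode_fields`` substitutes a degraded field set for the
    decode pass only, leaving the templates built from the intact cue.
    All randomness derives from ``seed``.
    """
    env = params.env()
    ss = np.random.SeedSequence(seed)
    (s_fields, s_conn, s_traj_tpl, s_traj_dec, s_noise_tpl, s_noise_dec) = ss.spawn(6)
    if fields is None:
        counts, active = dgmod.sample_field_counts(
            params.dg, np.random.default_rng(s_fields)
        )
        fields = dgmod.place_fields(
            counts, env, params.dg, np.random.default_rng(s_fields.spawn(1)[0]),
            active=active,
        )
    if proj is None:
        proj = ca3mod.sample_connectivity(
            params.ca3, params.dg.n_dg, np.random.default_rng(s_conn)
        )
    if decode_fields is None:
        decode_fields = fields

    traj_tpl = generate_trajectory(
        env, params.n_steps, params.step_length, params.turn_noise,
        seed=np.random.default_rng(s_traj_tpl),
    )
    traj_dec = generate_trajectory(
        env, params.n_steps, params.step_length, params.turn_noise,
        seed=np.random.default_rng(s_traj_dec),
    )

    h_tpl = _ca3_activations(fields, proj, traj_tpl.positions, env)
    r_tpl, _, _ = _rates_with_threshold(
        h_tpl, params, np.random.default_rng(s_noise_tpl)
    )
    templates = build_templates(r_tpl, bin_position(traj_tpl.positions, env), env.n_bins)

    h_dec = _ca3_activations(decode_fields, proj, traj_dec.positions, env)
    rates, thetas, mean_sp = _rates_with_threshold(
        h_dec, params, np.random.default_rng(s_noise_dec)
    )

    centers = bin_center(np.arange(env.n_bins), env)
    signal = _ca3_activations(fields, proj, centers, env)

    return Session(
        params=params,
        seed=seed,
        env=env,
        fields=fields,
        proj=proj,
        templates=templates,
        rates=rates,
        actual_bins=bin_position(traj_dec.positions, env),
        thetas=thetas,
        mean_sparsity=mean_sp,
        signal_map=signal,
    )


def train_projection(
    fields: DGFieldSet,
    proj: MossyProjection,
    params: SessionParams,
    gamma: float,
    n_train_steps: int,
    seed: int,
) -> MossyProjection:
    """Train the MF weights with the gated Hebbian rule along a trajectory.

    At each step the CA3 rates are computed with the per-step sparsity
    threshold, then every unit with positive rate relaxes its incoming
    weights toward the presynaptic DG rates with step ``gamma * eta_i``
    (weights clipped at 0, anatomy untouched).  Connections from DG units
    that are silent in this environment simply decay, which is tracked
    with a lazily accumulated per-row multiplier for speed.  Returns a new
    projection; the input is not modified.
    """
    if gamma < 0:
        raise ParameterError("gamma must be non-negative")
    env = params.env()
    ss = np.random.SeedSequence(seed)
    s_traj, s_noise = ss.spawn(2)
    traj = generate_trajectory(
        env, n_train_steps, params.step_length, params.turn_noise,
        seed=np.random.default_rng(s_traj),
    )
    beta_all, unit_ids = dgmod.dg_rate_matrix(fields, traj.positions, env)
    conn = proj.connectivity
    w_full = proj.weights.copy()
    w_act = w_full[:, unit_ids].copy()  # columns with possibly nonzero beta
    conn_act = conn[:, unit_ids]
    decay = np.ones(proj.n_ca3)  # lazy product of (1 - gamma*eta) per row
    zeroed = np.zeros(proj.n_ca3, dtype=bool)
    rng = np.random.default_rng(s_noise)
    target = params.ca3.target_sparsity
    for t in range(n_train_steps):
        beta = beta_all[t]
        h = w_act @ beta + rng.normal(0.0, params.ca3.noise_sd, size=proj.n_ca3)
        theta = ca3mod.threshold_for_target(h, target)
        eta = np.maximum(h - theta, 0.0)
        rows = np.flatnonzero(eta > 0.0)
        if gamma == 0.0 or rows.size == 0:
            continue
        step = gamma * eta[rows]
        fac = 1.0 - step
        w = w_act[rows]
        w += step[:, None] * (beta[None, :] - w)
        np.maximum(w, 0.0, out=w)
        w[~conn_act[rows]] = 0.0
        w_act[rows] = w
        decay[rows] *= fac
        zeroed[rows] |= fac < 0.0
    # silent-unit columns: pure decay toward zero (beta identically 0)
    decay = np.where(zeroed, 0.0, np.maximum(decay, 0.0))
    silent = np.ones(proj.n_dg, dtype=bool)
    silent[unit_ids] = False
    w_full[:, silent] *= decay[:, None]
    w_full[:, unit_ids] = w_act
    w_full[~conn] = 0.0
    return MossyProjection(connectivity=conn.copy(), weights=w_full, gamma=gamma)


def field_census(session: Session, min_bins: int = 3) -> tuple[float, float]:
    """Fractions of CA3 units with a place field, and with more than one.

    A unit *has a field* when its noise-free drive at the bin centers
    exceeds the session's mean threshold on a torus-connected component of
    at least ``min_bins`` bins (4-neighbour adjacency); components are its
    fields.  Returns (fraction of units with >= 1 field, fraction of
    field-bearing units with > 1 field).
    """
    side = session.env.side_bins
    theta_bar = float(session.thetas.mean())
    above = (session.signal_map > theta_bar).T.reshape(-1, side, side)
    n_units = above.shape[0]
    n_with = 0
    n_multi = 0
    for mask in above:
        n_fields = _count_components(mask, min_bins)
        if n_fields >= 1:
            n_with += 1
        if n_fields > 1:
            n_multi += 1
    frac_with = n_with / n_units
    frac_multi = n_multi / n_with if n_with else 0.0
    return frac_with, frac_multi


def _count_components(mask: np.ndarray, min_bins: int) -> int:
    """Torus-connected components of a boolean grid with >= min_bins cells."""
    side = mask.shape[0]
    seen = np.zeros_like(mask, dtype=bool)
    count = 0
    idx = np.argwhere(mask)
    for r0, c0 in idx:
        if seen[r0, c0]:
            continue
        stack = [(int(r0), int(c0))]
        seen[r0, c0] = True
        size = 0
        while stack:
            r, c = stack.pop()
            size += 1
            for rr, cc in (
                ((r + 1) % side, c),
                ((r - 1) % side, c),
                (r, (c + 1) % side),
                (r, (c - 1) % side),
            ):
                if mask[rr, cc] and not seen[rr, cc]:
                    seen[rr, cc] = True
                    stack.append((rr, cc))
        if size >= min_bins:
            count += 1
    return count
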