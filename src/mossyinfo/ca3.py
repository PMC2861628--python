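"""CA3 population: mossy-fiber connectivity, threshold-linear rates,
sparsity-controlling inhibition, and Hebbian plasticity.

Each CA3 unit receives a sparse random subset of the DG axons (mossy
fibers, MF): every (CA3, DG) pair is connected independently with
probability ``c_mf / n_dg``, so the in-degree is binomial with mean
``c_mf`` — Poisson to an excellent approximation at realistic sizes.
Weights are initialized uniformly to ``j_strength`` on existing
connections.

The CA3 transfer function is threshold-linear with unit gain:
``eta_i = max(h_i - theta, 0)`` where the activation
``h_i = sum_j c_ij w_ij beta_j + eps_i`` combines the DG drive with a
Gaussian noise term (fresh per unit and per time step) that stands in for
recurrent-collateral and perforant-path interference.  The threshold
models feedback inhibition: it is adjusted so that the population sparsity
``a = <eta>^2 / <eta^2>`` (Treves–Rolls) matches a target value, 0.1 by
default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dg import degrade_cue  # noqa: F401  (cue degradation operates on DG fields)
from .errors import (
    ConvergenceError,
    ParameterError,
    UndefinedSparsityError,
)

__all__ = [
    "CA3Params",
    "MossyProjection",
    "CA3Activity",
    "sample_connectivity",
    "ca3_rates",
    "sparsity",
    "adjust_threshold",
    "threshold_for_target",
    "thresholds_batch",
    "hebbian_update",
    "degrade_cue",
]


@dataclass(frozen=True)
class CA3Params:
    """CA3-side parameters.

    ``c_mf`` is the mean number of MF connections per CA3 unit, ``j_strength``
    the uniform MF synaptic strength (rescaled as 1/c_mf in connectivity
    sweeps so the total mean input stays fixed), ``noise_sd`` the SD of the
    Gaussian activation noise, and ``target_sparsity`` the sparsity the
    inhibition-mimicking threshold enforces.  The gain is fixed at 1.
    """

    n_ca3: int = 500
    c_mf: float = 50.0
    j_strength: float = 1.0
    noise_sd: float = 1.0
    gain: float = 1.0
    target_sparsity: float = 0.1

    def __post_init__(self) -> None:
        if self.n_ca3 < 1:
            raise ParameterError("n_ca3 must be >= 1")
        if self.c_mf < 0:
            raise ParameterError("c_mf must be non-negative")
        if self.j_strength < 0:
            raise ParameterError("j_strength must be non-negative")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")
        if self.gain != 1.0:
            raise ParameterError("the gain is fixed at 1 by the rate units")
        if not 0.0 < self.target_sparsity <= 1.0:
            raise ParameterError("target_sparsity must lie in (0, 1]")


@dataclass
class MossyProjection:
    """Binary DG→CA3 connectivity plus synaptic weights.

    Invariant: ``weights[i, j] == 0`` wherever ``connectivity[i, j]`` is
    False — plasticity cannot create anatomy.  ``gamma`` records the
    plasticity factor last applied (0 = frozen weights).
    """

    connectivity: np.ndarray  # (n_ca3, n_dg) bool
    weights: np.ndarray  # (n_ca3, n_dg) float
    gamma: float = 0.0

    @property
    def n_ca3(self) -> int:
        return self.connectivity.shape[0]

    @property
    def n_dg(self) -> int:
        return self.connectivity.shape[1]

    def in_degrees(self) -> np.ndarray:
        return self.connectivity.sum(axis=1)


def sample_connectivity(
    ca3: CA3Params,
    n_dg: int,
    rng_seed: int | None = None,
    exact_degree: bool = False,
) -> MossyProjection:
    """Sample the MF connectivity and initialize uniform weights.

    Each (i, j) pair is connected independently with probability
    ``c_mf / n_dg``.  With ``exact_degree=True`` every CA3 unit instead
    receives exactly ``round(c_mf)`` connections (a control mode).
    """
    if ca3.c_mf >= n_dg:
        raise ParameterError("c_mf must be smaller than n_dg")
    rng = np.random.default_rng(rng_seed)
    conn = np.zeros((ca3.n_ca3, n_dg), dtype=bool)
    if exact_degree:
        k = int(round(ca3.c_mf))
        for i in range(ca3.n_ca3):
            conn[i, rng.choice(n_dg, size=k, replace=False)] = True
    else:
        conn = rng.random((ca3.n_ca3, n_dg)) < (ca3.c_mf / n_dg)
    weights = np.where(conn, ca3.j_strength, 0.0)
    return MossyProjection(connectivity=conn, weights=weights)


@dataclass(frozen=True)
class CA3Activity:
    """Pre-threshold activations ``h``, rates ``eta = [h - theta]_+``,
    the applied threshold and the frozen noise draws."""

    activations: np.ndarray
    rates: np.ndarray
    theta: float
    noise: np.ndarray


def ca3_rates(
    proj: MossyProjection,
    dg_rate_vector: np.ndarray,
    theta: float,
    ca3: CA3Params,
    rng_seed: int | None = None,
    noise: np.ndarray | None = None,
) -> CA3Activity:
    """Noisy threshold-linear CA3 rates for one time step.

    ``h_i = sum_j w_ij beta_j + eps_i`` with fresh Gaussian noise (unless
    frozen draws are passed explicitly), then ``eta_i = [h_i - theta]_+``.
    """
    if not np.isfinite(theta):
        raise ParameterError("theta must be finite")
    beta = np.asarray(dg_rate_vector, dtype=float)
    if noise is None:
        rng = np.random.default_rng(rng_seed)
        noise = rng.normal(0.0, ca3.noise_sd, size=proj.n_ca3)
    h = proj.weights @ beta + noise
    rates = np.maximum(h - theta, 0.0)
    return CA3Activity(activations=h, rates=rates, theta=float(theta), noise=noise)


def sparsity(rates: np.ndarray) -> float:
    """Treves–Rolls population sparsity ``a = <eta>^2 / <eta^2>``.

    ``a`` lies in (0, 1]: 1/N for a one-hot vector, 1 for a constant
    positive vector.  Undefined (raises) for an all-zero vector.
    """
    r = np.asarray(rates, dtype=float)
    m2 = np.mean(r * r)
    if m2 == 0.0:
        raise UndefinedSparsityError("sparsity undefined for all-zero rates")
    m1 = np.mean(r)
    return float(m1 * m1 / m2)


def threshold_for_target(
    activations: np.ndarray,
    target: float,
    tol: float = 1e-3,
    max_iter: int = 200,
) -> float:
    """Bisect the threshold so that ``sparsity([h - theta]_+) == target``.

    Raising theta never increases the sparsity, so the map is monotone and
    bisection converges; an unattainable target (e.g. constant activations,
    where a == 1 for every theta below the activations) raises
    :class:`ConvergenceError`.
    """
    h = np.asarray(activations, dtype=float)
    if h.size < 2 or np.ptp(h) == 0.0:
        raise ConvergenceError("sparsity target unattainable: degenerate activations")
    lo = float(h.min()) - 1.0  # all units active: a close to its supremum
    hi = float(h.max())  # a -> 1/N as theta -> max(h)
    a_lo = sparsity(np.maximum(h - lo, 0.0))
    if a_lo < target:
        # push lo further down; a(theta) -> 1 as theta -> -inf
        for _ in range(60):
            lo = lo * 2.0 if lo < -1.0 else lo - 2.0 * (1.0 + np.ptp(h))
            a_lo = sparsity(np.maximum(h - lo, 0.0))
            if a_lo >= target:
                break
        else:
            raise ConvergenceError("sparsity target unattainable from below")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        eta = np.maximum(h - mid, 0.0)
        a = sparsity(eta) if eta.any() else 0.0
        if abs(a - target) < tol:
            return mid
        if a > target:
            lo = mid
        else:
            hi = mid
    raise ConvergenceError("threshold bisection did not converge")


def adjust_threshold(
    proj: MossyProjection,
    dg_rate_vector: np.ndarray,
    ca3: CA3Params,
    rng_seed: int | None = None,
    tol: float = 1e-3,
) -> float:
    """Threshold that realizes the target sparsity, with noise frozen.

    Draws one set of noise values, freezes them, and bisects the threshold
    until the realized Treves–Rolls sparsity matches
    ``ca3.target_sparsity`` within ``tol``.
    """
    rng = np.random.default_rng(rng_seed)
    noise = rng.normal(0.0, ca3.noise_sd, size=proj.n_ca3)
    h = proj.weights @ np.asarray(dg_rate_vector, dtype=float) + noise
    return threshold_for_target(h, ca3.target_sparsity, tol=tol)


def thresholds_batch(
    activations: np.ndarray,
    target: float,
    n_iter: int = 34,
    chunk: int = 20000,
) -> np.ndarray:
    """Per-row thresholds for a (T, N) activation array (vectorized bisection).

    Used on whole simulated sessions, where the threshold is re-adjusted at
    every time step to model tight inhibitory control.
    """
    A = np.asarray(activations)
    T, N = A.shape
    out = np.empty(T, dtype=np.float64)
    for s in range(0, T, chunk):
        e = min(s + chunk, T)
        a_chunk = A[s:e]
        lo = a_chunk.min(axis=1) - 4.0 * (np.ptp(a_chunk, axis=1) + 1.0)
        hi = a_chunk.max(axis=1)
        for _ in range(n_iter):
            mid = 0.5 * (lo + hi)
            eta = np.maximum(a_chunk - mid[:, None], 0.0)
            s1 = eta.sum(axis=1)
            s2 = np.einsum("ij,ij->i", eta, eta)
            with np.errstate(divide="ignore", invalid="ignore"):
                a = np.where(s2 > 0.0, s1 * s1 / (N * s2), 0.0)
            go_up = a > target
            lo = np.where(go_up, mid, lo)
            hi = np.where(go_up, hi, mid)
        out[s:e] = 0.5 * (lo + hi)
    return out


def hebbian_update(
    proj: MossyProjection,
    dg_rate_vector: np.ndarray,
    ca3_activity: CA3Activity,
    gamma: float,
) -> MossyProjection:
    """One step of postsynaptically gated Hebbian plasticity (in place).

    For each CA3 unit with ``eta_i > 0``, every existing connection relaxes
    toward the presynaptic rate: ``w_ij <- w_ij + gamma * eta_i *
    (beta_j - w_ij)``, clipped at 0.  Silent units (``eta_i = 0``) keep
    their rows untouched; ``gamma = 0`` is the identity; anatomy is never
    modified.  Returns the same projection object for chaining.
    """
    if gamma < 0:
        raise ParameterError("gamma must be non-negative")
    if gamma == 0.0:
        return proj
    eta = ca3_activity.rates
    beta = np.asarray(dg_rate_vector, dtype=float)
    rows = np.flatnonzero(eta > 0.0)
    if rows.size:
        w = proj.weights[rows]
        step = gamma * eta[rows, None]
        w += step * (beta[None, :] - w)
        np.maximum(w, 0.0, out=w)
        w[~proj.connectivity[rows]] = 0.0
        proj.weights[rows] = w
    proj.gamma = gamma
    return proj
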