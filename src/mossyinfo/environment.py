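"""Toroidal arena geometry, spatial binning and virtual-rat trajectories.

The arena is a flat square of side ``side_length`` with periodic boundary
conditions (a torus), so there are no walls and no border effects.  It is
discretized into ``side_bins x side_bins`` equal square bins for decoding
and occupancy statistics; positions themselves are continuous, with each
coordinate in the half-open interval ``[0, side_length)`` and the origin at
a corner.  One bin side equals one "grid unit".

The virtual rat performs a persistent random walk: at every time step it
moves a fixed distance in a direction obtained by perturbing the previous
heading with a small wrapped-Gaussian angle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, ParameterError

__all__ = [
    "EnvironmentGrid",
    "Trajectory",
    "make_grid",
    "torus_displacement",
    "torus_distance",
    "bin_position",
    "bin_center",
    "generate_trajectory",
    "occupancy",
]


@dataclass(frozen=True)
class EnvironmentGrid:
    """Square toroidal arena and its spatial discretization.

    Attributes
    ----------
    side_bins : int
        Number of bins per side (total bins = ``side_bins ** 2``).
    side_length : float
        Physical side in grid units; by convention 1 bin = 1 grid unit
        when ``side_length == side_bins``.
    """

    side_bins: int
    side_length: float

    def __post_init__(self) -> None:
        if self.side_bins < 2:
            raise ParameterError("side_bins must be an integer >= 2")
        if not np.isfinite(self.side_length) or self.side_length <= 0:
            raise ParameterError("side_length must be positive")

    @property
    def n_bins(self) -> int:
        return self.side_bins**2

    @property
    def bin_size(self) -> float:
        return self.side_length / self.side_bins

    @property
    def area(self) -> float:
        return self.side_length**2


def make_grid(side_bins: int = 20, side_length: float = 20.0) -> EnvironmentGrid:
    """Build an :class:`EnvironmentGrid` whose bins partition the square."""
    if int(side_bins) != side_bins:
        raise ParameterError("side_bins must be an integer")
    return EnvironmentGrid(int(side_bins), float(side_length))


def _as_positions(p) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.ndim == 0 or arr.shape[-1] != 2:
        raise InvalidInputError("positions must have shape (..., 2)")
    return arr


def _check_in_square(arr: np.ndarray, env: EnvironmentGrid) -> None:
    if np.any(arr < 0.0) or np.any(arr >= env.side_length):
        raise InvalidInputError(
            f"positions must lie in [0, {env.side_length}) per coordinate"
        )


def torus_displacement(p, q, env: EnvironmentGrid) -> np.ndarray:
    """Minimal-image vector from ``p`` to ``q`` on the torus.

    Each component of the result lies in ``[-side_length/2, side_length/2)``.
    """
    p = _as_positions(p)
    q = _as_positions(q)
    _check_in_square(p, env)
    _check_in_square(q, env)
    half = env.side_length / 2.0
    return (q - p + half) % env.side_length - half


def torus_distance(p, q, env: EnvironmentGrid) -> np.ndarray:
    """Torus (minimal-image) Euclidean distance between positions."""
    d = torus_displacement(p, q, env)
    return np.linalg.norm(d, axis=-1)


def bin_position(p, env: EnvironmentGrid):
    """Row-major index of the half-open bin containing each position.

    Bin 0 is the corner cell containing the origin; the index increases
    first along x (columns), then along y (rows).
    """
    arr = _as_positions(p)
    _check_in_square(arr, env)
    col = np.minimum((arr[..., 0] / env.bin_size).astype(np.int64), env.side_bins - 1)
    row = np.minimum((arr[..., 1] / env.bin_size).astype(np.int64), env.side_bins - 1)
    idx = row * env.side_bins + col
    return idx if idx.ndim else int(idx)


def bin_center(k, env: EnvironmentGrid) -> np.ndarray:
    """Position of the center of bin ``k`` (inverse of :func:`bin_position`)."""
    k = np.asarray(k)
    if np.any(k < 0) or np.any(k >= env.n_bins):
        raise InvalidInputError("bin index out of range")
    row, col = np.divmod(k, env.side_bins)
    return np.stack(
        [(col + 0.5) * env.bin_size, (row + 0.5) * env.bin_size], axis=-1
    )


@dataclass(frozen=True)
class Trajectory:
    """A persistent random walk on the torus.

    ``positions`` has shape ``(n_steps, 2)``; consecutive positions are
    exactly ``step_length`` apart in the torus metric.
    """

    positions: np.ndarray
    step_length: float
    turn_noise: float
    seed: int | None

    @property
    def n_steps(self) -> int:
        return self.positions.shape[0]


def generate_trajectory(
    env: EnvironmentGrid,
    n_steps: int,
    step_length: float = 0.5,
    turn_noise: float = 0.2,
    seed: int | None = None,
    start=None,
    heading: float | None = None,
) -> Trajectory:
    """Generate a persistent random walk of ``n_steps`` positions.

    The heading at step ``t`` equals the heading at ``t - 1`` plus a
    zero-mean Gaussian perturbation of standard deviation ``turn_noise``
    (radians).  With ``turn_noise = 0`` the walk is a straight geodesic.
    Reproducible given ``seed``.
    """
    if n_steps < 1:
        raise ParameterError("n_steps must be >= 1")
    if step_length <= 0:
        raise ParameterError("step_length must be positive")
    if turn_noise < 0:
        raise ParameterError("turn_noise must be non-negative")
    rng = np.random.default_rng(seed)
    L = env.side_length
    if start is None:
        start = rng.uniform(0.0, L, size=2)
    else:
        start = _as_positions(start)
        _check_in_square(start, env)
    if heading is None:
        heading = rng.uniform(0.0, 2.0 * np.pi)
    turns = rng.normal(0.0, turn_noise, size=n_steps - 1) if n_steps > 1 else np.empty(0)
    headings = heading + np.concatenate([[0.0], np.cumsum(turns)])
    steps = step_length * np.stack([np.cos(headings), np.sin(headings)], axis=-1)
    # position k = start + sum of the first k steps, wrapped onto the torus
    pos = (start + np.concatenate([[[0.0, 0.0]], np.cumsum(steps[:-1], axis=0)])) % L
    pos[pos >= L] -= L  # guard the half-open interval against rounding at 0-
    return Trajectory(pos, float(step_length), float(turn_noise), seed)


def occupancy(traj_or_bins, env: EnvironmentGrid) -> np.ndarray:
    """Bin occupancy counts of a trajectory (or of precomputed bin indices)."""
    if isinstance(traj_or_bins, Trajectory):
        bins = bin_position(traj_or_bins.positions, env)
    else:
        bins = np.asarray(traj_or_bins, dtype=np.int64)
        if np.any(bins < 0) or np.any(bins >= env.n_bins):
            raise InvalidInputError("bin index out of range")
    return np.bincount(bins, minlength=env.n_bins)
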