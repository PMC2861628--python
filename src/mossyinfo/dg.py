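"""Dentate-gyrus population: field counts, field placement and firing rates.

Only a small fraction ``p_active`` of granule cells is active in a given
environment.  Each active unit expresses a variable number ``q`` of place
fields drawn from one of three laws:

* model ``A`` — Poisson with mean ``nu`` (``q = 0`` is possible, so a unit
  can be flagged active yet remain silent);
* model ``B`` — a discrete exponential, implemented as the geometric law on
  ``q >= 1`` with mean ``nu``;
* model ``C`` — exactly one field per active unit.

Each field is an isotropic Gaussian bump of unit peak rate, truncated to
zero beyond a radius ``R = sqrt(field_area_ratio * A / pi)``; the Gaussian
width is tied to the cut as ``sigma_f = R / 2``, so the bump has decayed to
``exp(-2)`` of its peak at the truncation circle.  Field centers are drawn
uniformly over the arena and distances use the torus metric, so fields wrap
across edges.  DG firing is noise-free and threshold-free; a unit's rate is
the plain sum of its bumps, and overlapping fields can exceed the single
field peak.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .environment import EnvironmentGrid, _as_positions, _check_in_square
from .errors import ParameterError

__all__ = [
    "DGParams",
    "DGFieldSet",
    "sample_field_counts",
    "place_fields",
    "dg_rates",
    "dg_rate_matrix",
    "degrade_cue",
]


@dataclass(frozen=True)
class DGParams:
    """Parameters of the dentate population.

    ``n_dg`` granule cells; each is active in the environment with
    probability ``p_active``; active units draw their field count from the
    chosen ``model`` with mean ``nu`` (ignored for model C).
    ``field_area_ratio`` is the ratio between the area of one field and the
    arena area; ``peak_rate`` fixes the rate units (1 by convention).
    """

    n_dg: int = 15000
    p_active: float = 0.033
    nu: float = 1.7
    model: str = "A"
    field_area_ratio: float = 0.05
    peak_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.n_dg < 1:
            raise ParameterError("n_dg must be >= 1")
        if not 0.0 <= self.p_active <= 1.0:
            raise ParameterError("p_active must lie in [0, 1]")
        if self.model not in ("A", "B", "C"):
            raise ParameterError("model must be one of 'A', 'B', 'C'")
        if self.model != "C" and self.nu <= 0:
            raise ParameterError("nu must be positive")
        if not 0.0 < self.field_area_ratio < 1.0:
            raise ParameterError("field_area_ratio must lie in (0, 1)")
        if self.peak_rate <= 0:
            raise ParameterError("peak_rate must be positive")


def sample_field_counts(
    params: DGParams, rng_seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Sample per-unit field counts.

    Returns ``(counts, active)``: integer field counts (0 for units not
    flagged active) and the boolean activity flags.  Under model A an
    active unit may still draw ``q = 0``.
    """
    rng = np.random.default_rng(rng_seed)
    active = rng.random(params.n_dg) < params.p_active
    counts = np.zeros(params.n_dg, dtype=np.int64)
    m = int(active.sum())
    if m:
        if params.model == "A":
            counts[active] = rng.poisson(params.nu, m)
        elif params.model == "B":
            if params.nu < 1.0:
                raise ParameterError(
                    "model B needs nu >= 1 (geometric law on q >= 1)"
                )
            counts[active] = rng.geometric(1.0 / params.nu, m)
        else:  # model C
            counts[active] = 1
    return counts, active


@dataclass(frozen=True)
class DGFieldSet:
    """Sampled field geometry for one DG population in one environment.

    ``centers`` (n_fields, 2) holds all field centers, ``unit_of_field``
    the owning unit of each center (fields of one unit are contiguous).
    """

    counts: np.ndarray
    active: np.ndarray
    centers: np.ndarray
    unit_of_field: np.ndarray
    sigma_f: float
    radius: float
    peak_rate: float
    side_length: float

    @property
    def n_units(self) -> int:
        return self.counts.shape[0]

    @property
    def n_fields(self) -> int:
        return self.centers.shape[0]

    def units_with_fields(self) -> np.ndarray:
        return np.flatnonzero(self.counts > 0)


def field_radius(params: DGParams, env: EnvironmentGrid) -> float:
    """Truncation radius ``R = sqrt(field_area_ratio * A / pi)``."""
    return float(np.sqrt(params.field_area_ratio * env.area / np.pi))


def place_fields(
    counts: np.ndarray,
    env: EnvironmentGrid,
    params: DGParams,
    rng_seed: int | None = None,
    active: np.ndarray | None = None,
) -> DGFieldSet:
    """Place each field center uniformly and independently over the arena."""
    counts = np.asarray(counts, dtype=np.int64)
    if active is None:
        active = counts > 0
    rng = np.random.default_rng(rng_seed)
    n_fields = int(counts.sum())
    centers = rng.uniform(0.0, env.side_length, size=(n_fields, 2))
    unit_of_field = np.repeat(np.arange(counts.shape[0]), counts)
    R = field_radius(params, env)
    return DGFieldSet(
        counts=counts,
        active=np.asarray(active, dtype=bool),
        centers=centers,
        unit_of_field=unit_of_field,
        sigma_f=R / 2.0,
        radius=R,
        peak_rate=params.peak_rate,
        side_length=env.side_length,
    )


def _bump_values(fields: DGFieldSet, positions: np.ndarray) -> np.ndarray:
    """Per-field truncated-Gaussian values at each position: (T, n_fields)."""
    L = fields.side_length
    half = L / 2.0
    dx = (positions[:, 0:1] - fields.centers[None, :, 0] + half) % L - half
    dy = (positions[:, 1:2] - fields.centers[None, :, 1] + half) % L - half
    d2 = dx * dx + dy * dy
    out = np.exp(-d2 / (2.0 * fields.sigma_f**2))
    out[d2 > fields.radius**2] = 0.0
    return fields.peak_rate * out


def dg_rates(fields: DGFieldSet, p, env: EnvironmentGrid) -> np.ndarray:
    """DG rate vector (length n_dg) at a single position."""
    pos = _as_positions(p).reshape(1, 2)
    _check_in_square(pos, env)
    rates = np.zeros(fields.n_units)
    if fields.n_fields:
        vals = _bump_values(fields, pos)[0]
        np.add.at(rates, fields.unit_of_field, vals)
    return rates


def dg_rate_matrix(
    fields: DGFieldSet,
    positions: np.ndarray,
    env: EnvironmentGrid,
    chunk: int = 20000,
) -> tuple[np.ndarray, np.ndarray]:
    """Rates of all field-bearing units along a position sequence.

    Returns ``(rates, unit_ids)`` where ``rates`` has shape
    ``(n_positions, len(unit_ids))`` and ``unit_ids`` are the units with at
    least one field.  Silent units are omitted (their rate is identically
    zero).
    """
    positions = _as_positions(positions)
    _check_in_square(positions, env)
    unit_ids = fields.units_with_fields()
    T = positions.shape[0]
    out = np.empty((T, unit_ids.shape[0]), dtype=np.float64)
    if unit_ids.shape[0] == 0:
        return out, unit_ids
    # fields are stored unit-contiguous: reduce per-field values by segment
    boundaries = np.concatenate([[0], np.cumsum(fields.counts[unit_ids])])[:-1]
    for lo in range(0, T, chunk):
        hi = min(lo + chunk, T)
        vals = _bump_values(fields, positions[lo:hi])
        out[lo:hi] = np.add.reduceat(vals, boundaries, axis=1)
    return out, unit_ids


def degrade_cue(
    fields: DGFieldSet, fraction: float, rng_seed: int | None = None
) -> DGFieldSet:
    """Silence a random subset of the normally active units.

    A share ``fraction`` of the active units keeps its fields; the rest are
    silenced (counts zeroed, fields removed) for the whole test.  The
    selection is fixed by ``rng_seed``.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ParameterError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    active_ids = np.flatnonzero(fields.active)
    n_keep = int(round(fraction * active_ids.shape[0]))
    keep_ids = rng.choice(active_ids, size=n_keep, replace=False)
    keep_mask = np.zeros(fields.n_units, dtype=bool)
    keep_mask[keep_ids] = True
    counts = np.where(keep_mask, fields.counts, 0)
    field_keep = keep_mask[fields.unit_of_field]
    return replace(
        fields,
        counts=counts,
        active=fields.active & keep_mask,
        centers=fields.centers[field_keep],
        unit_of_field=fields.unit_of_field[field_keep],
    )
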