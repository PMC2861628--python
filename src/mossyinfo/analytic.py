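"""Analytical route to the single-unit spatial information.

A CA3 unit's noise-free drive is a sum of identical truncated-Gaussian
bumps, one per DG field feeding it; with uniform weights the drive depends
only on the *total* number of fields K, no matter how many presynaptic
units carry them.  The quenched average over connectivity and field counts
therefore reduces to an expansion in K with coefficients

    psi_K = P(total fields feeding a unit = K),

the compound law of a Poisson number (mean ``lambda = c_mf * p_active``) of
active inputs, each carrying a model-dependent number of fields (Poisson
for model A, geometric for model B, exactly one for model C).  The
coefficients are computed with the exact compound-Poisson (Panjer)
recursion and cross-checked against Monte Carlo in the test suite.

For given K, the channel from position x (uniform over the arena) to the
rate eta = [s(x) - theta + eps]_+ is mixed discrete/continuous: an atom at
zero (the below-threshold Gaussian tail) plus a truncated Gaussian density.
The single-unit information, the equivocation and the response entropy are
evaluated by numerical quadrature on a spatial grid and an eta grid, with
the zero atom treated exactly, then averaged over seeded Monte-Carlo draws
of the field centers and finally over K with weights psi_K.

The threshold is tied to the CA3 sparsity through the Treves–Rolls relation
a(theta) evaluated over the same quenched ensemble, inverted by bisection
when a target sparsity rather than a threshold is prescribed.

Only the first-order (single-unit) term is computed here; population
information is at most reported as N times this value.  The higher-order
correlation corrections are out of scope.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import ndtr, xlogy
from scipy.stats import geom, poisson

from .errors import ConvergenceError, ParameterError

__all__ = [
    "KFieldDecomposition",
    "AnalyticParams",
    "AnalyticInfo",
    "field_count_coeffs",
    "sample_total_fields",
    "limit_equivalence_check",
    "analytic_channel",
    "single_unit_info",
    "equivocation_analytic",
    "entropy_analytic",
    "sparsity_given_threshold",
    "threshold_for_sparsity",
    "linear_limit_info",
]

_SQRT2PI = np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class KFieldDecomposition:
    """Coefficients ``psi_K`` of the K-field expansion.

    ``psi[K]`` is the probability that the active DG units presynaptic to a
    CA3 unit carry K fields in total; ``lam`` is the mean number of active
    inputs, ``nu`` the mean fields per active input (None for model C).
    """

    psi: np.ndarray
    lam: float
    nu: float | None
    model: str
    k_max: int

    def tail(self) -> float:
        return float(max(1.0 - self.psi.sum(), 0.0))


def _severity_pmf(model: str, nu: float | None, k_max: int) -> np.ndarray:
    """Per-active-unit field-count law f(q), q = 0..k_max."""
    q = np.arange(k_max + 1)
    if model == "A":
        return poisson.pmf(q, nu)
    if model == "B":
        if nu is None or nu < 1.0:
            raise ParameterError("model B needs nu >= 1 (geometric on q >= 1)")
        return np.concatenate([[0.0], geom.pmf(q[1:], 1.0 / nu)])
    if model == "C":
        out = np.zeros(k_max + 1)
        out[min(1, k_max)] = 1.0
        return out
    raise ParameterError("model must be one of 'A', 'B', 'C'")


def field_count_coeffs(
    model: str,
    lam: float,
    nu: float | None = None,
    k_max: int = 30,
    tail_tol: float = 1e-6,
) -> KFieldDecomposition:
    """Compound-Poisson coefficients psi_K via the Panjer recursion.

    The truncation order is auto-extended (doubling, up to 4096) until the
    tail mass drops below ``tail_tol``; model C reduces exactly to the
    Poisson(lam) mass function.
    """
    if lam <= 0:
        raise ParameterError("lambda (mean active inputs) must be positive")
    if model == "C":
        k = k_max
        psi = poisson.pmf(np.arange(k + 1), lam)
        while 1.0 - psi.sum() > tail_tol and k < 4096:
            k *= 2
            psi = poisson.pmf(np.arange(k + 1), lam)
        return KFieldDecomposition(psi, float(lam), None, model, k)
    k = k_max
    while True:
        f = _severity_pmf(model, nu, k)
        # absorb the severity zero-mass into the Poisson rate
        lam_eff = lam * (1.0 - f[0])
        g = np.zeros_like(f)
        if lam_eff > 0:
            g[1:] = f[1:] / (1.0 - f[0])
        psi = np.zeros(k + 1)
        psi[0] = np.exp(-lam_eff)
        j = np.arange(k + 1)
        jg = j * g
        for K in range(1, k + 1):
            psi[K] = lam_eff / K * np.dot(jg[1 : K + 1], psi[K - 1 :: -1])
        if 1.0 - psi.sum() <= tail_tol or k >= 4096:
            if 1.0 - psi.sum() > tail_tol:
                raise ConvergenceError("psi_K tail did not fall below tolerance")
            return KFieldDecomposition(psi, float(lam), float(nu), model, k)
        k *= 2


def sample_total_fields(
    model: str, lam: float, nu: float | None, n_draws: int, rng_seed: int | None = None
) -> np.ndarray:
    """Monte-Carlo draws of the total field count K (independent oracle).

    Draws the number of active inputs m ~ Poisson(lam) and sums m
    field-count draws, using the closed forms for the sums (sum of m
    Poissons is Poisson, sum of m geometrics is m + negative binomial).
    """
    rng = np.random.default_rng(rng_seed)
    m = rng.poisson(lam, n_draws)
    if model == "A":
        return rng.poisson(nu * m)
    if model == "B":
        out = np.zeros(n_draws, dtype=np.int64)
        pos = m > 0
        out[pos] = m[pos] + rng.negative_binomial(m[pos], 1.0 / nu)
        return out
    if model == "C":
        return m
    raise ParameterError("model must be one of 'A', 'B', 'C'")


def limit_equivalence_check(
    model: str, lam_nu: float, nus, k_max: int = 64
) -> np.ndarray:
    """Sup-norm discrepancy between psi_K and the single-field limit.

    For a sequence of ``nu`` values with ``lam * nu`` held fixed, compares
    the model-A/B coefficients against the Poisson(lam*nu) masses of model
    C; the discrepancy must shrink as ``nu`` decreases.
    """
    if model not in ("A", "B"):
        raise ParameterError("the limit check applies to models A and B")
    target = poisson.pmf(np.arange(k_max + 1), lam_nu)
    out = []
    for nu in nus:
        dec = field_count_coeffs(model, lam_nu / nu, nu, k_max=k_max)
        k = min(dec.psi.shape[0], k_max + 1)
        out.append(float(np.max(np.abs(dec.psi[:k] - target[:k]))))
    return np.array(out)


@dataclass(frozen=True)
class AnalyticParams:
    """Model plus quadrature settings for the analytic estimate.

    Model symbols: ``lam = c_mf * p_active`` active inputs per CA3 unit,
    ``nu`` mean fields per input, ``j_strength`` (J) the MF weight,
    ``noise_sd`` (delta) the Gaussian noise SD, ``theta`` the threshold
    (resolved from ``target_sparsity`` when None).  Quadrature: spatial
    grid of ``grid_points^2`` points, ``n_eta`` points on the rate axis,
    ``n_configs`` Monte-Carlo field-center configurations per K (seeded),
    ``n_point_samples`` draws for the sparsity relation.
    """

    c_mf: float = 50.0
    p_active: float = 0.033
    nu: float = 1.7
    model: str = "A"
    j_strength: float = 1.0
    noise_sd: float = 1.0
    theta: float | None = None
    target_sparsity: float = 0.1
    field_area_ratio: float = 0.05
    side_length: float = 20.0
    grid_points: int = 40
    n_eta: int = 241
    n_configs: int = 2000
    k_tail_tol: float = 1e-6
    psi_floor: float = 1e-5
    n_point_samples: int = 200_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c_mf <= 0 or not 0 < self.p_active <= 1:
            raise ParameterError("need c_mf > 0 and p_active in (0, 1]")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be positive for the analytic route")
        if min(self.grid_points, self.n_eta, self.n_configs) < 2:
            raise ParameterError("quadrature settings must be >= 2")

    @property
    def lam(self) -> float:
        return self.c_mf * self.p_active

    @property
    def area(self) -> float:
        return self.side_length**2

    @property
    def radius(self) -> float:
        return float(np.sqrt(self.field_area_ratio * self.area / np.pi))

    @property
    def sigma_f(self) -> float:
        return self.radius / 2.0

    def coeffs(self) -> KFieldDecomposition:
        return field_count_coeffs(
            self.model, self.lam, self.nu, tail_tol=self.k_tail_tol
        )


def _config_signal(params: AnalyticParams, K: int, rng) -> np.ndarray:
    """Noise-free drive J*sum of K bumps on the spatial grid (flattened)."""
    L = params.side_length
    g = params.grid_points
    ax = (np.arange(g) + 0.5) * (L / g)
    X, Y = np.meshgrid(ax, ax, indexing="xy")
    centers = rng.uniform(0.0, L, size=(K, 2))
    u = np.zeros(g * g)
    half = L / 2.0
    for cx, cy in centers:
        dx = (X.ravel() - cx + half) % L - half
        dy = (Y.ravel() - cy + half) % L - half
        d2 = dx * dx + dy * dy
        b = np.exp(-d2 / (2.0 * params.sigma_f**2))
        b[d2 > params.radius**2] = 0.0
        u += b
    return params.j_strength * u


def _channel_stats(
    u: np.ndarray, theta: float, delta: float, n_eta: int
) -> tuple[float, float, float]:
    """(information, response entropy, equivocation) in bits for one config.

    The response eta = [u(x) - theta + eps]_+ has an atom at zero of weight
    Phi((theta - u)/delta) and a truncated-Gaussian density above zero; the
    atom is handled exactly and the continuous branch by trapezoidal
    quadrature, with the same discretization for all three quantities so
    that entropy - equivocation = information holds to machine precision.
    """
    shift = u - theta  # mean of the pre-rectification Gaussian
    p0 = ndtr(-shift / delta)  # per-position atom weight
    p0_bar = p0.mean()
    eta_max = max(float(shift.max()), 0.0) + 6.0 * delta
    eta = np.linspace(0.0, eta_max, n_eta)
    z = (eta[None, :] - shift[:, None]) / delta
    f = np.exp(-0.5 * z * z) / (delta * _SQRT2PI)  # (n_x, n_eta)
    f_bar = f.mean(axis=0)

    log2_f = np.log2(f, out=np.zeros_like(f), where=f > 0)
    log2_fbar = np.log2(f_bar, out=np.zeros_like(f_bar), where=f_bar > 0)

    # information: atom term + continuous KL term, averaged over x
    log2_p0 = np.log2(p0, out=np.zeros_like(p0), where=p0 > 0)
    atom = np.where(p0 > 0, p0 * (log2_p0 - np.log2(p0_bar)), 0.0)
    kl_cont = np.trapezoid(f * (log2_f - log2_fbar[None, :]), eta, axis=1)
    info = float(atom.mean() + kl_cont.mean())

    h_resp = float(-xlogy(p0_bar, p0_bar) / np.log(2.0) - np.trapezoid(f_bar * log2_fbar, eta))
    equiv = h_resp - info
    return info, h_resp, equiv


def _config_rng(seed: int, K: int, i: int):
    """Deterministic per-(K, config) stream, shared across parameter sets
    with the same seed so that comparisons cancel Monte-Carlo noise."""
    return np.random.default_rng(np.random.SeedSequence([seed, K, i]))


@dataclass(frozen=True)
class AnalyticInfo:
    """Quenched-averaged single-unit channel quantities (bits)."""

    info_bits: float
    entropy_bits: float
    equivocation_bits: float
    linear_limit_bits: float
    theta: float
    psi: np.ndarray
    per_k_info: np.ndarray
    mc_se_bits: float


@functools.lru_cache(maxsize=32)
def analytic_channel(params: AnalyticParams) -> AnalyticInfo:
    """Evaluate information, entropy, equivocation and the linear-limit
    value over the quenched ensemble (psi_K-weighted, seeded Monte Carlo
    over field centers)."""
    theta = (
        params.theta
        if params.theta is not None
        else threshold_for_sparsity(params.target_sparsity, params)
    )
    dec = params.coeffs()
    psi = dec.psi
    ks = [K for K in range(1, psi.shape[0]) if psi[K] > params.psi_floor]
    delta = params.noise_sd
    info_k = np.zeros(psi.shape[0])
    ent_k = np.zeros(psi.shape[0])
    eq_k = np.zeros(psi.shape[0])
    lin_k = np.zeros(psi.shape[0])
    var_sum = 0.0
    # K = 0: constant (pure-noise) response carries no information
    _, h0, e0 = _channel_stats(np.zeros(1), theta, delta, params.n_eta)
    ent_k[0], eq_k[0] = h0, e0
    for K in ks:
        vals = np.empty(params.n_configs)
        for i in range(params.n_configs):
            u = _config_signal(params, K, _config_rng(params.seed, K, i))
            mi, h, eq = _channel_stats(u, theta, delta, params.n_eta)
            vals[i] = mi
            ent_k[K] += h
            eq_k[K] += eq
            v = float(np.var(u))
            lin_k[K] += 0.5 * np.log2(1.0 + v / delta**2)
        info_k[K] = vals.mean()
        ent_k[K] /= params.n_configs
        eq_k[K] /= params.n_configs
        lin_k[K] /= params.n_configs
        var_sum += psi[K] ** 2 * vals.var(ddof=1) / params.n_configs
    return AnalyticInfo(
        info_bits=float(psi @ info_k),
        entropy_bits=float(psi @ ent_k),
        equivocation_bits=float(psi @ eq_k),
        linear_limit_bits=float(psi @ lin_k),
        theta=float(theta),
        psi=psi,
        per_k_info=info_k,
        mc_se_bits=float(np.sqrt(var_sum)),
    )


def single_unit_info(params: AnalyticParams) -> float:
    """Single-unit spatial information (bits), quenched-averaged."""
    return analytic_channel(params).info_bits


def equivocation_analytic(params: AnalyticParams) -> float:
    """Quenched-averaged equivocation (conditional response entropy, bits)."""
    return analytic_channel(params).equivocation_bits


def entropy_analytic(params: AnalyticParams) -> float:
    """Quenched-averaged response entropy (bits)."""
    return analytic_channel(params).entropy_bits


def linear_limit_info(params: AnalyticParams) -> float:
    """Threshold-less linear-unit information (bits).

    Closed spatial signal-to-noise form ``1/2 log2(1 + Var_x(s)/delta^2)``
    per field configuration, psi_K-averaged over the same seeded center
    draws as :func:`single_unit_info`, to which the latter converges as
    theta -> -infinity in the weak-signal regime.
    """
    return analytic_channel(params).linear_limit_bits


# ---------------------------------------------------------------------------
# sparsity <-> threshold relation


@functools.lru_cache(maxsize=32)
def _point_signal_samples(params: AnalyticParams) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo draws of the noise-free drive at one position.

    Returns (weights, samples): for each K with non-negligible psi_K, a
    block of draws of s_K = J * sum of K bump values at a uniformly random
    point, each draw weighted by psi_K / block size.  A bump seen from a
    uniform point is zero with probability 1 - f (f the field/arena area
    ratio) and exp(-d^2 / 2 sigma^2) with d^2 uniform on (0, R^2) otherwise.
    """
    dec = params.coeffs()
    psi = dec.psi
    ks = [K for K in range(1, psi.shape[0]) if psi[K] > params.psi_floor]
    n_per_k = max(2000, params.n_point_samples // max(len(ks), 1))
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 2**20]))
    weights = [psi[0]]
    samples = [0.0]
    f_ratio = params.field_area_ratio
    for K in ks:
        covered = rng.random((n_per_k, K)) < f_ratio
        d2 = rng.uniform(0.0, params.radius**2, size=(n_per_k, K))
        vals = np.exp(-d2 / (2.0 * params.sigma_f**2)) * covered
        s = params.j_strength * vals.sum(axis=1)
        samples.append(s)
        weights.append(np.full(n_per_k, psi[K] / n_per_k))
    return np.concatenate([np.atleast_1d(w) for w in weights]), np.concatenate(
        [np.atleast_1d(s) for s in samples]
    )


def _rectified_moments(shift: np.ndarray, delta: float):
    """First two moments of [shift + eps]_+ with eps ~ N(0, delta^2)."""
    t = shift / delta
    phi = np.exp(-0.5 * t * t) / _SQRT2PI
    Phi = ndtr(t)
    m1 = shift * Phi + delta * phi
    m2 = (shift**2 + delta**2) * Phi + shift * delta * phi
    return m1, m2


def sparsity_given_threshold(theta: float, params: AnalyticParams) -> float:
    """Treves–Rolls sparsity a(theta) over the quenched ensemble.

    ``a = <eta>^2 / <eta^2>`` with averages over space, noise, field counts
    (psi_K) and field centers; strictly decreasing in theta.
    """
    w, s = _point_signal_samples(params)
    m1, m2 = _rectified_moments(s - theta, params.noise_sd)
    return float((w @ m1) ** 2 / (w @ m2))


def threshold_for_sparsity(
    a_target: float, params: AnalyticParams, tol: float = 1e-3
) -> float:
    """Invert a(theta) by bisection to |a - a_target| < tol."""
    if not 0.0 < a_target < 1.0:
        raise ParameterError("target sparsity must lie in (0, 1)")
    w, s = _point_signal_samples(params)
    delta = params.noise_sd
    lo = float(s.min()) - 40.0 * delta  # a -> 1 as theta -> -inf
    hi = float(s.max()) + 40.0 * delta  # a -> 0+

    def a_of(th):
        m1, m2 = _rectified_moments(s - th, delta)
        return float((w @ m1) ** 2 / (w @ m2))

    if a_of(lo) < a_target:
        raise ParameterError("target sparsity outside the attainable range")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        a = a_of(mid)
        if abs(a - a_target) < tol:
            return mid
        if a > a_target:
            lo = mid
        else:
            hi = mid
    raise ConvergenceError("sparsity-threshold inversion did not converge")
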