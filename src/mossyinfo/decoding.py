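"""Template decoding of position from CA3 rates and information estimation.

Position is decoded, time step by time step, by comparing the firing-rate
vector of a sample of CA3 units with the mean vector recorded at each
spatial bin during an independent template pass ("maximum-likelihood
Euclidean distance decoding"): the bin whose template is closest wins, ties
going to the lowest bin index.

The (actual bin, decoded bin) pairs accumulate into a localization
("confusion") matrix in two forms:

* **full** — counts over all (actual, decoded) bin pairs, a
  ``side^2 x side^2`` matrix that needs of order ``side^4`` events to be
  sampled;
* **simplified** — counts over the minimal-image *displacement*
  (decoded − actual), a ``side x side`` matrix that is well sampled within
  a few thousand events but assumes translation-invariant errors.

Plug-in mutual information is computed in bits.  For the full matrix,
``I = H(decoded) − H(decoded | actual)``; for the simplified matrix, by the
translation-invariant construction, ``I = H(decoded) − H(displacement)``,
so that in both cases information and the corresponding equivocation add
up to the same decoded-position entropy.  The limited-sampling bias is
removed with the first-order Panzeri–Treves correction (naive counting of
occupied response bins).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.special import xlogy

from .errors import FitError, InvalidInputError, ParameterError

__all__ = [
    "TemplateSet",
    "LocalizationMatrix",
    "InfoEstimate",
    "InfoCurve",
    "build_templates",
    "decode_step",
    "decode",
    "build_localization",
    "mutual_information",
    "bias_correction",
    "info_vs_sample_size",
    "average_curve",
    "fit_info_curve",
]

_LN2 = np.log(2.0)


@dataclass(frozen=True)
class TemplateSet:
    """Per-bin mean rate vectors from a dedicated template pass.

    ``means`` has shape (n_bins, n_units).  Bins never visited during the
    template pass receive the population-mean template; they are listed in
    ``missing`` and a warning is emitted when any exist.
    """

    means: np.ndarray
    visits: np.ndarray
    missing: tuple[int, ...] = ()

    @property
    def n_bins(self) -> int:
        return self.means.shape[0]

    @property
    def n_units(self) -> int:
        return self.means.shape[1]


def build_templates(
    rates: np.ndarray, bins: np.ndarray, n_bins: int
) -> TemplateSet:
    """Average the rate vectors over each visited bin."""
    rates = np.asarray(rates, dtype=np.float64)
    bins = np.asarray(bins, dtype=np.int64)
    if rates.shape[0] != bins.shape[0]:
        raise InvalidInputError("rates and bins must have equal length")
    visits = np.bincount(bins, minlength=n_bins)
    sums = np.zeros((n_bins, rates.shape[1]))
    np.add.at(sums, bins, rates)
    means = np.divide(
        sums, visits[:, None], out=np.zeros_like(sums), where=visits[:, None] > 0
    )
    missing = tuple(int(b) for b in np.flatnonzero(visits == 0))
    if missing:
        warnings.warn(
            f"{len(missing)} bins unvisited in template pass; "
            "using the population-mean template for them",
            stacklevel=2,
        )
        means[list(missing)] = rates.mean(axis=0)
    return TemplateSet(means=means, visits=visits, missing=missing)


def decode(rates: np.ndarray, templates: TemplateSet, chunk: int = 20000) -> np.ndarray:
    """Decoded bin for each time step (vectorized argmin of Euclidean distance).

    Ties are broken deterministically toward the lowest bin index.
    """
    if templates.n_bins == 0:
        raise InvalidInputError("empty template set")
    r = np.atleast_2d(np.asarray(rates, dtype=np.float64))
    if r.shape[1] != templates.n_units:
        raise InvalidInputError("rate vector dimension does not match templates")
    T = templates.means
    t_sq = np.einsum("bu,bu->b", T, T)
    out = np.empty(r.shape[0], dtype=np.int64)
    for s in range(0, r.shape[0], chunk):
        e = min(s + chunk, r.shape[0])
        # squared distance up to the |r|^2 constant: |T_b|^2 - 2 r . T_b
        scores = t_sq[None, :] - 2.0 * (r[s:e] @ T.T)
        out[s:e] = np.argmin(scores, axis=1)
    return out


def decode_step(rate_vector: np.ndarray, templates: TemplateSet) -> int:
    """Decode a single rate vector to the bin of the closest template."""
    return int(decode(np.asarray(rate_vector)[None, :], templates)[0])


@dataclass(frozen=True)
class LocalizationMatrix:
    """Counts of decoding events.

    ``full`` is (n_bins, n_bins) over (actual, decoded) pairs; ``simplified``
    is (side, side) over minimal-image displacements; the decoded and actual
    marginals are kept for entropy bookkeeping.
    """

    full: np.ndarray
    simplified: np.ndarray
    decoded_counts: np.ndarray
    actual_counts: np.ndarray
    n_events: int
    side_bins: int


def build_localization(
    actual_bins: np.ndarray, decoded_bins: np.ndarray, side_bins: int
) -> LocalizationMatrix:
    """Compile (actual, decoded) pairs into full and displacement matrices."""
    a = np.asarray(actual_bins, dtype=np.int64)
    d = np.asarray(decoded_bins, dtype=np.int64)
    if a.shape != d.shape:
        raise InvalidInputError("actual and decoded sequences must have equal length")
    nb = side_bins * side_bins
    if a.size and (a.min() < 0 or a.max() >= nb or d.min() < 0 or d.max() >= nb):
        raise InvalidInputError("bin index out of range")
    full = np.bincount(a * nb + d, minlength=nb * nb).reshape(nb, nb)
    ar, ac = np.divmod(a, side_bins)
    dr, dc = np.divmod(d, side_bins)
    drow = (dr - ar) % side_bins
    dcol = (dc - ac) % side_bins
    simplified = np.bincount(
        drow * side_bins + dcol, minlength=nb
    ).reshape(side_bins, side_bins)
    return LocalizationMatrix(
        full=full,
        simplified=simplified,
        decoded_counts=np.bincount(d, minlength=nb),
        actual_counts=np.bincount(a, minlength=nb),
        n_events=int(a.size),
        side_bins=side_bins,
    )


@dataclass(frozen=True)
class InfoEstimate:
    """Plug-in information bookkeeping for one localization matrix.

    Invariants: ``corrected = max(raw - bias, 0)`` and
    ``raw = decoded_entropy - equivocation`` exactly (same-matrix plug-in
    identity).  For the simplified matrix the displacement entropy plays
    the role of the equivocation.
    """

    raw_bits: float
    bias_bits: float
    corrected_bits: float
    equivocation_bits: float
    decoded_entropy_bits: float
    which: str
    n_events: int


def _entropy_bits(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-np.sum(p * np.log2(p)))


def mutual_information(matrix: LocalizationMatrix, which: str = "full") -> InfoEstimate:
    """Plug-in mutual information in bits (0·log 0 := 0), uncorrected.

    ``which='full'``: I = H(decoded) − Σ_a p(a) H(decoded | a).
    ``which='simplified'``: I = H(decoded) − H(displacement), the
    translation-invariant construction.
    """
    if matrix.n_events <= 0:
        raise InvalidInputError("no decoding events")
    h_dec = _entropy_bits(matrix.decoded_counts)
    if which == "full":
        rows = matrix.full
        row_tot = rows.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_rows = np.where(row_tot[:, None] > 0, rows / row_tot[:, None], 0.0)
        h_rows = -np.sum(xlogy(p_rows, p_rows), axis=1) / _LN2
        equiv = float(np.sum(row_tot / matrix.n_events * h_rows))
    elif which == "simplified":
        equiv = _entropy_bits(matrix.simplified)
    else:
        raise ParameterError("which must be 'full' or 'simplified'")
    raw = h_dec - equiv
    return InfoEstimate(
        raw_bits=raw,
        bias_bits=0.0,
        corrected_bits=raw,
        equivocation_bits=equiv,
        decoded_entropy_bits=h_dec,
        which=which,
        n_events=matrix.n_events,
    )


def bias_correction(
    estimate: InfoEstimate, matrix: LocalizationMatrix
) -> InfoEstimate:
    """First-order Panzeri–Treves limited-sampling correction.

    For the full matrix the bias is
    ``[Σ_a (R_a − 1) − (R − 1)] / (2 N ln 2)`` with ``R_a`` the occupied
    decoded bins in row ``a`` and ``R`` those in the decoded marginal;
    for the simplified construction the analogous expression is
    ``[(R_disp − 1) − (R_dec − 1)] / (2 N ln 2)``.  The corrected value is
    never driven below 0.
    """
    n = matrix.n_events
    r_dec = int(np.count_nonzero(matrix.decoded_counts))
    if estimate.which == "full":
        r_rows = np.count_nonzero(matrix.full, axis=1)
        r_rows = r_rows[matrix.full.sum(axis=1) > 0]
        bias = (np.sum(r_rows - 1) - (r_dec - 1)) / (2.0 * n * _LN2)
    else:
        r_disp = int(np.count_nonzero(matrix.simplified))
        bias = ((r_disp - 1) - (r_dec - 1)) / (2.0 * n * _LN2)
    corrected = max(estimate.raw_bits - bias, 0.0)
    return replace(estimate, bias_bits=float(bias), corrected_bits=float(corrected))


def info_vs_sample_size(
    rates: np.ndarray,
    actual_bins: np.ndarray,
    templates: TemplateSet,
    sizes,
    n_samples: int,
    side_bins: int,
    rng_seed: int | None = None,
    which=("full", "simplified"),
    correct: bool = True,
) -> pd.DataFrame:
    """Corrected information for random CA3 unit samples of several sizes.

    For each size ``n`` the same decoding pass is repeated for
    ``n_samples`` random unit subsets; rows of the returned long-format
    frame carry (n, sample index, matrix type, raw/bias/corrected bits,
    equivocation, decoded entropy, and the unit ids used).
    """
    rates = np.asarray(rates)
    n_units = rates.shape[1]
    rows = []
    rng = np.random.default_rng(rng_seed)
    for n in sizes:
        if n > n_units:
            raise ParameterError("sample size exceeds population size")
        for s in range(n_samples):
            units = np.sort(rng.choice(n_units, size=n, replace=False))
            sub_templates = TemplateSet(
                means=templates.means[:, units],
                visits=templates.visits,
                missing=templates.missing,
            )
            decoded = decode(rates[:, units], sub_templates)
            matrix = build_localization(actual_bins, decoded, side_bins)
            for w in which:
                est = mutual_information(matrix, w)
                if correct:
                    est = bias_correction(est, matrix)
                rows.append(
                    {
                        "n": int(n),
                        "sample": s,
                        "which": w,
                        "raw_bits": est.raw_bits,
                        "bias_bits": est.bias_bits,
                        "corrected_bits": est.corrected_bits,
                        "equivocation_bits": est.equivocation_bits,
                        "decoded_entropy_bits": est.decoded_entropy_bits,
                        "units": ",".join(map(str, units)),
                    }
                )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class InfoCurve:
    """Mean corrected information versus sample size, with optional fit."""

    n: np.ndarray
    bits: np.ndarray
    sd: np.ndarray
    i1: float | None = None
    i_tot: float | None = None


def average_curve(df: pd.DataFrame, which: str = "full") -> InfoCurve:
    """Average the per-sample corrected bits over samples for each size."""
    sub = df[df["which"] == which]
    g = sub.groupby("n")["corrected_bits"]
    n = np.array(sorted(g.groups))
    return InfoCurve(
        n=n,
        bits=g.mean().loc[n].to_numpy(),
        sd=g.std(ddof=0).loc[n].to_numpy(),
    )


def _saturating(n, i1, i_tot):
    return i_tot * (1.0 - np.exp(-n * i1 / i_tot))


def fit_info_curve(n, bits) -> tuple[float, float]:
    """Least-squares fit of ``I(n) = I_tot (1 − exp(−n I₁ / I_tot))``.

    Returns the initial slope ``I₁`` (bits/unit) and the saturation level
    ``I_tot`` (bits).  Initialization: ``I₁`` from the first point,
    ``I_tot`` from the last.
    """
    n = np.asarray(n, dtype=float)
    bits = np.asarray(bits, dtype=float)
    if np.unique(n).size < 3:
        raise ParameterError("need at least 3 distinct sample sizes to fit")
    p0 = (max(bits[0] / n[0], 1e-6), max(bits[-1], 1e-6))
    try:
        popt, _ = curve_fit(
            _saturating,
            n,
            bits,
            p0=p0,
            bounds=([1e-12, 1e-12], [np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - diagnostics
        raise FitError(f"information-curve fit failed: {exc}") from exc
    return float(popt[0]), float(popt[1])
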