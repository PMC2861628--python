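"""Parameter sweeps and end-to-end experiments, with seeds and tabular output.

Every experiment is a thin orchestration of the library modules: simulate
sessions (:mod:`mossyinfo.simulate`), decode and estimate information
(:mod:`mossyinfo.decoding`), and, where meaningful, the analytic
single-unit estimate (:mod:`mossyinfo.analytic`).  Results come back as
long-format :class:`pandas.DataFrame` tables in which every row carries the
full parameter set and seed, so runs are bit-reproducible from
(config, seed).

Two scale profiles are provided: ``paper`` (15000 DG x 500 CA3, 400k-step
trajectories) and ``desk`` (5000 x 200, 100k steps), the latter suitable
for interactive work and continuous testing.  When ``c_mf`` or ``p_active``
is swept, the MF strength J is rescaled inversely so the mean total DG
input per CA3 unit stays fixed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .analytic import AnalyticParams, single_unit_info
from .ca3 import CA3Params
from .decoding import average_curve, fit_info_curve, info_vs_sample_size
from .dg import DGParams, degrade_cue
from .errors import ParameterError
from .simulate import SessionParams, field_census, run_session, train_projection

__all__ = [
    "Profile",
    "PROFILES",
    "ExperimentConfig",
    "session_params",
    "analytic_params",
    "run_info_session",
    "run_sweep_connectivity",
    "run_sweep_field_multiplicity",
    "run_sweep_dg_activity",
    "run_dark_information",
    "run_plasticity",
    "run_degraded_cue",
]


@dataclass(frozen=True)
class Profile:
    """Scale profile: network size, run length and sampling plan."""

    n_dg: int
    n_ca3: int
    n_steps: int
    sizes: tuple[int, ...]
    n_unit_samples: int
    n_traj: int
    train_steps: int
    analytic_configs: int
    grid_points: int


PROFILES: dict[str, Profile] = {
    "paper": Profile(
        n_dg=15000, n_ca3=500, n_steps=400_000,
        sizes=(1, 2, 5, 10, 20, 50, 100, 200), n_unit_samples=10, n_traj=4,
        train_steps=100_000, analytic_configs=2000, grid_points=40,
    ),
    "desk": Profile(
        n_dg=5000, n_ca3=200, n_steps=100_000,
        sizes=(1, 2, 5, 10, 20, 50), n_unit_samples=8, n_traj=3,
        train_steps=20_000, analytic_configs=250, grid_points=32,
    ),
}


@dataclass(frozen=True)
class ExperimentConfig:
    """Run recipe: profile name, master seed and per-field overrides.

    ``overrides`` may replace any attribute of :class:`DGParams`,
    :class:`CA3Params`, :class:`SessionParams` or :class:`Profile` by name
    (e.g. ``{"n_steps": 20000, "c_mf": 15}``); unknown keys raise.
    """

    profile: str = "desk"
    seed: int = 0
    overrides: tuple[tuple[str, object], ...] = ()

    @staticmethod
    def make(profile: str = "desk", seed: int = 0, **overrides) -> "ExperimentConfig":
        return ExperimentConfig(profile, seed, tuple(sorted(overrides.items())))


def _split_overrides(config: ExperimentConfig):
    prof = PROFILES[config.profile]
    dg_fields = {f.name for f in dataclasses.fields(DGParams)}
    ca3_fields = {f.name for f in dataclasses.fields(CA3Params)}
    sess_fields = {f.name for f in dataclasses.fields(SessionParams)}
    prof_fields = {f.name for f in dataclasses.fields(Profile)}
    dg_kw, ca3_kw, sess_kw, prof_kw = {}, {}, {}, {}
    for key, val in config.overrides:
        if key in dg_fields:
            dg_kw[key] = val
        elif key in ca3_fields:
            ca3_kw[key] = val
        elif key in sess_fields:
            sess_kw[key] = val
        elif key in prof_fields:
            prof_kw[key] = val
        else:
            raise ParameterError(f"unknown override {key!r}")
    prof = replace(prof, **prof_kw)
    return prof, dg_kw, ca3_kw, sess_kw


def session_params(config: ExperimentConfig) -> SessionParams:
    """Resolve a config into concrete session parameters."""
    prof, dg_kw, ca3_kw, sess_kw = _split_overrides(config)
    dg = DGParams(**{"n_dg": prof.n_dg, **dg_kw})
    ca3 = CA3Params(**{"n_ca3": prof.n_ca3, **ca3_kw})
    return SessionParams(dg=dg, ca3=ca3, **{"n_steps": prof.n_steps, **sess_kw})


def analytic_params(config: ExperimentConfig, **extra) -> AnalyticParams:
    """Analytic-estimate parameters matching a session config."""
    prof, dg_kw, ca3_kw, _ = _split_overrides(config)
    return AnalyticParams(
        c_mf=ca3_kw.get("c_mf", 50.0),
        p_active=dg_kw.get("p_active", 0.033),
        nu=dg_kw.get("nu", 1.7),
        model=dg_kw.get("model", "A"),
        j_strength=ca3_kw.get("j_strength", 1.0),
        noise_sd=ca3_kw.get("noise_sd", 1.0),
        target_sparsity=ca3_kw.get("target_sparsity", 0.1),
        field_area_ratio=dg_kw.get("field_area_ratio", 0.05),
        n_configs=prof.analytic_configs,
        grid_points=prof.grid_points,
        seed=config.seed,
        **extra,
    )


def run_info_session(
    sp: SessionParams,
    seed: int,
    sizes,
    n_samples: int,
    which=("full", "simplified"),
    fields=None,
    proj=None,
    decode_fields=None,
):
    """One session plus its information-versus-sample-size table."""
    sess = run_session(sp, seed, fields=fields, proj=proj, decode_fields=decode_fields)
    df = info_vs_sample_size(
        sess.rates,
        sess.actual_bins,
        sess.templates,
        sizes,
        n_samples,
        sess.env.side_bins,
        rng_seed=seed + 1,
        which=which,
    )
    df["seed"] = seed
    return df, sess


def _fit_row(df: pd.DataFrame, which: str) -> dict:
    curve = average_curve(df, which)
    i1, itot = fit_info_curve(curve.n, curve.bits)
    return {"which": which, "i1_bits": i1, "i_tot_bits": itot}


def _sweep_one_value(
    config: ExperimentConfig,
    label: str,
    value: float,
    sp: SessionParams,
    ap: AnalyticParams | None,
    with_census: bool,
) -> pd.DataFrame:
    prof, _, _, _ = _split_overrides(config)
    frames = []
    census = []
    for t in range(prof.n_traj):
        df, sess = run_info_session(
            sp, config.seed + 101 * t, prof.sizes, prof.n_unit_samples
        )
        frames.append(df)
        if with_census:
            census.append(field_census(sess))
    big = pd.concat(frames, ignore_index=True)
    rows = []
    for which in ("full", "simplified"):
        try:
            fit = _fit_row(big, which)
        except Exception as exc:  # propagate per row, never abort the sweep
            fit = {"which": which, "i1_bits": np.nan, "i_tot_bits": np.nan,
                   "error": str(exc)}
        curve = average_curve(big, which)
        row = {
            label: value,
            "mean_bits_10": float(
                np.interp(10, curve.n, curve.bits)
            ),
            "analytic_bits": single_unit_info(ap) if ap is not None else np.nan,
            "seed": config.seed,
            **fit,
        }
        if census:
            row["frac_with_field"] = float(np.mean([c[0] for c in census]))
            row["frac_multi_field"] = float(np.mean([c[1] for c in census]))
        rows.append(row)
    return pd.DataFrame(rows)


def run_sweep_connectivity(
    config: ExperimentConfig, values=(5, 15, 50, 150, 500)
) -> pd.DataFrame:
    """Sweep the MF connectivity c_mf with J rescaled as 50/c_mf.

    Reports fitted I1/I_tot (full and simplified matrices), the analytic
    single-unit value, and the CA3 field-census fractions per value.
    """
    out = []
    for c in values:
        cfg = ExperimentConfig(
            config.profile, config.seed,
            config.overrides + (("c_mf", float(c)), ("j_strength", 50.0 / c)),
        )
        sp = session_params(cfg)
        ap = analytic_params(cfg)
        out.append(_sweep_one_value(cfg, "c_mf", float(c), sp, ap, with_census=True))
    return pd.concat(out, ignore_index=True)


def run_sweep_field_multiplicity(
    config: ExperimentConfig, nus=(0.85, 1.7, 3.4), product: float = 2.805
) -> pd.DataFrame:
    """Vary the mean fields per DG unit at fixed mean fields per CA3 input.

    c_mf is adjusted so that c_mf * p_active * nu stays at ``product``;
    J is left at its standard value since the mean input is unchanged.
    """
    out = []
    for nu in nus:
        c = product / (0.033 * nu)
        cfg = ExperimentConfig(
            config.profile, config.seed,
            config.overrides + (("c_mf", float(c)), ("nu", float(nu))),
        )
        sp = session_params(cfg)
        ap = analytic_params(cfg)
        out.append(_sweep_one_value(cfg, "nu", float(nu), sp, ap, with_census=False))
    df = pd.concat(out, ignore_index=True)
    for which in ("full", "simplified"):
        sub = df[df["which"] == which]["mean_bits_10"]
        df.loc[df["which"] == which, "flatness"] = (
            (sub.max() - sub.min()) / sub.mean() if sub.mean() else np.nan
        )
    return df


def run_sweep_dg_activity(
    config: ExperimentConfig, values=(0.0066, 0.0165, 0.033, 0.099, 0.33)
) -> pd.DataFrame:
    """Sweep the DG activity probability with J rescaled as 0.033/p."""
    out = []
    for p in values:
        cfg = ExperimentConfig(
            config.profile, config.seed,
            config.overrides + (("p_active", float(p)), ("j_strength", 0.033 / p)),
        )
        sp = session_params(cfg)
        ap = analytic_params(cfg)
        out.append(_sweep_one_value(cfg, "p_active", float(p), sp, ap, with_census=False))
    return pd.concat(out, ignore_index=True)


def run_dark_information(config: ExperimentConfig) -> pd.DataFrame:
    """Full versus simplified decoding at standard parameters.

    For each sample size reports both information measures together with
    their equivocations and the decoded-position entropy, plus the
    conditional entropy of the sample-averaged full matrix — the four-way
    bookkeeping in which each (information + equivocation) pair adds up to
    the decoded entropy.
    """
    from .decoding import (
        LocalizationMatrix,
        TemplateSet,
        bias_correction,
        build_localization,
        decode,
        mutual_information,
    )

    prof, _, _, _ = _split_overrides(config)
    sp = session_params(config)
    sess = run_session(sp, config.seed)
    rng = np.random.default_rng(config.seed + 1)
    rows = []
    for n in prof.sizes:
        fulls = []
        for s in range(prof.n_unit_samples):
            units = np.sort(rng.choice(sp.ca3.n_ca3, size=n, replace=False))
            tpl = TemplateSet(
                sess.templates.means[:, units], sess.templates.visits,
                sess.templates.missing,
            )
            decoded = decode(sess.rates[:, units], tpl)
            mat = build_localization(sess.actual_bins, decoded, sess.env.side_bins)
            fulls.append(mat)
            for which in ("full", "simplified"):
                est = bias_correction(mutual_information(mat, which), mat)
                rows.append(
                    {
                        "n": n, "sample": s, "which": which,
                        "raw_bits": est.raw_bits,
                        "corrected_bits": est.corrected_bits,
                        "equivocation_bits": est.equivocation_bits,
                        "decoded_entropy_bits": est.decoded_entropy_bits,
                        "seed": config.seed,
                    }
                )
        # conditional entropy of the sample-averaged full matrix
        avg = LocalizationMatrix(
            full=np.sum([m.full for m in fulls], axis=0),
            simplified=np.sum([m.simplified for m in fulls], axis=0),
            decoded_counts=np.sum([m.decoded_counts for m in fulls], axis=0),
            actual_counts=np.sum([m.actual_counts for m in fulls], axis=0),
            n_events=sum(m.n_events for m in fulls),
            side_bins=sess.env.side_bins,
        )
        est = mutual_information(avg, "full")
        rows.append(
            {
                "n": n, "sample": -1, "which": "sample_averaged_full",
                "raw_bits": est.raw_bits,
                "corrected_bits": est.raw_bits,
                "equivocation_bits": est.equivocation_bits,
                "decoded_entropy_bits": est.decoded_entropy_bits,
                "seed": config.seed,
            }
        )
    return pd.DataFrame(rows)


def run_plasticity(
    config: ExperimentConfig, gammas=(0.0, 0.01, 0.1), c_mf_values=(15, 50, 150)
) -> pd.DataFrame:
    """Information versus connectivity for different learning factors.

    Weights are first trained along a trajectory with the gated Hebbian
    rule, then frozen and evaluated exactly as in the no-plasticity runs.
    """
    prof, _, _, _ = _split_overrides(config)
    rows = []
    for gamma in gammas:
        for c in c_mf_values:
            cfg = ExperimentConfig(
                config.profile, config.seed,
                config.overrides + (("c_mf", float(c)), ("j_strength", 50.0 / c)),
            )
            sp = session_params(cfg)
            sess0 = run_session(sp, cfg.seed)  # quenched sample to train on
            proj = (
                train_projection(
                    sess0.fields, sess0.proj, sp, gamma, prof.train_steps,
                    cfg.seed + 7,
                )
                if gamma > 0
                else sess0.proj
            )
            df, _ = run_info_session(
                sp, cfg.seed, prof.sizes, prof.n_unit_samples,
                fields=sess0.fields, proj=proj,
            )
            for which in ("full", "simplified"):
                fit = _fit_row(df, which)
                rows.append({"gamma": gamma, "c_mf": float(c), "seed": cfg.seed, **fit})
    return pd.DataFrame(rows)


def run_degraded_cue(
    config: ExperimentConfig,
    fractions=(0.25, 0.5, 0.75, 1.0),
    gammas=(0.0, 0.1),
) -> pd.DataFrame:
    """Information recovered from a degraded DG cue, with/without plasticity.

    A random subset of the normally active DG units is silenced for the
    decode pass; templates keep the intact cue.  Reports fitted I1 and
    I_tot per cue fraction and the mean second difference of I1 in the
    fraction (curvature: ~0 for linear growth, positive for supralinear).
    """
    prof, _, _, _ = _split_overrides(config)
    sp = session_params(config)
    rows = []
    for gamma in gammas:
        sess0 = run_session(sp, config.seed)
        proj = (
            train_projection(
                sess0.fields, sess0.proj, sp, gamma, prof.train_steps,
                config.seed + 7,
            )
            if gamma > 0
            else sess0.proj
        )
        for frac in fractions:
            cue = (
                degrade_cue(sess0.fields, frac, config.seed + 13)
                if frac < 1.0
                else sess0.fields
            )
            df, _ = run_info_session(
                sp, config.seed, prof.sizes, prof.n_unit_samples,
                fields=sess0.fields, proj=proj, decode_fields=cue,
            )
            fit = _fit_row(df, "full")
            rows.append({"gamma": gamma, "cue_fraction": frac, "seed": config.seed,
                         **fit})
    out = pd.DataFrame(rows)
    for gamma in gammas:
        sub = out[out["gamma"] == gamma].sort_values("cue_fraction")
        i1 = sub["i1_bits"].to_numpy()
        curv = float(np.mean(np.diff(i1, 2))) if i1.size >= 3 else np.nan
        out.loc[out["gamma"] == gamma, "i1_curvature"] = curv
    return out
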