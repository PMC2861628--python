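"""Import/export of trajectories, field sets, matrices and info curves.

Tabular data goes through CSV (pandas); array bundles through HDF5 (h5py).
External rate data for the decoding layer is accepted as a CSV/HDF5 table
with columns ``step, x, y, unit_0, unit_1, ...``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .decoding import LocalizationMatrix
from .dg import DGFieldSet
from .environment import EnvironmentGrid, Trajectory

__all__ = [
    "trajectory_to_csv",
    "trajectory_from_csv",
    "trajectory_to_hdf5",
    "fieldset_to_hdf5",
    "fieldset_from_hdf5",
    "fieldset_summary_csv",
    "localization_to_hdf5",
    "rates_table_to_csv",
    "rates_table_from_csv",
    "curve_to_json",
]


def trajectory_to_csv(traj: Trajectory, path) -> None:
    pd.DataFrame(
        {
            "step": np.arange(traj.n_steps),
            "x": traj.positions[:, 0],
            "y": traj.positions[:, 1],
        }
    ).to_csv(path, index=False)


def trajectory_from_csv(path, step_length: float, turn_noise: float = 0.0) -> Trajectory:
    df = pd.read_csv(path)
    return Trajectory(
        df[["x", "y"]].to_numpy(float), step_length, turn_noise, seed=None
    )


def trajectory_to_hdf5(traj: Trajectory, path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("positions", data=traj.positions)
        d.attrs["step_length"] = traj.step_length
        d.attrs["turn_noise"] = traj.turn_noise


def fieldset_to_hdf5(fields: DGFieldSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=fields.counts)
        f.create_dataset("active", data=fields.active)
        f.create_dataset("centers", data=fields.centers)
        f.create_dataset("unit_of_field", data=fields.unit_of_field)
        f.attrs.update(
            sigma_f=fields.sigma_f,
            radius=fields.radius,
            peak_rate=fields.peak_rate,
            side_length=fields.side_length,
        )


def fieldset_from_hdf5(path) -> DGFieldSet:
    with h5py.File(path, "r") as f:
        return DGFieldSet(
            counts=f["counts"][:],
            active=f["active"][:].astype(bool),
            centers=f["centers"][:],
            unit_of_field=f["unit_of_field"][:],
            sigma_f=float(f.attrs["sigma_f"]),
            radius=float(f.attrs["radius"]),
            peak_rate=float(f.attrs["peak_rate"]),
            side_length=float(f.attrs["side_length"]),
        )


def fieldset_summary_csv(fields: DGFieldSet, path) -> None:
    """One row per unit: id, field count, semicolon-joined center list."""
    centers: list[list[str]] = [[] for _ in range(fields.n_units)]
    for (x, y), u in zip(fields.centers, fields.unit_of_field):
        centers[u].append(f"({x:.3f},{y:.3f})")
    pd.DataFrame(
        {
            "unit": np.arange(fields.n_units),
            "q": fields.counts,
            "active": fields.active,
            "centers": [";".join(c) for c in centers],
        }
    ).to_csv(path, index=False)


def localization_to_hdf5(matrix: LocalizationMatrix, path, **metadata) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("full", data=matrix.full, compression="gzip")
        f.create_dataset("simplified", data=matrix.simplified)
        f.create_dataset("decoded_counts", data=matrix.decoded_counts)
        f.create_dataset("actual_counts", data=matrix.actual_counts)
        f.attrs["n_events"] = matrix.n_events
        f.attrs["side_bins"] = matrix.side_bins
        for k, v in metadata.items():
            f.attrs[k] = v


def rates_table_to_csv(rates: np.ndarray, positions: np.ndarray, path) -> None:
    """Population rate time series plus position time series, one row per step."""
    df = pd.DataFrame(rates, columns=[f"unit_{i}" for i in range(rates.shape[1])])
    df.insert(0, "step", np.arange(rates.shape[0]))
    df["x"] = positions[:, 0]
    df["y"] = positions[:, 1]
    df.to_csv(path, index=False)


def rates_table_from_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Returns (rates, positions) from the documented tabular format."""
    df = pd.read_csv(path)
    unit_cols = [c for c in df.columns if c.startswith("unit_")]
    return df[unit_cols].to_numpy(float), df[["x", "y"]].to_numpy(float)


def curve_to_json(curve, path) -> None:
    payload = {
        "n": np.asarray(curve.n).tolist(),
        "bits": np.asarray(curve.bits).tolist(),
        "sd": np.asarray(curve.sd).tolist(),
        "i1": curve.i1,
        "i_tot": curve.i_tot,
    }
    Path(path).write_text(json.dumps(payload, indent=2))
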