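"""HDF5 persistence for networks, trajectories and overlaps."""

from __future__ import annotations

from typing import Optional

import h5py
import numpy as np
import scipy.sparse as sp

from .dynamics import RateTrajectory
from .metrics import OverlapTrajectory
from .network import ConnectivityMatrix, PatternSequence

__all__ = ["save_network", "load_network", "save_overlaps", "load_overlaps", "save_trajectory"]


def save_network(
    path: str, patterns: PatternSequence, conn: ConnectivityMatrix
) -> None:
    """Patterns + connectivity in one file (weights in CSR triplet form)."""
    J = conn.weights.tocsr()
    with h5py.File(path, "w") as f:
        f.create_dataset("patterns", data=patterns.xi, compression="gzip")
        f.create_dataset("weights/data", data=J.data, compression="gzip")
        f.create_dataset("weights/indices", data=J.indices, compression="gzip")
        f.create_dataset("weights/indptr", data=J.indptr, compression="gzip")
        f.create_dataset("z_profile", data=conn.z)
        f.attrs.update(
            {
                "N": conn.N,
                "P": patterns.P,
                "A": conn.A,
                "c": conn.c,
                "pattern_seed": patterns.seed,
                "connectivity_seed": conn.seed,
                "normalization": conn.normalization,
            }
        )
        if conn.pop_sizes is not None:
            f.attrs["N_a"], f.attrs["N_s"] = conn.pop_sizes


def load_network(path: str) -> tuple[PatternSequence, ConnectivityMatrix]:
    with h5py.File(path, "r") as f:
        xi = f["patterns"][...]
        N = int(f.attrs["N"])
        J = sp.csr_matrix(
            (f["weights/data"][...], f["weights/indices"][...], f["weights/indptr"][...]),
            shape=(N, N),
        )
        patterns = PatternSequence(xi=xi, seed=int(f.attrs["pattern_seed"]))
        pop = None
        if "N_a" in f.attrs:
            pop = (int(f.attrs["N_a"]), int(f.attrs["N_s"]))
        conn = ConnectivityMatrix(
            weights=J,
            c=float(f.attrs["c"]),
            A=float(f.attrs["A"]),
            z=f["z_profile"][...],
            seed=int(f.attrs["connectivity_seed"]),
            normalization=str(f.attrs["normalization"]),  # type: ignore[arg-type]
            pop_sizes=pop,
        )
    return patterns, conn


def save_overlaps(path: str, overlaps: OverlapTrajectory) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("m", data=overlaps.m, compression="gzip")
        f.create_dataset("times", data=overlaps.times)
        f.attrs["scope"] = overlaps.scope


def load_overlaps(path: str) -> OverlapTrajectory:
    with h5py.File(path, "r") as f:
        return OverlapTrajectory(
            m=f["m"][...], times=f["times"][...], scope=str(f.attrs["scope"])  # type: ignore[arg-type]
        )


def save_trajectory(path: str, traj: RateTrajectory) -> None:
    """Rates (if recorded), times and run metadata."""
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=traj.times)
        if traj.rates is not None:
            f.create_dataset("rates", data=traj.rates, compression="gzip")
        if traj.overlaps_raw is not None:
            f.create_dataset("overlaps", data=traj.overlaps_raw, compression="gzip")
        f.attrs.update(
            {"dt": traj.dt, "tau": traj.tau, "seed": traj.seed, "stopped_early": traj.stopped_early}
        )
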