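"""Plain-text serialization for every artifact the pipeline produces.

All formats are TSV or JSON so that runs are diffable and reproducible;
each writer has a reader that round-trips values bit-exactly at double
precision.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from gcprobe.gc_core import (
    CountMatrix,
    GCProbeError,
    GrandCanonicalEnsemble,
    PartitionFunctions,
)
from gcprobe.lattice import LatticeModel


def write_occupancies(occ: Mapping[int, "np.ndarray"], path: str | Path) -> None:
    """Occupancy stream as TSV with columns trajectory_N, frame, k_A."""
    rows = [
        (int(N), i, int(k))
        for N in sorted(occ)
        for i, k in enumerate(occ[N])
    ]
    pd.DataFrame(rows, columns=["trajectory_N", "frame", "k_A"]).to_csv(
        path, sep="\t", index=False
    )


def read_occupancies(path: str | Path) -> dict[int, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    for col in ("trajectory_N", "frame", "k_A"):
        if col not in df.columns:
            raise GCProbeError(f"occupancy TSV missing column {col!r}")
    return {
        int(N): g.sort_values("frame")["k_A"].to_numpy(dtype=int)
        for N, g in df.groupby("trajectory_N")
    }


def write_count_matrix(counts: CountMatrix, path: str | Path) -> None:
    """Count matrix as TSV: header of k values, one row per N (1..N_max)."""
    n = counts.N_max
    df = pd.DataFrame(
        counts.t[1:], index=pd.Index(range(1, n + 1), name="N"),
        columns=[f"k{k}" for k in range(n + 1)],
    )
    df.to_csv(path, sep="\t")


def read_count_matrix(path: str | Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col="N")
    n = df.shape[1] - 1
    t = np.zeros((n + 1, n + 1))
    t[df.index.to_numpy()] = df.to_numpy(dtype=float)
    return CountMatrix(t)


def write_partition_functions(
    pf: PartitionFunctions, path: str | Path, gce: GrandCanonicalEnsemble | None = None
) -> None:
    payload: dict = {
        "omega_A": pf.omega_A.tolist(),
        "omega_B": pf.omega_B.tolist(),
        "gauge": pf.gauge,
        "iterations": pf.iterations,
        "residual": pf.residual,
        "converged": pf.converged,
    }
    if gce is not None:
        payload.update(
            beta_mu=gce.beta_mu,
            temperature_K=gce.temperature,
            P_A=gce.P_A.tolist(),
            P_B=gce.P_B.tolist(),
        )
    Path(path).write_text(json.dumps(payload, indent=1))


def read_partition_functions(path: str | Path) -> PartitionFunctions:
    d = json.loads(Path(path).read_text())
    return PartitionFunctions(
        np.asarray(d["omega_A"]),
        np.asarray(d["omega_B"]),
        gauge=d.get("gauge", "omega0=1"),
        iterations=int(d.get("iterations", 0)),
        residual=float(d.get("residual", 0.0)),
        converged=bool(d.get("converged", True)),
    )


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_lattice_config(path: str | Path) -> LatticeModel:
    """Lattice model from a small YAML/key-value config (S_A, S_B, eps, N_max)."""
    d = yaml.safe_load(Path(path).read_text())
    if not isinstance(d, dict) or "S_A" not in d or "S_B" not in d:
        raise GCProbeError("lattice config must define S_A and S_B")
    return LatticeModel(
        S_A=int(d["S_A"]),
        S_B=int(d["S_B"]),
        eps=float(d.get("eps", 0.0)),
        N_max=int(d["N_max"]) if "N_max" in d else None,
    )


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
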