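"""Geometric extraction of region occupancies and nucleotide binding states.

The binding region A is a sphere of radius ``r_A`` (default 3 nm) centered
on the RNA center of mass; everything else is the buffer B.  A probe copy is
counted in region A when its center of mass lies within the sphere under the
minimum-image convention.  A probe binds a nucleotide when (a) that
nucleotide's O2' atom is the nearest one to the probe's reactive carbonyl
carbon (C7) and (b) their distance is below ``r_th`` (default 3.5 Angstrom).
A nucleotide is "bound" when at least one probe binds it.  The 3.5 Angstrom
binding threshold is far smaller than the 3 nm region radius, so a binding
probe is always inside region A; this is relied on rather than checked.

All coordinates are handled in nanometers internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from gcprobe.gc_core import GCProbeError

_SHIFT_COEFS = np.array(
    [[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)],
    dtype=float,
)


@dataclass(frozen=True)
class ProbeFrame:
    """One trajectory frame reduced to the coordinates the analysis needs.

    Attributes
    ----------
    o2prime_positions: (n_nucleotides, 3) array, nm
    probe_c7_positions: (n_probes, 3) array, nm
    probe_com_positions: (n_probes, 3) array, nm
    rna_com: (3,) array, nm
    box: (3, 3) triclinic cell vectors (rows), nm
    nucleotide_ids: optional labels (e.g. residue numbers); defaults to 0..n-1
    """

    o2prime_positions: np.ndarray
    probe_c7_positions: np.ndarray
    probe_com_positions: np.ndarray
    rna_com: np.ndarray
    box: np.ndarray
    nucleotide_ids: tuple = ()

    def __post_init__(self) -> None:
        for name in ("o2prime_positions", "probe_c7_positions", "probe_com_positions"):
            arr = np.atleast_2d(np.asarray(getattr(self, name), dtype=float))
            if arr.size and arr.shape[1] != 3:
                raise GCProbeError(f"{name} must be an (n, 3) array")
            if not np.all(np.isfinite(arr)):
                raise GCProbeError(f"{name} contains non-finite coordinates")
            object.__setattr__(self, name, arr.reshape(-1, 3))
        object.__setattr__(self, "rna_com", np.asarray(self.rna_com, dtype=float))
        box = np.asarray(self.box, dtype=float)
        if box.shape != (3, 3) or abs(np.linalg.det(box)) <= 0:
            raise GCProbeError("box must be a nonsingular (3, 3) cell matrix")
        object.__setattr__(self, "box", box)
        if not self.nucleotide_ids:
            object.__setattr__(
                self, "nucleotide_ids", tuple(range(self.o2prime_positions.shape[0]))
            )

    @property
    def n_probes(self) -> int:
        return self.probe_c7_positions.shape[0]


def buffer_volume_from_box(box: np.ndarray, r_A: float = 3.0) -> float:
    """Buffer volume V_B = V_box - (4/3) pi r_A^3, both in nm^3.

    Convenience for calibration when the binding sphere is carved out of a
    periodic cell; region A remains an analysis-time choice, so V_B can
    also be supplied directly.
    """
    box = np.asarray(box, dtype=float)
    v_box = abs(np.linalg.det(box))
    v_B = v_box - 4.0 / 3.0 * np.pi * r_A**3
    if v_B <= 0:
        raise GCProbeError("binding sphere exceeds the box volume")
    return float(v_B)


def min_image_distance_matrix(
    a: np.ndarray, b: np.ndarray, box: np.ndarray
) -> np.ndarray:
    """Pairwise minimum-image distances between point sets in a triclinic cell.

    Searches the 27 neighbor images; exact for cells where the minimum image
    lies within one lattice shift, which holds for the boxes used here.
    """
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    disp = b[None, :, :] - a[:, None, :]
    shifts = _SHIFT_COEFS @ box
    d = np.linalg.norm(disp[:, :, None, :] + shifts[None, None, :, :], axis=-1)
    return d.min(axis=2)


def assign_region_occupancy(frame: ProbeFrame, r_A: float = 3.0) -> int:
    """Number of probes whose center of mass lies within r_A (nm) of the RNA.

    Closed ball: a probe exactly at the boundary counts as inside.
    """
    if r_A <= 0:
        raise GCProbeError("r_A must be positive")
    if frame.n_probes == 0:
        return 0
    d = min_image_distance_matrix(
        frame.rna_com[None, :], frame.probe_com_positions, frame.box
    )[0]
    return int(np.sum(d <= r_A))


def detect_binding(frame: ProbeFrame, r_th: float = 3.5) -> np.ndarray:
    """Per-nucleotide binding map for one frame.

    Returns an integer array over nucleotides: the index of a probe bound to
    that nucleotide, or -1 if none.  A probe is assigned to the nucleotide
    whose O2' is nearest to its C7 (ties broken toward the lowest nucleotide
    index) and binds it only if that distance is strictly below ``r_th``,
    given in Angstrom.
    """
    if r_th <= 0:
        raise GCProbeError("r_th must be positive")
    n_nuc = frame.o2prime_positions.shape[0]
    bound_by = np.full(n_nuc, -1, dtype=int)
    if frame.n_probes == 0 or n_nuc == 0:
        return bound_by
    d = min_image_distance_matrix(
        frame.probe_c7_positions, frame.o2prime_positions, frame.box
    )
    nearest = d.argmin(axis=1)  # argmin takes the lowest index on ties
    r_th_nm = r_th / 10.0
    for probe, nuc in enumerate(nearest):
        if d[probe, nuc] < r_th_nm:
            bound_by[nuc] = probe
    return bound_by


def build_binding_table(
    frames: Iterable[ProbeFrame],
    trajectory_N: int,
    r_A: float = 3.0,
    r_th: float = 3.5,
) -> pd.DataFrame:
    """Tabulate occupancy and per-nucleotide binding flags over frames.

    Columns: ``trajectory_N``, ``frame``, ``k_A``, then one 0/1 column
    ``nuc_<id>`` per nucleotide.
    """
    records = []
    ids: tuple = ()
    for i, frame in enumerate(frames):
        if not ids:
            ids = frame.nucleotide_ids
        elif frame.nucleotide_ids != ids:
            raise GCProbeError(f"frame {i}: nucleotide ids differ from earlier frames")
        k = assign_region_occupancy(frame, r_A)
        if k > trajectory_N:
            raise GCProbeError(
                f"frame {i}: occupancy {k} exceeds trajectory copy number {trajectory_N}"
            )
        bound = detect_binding(frame, r_th) >= 0
        rec = {"trajectory_N": trajectory_N, "frame": i, "k_A": k}
        rec.update({f"nuc_{nid}": int(b) for nid, b in zip(ids, bound)})
        records.append(rec)
    return pd.DataFrame.from_records(records)


def nucleotide_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith("nuc_")]


def tabulate_pair_states(table: pd.DataFrame, i, j) -> pd.Series:
    """Per-frame pairwise binding state for nucleotides i and j.

    States: '00' both unbound, '10' only i bound, '01' only j bound,
    '11' both bound.  Because each probe binds at most one nucleotide (its
    nearest), '11' always involves two distinct probe copies.  Frame order
    is preserved so the states align with frame weights.
    """
    if i == j:
        raise GCProbeError("pair states require two distinct nucleotides")
    for nid in (i, j):
        if f"nuc_{nid}" not in table.columns:
            raise GCProbeError(f"unknown nucleotide id {nid!r} in binding table")
    bi = table[f"nuc_{i}"].to_numpy().astype(int)
    bj = table[f"nuc_{j}"].to_numpy().astype(int)
    states = np.char.add(bi.astype(str), bj.astype(str))
    return pd.Series(states, index=table.index, name=f"pair_{i}_{j}")


def read_trajectory(
    topology: str,
    trajectory: str | None = None,
    nucleotide_selection: str = "nucleic",
    o2prime_name: str = "O2'",
    probe_resname: str = "1M7",
    probe_c7_name: str = "C7",
    exclude_resids: Sequence[int] = (),
) -> Iterator[ProbeFrame]:
    """Stream :class:`ProbeFrame` objects from an MD trajectory.

    Frames are yielded lazily, so the full trajectory is never held in
    memory.  ``exclude_resids`` drops restrained terminal bases from the
    nucleotide set.  Coordinates are converted from the reader's Angstrom
    convention to nm.

    Raises
    ------
    GCProbeError
        If a selected nucleotide lacks an O2' atom or a probe residue lacks
        its C7 atom; the offending residue is named.
    """
    import MDAnalysis as mda

    u = mda.Universe(topology) if trajectory is None else mda.Universe(topology, trajectory)
    nucs = u.select_atoms(nucleotide_selection).residues
    if exclude_resids:
        nucs = nucs[~np.isin(nucs.resids, np.asarray(exclude_resids))]
    if len(nucs) == 0:
        raise GCProbeError("nucleotide selection matched no residues")
    o2_atoms = []
    for res in nucs:
        sel = res.atoms.select_atoms(f"name {o2prime_name}")
        if len(sel) != 1:
            raise GCProbeError(
                f"residue {res.resname}{res.resid}: expected one {o2prime_name} atom, "
                f"found {len(sel)}"
            )
        o2_atoms.append(sel[0])
    o2_group = sum(o2_atoms[1:], o2_atoms[0].universe.atoms[[o2_atoms[0].index]])
    probes = u.select_atoms(f"resname {probe_resname}").residues
    if len(probes) == 0:
        raise GCProbeError(f"no probe residues with resname {probe_resname!r}")
    c7_atoms = []
    for res in probes:
        sel = res.atoms.select_atoms(f"name {probe_c7_name}")
        if len(sel) != 1:
            raise GCProbeError(
                f"probe residue {res.resname}{res.resid}: expected one "
                f"{probe_c7_name} atom, found {len(sel)}"
            )
        c7_atoms.append(sel[0])
    nuc_atoms_all = nucs.atoms
    ids = tuple(int(r) for r in nucs.resids)

    for _ in u.trajectory:
        box = u.dimensions
        if box is None or box[:3].min() <= 0:
            raise GCProbeError("trajectory frame carries no valid box dimensions")
        from MDAnalysis.lib.mdamath import triclinic_vectors

        cell = triclinic_vectors(box) / 10.0
        yield ProbeFrame(
            o2prime_positions=o2_group.positions / 10.0,
            probe_c7_positions=np.array([a.position for a in c7_atoms]) / 10.0,
            probe_com_positions=np.array(
                [res.atoms.center_of_mass() for res in probes]
            )
            / 10.0,
            rna_com=nuc_atoms_all.center_of_mass() / 10.0,
            box=cell,
            nucleotide_ids=ids,
        )
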