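"""Synthetic-data generators with exactly known ground truth.

Every generator here is enumeration-based rather than Monte-Carlo-based, so
each fixture carries its exact reference quantities: regional partition
functions, concentration-dependent reactivities, and pairwise free-energy
couplings.  That makes the generators usable as independent oracles for the
estimation pipeline, not just as input factories.

The binding model places ``N`` indistinguishable probes among three kinds of
slots: ``M`` nucleotide sites in region A (site energies ``e_i`` and
pairwise couplings ``J_ij``, both in k_B T; negative J = cooperative), ``F``
featureless free slots in region A, and ``S_B`` buffer slots in region B.
All slots obey mutual exclusion.  Given the region-A occupancy k the site
configuration is independent of the buffer, so regional partition functions
factorize exactly as assumed by the reweighting estimator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import comb

from gcprobe.binding import ProbeFrame
from gcprobe.gc_core import GCProbeError, PartitionFunctions

_MAX_SITES = 12
_MAX_NMAX = 16


@dataclass(frozen=True)
class SyntheticBindingModel:
    """Exactly enumerable probe-binding model.

    Attributes
    ----------
    e: per-site binding energies, k_B T (length M).
    J: symmetric pairwise couplings, k_B T; negative = cooperative.
    F: featureless free slots in region A.
    S_B: buffer capacity (exclusion slots in region B).
    N_max: largest simulated copy number.
    V_B: buffer volume in nm^3, used to map concentration to occupancy.
    """

    e: np.ndarray
    J: np.ndarray
    F: int = 4
    S_B: int = 12
    N_max: int = 6
    V_B: float = 12.0

    def __post_init__(self) -> None:
        e = np.atleast_1d(np.asarray(self.e, dtype=float))
        J = np.asarray(self.J, dtype=float)
        M = e.shape[0]
        if J.shape != (M, M) or not np.allclose(J, J.T):
            raise GCProbeError("J must be a symmetric (M, M) matrix")
        if M > _MAX_SITES or self.N_max > _MAX_NMAX:
            raise GCProbeError(
                f"enumeration guard: M <= {_MAX_SITES} and N_max <= {_MAX_NMAX}"
            )
        if self.F < 0 or self.S_B < 1 or self.N_max < 1 or self.V_B <= 0:
            raise GCProbeError("invalid slot counts or buffer volume")
        if self.N_max > M + self.F + self.S_B:
            raise GCProbeError("N_max exceeds the total slot capacity")
        object.__setattr__(self, "e", e)
        object.__setattr__(self, "J", J)

    @property
    def M(self) -> int:
        return self.e.shape[0]


@dataclass(frozen=True)
class ExactReference:
    """Exact quantities of a :class:`SyntheticBindingModel` by enumeration."""

    model: SyntheticBindingModel
    subsets: tuple            # bitmasks over nucleotide sites
    subset_sizes: np.ndarray
    subset_weights: np.ndarray  # exp(-E(S))
    omega_A: np.ndarray       # over k = 0 .. M + F
    omega_B: np.ndarray       # over k = 0 .. S_B

    def partition_functions(self, N_max: int | None = None) -> PartitionFunctions:
        """Exact omegas packaged for the gc_core machinery, truncated at N_max."""
        n = (N_max if N_max is not None else self.model.N_max) + 1
        oa = np.zeros(n)
        ob = np.zeros(n)
        oa[: min(n, self.omega_A.size)] = self.omega_A[:n]
        ob[: min(n, self.omega_B.size)] = self.omega_B[:n]
        return PartitionFunctions(oa, ob, gauge="exact")

    def _site_restricted_omega(self, keep: np.ndarray) -> np.ndarray:
        """Omega_A restricted to subsets satisfying a boolean mask."""
        model = self.model
        omega = np.zeros(model.M + model.F + 1)
        for s, size, w in zip(self.subsets, self.subset_sizes, self.subset_weights):
            if not keep[s]:
                continue
            for nf in range(model.F + 1):
                omega[size + nf] += w * comb(model.F, nf)
        return omega

    def _gc_mix(self, omega_restricted: np.ndarray, beta_mu: float) -> float:
        """sum_k restricted(k) z^k / sum_k omega_A(k) z^k, truncated at N_max."""
        kmax = min(self.model.N_max, self.omega_A.size - 1)
        k = np.arange(kmax + 1, dtype=float)
        z_pow = np.exp(beta_mu * k)
        num = float(np.dot(omega_restricted[: kmax + 1], z_pow))
        den = float(np.dot(self.omega_A[: kmax + 1], z_pow))
        return num / den

    def exact_reactivity(self, beta_mu: float) -> np.ndarray:
        """Exact grand-canonical bound probability per nucleotide site."""
        out = np.zeros(self.model.M)
        for i in range(self.model.M):
            keep = np.array([bool(s >> i & 1) for s in range(2 ** self.model.M)])
            out[i] = self._gc_mix(self._site_restricted_omega(keep), beta_mu)
        return out

    def exact_pair_frequencies(self, beta_mu: float, i: int, j: int) -> np.ndarray:
        """Exact (p00, p01, p10, p11) for sites i and j at fixed beta*mu."""
        p = np.zeros(4)
        for a, (si, sj) in enumerate([(0, 0), (0, 1), (1, 0), (1, 1)]):
            keep = np.array(
                [(s >> i & 1) == si and (s >> j & 1) == sj
                 for s in range(2 ** self.model.M)]
            )
            p[a] = self._gc_mix(self._site_restricted_omega(keep), beta_mu)
        return p / p.sum()

    def exact_coupling(self, beta_mu: float) -> np.ndarray:
        """Exact free-energy coupling matrix (k_B T) at fixed beta*mu."""
        M = self.model.M
        ddg = np.full((M, M), np.nan)
        for i, j in itertools.combinations(range(M), 2):
            p00, p01, p10, p11 = self.exact_pair_frequencies(beta_mu, i, j)
            ddg[i, j] = ddg[j, i] = -np.log((p11 * p00) / (p10 * p01))
        return ddg


def enumerate_reference(model: SyntheticBindingModel) -> ExactReference:
    """Exhaustively enumerate the model's site subsets and partition functions."""
    M, F = model.M, model.F
    subsets = tuple(range(2**M))
    sizes = np.array([bin(s).count("1") for s in subsets])
    weights = np.zeros(len(subsets))
    for s in subsets:
        occ = [i for i in range(M) if s >> i & 1]
        E = sum(model.e[i] for i in occ)
        E += sum(model.J[i, j] for i, j in itertools.combinations(occ, 2))
        weights[s] = np.exp(-E)
    omega_A = np.zeros(M + F + 1)
    for s in subsets:
        for nf in range(F + 1):
            omega_A[sizes[s] + nf] += weights[s] * comb(F, nf)
    omega_B = comb(model.S_B, np.arange(model.S_B + 1))
    return ExactReference(model, subsets, sizes, weights, omega_A, omega_B)


def synth_binding_trajectories(
    model: SyntheticBindingModel,
    n_frames: int,
    seed: int,
) -> tuple[dict[int, np.ndarray], pd.DataFrame, ExactReference]:
    """Sample canonical trajectories for every N with exact references.

    For each ``N`` in 1..N_max, frames are drawn i.i.d. from the exact
    canonical distribution over (site subset, free-slot count, buffer count)
    configurations.  Returns the occupancy sequences consumed by the
    reweighting core, the matching binding table (columns ``trajectory_N``,
    ``frame``, ``k_A``, ``nuc_0`` .. ``nuc_{M-1}``), and the
    :class:`ExactReference` oracle.
    """
    if n_frames < 0:
        raise GCProbeError("n_frames must be nonnegative")
    ref = enumerate_reference(model)
    rng = np.random.default_rng(seed)
    occ: dict[int, np.ndarray] = {}
    records = []
    for N in range(1, model.N_max + 1):
        patterns = []
        pw = []
        for s, size, w in zip(ref.subsets, ref.subset_sizes, ref.subset_weights):
            for nf in range(model.F + 1):
                k = size + nf
                nb = N - k
                if nb < 0 or nb > model.S_B:
                    continue
                patterns.append((s, k))
                pw.append(w * comb(model.F, nf) * comb(model.S_B, nb))
        pw = np.asarray(pw)
        pw = pw / pw.sum()
        draws = rng.choice(len(patterns), size=n_frames, p=pw)
        ks = np.empty(n_frames, dtype=int)
        for f, d in enumerate(draws):
            s, k = patterns[d]
            ks[f] = k
            rec = {"trajectory_N": N, "frame": f, "k_A": k}
            rec.update({f"nuc_{i}": (s >> i) & 1 for i in range(model.M)})
            records.append(rec)
        occ[N] = ks
    return occ, pd.DataFrame.from_records(records), ref


# ---------------------------------------------------------------------------
# Geometric probe-frame fixtures

_RING_RADIUS = 1.0     # nm, nucleotide ring around the RNA center
_BOUND_OFFSET = 0.30   # nm, C7 placed 3.0 Angstrom from the target O2'
_FAR_Z = 1.8           # nm, parking spot for unbound in-region probes


def synth_probe_frames(
    patterns: Sequence[Sequence],
    n_nucleotides: int,
    r_A: float = 3.0,
    box_edge: float = 20.0,
) -> list[ProbeFrame]:
    """Construct coordinate frames realizing prescribed binding patterns.

    Each frame pattern is a sequence of probe placements: an integer ``i``
    binds nucleotide ``i`` (C7 placed 3.0 Angstrom from its O2', farther
    from all others), ``"in"`` is unbound inside region A, ``"out"`` is
    unbound outside the region, and ``"boundary"`` sits exactly at ``r_A``
    (counted inside by the closed-ball convention).  Nucleotide O2' atoms
    sit on a ring of radius 1 nm around the origin, so geometry checks are
    exact by construction.  At most two probes may bind the same nucleotide
    per frame.
    """
    if n_nucleotides < 1:
        raise GCProbeError("need at least one nucleotide")
    ang = 2 * np.pi * np.arange(n_nucleotides) / max(n_nucleotides, 3)
    o2 = np.stack(
        [_RING_RADIUS * np.cos(ang), _RING_RADIUS * np.sin(ang), np.zeros_like(ang)],
        axis=1,
    )
    if n_nucleotides > 1:
        spacing = np.linalg.norm(o2[0] - o2[1])
        if spacing <= 2 * _BOUND_OFFSET:
            raise GCProbeError("too many nucleotides: ring spacing breaks nearest rule")
    box = np.eye(3) * box_edge
    frames = []
    for fi, pat in enumerate(patterns):
        c7 = []
        seen: dict[int, int] = {}
        out_count = 0
        in_count = 0
        for item in pat:
            if isinstance(item, (int, np.integer)):
                i = int(item)
                if not 0 <= i < n_nucleotides:
                    raise GCProbeError(f"frame {fi}: unknown nucleotide index {i}")
                n_prev = seen.get(i, 0)
                if n_prev >= 2:
                    raise GCProbeError(
                        f"frame {fi}: more than two probes bound to nucleotide {i}"
                    )
                seen[i] = n_prev + 1
                side = 1.0 if n_prev == 0 else -1.0
                c7.append(o2[i] + np.array([0.0, 0.0, side * _BOUND_OFFSET]))
            elif item == "in":
                in_count += 1
                c7.append(np.array([0.0, 0.0, _FAR_Z + 0.2 * in_count]))
            elif item == "out":
                out_count += 1
                c7.append(np.array([0.0, 0.0, r_A + 1.0 + 0.5 * out_count]))
            elif item == "boundary":
                c7.append(np.array([r_A, 0.0, 0.0]))
            else:
                raise GCProbeError(f"frame {fi}: unknown placement {item!r}")
        c7_arr = np.array(c7).reshape(-1, 3)
        frames.append(
            ProbeFrame(
                o2prime_positions=o2,
                probe_c7_positions=c7_arr,
                probe_com_positions=c7_arr.copy(),  # point probes: COM at C7
                rna_com=np.zeros(3),
                box=box,
            )
        )
    return frames


def write_probe_pdb(frames: Sequence[ProbeFrame], path) -> None:
    """Write frames as a multi-model text PDB consumable by the MD reader.

    Nucleotides become one-atom-pair residues ``RNU`` (O2' plus a C1'
    placeholder so the residue center of mass is defined); probes become
    single-atom ``1M7`` residues carrying only the C7 atom, so the probe
    center of mass coincides with C7 as in the synthetic frames.
    Coordinates are written in Angstrom; each MODEL carries its CRYST1 box.
    """
    lines: list[str] = []
    for mi, fr in enumerate(frames, start=1):
        edge = np.diag(fr.box) * 10.0
        if not np.allclose(fr.box, np.diag(np.diag(fr.box))):
            raise GCProbeError("PDB fixture writer supports orthorhombic boxes only")
        lines.append(f"MODEL     {mi}")
        lines.append(
            f"CRYST1{edge[0]:9.3f}{edge[1]:9.3f}{edge[2]:9.3f}"
            "  90.00  90.00  90.00 P 1           1"
        )
        ser = 1
        for i, pos in enumerate(fr.o2prime_positions * 10.0):
            x, y, z = pos
            lines.append(
                f"ATOM  {ser:5d}  O2' RNU A{i + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           O"
            )
            ser += 1
            lines.append(
                f"ATOM  {ser:5d}  C1' RNU A{i + 1:4d}    "
                f"{x + 1:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
            ser += 1
        for j, pos in enumerate(fr.probe_c7_positions * 10.0):
            x, y, z = pos
            lines.append(
                f"ATOM  {ser:5d}  C7  1M7 B{j + 101:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
            ser += 1
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def synth_read_table(
    betas: Sequence[float],
    amplitudes: Sequence[float],
    channels: Mapping[str, float],
    gnra_flags: Sequence[bool],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Raw-read table following per-nucleotide power laws R = a * C^beta.

    Multiplicative lognormal noise of log-sd ``noise_sd`` is applied per
    read.  The output mimics a capillary-electrophoresis export: columns
    ``position``, ``gnra`` and one raw-read column per channel.
    """
    betas = np.asarray(betas, dtype=float)
    amps = np.asarray(amplitudes, dtype=float)
    if betas.shape != amps.shape or betas.shape[0] != len(gnra_flags):
        raise GCProbeError("betas, amplitudes, and gnra_flags must align")
    rng = np.random.default_rng(seed)
    out = pd.DataFrame(
        {"position": np.arange(betas.shape[0]), "gnra": list(gnra_flags)}
    )
    for col, conc in channels.items():
        vals = amps * conc**betas
        if noise_sd > 0:
            vals = vals * np.exp(rng.normal(0.0, noise_sd, size=vals.shape))
        out[col] = vals
    return out
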