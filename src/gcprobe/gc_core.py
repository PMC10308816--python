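"""Maximum-likelihood grand-canonical reweighting of fixed-N simulations.

A set of canonical simulations, each holding a fixed number ``N`` of copies
of one molecular species, is combined into a single grand-canonical ensemble.
The simulation box is split into a binding region ``A`` and a buffer region
``B`` that are assumed statistically decoupled, so the canonical probability
of seeing ``k`` copies in region A factorizes as

    P^N(k) = Omega_A(k) * Omega_B(N - k) / Z_N ,

with regional canonical partition functions ``Omega_A`` and ``Omega_B`` and
``Z_N = sum_k Omega_A(k) Omega_B(N-k)``.  The partition functions are
estimated by maximum likelihood from the pooled occupancy histograms, the
chemical potential is calibrated against a target buffer concentration by
bisection, and each simulation frame receives a weight that depends only on
its region-A occupancy.  Ensemble averages computed with those weights are
smooth functions of the reagent concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

#: Conversion constant: 1 particle / nm^3 expressed in mol/L.
PARTICLE_PER_NM3_IN_MOLAR = 1.660539

#: Boltzmann constant in kcal/(mol K), for optional unit conversions.
KB_KCAL_PER_MOL_K = 0.0019872041


class GCProbeError(ValueError):
    """Base class for domain errors raised by this package."""


class ConcentrationCeilingError(GCProbeError):
    """Requested concentration exceeds the range supported by the sampled N.

    Because the grand-canonical distribution is truncated at the largest
    simulated copy number, concentrations whose mean buffer occupancy would
    exceed the supported range cannot be represented.
    """

    def __init__(self, requested: float, ceiling: float):
        self.requested = requested
        self.ceiling = ceiling
        super().__init__(
            f"requested concentration {requested:g} mol/L is at or above the "
            f"attainable ceiling of {ceiling:g} mol/L for this set of "
            "simulations; add trajectories with more copies to extend the range"
        )


class NotConvergedError(GCProbeError):
    """Fixed-point iteration did not reach the requested tolerance."""


@dataclass(frozen=True)
class CountMatrix:
    """Triangular matrix of per-trajectory occupancy counts.

    ``t[N, k]`` holds the (possibly fractionally reweighted) number of frames
    of the trajectory with ``N`` total copies in which exactly ``k`` copies
    were inside region A.  Row 0 is kept for alignment and is always zero;
    entries with ``k > N`` are impossible and must be zero.

    Attributes
    ----------
    t:
        Array of shape ``(N_max + 1, N_max + 1)``; float so that
        Dirichlet-weighted bootstrap counts are representable.
    """

    t: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if t.ndim != 2 or t.shape[0] != t.shape[1]:
            raise GCProbeError(f"count matrix must be square, got shape {t.shape}")
        if np.any(t < 0) or not np.all(np.isfinite(t)):
            raise GCProbeError("count matrix entries must be finite and nonnegative")
        if np.any(np.triu(t, k=1) != 0):
            raise GCProbeError("count matrix must be lower-triangular (t[N, k] = 0 for k > N)")
        object.__setattr__(self, "t", t)

    @property
    def N_max(self) -> int:
        return self.t.shape[0] - 1

    @property
    def A(self) -> np.ndarray:
        """Pooled counts of region-A occupancy: ``A_k = sum_N t[N, k]``."""
        return self.t.sum(axis=0)

    @property
    def B(self) -> np.ndarray:
        """Pooled counts of region-B occupancy: ``B_k = sum_N t[N, N - k]``."""
        B = np.zeros(self.N_max + 1)
        for N in range(1, self.N_max + 1):
            for k in range(0, N + 1):
                B[N - k] += self.t[N, k]
        return B

    @property
    def L(self) -> np.ndarray:
        """Frames per trajectory, ``L_N = sum_k t[N, k]`` (index 0 unused)."""
        return self.t.sum(axis=1)

    @property
    def n_frames(self) -> float:
        return float(self.t.sum())

    def rescaled(self, trajectory_weights: Mapping[int, float] | np.ndarray) -> "CountMatrix":
        """Return a copy with each trajectory's counts multiplied by a weight.

        Used by the Bayesian bootstrap, where whole trajectories are the
        resampling unit and receive Dirichlet weights.
        """
        w = np.zeros(self.N_max + 1)
        if isinstance(trajectory_weights, Mapping):
            for N, wn in trajectory_weights.items():
                w[int(N)] = float(wn)
        else:
            arr = np.asarray(trajectory_weights, dtype=float)
            if arr.shape != (self.N_max + 1,):
                raise GCProbeError(
                    f"trajectory weight vector must have length {self.N_max + 1}"
                )
            w = arr
        if np.any(w < 0):
            raise GCProbeError("trajectory weights must be nonnegative")
        return CountMatrix(self.t * w[:, None])


@dataclass(frozen=True)
class PartitionFunctions:
    """Maximum-likelihood regional canonical partition functions.

    ``omega_A[k]`` (``omega_B[k]``) is the estimated statistical weight of
    region A (B) hosting exactly ``k`` copies, under the gauge convention
    recorded in ``gauge``.  Occupancies never observed in the data have
    weight exactly zero.
    """

    omega_A: np.ndarray
    omega_B: np.ndarray
    gauge: str = "omega0=1"
    iterations: int = 0
    residual: float = 0.0
    converged: bool = True

    def __post_init__(self) -> None:
        oa = np.asarray(self.omega_A, dtype=float)
        ob = np.asarray(self.omega_B, dtype=float)
        if oa.shape != ob.shape or oa.ndim != 1:
            raise GCProbeError("omega_A and omega_B must be 1-D arrays of equal length")
        if np.any(oa < 0) or np.any(ob < 0):
            raise GCProbeError("partition-function entries must be nonnegative")
        object.__setattr__(self, "omega_A", oa)
        object.__setattr__(self, "omega_B", ob)

    @property
    def N_max(self) -> int:
        return self.omega_A.shape[0] - 1

    @property
    def Z(self) -> np.ndarray:
        """Canonical normalizations ``Z_N = sum_k omega_A(k) omega_B(N-k)``."""
        return _convolve_Z(self.omega_A, self.omega_B)

    def rescaled(self, lam: float) -> "PartitionFunctions":
        """Apply the gauge transformation ``omega(k) -> lam^k omega(k)``.

        Applied to both regions this leaves every canonical probability, and
        every concentration-indexed observable after re-calibration of the
        chemical potential, unchanged.  Exposed for testing gauge invariance.
        """
        k = np.arange(self.N_max + 1, dtype=float)
        fac = np.power(float(lam), k)
        return PartitionFunctions(
            self.omega_A * fac,
            self.omega_B * fac,
            gauge=f"{self.gauge}*lambda^k(lambda={lam:g})",
            iterations=self.iterations,
            residual=self.residual,
            converged=self.converged,
        )


@dataclass(frozen=True)
class GrandCanonicalEnsemble:
    """Grand-canonical occupancy distributions of both regions at fixed beta*mu."""

    beta_mu: float
    temperature: float
    P_A: np.ndarray
    P_B: np.ndarray

    @property
    def N_max(self) -> int:
        return self.P_A.shape[0] - 1


@dataclass(frozen=True)
class BufferSpec:
    """Physical description of the buffer region used for mu calibration.

    Attributes
    ----------
    V_B:
        Buffer-region volume in nm^3 (the box volume minus the binding
        sphere for MD data, or the site count for lattice data expressed
        through the conversion constant).
    concentration:
        Target reagent concentration in mol/L.
    temperature:
        Temperature in kelvin; only used for unit conversions.
    """

    V_B: float
    concentration: float
    temperature: float = 300.0

    def __post_init__(self) -> None:
        if self.V_B <= 0:
            raise GCProbeError("buffer volume V_B must be positive")
        if self.concentration <= 0:
            raise GCProbeError("target concentration must be positive")

    @property
    def target_occupancy(self) -> float:
        """Mean particle number in the buffer corresponding to the concentration."""
        return self.concentration * self.V_B / PARTICLE_PER_NM3_IN_MOLAR


#: Per-frame weights; columns: trajectory_N, frame, k_A, weight.
FrameWeightTable = pd.DataFrame


def _convolve_Z(omega_A: np.ndarray, omega_B: np.ndarray) -> np.ndarray:
    """Z_N = sum_k omega_A(k) omega_B(N - k) for N = 0 .. N_max."""
    full = np.convolve(omega_A, omega_B)
    return full[: omega_A.shape[0]]


def build_count_matrix(
    occupancy_sequences: Mapping[int, Sequence[int]],
) -> CountMatrix:
    """Histogram per-frame region-A occupancies into a count matrix.

    Parameters
    ----------
    occupancy_sequences:
        Maps the trajectory copy number ``N`` to the sequence of per-frame
        region-A occupancies ``k``.  Missing ``N`` (or empty sequences) are
        allowed and yield empty rows: the estimator copes with missing
        simulations.
    """
    if not occupancy_sequences:
        raise GCProbeError("no occupancy sequences provided")
    N_max = max(int(N) for N in occupancy_sequences)
    if N_max < 1:
        raise GCProbeError("trajectory copy numbers must be >= 1")
    t = np.zeros((N_max + 1, N_max + 1))
    for N, seq in occupancy_sequences.items():
        N = int(N)
        if N < 1:
            raise GCProbeError(f"trajectory copy number must be >= 1, got N={N}")
        ks = np.asarray(list(seq), dtype=int)
        if ks.size == 0:
            continue
        bad = np.nonzero((ks < 0) | (ks > N))[0]
        if bad.size:
            raise GCProbeError(
                f"trajectory N={N}, frame {bad[0]}: occupancy {ks[bad[0]]} "
                f"outside the valid range 0..{N}"
            )
        t[N, : N + 1] += np.bincount(ks, minlength=N + 1)
    return CountMatrix(t)


def log_likelihood(counts: CountMatrix, pf: PartitionFunctions) -> float:
    """Log-likelihood of the count matrix under given partition functions.

    ``sum_{N,k} t[N,k] * log(omega_A(k) omega_B(N-k) / Z_N)``.  Invariant
    under the lambda^k gauge transformation.
    """
    t = counts.t
    N_max = counts.N_max
    if pf.N_max != N_max:
        raise GCProbeError("partition functions and counts have mismatched N_max")
    Z = pf.Z
    total = 0.0
    for N in range(1, N_max + 1):
        row = t[N, : N + 1]
        if row.sum() == 0:
            continue
        w = pf.omega_A[: N + 1] * pf.omega_B[N::-1]
        if Z[N] <= 0:
            raise GCProbeError(f"Z_N is zero for N={N} with observed frames")
        observed = row > 0
        if np.any(observed & (w <= 0)):
            k_bad = int(np.nonzero(observed & (w <= 0))[0][0])
            raise GCProbeError(
                f"data outside model support: t[{N},{k_bad}] > 0 but "
                "omega_A(k)*omega_B(N-k) = 0"
            )
        total += float(np.sum(row[observed] * (np.log(w[observed]) - np.log(Z[N]))))
    return total


def solve_partition_functions(
    counts: CountMatrix,
    tol: float = 1e-10,
    max_iter: int = 100_000,
    raise_on_failure: bool = False,
    likelihood_history: list | None = None,
) -> PartitionFunctions:
    """Maximum-likelihood estimate of the regional partition functions.

    Iterates the self-consistent equations

        omega_A(k) <- A_k / sum_N L_N * omega_B(N - k) / Z_N
        omega_B(k) <- B_k / sum_N L_N * omega_A(N - k) / Z_N

    with ``Z_N`` recomputed after each half-update and the gauge re-fixed
    (``omega_A(0) = omega_B(0) = 1``) after every sweep.  Occupancies with
    zero pooled counts are pinned to zero and excluded from the updates.
    Stops when the maximum relative change over nonzero entries drops below
    ``tol``.

    Parameters
    ----------
    raise_on_failure:
        If True, raise :class:`NotConvergedError` at ``max_iter``; otherwise
        return the last iterate flagged ``converged=False``.
    likelihood_history:
        If a list is supplied, the log-likelihood after every sweep is
        appended to it; it is non-decreasing, which serves as a monitor of
        the iteration.
    """
    if tol <= 0:
        raise GCProbeError("tol must be positive")
    A = counts.A
    B = counts.B
    L = counts.L
    if counts.n_frames == 0:
        raise GCProbeError("count matrix has no frames")
    N_max = counts.N_max
    maskA = A > 0
    maskB = B > 0

    omega_A = maskA.astype(float)
    omega_B = maskB.astype(float)
    Ns = np.nonzero(L > 0)[0]  # trajectories that contribute

    def half_update(target_mask, marginal, omega_other):
        # denominators: D_k = sum_N L_N * omega_other(N - k) / Z_N
        Z = _convolve_Z(omega_A, omega_B)
        D = np.zeros(N_max + 1)
        for N in Ns:
            # omega_other(N - k) for k = 0..N
            D[: N + 1] += L[N] * omega_other[N::-1] / Z[N]
        new = np.zeros(N_max + 1)
        ok = target_mask & (D > 0)
        new[ok] = marginal[ok] / D[ok]
        return new

    def gauge_fix(oa, ob):
        # divide by the first supported entry of each region (k = 0 when observed)
        ka = int(np.nonzero(oa > 0)[0][0])
        kb = int(np.nonzero(ob > 0)[0][0])
        return oa / oa[ka], ob / ob[kb]

    residual = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        prev_A, prev_B = omega_A, omega_B
        omega_A = half_update(maskA, A, omega_B)
        omega_B = half_update(maskB, B, omega_A)
        omega_A, omega_B = gauge_fix(omega_A, omega_B)
        if likelihood_history is not None:
            likelihood_history.append(
                log_likelihood(counts, PartitionFunctions(omega_A, omega_B))
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            relA = np.abs(omega_A[maskA] - prev_A[maskA]) / omega_A[maskA]
            relB = np.abs(omega_B[maskB] - prev_B[maskB]) / omega_B[maskB]
        residual = float(max(relA.max(initial=0.0), relB.max(initial=0.0)))
        if residual < tol:
            return PartitionFunctions(
                omega_A, omega_B, iterations=it, residual=residual, converged=True
            )
    if raise_on_failure:
        raise NotConvergedError(
            f"fixed-point iteration did not converge in {max_iter} sweeps "
            f"(residual {residual:g} > tol {tol:g})"
        )
    return PartitionFunctions(
        omega_A, omega_B, iterations=it, residual=residual, converged=False
    )


def gc_distribution(
    pf: PartitionFunctions, beta_mu: float, temperature: float = 300.0
) -> GrandCanonicalEnsemble:
    """Grand-canonical occupancy distribution at dimensionless beta*mu.

    ``P(k) = omega(k) exp(beta_mu * k) / Xi`` per region, evaluated in the
    log domain so that large ``|beta_mu|`` cannot overflow.  The support is
    truncated at the largest simulated copy number, so concentrations whose
    mass would extend beyond it are unreliable.
    """
    k = np.arange(pf.N_max + 1, dtype=float)

    def dist(omega: np.ndarray) -> np.ndarray:
        if not np.any(omega > 0):
            raise GCProbeError("partition function has empty support")
        with np.errstate(divide="ignore"):
            logw = np.where(omega > 0, np.log(np.where(omega > 0, omega, 1.0)), -np.inf)
        logw = logw + beta_mu * k
        P = np.exp(logw - logsumexp(logw[np.isfinite(logw)]))
        P[~np.isfinite(logw)] = 0.0
        return P / P.sum()

    return GrandCanonicalEnsemble(
        beta_mu=float(beta_mu),
        temperature=float(temperature),
        P_A=dist(pf.omega_A),
        P_B=dist(pf.omega_B),
    )


def mean_occupancy(gce: GrandCanonicalEnsemble) -> tuple[float, float]:
    """Grand-canonical mean copy numbers ``(<k>_A, <k>_B)``."""
    k = np.arange(gce.N_max + 1, dtype=float)
    return float(np.dot(k, gce.P_A)), float(np.dot(k, gce.P_B))


def concentration_ceiling(pf: PartitionFunctions, V_B: float) -> float:
    """Largest representable concentration (mol/L) given the truncated support."""
    k_top = int(np.nonzero(pf.omega_B > 0)[0][-1])
    return k_top * PARTICLE_PER_NM3_IN_MOLAR / V_B


def mu_from_concentration(
    pf: PartitionFunctions,
    buffer: BufferSpec,
    rel_tol: float = 1e-12,
    max_iter: int = 500,
) -> float:
    """Calibrate beta*mu so the mean buffer occupancy matches a concentration.

    The mean occupancy is strictly increasing in beta*mu, so the root is
    bracketed by geometric expansion and then refined by bisection until the
    relative mismatch falls below ``rel_tol``.

    Raises
    ------
    ConcentrationCeilingError
        If the target occupancy meets or exceeds the largest supported
        buffer occupancy (distribution truncated at the sampled N_max).
    """
    target = buffer.target_occupancy
    k_top = int(np.nonzero(pf.omega_B > 0)[0][-1])
    if target >= k_top:
        raise ConcentrationCeilingError(
            buffer.concentration, concentration_ceiling(pf, buffer.V_B)
        )
    if target <= 0:
        raise GCProbeError("target occupancy must be positive")

    def mean_B(bm: float) -> float:
        return mean_occupancy(gc_distribution(pf, bm, buffer.temperature))[1]

    lo, hi = -1.0, 1.0
    span = 1.0
    while mean_B(lo) > target:
        span *= 2.0
        lo -= span
    span = 1.0
    while mean_B(hi) < target:
        span *= 2.0
        hi += span
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        m = mean_B(mid)
        if abs(m - target) <= rel_tol * target:
            return mid
        if m < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def frame_weights(
    pf: PartitionFunctions,
    beta_mu: float,
    counts: CountMatrix,
    occupancy_sequences: Mapping[int, Sequence[int]],
    temperature: float = 300.0,
) -> FrameWeightTable:
    """Per-frame grand-canonical weights for the concatenated trajectories.

    A frame with region-A occupancy ``k`` receives weight proportional to
    ``P_A(k) / A_k``: the target grand-canonical mass at ``k`` shared evenly
    among the pooled frames that sampled it.  Frames with equal ``k`` are
    exchangeable under the region-decoupling assumption, and this is the
    unique choice for which the weighted occupancy histogram reproduces the
    grand-canonical distribution exactly.
    """
    gce = gc_distribution(pf, beta_mu, temperature)
    A = counts.A
    rows: list[tuple[int, int, int]] = []
    for N in sorted(occupancy_sequences):
        for i, k in enumerate(occupancy_sequences[N]):
            rows.append((int(N), i, int(k)))
    if not rows:
        raise GCProbeError("no frames to weight")
    ks = np.array([r[2] for r in rows])
    if np.any(A[ks] <= 0):
        bad = rows[int(np.nonzero(A[ks] <= 0)[0][0])]
        raise GCProbeError(
            f"frame (N={bad[0]}, frame={bad[1]}) has occupancy k={bad[2]} "
            "never seen in the count matrix"
        )
    w = gce.P_A[ks] / A[ks]
    w = w / w.sum()
    return pd.DataFrame(
        {
            "trajectory_N": [r[0] for r in rows],
            "frame": [r[1] for r in rows],
            "k_A": ks,
            "weight": w,
        }
    )


def gc_average(weights: FrameWeightTable, observable: Iterable[float]) -> float:
    """Weighted ensemble average ``sum_i w_i O_i`` of a per-frame observable."""
    obs = np.asarray(list(observable), dtype=float)
    w = weights["weight"].to_numpy()
    if obs.shape != w.shape:
        raise GCProbeError(
            f"observable has {obs.shape[0]} values but there are {w.shape[0]} frames"
        )
    return float(np.dot(w, obs))
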