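"""Exactly solvable lattice model used as ground truth for the reweighting core.

The lattice has ``S_A`` sites in a binding region A and ``S_B`` sites in a
buffer region B.  Particles interact only through mutual exclusion (at most
one per site).  Two variants exist: a purely entropic lattice, whose regional
partition functions are binomial coefficients, and a lattice with a single
stabilizing site in region A contributing a free energy ``eps`` (in k_B T;
negative values stabilize), mimicking a reagent binding an RNA placed in
region A.  Everything is available in closed form, so the model doubles as
an exact oracle and as a direct canonical sampler for validating the
maximum-likelihood estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import comb
from scipy.stats import binom

from gcprobe.gc_core import GCProbeError


@dataclass(frozen=True)
class LatticeModel:
    S_A: int
    S_B: int
    eps: float = 0.0
    N_max: int | None = None

    def __post_init__(self) -> None:
        if self.S_A < 1 or self.S_B < 1:
            raise GCProbeError("S_A and S_B must each be >= 1")
        n_max = self.N_max if self.N_max is not None else self.S_A + self.S_B
        if n_max > self.S_A + self.S_B:
            raise GCProbeError("N_max cannot exceed the total number of sites")
        object.__setattr__(self, "N_max", int(n_max))


def exact_omega(model: LatticeModel, region: str) -> np.ndarray:
    """Exact canonical partition function Omega(k) of one region, k = 0..S.

    Region B is always purely entropic: ``Omega_B(k) = C(S_B, k)``.  Region A
    with a stabilizing site splits by whether that site is occupied:

        Omega_A(k) = C(S_A - 1, k) + C(S_A - 1, k - 1) * exp(-eps)
    """
    if region == "B":
        S = model.S_B
        return comb(S, np.arange(S + 1))
    if region != "A":
        raise GCProbeError(f"region must be 'A' or 'B', got {region!r}")
    S = model.S_A
    k = np.arange(S + 1)
    if model.eps == 0.0:
        return comb(S, k)
    return comb(S - 1, k) + comb(S - 1, k - 1) * np.exp(-model.eps)


def _padded_omegas(model: LatticeModel) -> tuple[np.ndarray, np.ndarray]:
    """Both omegas zero-padded to a common length S_A + S_B + 1."""
    size = model.S_A + model.S_B + 1
    oa = np.zeros(size)
    ob = np.zeros(size)
    oa[: model.S_A + 1] = exact_omega(model, "A")
    ob[: model.S_B + 1] = exact_omega(model, "B")
    return oa, ob


def exact_canonical_distribution(model: LatticeModel, N: int) -> np.ndarray:
    """P^N(k) = Omega_A(k) Omega_B(N-k) / Z_N over k = 0..N.

    For the purely entropic lattice this is the hypergeometric law
    ``C(S_A, k) C(S_B, N-k) / C(S_A + S_B, N)`` (Vandermonde identity).
    """
    if N < 0 or N > model.N_max:
        raise GCProbeError(f"N must lie in 0..{model.N_max}, got {N}")
    oa, ob = _padded_omegas(model)
    w = np.array([oa[k] * ob[N - k] if N - k >= 0 else 0.0 for k in range(N + 1)])
    return w / w.sum()


def exact_gc_distribution(
    model: LatticeModel, beta_mu: float
) -> tuple[np.ndarray, np.ndarray]:
    """Grand-canonical occupancy laws (P_A, P_B) at fugacity z = exp(beta_mu).

    For the entropic case each region is binomial with per-site success
    probability z / (1 + z).
    """
    z = np.exp(beta_mu)
    oa, ob = _padded_omegas(model)

    def dist(omega: np.ndarray, size: int) -> np.ndarray:
        k = np.arange(size + 1)
        w = omega[: size + 1] * z**k
        return w / w.sum()

    return dist(oa, model.S_A), dist(ob, model.S_B)


def exact_binomial_gc(S: int, beta_mu: float) -> np.ndarray:
    """Closed-form entropic-region occupancy law: Binomial(S, z/(1+z))."""
    z = np.exp(beta_mu)
    return binom.pmf(np.arange(S + 1), S, z / (1.0 + z))


def sample_canonical(
    model: LatticeModel, N: int, n_frames: int, seed: int
) -> np.ndarray:
    """Draw i.i.d. region-A occupancies from the exact canonical law.

    Site configurations factorize given k, so direct sampling of k is exact
    and no Markov chain is needed.  Deterministic under ``seed``.
    """
    if n_frames < 0:
        raise GCProbeError("n_frames must be nonnegative")
    p = exact_canonical_distribution(model, N)
    rng = np.random.default_rng(seed)
    return rng.choice(np.arange(N + 1), size=n_frames, p=p)


def sample_occupancy_sequences(
    model: LatticeModel, n_frames: int, seed: int
) -> dict[int, np.ndarray]:
    """Canonical occupancy sequences for every N in 1..N_max.

    Convenience wrapper emitting the mapping consumed by
    :func:`gcprobe.gc_core.build_count_matrix`; each trajectory gets an
    independent seed derived from ``seed``.
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=model.N_max + 1)
    return {
        N: sample_canonical(model, N, n_frames, int(seeds[N]))
        for N in range(1, model.N_max + 1)
    }
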