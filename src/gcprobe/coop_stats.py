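"""Concentration-dependent reactivities, power-law fits, and couplings.

A nucleotide's reactivity ``R_i(C)`` is estimated as the grand-canonical
probability of observing it bound to any probe copy, computed by reweighting
the pooled frames at the chemical potential calibrated to concentration
``C``.  Nonlinearity of ``R_i(C)`` is quantified by fitting power laws
``R = alpha * C^beta`` in log-log space; ``beta > 1`` signals predominantly
cooperative binding, ``beta < 1`` anticooperative, and ``alpha`` is the
reactivity extrapolated to 1 M.  Pairwise cooperativity is measured by the
free-energy coupling

    ddG_ij = -k_B T * ln[(p11 * p00) / (p10 * p01)]

from the reweighted frequencies of the four pairwise binding states;
negative values mean binding one nucleotide increases the other's affinity.
Uncertainties come from a Bayesian bootstrap that treats whole trajectories
as the resampling unit, and multiple pairs are screened with the
Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import linregress
from statsmodels.stats.multitest import multipletests

from gcprobe import binding as _binding
from gcprobe.gc_core import (
    BufferSpec,
    CountMatrix,
    GCProbeError,
    KB_KCAL_PER_MOL_K,
    PartitionFunctions,
    concentration_ceiling,
    gc_distribution,
    mu_from_concentration,
    solve_partition_functions,
)


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares power law R = alpha * C^beta fitted on log-log axes."""

    alpha: float
    beta: float
    se_alpha: float
    se_beta: float
    c_min: float
    c_max: float


@dataclass(frozen=True)
class CouplingMatrix:
    """Pairwise free-energy couplings with significance annotations.

    ``ddg`` is in k_B T; the diagonal is undefined (NaN) and pairs where any
    of the four state frequencies vanished are flagged undefined rather than
    reported as infinite.
    """

    nucleotides: tuple
    ddg: np.ndarray
    defined: np.ndarray
    temperature: float = 300.0
    bootstrap_fraction: np.ndarray | None = None
    significant_cooperative: np.ndarray | None = None
    significant_anticooperative: np.ndarray | None = None

    @property
    def ddg_kcal_per_mol(self) -> np.ndarray:
        return self.ddg * KB_KCAL_PER_MOL_K * self.temperature

    def pairs(self) -> list[tuple]:
        return list(itertools.combinations(self.nucleotides, 2))


def n_pair_hypotheses(n_nucleotides: int) -> int:
    """Number of unordered nucleotide pairs tested simultaneously."""
    return n_nucleotides * (n_nucleotides - 1) // 2


def default_concentration_grid(
    pf: PartitionFunctions, V_B: float, n_points: int = 20, c_low: float = 1e-5
) -> np.ndarray:
    """Log-spaced grid from ``c_low`` up to just below the supported ceiling."""
    ceiling = concentration_ceiling(pf, V_B)
    return np.geomspace(c_low, 0.95 * ceiling, n_points)


def _weights_from_binding(
    table: pd.DataFrame,
    counts: CountMatrix,
    pf: PartitionFunctions,
    beta_mu: float,
    temperature: float,
) -> np.ndarray:
    """Frame weights aligned with the rows of a binding table."""
    gce = gc_distribution(pf, beta_mu, temperature)
    A = counts.A
    ks = table["k_A"].to_numpy().astype(int)
    if np.any(A[ks] <= 0):
        bad = int(np.nonzero(A[ks] <= 0)[0][0])
        raise GCProbeError(
            f"binding-table row {bad} has occupancy k={ks[bad]} with no counts"
        )
    w = gce.P_A[ks] / A[ks]
    return w / w.sum()


def reactivity_profile(
    table: pd.DataFrame,
    counts: CountMatrix,
    pf: PartitionFunctions,
    V_B: float,
    concentration_grid: Sequence[float],
    temperature: float = 300.0,
) -> pd.DataFrame:
    """Grand-canonical bound probability per nucleotide across concentrations.

    Returns a long-format table with columns ``nucleotide``,
    ``concentration_M`` and ``R``.  Each grid point calibrates its own
    chemical potential, so the curves are smooth in concentration by
    construction.  Grid points above the supported ceiling raise
    :class:`~gcprobe.gc_core.ConcentrationCeilingError` naming the ceiling.
    """
    nuc_cols = _binding.nucleotide_columns(table)
    if not nuc_cols:
        raise GCProbeError("binding table has no nucleotide columns")
    records = []
    for C in concentration_grid:
        beta_mu = mu_from_concentration(pf, BufferSpec(V_B, C, temperature))
        w = _weights_from_binding(table, counts, pf, beta_mu, temperature)
        for col in nuc_cols:
            records.append(
                {
                    "nucleotide": col.removeprefix("nuc_"),
                    "concentration_M": float(C),
                    "R": float(np.dot(w, table[col].to_numpy())),
                }
            )
    return pd.DataFrame.from_records(records)


def fit_power_law(
    concentrations: Sequence[float],
    R: Sequence[float],
    c_min: float = 1e-3,
    c_max: float = 1e-2,
) -> PowerLawFit:
    """Fit R = alpha * C^beta by ordinary least squares on the logarithms.

    The default window 1e-3 to 1e-2 M targets the range where higher-order
    (cooperative) contributions emerge while statistics remain reliable.
    All reactivities inside the window must be positive.
    """
    C = np.asarray(concentrations, dtype=float)
    r = np.asarray(R, dtype=float)
    sel = (C >= c_min) & (C <= c_max)
    if sel.sum() < 2:
        raise GCProbeError("need at least two concentrations in the fitting window")
    if np.any(r[sel] <= 0):
        raise GCProbeError("nonpositive reactivity inside the fitting window")
    res = linregress(np.log(C[sel]), np.log(r[sel]))
    alpha = float(np.exp(res.intercept))
    se_alpha = alpha * float(res.intercept_stderr)
    return PowerLawFit(
        alpha=alpha,
        beta=float(res.slope),
        se_alpha=se_alpha,
        se_beta=float(res.stderr),
        c_min=c_min,
        c_max=c_max,
    )


def pair_state_frequencies(
    table: pd.DataFrame, weights: np.ndarray, i, j
) -> np.ndarray:
    """Weighted frequencies (p00, p01, p10, p11) of the pairwise states."""
    bi = table[f"nuc_{i}"].to_numpy().astype(int)
    bj = table[f"nuc_{j}"].to_numpy().astype(int)
    idx = 2 * bi + bj  # 0->00, 1->01, 2->10, 3->11
    p = np.bincount(idx, weights=weights, minlength=4)
    return p / p.sum()


def coupling_from_frequencies(p: Sequence[float]) -> float:
    """Free-energy coupling in k_B T from (p00, p01, p10, p11); NaN if undefined."""
    p = np.asarray(p, dtype=float)
    if p.shape != (4,):
        raise GCProbeError("expected four pairwise state frequencies")
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise GCProbeError("pairwise state frequencies must sum to 1")
    if np.any(p == 0):
        return float("nan")
    p00, p01, p10, p11 = p
    return float(-np.log((p11 * p00) / (p10 * p01)))


def coupling_matrix(
    frequencies: Mapping[tuple, Sequence[float]],
    nucleotides: Sequence,
    temperature: float = 300.0,
) -> CouplingMatrix:
    """Assemble the symmetric coupling matrix from per-pair state frequencies."""
    nucs = tuple(nucleotides)
    n = len(nucs)
    ddg = np.full((n, n), np.nan)
    defined = np.zeros((n, n), dtype=bool)
    index = {nid: a for a, nid in enumerate(nucs)}
    for (i, j), p in frequencies.items():
        a, b = index[i], index[j]
        val = coupling_from_frequencies(p)
        ddg[a, b] = ddg[b, a] = val
        defined[a, b] = defined[b, a] = np.isfinite(val)
    return CouplingMatrix(nucs, ddg, defined, temperature=temperature)


def coupling_matrix_at_concentration(
    table: pd.DataFrame,
    counts: CountMatrix,
    pf: PartitionFunctions,
    V_B: float,
    concentration: float = 5.7e-3,
    temperature: float = 300.0,
) -> CouplingMatrix:
    """Coupling matrix from a binding table, reweighted to one concentration.

    The 5.7 mM default is an intermediate concentration representative of
    typical probing conditions.
    """
    beta_mu = mu_from_concentration(pf, BufferSpec(V_B, concentration, temperature))
    w = _weights_from_binding(table, counts, pf, beta_mu, temperature)
    nucs = [c.removeprefix("nuc_") for c in _binding.nucleotide_columns(table)]
    freqs = {
        (i, j): pair_state_frequencies(table, w, i, j)
        for i, j in itertools.combinations(nucs, 2)
    }
    return coupling_matrix(freqs, nucs, temperature)


def bayesian_bootstrap(
    analysis: Callable[[np.ndarray], np.ndarray | float],
    n_trajectories: int,
    n_iter: int = 10_000,
    seed: int = 0,
) -> np.ndarray:
    """Bayesian bootstrap over whole trajectories.

    Each iteration draws trajectory weights from a flat Dirichlet and hands
    them to ``analysis``, which is expected to rescale the per-trajectory
    frame counts, re-solve the partition functions, re-calibrate the
    chemical potential, and recompute its observable.  Treating entire
    trajectories as single data points makes the uncertainty estimate
    immune to within-trajectory autocorrelation.

    Returns an array of shape ``(n_iter, ...)`` stacking the outputs.
    """
    if n_trajectories < 2:
        raise GCProbeError("bootstrap needs at least two trajectories")
    if n_iter < 1:
        raise GCProbeError("n_iter must be positive")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_iter):
        w = rng.dirichlet(np.ones(n_trajectories))
        out.append(np.asarray(analysis(w), dtype=float))
    return np.stack(out)


def frame_level_bootstrap(
    counts: CountMatrix,
    analysis: Callable[[CountMatrix], np.ndarray | float],
    n_iter: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Bayesian bootstrap treating individual frames as the resampling unit.

    Each trajectory's occupancy histogram is replaced by a Dirichlet draw
    with its observed counts as concentration parameters (realized through
    per-cell gamma variates), preserving the trajectory length.  This is the
    calibrated choice for independently sampled frames, e.g. the direct
    lattice sampler; for correlated MD trajectories use
    :func:`bayesian_bootstrap` over whole trajectories instead.
    """
    if n_iter < 1:
        raise GCProbeError("n_iter must be positive")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_iter):
        t2 = np.zeros_like(counts.t)
        for N in range(1, counts.N_max + 1):
            row = counts.t[N, : N + 1]
            L_N = row.sum()
            if L_N == 0:
                continue
            g = rng.gamma(np.maximum(row, 0.0))
            t2[N, : N + 1] = L_N * g / g.sum()
        out.append(np.asarray(analysis(CountMatrix(t2)), dtype=float))
    return np.stack(out)


def bootstrap_sign_pvalues(samples: np.ndarray, point_estimates: np.ndarray) -> np.ndarray:
    """Empirical p-values: fraction of bootstrap draws contradicting the sign.

    Uses the (r + 1) / (B + 1) correction so p-values are never exactly
    zero with finite bootstrap size B.
    """
    samples = np.atleast_2d(samples)
    est = np.atleast_1d(point_estimates)
    B = samples.shape[0]
    opposite = np.where(est < 0, samples >= 0, samples <= 0)
    r = opposite.sum(axis=0)
    return (r + 1.0) / (B + 1.0)


def bh_select(p_values: Sequence[float], alpha: float = 0.01, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up selection at FDR level alpha.

    ``m`` cross-checks the declared number of simultaneous hypotheses
    against the supplied p-values.  Returns a boolean rejection mask in the
    input order.
    """
    p = np.asarray(p_values, dtype=float)
    if m is not None and m != p.shape[0]:
        raise GCProbeError(f"declared m={m} but received {p.shape[0]} p-values")
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    reject, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject


def flag_significant_couplings(
    cm: CouplingMatrix,
    bootstrap_samples: Mapping[tuple, np.ndarray],
    alpha: float = 0.01,
) -> CouplingMatrix:
    """Annotate a coupling matrix with BH-controlled significance flags.

    Per pair, the empirical p-value is the fraction of bootstrap iterations
    whose coupling has the sign opposite to the point estimate.  Pairs with
    undefined couplings are excluded from the multiple-testing correction.
    Cooperative (ddG < 0) and anticooperative (ddG > 0) flags are reported
    separately.
    """
    nucs = cm.nucleotides
    index = {nid: a for a, nid in enumerate(nucs)}
    n = len(nucs)
    frac = np.full((n, n), np.nan)
    tested, pvals = [], []
    for (i, j), samp in bootstrap_samples.items():
        a, b = index[i], index[j]
        if not cm.defined[a, b]:
            continue
        est = cm.ddg[a, b]
        samp = np.asarray(samp, dtype=float)
        samp = samp[np.isfinite(samp)]
        if samp.size == 0:
            continue
        pv = float(bootstrap_sign_pvalues(samp[:, None], np.array([est]))[0])
        frac[a, b] = frac[b, a] = pv
        tested.append((a, b))
        pvals.append(pv)
    coop = np.zeros((n, n), dtype=bool)
    anti = np.zeros((n, n), dtype=bool)
    if tested:
        reject = bh_select(pvals, alpha=alpha, m=len(pvals))
        for (a, b), rej in zip(tested, reject):
            if not rej:
                continue
            if cm.ddg[a, b] < 0:
                coop[a, b] = coop[b, a] = True
            else:
                anti[a, b] = anti[b, a] = True
    return CouplingMatrix(
        nucs,
        cm.ddg,
        cm.defined,
        temperature=cm.temperature,
        bootstrap_fraction=frac,
        significant_cooperative=coop,
        significant_anticooperative=anti,
    )
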