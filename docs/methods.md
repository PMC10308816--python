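# Methods

## Model and estimator

The package assumes a simulation volume partitioned into a binding region A
and a buffer region B that are statistically decoupled: conditional on the
number `k` of controlled-species copies in A, the configurations of the two
regions are independent. Under this assumption the canonical occupancy law
of the simulation with `N` copies factorizes as
`P^N(k) = Ω_A(k) Ω_B(N−k) / Z_N` with regional canonical partition
functions Ω. The likelihood of the pooled count matrix `t_Nk` depends on
the Ω's only through these laws; maximizing it under the per-N
normalization constraints (eliminating the Lagrange multipliers
analytically — they reduce to the normalizations `Z_N`, never materialized)
yields the coupled stationarity equations

    Ω_A(k) = A_k / Σ_N L_N Ω_B(N−k)/Z_N,
    Ω_B(k) = B_k / Σ_N L_N Ω_A(N−k)/Z_N.

These are iterated as alternating half-updates, recomputing `Z_N` after
each half-sweep. The log-likelihood is non-decreasing across sweeps
(asserted per iteration in the tests), and convergence is declared when the
maximum relative change of all supported Ω entries falls below `tol`
(default 1e-10; `max_iter` default 100000, both overridable). Failure to
converge is flagged on the result, never silent. Trajectories may be
missing (`L_N = 0`): they simply drop out of the sums. Counts may be
real-valued, which is how Dirichlet-weighted bootstrap counts enter the
solver unchanged.

### Gauge freedom

The likelihood is invariant under `Ω_A(k) → λ^k Ω_A(k)`,
`Ω_B(k) → λ^k Ω_B(k)`: λ is statistically unidentifiable. The solver fixes
`Ω_A(0) = Ω_B(0) = 1` after every sweep (anchoring at the first supported
occupancy when `k = 0` was never observed), but a residual λ drift between
the estimate and any external reference is expected and harmless: the
chemical potential is always re-calibrated from a physical concentration
through region B, which makes every concentration-indexed observable
exactly gauge-invariant (tested to 1e-10, not assumed). Where tests compare
raw Ω vectors against exact references, the residual gauge is first removed
by a log-linear fit of `log(Ω_B_est/Ω_B_exact)` versus `k`.

### Occupancies with zero support

`Ω(k)` is pinned to 0 exactly when the pooled marginal count is zero, and
such entries are excluded from the update denominators. Requesting frame
weights for an occupancy never seen in the counts is an error rather than a
silent zero, because the estimator has no information there.

## Chemical potential and concentration

All chemical potentials are dimensionless (βμ); physical unit conversions
use k_B T at the configured temperature (default 300 K). The molarity of
the buffer region maps to a target mean occupancy through
`⟨k⟩_B = C · V_B / 1.660539` (1 particle/nm³ ≡ 1.660539 mol/L). Since the
grand-canonical mean occupancy is strictly increasing in βμ, the inverse
problem is solved by geometric bracket expansion followed by bisection, to
a relative occupancy tolerance of 1e-12 (tighter than the 1e-8 round-trip
contract so that gauge-invariance residuals stay below 1e-10). All
`exp(βμ·k)` sums are evaluated in the log domain (logsumexp), so extreme
chemical potentials cannot overflow.

Because the estimated distributions are truncated at the largest simulated
copy number, only concentrations whose buffer occupancy stays below the
supported maximum are representable; beyond that the code raises an error
naming the attainable ceiling rather than extrapolating. The buffer volume
`V_B` is supplied by the user, since region A is an analysis-time choice;
a helper value can be computed as `V_box − (4/3)π r_A³`. Note that for the
MD setting this work targets (box ≈ 439 nm³, r_A = 3 nm) this formula gives
≈ 326 nm³, not the ≈ 316 nm³ sometimes quoted alongside those inputs; the
code computes the formula value.

## Frame weights

A frame with region-A occupancy `k` receives weight
`w(k) ∝ P_A^GC(k)/A_k`. Frames with equal `k` are exchangeable under the
decoupling assumption, and dividing the target grand-canonical mass at `k`
evenly among the pooled frames that sampled it is the unique choice for
which the weighted occupancy histogram equals the grand-canonical law
exactly (asserted to 1e-12).

## Binding geometry

Region membership uses the probe center of mass inside a closed ball of
radius `r_A` (default 3 nm) around the per-frame RNA center of mass. A
probe binds the nucleotide whose O2′ atom is nearest to the probe's
reactive carbonyl carbon (C7), provided the distance is strictly below
`r_th` (default 3.5 Å); exact-tie nearest distances are broken toward the
lowest nucleotide index (a measure-zero event; determinism preferred). No
check is made that a binding probe also lies inside region A: with
3.5 Å ≪ 3 nm the implication is geometric. Distances use the triclinic
minimum-image convention, implemented as an explicit 27-image search,
which is exact for all cells whose minimum image lies within one lattice
shift (every box used here). Restrained terminal bases can be excluded
from the nucleotide set at read time. The covalent acylation step is not
modeled; reactivity is identified with the physical bound-state
probability.

## Cooperativity statistics

Reactivity `R_i(C)` is the reweighted frequency of nucleotide `i` being
bound, evaluated on a log-spaced concentration grid (default 20 points from
1e-5 M to just below the ceiling), each grid point with its own calibrated
βμ — the curves are smooth in C by construction. Power laws `R = α·C^β`
are fitted by ordinary least squares in log–log space on the default
window 1e-3 to 1e-2 M, the range where higher-order (cooperative)
contributions emerge while remaining within typical experimental
concentrations; α is the 1 M extrapolation. Pairwise couplings use the
log-odds form `ΔΔG_ij = −k_B T ln[(p11 p00)/(p10 p01)]` on the reweighted
pairwise state frequencies, reported in k_B T (kcal/mol available via the
configured temperature); pairs with any vanishing cell are flagged
undefined rather than infinite, and excluded from multiple testing with an
explicit flag. The representative coupling matrix defaults to C = 5.7 mM,
an intermediate concentration among those typically probed.

## Uncertainty and significance

Two bootstrap schemes are provided, chosen by the correlation structure of
the input:

- **Trajectory-level Bayesian bootstrap** (`bayesian_bootstrap`): each
  iteration draws flat-Dirichlet weights over whole trajectories, rescales
  their counts, re-solves Ω, re-calibrates μ, and recomputes the
  observable (default 10000 iterations). Treating entire trajectories as
  single data points makes the estimate immune to within-trajectory
  autocorrelation, which is the relevant failure mode for MD data.
- **Frame-level Bayesian bootstrap** (`frame_level_bootstrap`): per-cell
  gamma-weighted resampling of each trajectory's occupancy histogram. This
  is the calibrated choice when frames are independent draws — as in the
  direct lattice sampler — where a trajectory-level scheme over only a
  handful of trajectories is noticeably under-dispersed.

Empirical sign p-values use the (r+1)/(B+1) correction so finite bootstraps
never produce exact zeros. Significance over the
`m = n(n−1)/2` simultaneous pair hypotheses (28 for 8 nucleotides) is
controlled with the Benjamini–Hochberg step-up procedure at α = 0.01 by
default, with cooperative and anticooperative directions flagged
separately.

## Experimental concentration series

Raw capillary-electrophoresis reads are made comparable across
concentration channels by clipping negatives to zero *before* summation
(dividing by a total still containing negatives could flip signs — the
operative ordering ambiguity is resolved this way), dividing by the channel
sum, and multiplying by the channel's nominal concentration (expressed in
mM). This enforces a linear dependence of the average read on
concentration while preserving position- and concentration-dependence.
Per-nucleotide power laws are fitted across channels as above; because the
1 M extrapolation α amplifies exponent errors, the shifted amplitude
`α·0.0125^β` (reactivity at 12.5 mM, the highest channel) is reported
alongside. Group comparisons (GNRA-loop vs other nucleotides, plus the
first-position G subgroup) use Welch's t-test by default, with a
pooled-variance option; groups with fewer than two members get means but
no test.

## Synthetic data

The synthetic binding model places N mutually excluding probes among M
nucleotide sites (energies `e_i`, pairwise couplings `J_ij`, both k_B T),
F featureless free slots in region A, and S_B buffer slots. Everything is
generated by exact enumeration (guarded at M ≤ 12, N_max ≤ 16) rather than
MCMC, so every fixture carries exact reference partition functions,
reactivities, and couplings; with only one coupled pair the marginal
log-odds coupling equals `J_ij` exactly at every fugacity. Geometric probe
frames place each bound probe's C7 at 3.0 Å from its target O2′ on a 1 nm
nucleotide ring, making detection round-trips exact by construction, and
can be serialized as multi-model PDB files to exercise the MD reader path.
What these fixtures deliberately do not emulate: realistic RNA/probe
geometry, conformational dynamics coupling binding sites (cooperativity is
injected as a direct pair energy, not mediated by structure), frame
autocorrelation, or force-field physics. Passing tests therefore validate
the estimators and their statistical calibration, not the MD model behind
any particular application.

## Problem sizes

Test and acceptance runs use the entropic lattice at S_A = 3, S_B = 5,
N = 1..6 with 10⁵ frames per trajectory, and the coupled two-site model
(J = −1 k_B T, F = 2, S_B = 12, N_max = 6, V_B = 316 nm³ so that
concentrations land on the mM scale of real probing experiments) at 1500
frames per trajectory and 100 replicates. These sizes put the statistical
errors at the percent level, small enough to resolve the injected effects
while keeping the full suite fast.
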