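import numpy as np
import pytest

from gcprobe import fixtures as fx
from gcprobe import gc_core, lattice


@pytest.fixture(scope="session")
def entropic_lattice():
    return lattice.LatticeModel(S_A=3, S_B=5, N_max=6)


@pytest.fixture(scope="session")
def lattice_occupancies(entropic_lattice):
    return lattice.sample_occupancy_sequences(entropic_lattice, 20_000, seed=11)


@pytest.fixture(scope="session")
def lattice_counts(lattice_occupancies):
    return gc_core.build_count_matrix(lattice_occupancies)


@pytest.fixture(scope="session")
def lattice_pf(lattice_counts):
    return gc_core.solve_partition_functions(lattice_counts)


@pytest.fixture(scope="session")
def coupled_model():
    """Two coupled nucleotide sites (J = -1 k_B T) in an MD-scale buffer."""
    J = np.array([[0.0, -1.0], [-1.0, 0.0]])
    return fx.SyntheticBindingModel(
        e=np.zeros(2), J=J, F=2, S_B=12, N_max=6, V_B=316.0
    )


@pytest.fixture(scope="session")
def coupled_data(coupled_model):
    occ, table, ref = fx.synth_binding_trajectories(coupled_model, 4000, seed=7)
    counts = gc_core.build_count_matrix(occ)
    pf = gc_core.solve_partition_functions(counts)
    return occ, table, counts, pf, ref


def gauge_corrected_ratios(pf, exact_A, exact_B):
    """Divide out the residual lambda^k gauge before comparing to exact omegas.

    The likelihood determines the omegas only up to a common lambda^k
    rescaling, so lambda is estimated by a log-linear fit of the region-B
    mismatch and removed from both regions.
    """
    nB = exact_B.shape[0] - 1
    ks = np.arange(1, nB + 1)
    log_lam = np.polyfit(ks, np.log(pf.omega_B[1 : nB + 1] / exact_B[1:]), 1)[0]
    lam = np.exp(log_lam)
    nA = exact_A.shape[0] - 1
    corr_A = pf.omega_A[: nA + 1] / lam ** np.arange(nA + 1) / exact_A
    corr_B = pf.omega_B[: nB + 1] / lam ** np.arange(nB + 1) / exact_B
    return corr_A, corr_B
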