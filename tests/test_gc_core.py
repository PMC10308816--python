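"""Unit and property tests for the maximum-likelihood reweighting core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gcprobe import gc_core as G
from gcprobe import lattice as L
from gcprobe.gc_core import (
    BufferSpec,
    ConcentrationCeilingError,
    GCProbeError,
    PartitionFunctions,
)

from conftest import gauge_corrected_ratios


class TestBuildCountMatrix:
    def test_single_trajectory_direct_count(self):
        cm = G.build_count_matrix({1: [0, 1, 1, 0]})
        assert cm.t[1, 0] == 2 and cm.t[1, 1] == 2
        np.testing.assert_array_equal(cm.A, [2, 2])
        np.testing.assert_array_equal(cm.B, [2, 2])
        np.testing.assert_array_equal(cm.L, [0, 4])

    def test_missing_simulation_gives_empty_row(self):
        cm = G.build_count_matrix({1: [0, 1], 2: [], 3: [1, 2, 3]})
        assert cm.L[2] == 0
        assert np.all(cm.t[2] == 0)

    def test_two_trajectory_marginals_by_enumeration(self):
        # frames: N=1 -> B-occupancies (0, 0); N=2 -> B-occupancies (2, 1, 0)
        cm = G.build_count_matrix({1: [1, 1], 2: [0, 1, 2]})
        np.testing.assert_array_equal(cm.A, [1, 3, 1])
        np.testing.assert_array_equal(cm.B, [3, 1, 1])
        np.testing.assert_array_equal(cm.L, [0, 2, 3])

    def test_occupancy_above_n_rejected_with_location(self):
        with pytest.raises(GCProbeError, match="N=2, frame 1"):
            G.build_count_matrix({2: [0, 3]})

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        st.dictionaries(
            st.integers(1, 5),
            st.lists(st.integers(0, 5), max_size=30),
            min_size=1,
        )
    )
    def test_marginal_conservation(self, seqs):
        seqs = {N: [min(k, N) for k in ks] for N, ks in seqs.items()}
        cm = G.build_count_matrix(seqs)
        total = sum(len(v) for v in seqs.values())
        assert cm.A.sum() == cm.B.sum() == cm.L.sum() == total
        assert np.all(np.triu(cm.t, k=1) == 0)


class TestSolver:
    def test_exact_lattice_counts_recover_binomials(self):
        # counts exactly proportional to the hypergeometric canonical law
        model = L.LatticeModel(3, 5, N_max=6)
        t = np.zeros((7, 7))
        for N in range(1, 7):
            t[N, : N + 1] = 1e6 * L.exact_canonical_distribution(model, N)
        cm = G.CountMatrix(t)
        pf = G.solve_partition_functions(cm, tol=1e-13)
        corr_A, corr_B = gauge_corrected_ratios(
            pf, L.exact_omega(model, "A"), L.exact_omega(model, "B")
        )
        np.testing.assert_allclose(corr_A, 1.0, rtol=1e-6)
        np.testing.assert_allclose(corr_B, 1.0, rtol=1e-6)

    def test_single_trajectory_equal_odds(self):
        pf = G.solve_partition_functions(G.build_count_matrix({1: [0, 1, 0, 1]}))
        assert pf.omega_A[1] / pf.omega_B[1] == pytest.approx(1.0, rel=1e-8)

    def test_zero_support_entry_stays_zero(self, entropic_lattice):
        occ = L.sample_occupancy_sequences(entropic_lattice, 2000, seed=5)
        occ = {N: ks[ks != 3] for N, ks in occ.items()}  # remove all k=3 frames
        cm = G.build_count_matrix(occ)
        assert cm.A[3] == 0
        pf = G.solve_partition_functions(cm)
        assert pf.omega_A[3] == 0.0
        assert pf.converged

    def test_all_zero_counts_rejected(self):
        with pytest.raises(GCProbeError):
            G.solve_partition_functions(G.CountMatrix(np.zeros((3, 3))))

    def test_non_convergence_is_flagged(self, lattice_counts):
        pf = G.solve_partition_functions(lattice_counts, tol=1e-14, max_iter=2)
        assert not pf.converged
        with pytest.raises(G.NotConvergedError):
            G.solve_partition_functions(
                lattice_counts, tol=1e-14, max_iter=2, raise_on_failure=True
            )

    def test_likelihood_nondecreasing_each_sweep(self, lattice_counts):
        hist = []
        G.solve_partition_functions(lattice_counts, likelihood_history=hist)
        diffs = np.diff(hist)
        assert np.all(diffs >= -1e-8)

    def test_missing_trajectory_changes_ratios_within_noise(self, entropic_lattice):
        occ = L.sample_occupancy_sequences(entropic_lattice, 50_000, seed=21)
        full = G.solve_partition_functions(G.build_count_matrix(occ))
        occ[3] = np.array([], dtype=int)
        part = G.solve_partition_functions(G.build_count_matrix(occ))
        exact_A = L.exact_omega(entropic_lattice, "A")
        exact_B = L.exact_omega(entropic_lattice, "B")
        for pf in (full, part):
            corr_A, corr_B = gauge_corrected_ratios(pf, exact_A, exact_B)
            np.testing.assert_allclose(corr_A, 1.0, atol=0.05)
            np.testing.assert_allclose(corr_B, 1.0, atol=0.05)


class TestLogLikelihood:
    def test_matches_entropy_for_self_consistent_counts(self):
        model = L.LatticeModel(2, 3, N_max=4)
        t = np.zeros((5, 5))
        L_N = [0, 100, 200, 300, 400]
        for N in range(1, 5):
            t[N, : N + 1] = L_N[N] * L.exact_canonical_distribution(model, N)
        cm = G.CountMatrix(t)
        size = 5
        oa = np.zeros(size)
        ob = np.zeros(size)
        oa[:3] = L.exact_omega(model, "A")
        ob[:4] = L.exact_omega(model, "B")
        pf = PartitionFunctions(oa, ob)
        from scipy.special import xlogy

        expected = 0.0
        for N in range(1, 5):
            p = L.exact_canonical_distribution(model, N)
            expected += L_N[N] * np.sum(xlogy(p, p))
        assert G.log_likelihood(cm, pf) == pytest.approx(expected, rel=1e-12)

    def test_gauge_invariance(self, lattice_counts, lattice_pf):
        base = G.log_likelihood(lattice_counts, lattice_pf)
        shifted = G.log_likelihood(lattice_counts, lattice_pf.rescaled(3.7))
        assert abs(shifted - base) / abs(base) < 1e-12

    def test_single_frame_closed_form(self):
        cm = G.build_count_matrix({1: [1]})
        pf = PartitionFunctions(np.array([1.0, 1.0]), np.array([1.0, 1.0]))
        assert G.log_likelihood(cm, pf) == pytest.approx(-np.log(2))

    def test_data_outside_support_rejected(self):
        cm = G.build_count_matrix({1: [0, 1]})
        pf = PartitionFunctions(np.array([1.0, 0.0]), np.array([1.0, 1.0]))
        with pytest.raises(GCProbeError, match="support"):
            G.log_likelihood(cm, pf)


class TestGCDistribution:
    def test_entropic_binomial_at_zero_mu(self):
        pf = PartitionFunctions(np.array([1.0, 2.0, 1.0]), np.array([1.0, 2.0, 1.0]))
        gce = G.gc_distribution(pf, 0.0)
        np.testing.assert_allclose(gce.P_A, [0.25, 0.5, 0.25], atol=1e-14)

    def test_low_mu_limit_concentrates_on_zero(self, lattice_pf):
        gce = G.gc_distribution(lattice_pf, -200.0)
        assert gce.P_A[0] == pytest.approx(1.0, abs=1e-12)
        assert gce.P_B[0] == pytest.approx(1.0, abs=1e-12)

    def test_two_term_normalization(self):
        pf = PartitionFunctions(np.array([1.0, 1.0]), np.array([1.0, 1.0]))
        gce = G.gc_distribution(pf, np.log(3.0))
        np.testing.assert_allclose(gce.P_A, [0.25, 0.75], atol=1e-14)

    def test_overflow_safe_at_extreme_mu(self, lattice_pf):
        for bm in (-2000.0, 2000.0):
            gce = G.gc_distribution(lattice_pf, bm)
            assert np.all(np.isfinite(gce.P_A))
            assert gce.P_A.sum() == pytest.approx(1.0, abs=1e-12)

    def test_distributions_normalized(self, lattice_pf):
        gce = G.gc_distribution(lattice_pf, 0.73)
        assert gce.P_A.sum() == pytest.approx(1.0, abs=1e-12)
        assert gce.P_B.sum() == pytest.approx(1.0, abs=1e-12)


class TestMeanOccupancy:
    def test_exclusion_lattice_closed_form(self):
        # Omega_B(k) = C(4, k), z = 3 -> mean 4z/(1+z) = 3
        ob = np.array([1.0, 4.0, 6.0, 4.0, 1.0])
        pf = PartitionFunctions(np.ones(5), ob)
        _, mean_B = G.mean_occupancy(G.gc_distribution(pf, np.log(3.0)))
        assert mean_B == pytest.approx(3.0, rel=1e-12)

    def test_concentrated_distribution(self, lattice_pf):
        gce = G.gc_distribution(lattice_pf, -300.0)
        mean_A, mean_B = G.mean_occupancy(gce)
        assert mean_A == pytest.approx(0.0, abs=1e-10)

    def test_strictly_increasing_in_mu(self, lattice_pf):
        mus = np.linspace(-4, 4, 15)
        means = [G.mean_occupancy(G.gc_distribution(lattice_pf, m))[1] for m in mus]
        assert np.all(np.diff(means) > 0)


class TestMuCalibration:
    def test_half_filled_buffer_is_zero_mu(self):
        # entropic lattice: mean_B = S_B/2 iff z = 1
        ob = np.array([1.0, 5.0, 10.0, 10.0, 5.0, 1.0])
        pf = PartitionFunctions(np.ones(6), ob)
        V_B = 10.0
        target_conc = 2.5 * G.PARTICLE_PER_NM3_IN_MOLAR / V_B
        bm = G.mu_from_concentration(pf, BufferSpec(V_B, target_conc))
        assert bm == pytest.approx(0.0, abs=1e-9)

    def test_round_trip_consistency(self, lattice_pf):
        V_B = 8.0
        for conc in np.geomspace(1e-3, 0.5, 6):
            buf = BufferSpec(V_B, conc)
            bm = G.mu_from_concentration(lattice_pf, buf)
            _, mean_B = G.mean_occupancy(G.gc_distribution(lattice_pf, bm))
            assert mean_B == pytest.approx(buf.target_occupancy, rel=1e-8)

    def test_above_ceiling_names_the_ceiling(self, lattice_pf):
        V_B = 8.0
        ceiling = G.concentration_ceiling(lattice_pf, V_B)
        with pytest.raises(ConcentrationCeilingError) as err:
            G.mu_from_concentration(lattice_pf, BufferSpec(V_B, ceiling * 2))
        assert f"{ceiling:g}" in str(err.value)


class TestFrameWeights:
    def test_uniform_when_all_frames_share_k(self):
        occ = {2: [1, 1, 1, 1]}
        cm = G.build_count_matrix(occ)
        pf = PartitionFunctions(np.ones(3), np.ones(3))
        w = G.frame_weights(pf, 0.3, cm, occ)
        np.testing.assert_allclose(w["weight"], 0.25, atol=1e-15)

    def test_weighted_histogram_identity(self, lattice_pf, lattice_counts,
                                         lattice_occupancies):
        bm = 0.4
        w = G.frame_weights(lattice_pf, bm, lattice_counts, lattice_occupancies)
        hist = np.bincount(
            w["k_A"], weights=w["weight"], minlength=lattice_pf.N_max + 1
        )
        np.testing.assert_allclose(
            hist, G.gc_distribution(lattice_pf, bm).P_A, atol=1e-12
        )
        assert w["weight"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_three_frame_case(self):
        occ = {1: [0, 0, 1]}
        cm = G.build_count_matrix(occ)
        pf = PartitionFunctions(np.array([1.0, 1.0]), np.array([1.0, 1.0]))
        w = G.frame_weights(pf, 0.0, cm, occ)
        np.testing.assert_allclose(w["weight"], [0.25, 0.25, 0.5], atol=1e-14)

    def test_unseen_occupancy_rejected(self):
        cm = G.build_count_matrix({2: [0, 2]})
        pf = G.solve_partition_functions(G.build_count_matrix({2: [0, 1, 2]}))
        with pytest.raises(GCProbeError, match="never seen"):
            G.frame_weights(pf, 0.0, cm, {2: [0, 1, 2]})


class TestGCAverage:
    def test_constant_observable(self, lattice_pf, lattice_counts, lattice_occupancies):
        w = G.frame_weights(lattice_pf, 0.1, lattice_counts, lattice_occupancies)
        n = len(w)
        assert G.gc_average(w, np.full(n, 3.25)) == pytest.approx(3.25)

    def test_indicator_recovers_gc_mass(self, lattice_pf, lattice_counts,
                                        lattice_occupancies):
        bm = -0.2
        w = G.frame_weights(lattice_pf, bm, lattice_counts, lattice_occupancies)
        ind = (w["k_A"] == 2).to_numpy(dtype=float)
        assert G.gc_average(w, ind) == pytest.approx(
            G.gc_distribution(lattice_pf, bm).P_A[2], abs=1e-12
        )

    def test_length_mismatch_rejected(self, lattice_pf, lattice_counts,
                                      lattice_occupancies):
        w = G.frame_weights(lattice_pf, 0.0, lattice_counts, lattice_occupancies)
        with pytest.raises(GCProbeError):
            G.gc_average(w, [1.0, 2.0])


class TestGaugeInvariance:
    def test_observables_invariant_under_lambda_rescaling(
        self, lattice_pf, lattice_counts, lattice_occupancies
    ):
        """lambda^k rescaling + mu re-calibration leaves observables unchanged."""
        V_B = 8.0
        obs = (np.concatenate(
            [np.asarray(lattice_occupancies[N]) for N in sorted(lattice_occupancies)]
        ) >= 2).astype(float)
        for lam in (0.2, 1.0, 5.0):
            pf2 = lattice_pf.rescaled(lam)
            for conc in (0.05, 0.2):
                vals = []
                for pf in (lattice_pf, pf2):
                    bm = G.mu_from_concentration(pf, BufferSpec(V_B, conc))
                    w = G.frame_weights(pf, bm, lattice_counts, lattice_occupancies)
                    vals.append(G.gc_average(w, obs))
                assert abs(vals[0] - vals[1]) < 1e-10
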