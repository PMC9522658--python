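"""SVD decomposition: linear-algebra identities, autocorrelation, rank
selection, reconstruction and component readouts, including parameter
recovery and perturbation detection on simulated waveforms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import linalg as sla

from lysoscan.decompose import (compartment_energies, component_readouts,
                                decompose, lag1_autocorrelation,
                                match_components, reconstruct, select_rank)
from lysoscan.scenarios import e64_inhibited, healthy_s1, separable_scenario
from lysoscan.simulate import (compartment_spatial_profiles, ideal_waveform,
                               simulate_waveform)


class TestDecompose:
    def test_diagonal_matrix_singular_values(self):
        r = decompose(np.diag([3.0, 2.0]))
        assert np.allclose(r.S, [3.0, 2.0])

    def test_rank_one_matrix(self):
        r = decompose(np.ones((2, 2)))
        assert np.allclose(r.S, [2.0, 0.0], atol=1e-12)

    def test_singular_values_match_eigensolver_oracle(self, rng):
        # sqrt of eigenvalues of A^T A from an independent eigensolver
        for m in range(2, 11):
            for n in range(2, 11):
                A = rng.normal(size=(m, n))
                r = decompose(A)
                ev = np.sort(sla.eigh(A.T @ A, eigvals_only=True))[::-1]
                expect = np.sqrt(np.clip(ev[: min(m, n)], 0, None))
                assert np.allclose(r.S, expect, atol=1e-10)

    def test_orthonormality_and_reconstruction_identity(self, rng):
        A = rng.normal(size=(6, 5))
        r = decompose(A)
        assert np.allclose(r.U.T @ r.U, np.eye(6), atol=1e-8)
        assert np.allclose(r.V.T @ r.V, np.eye(5), atol=1e-8)
        full = reconstruct(r, min(A.shape))
        assert np.linalg.norm(full - A) <= 1e-8 * np.linalg.norm(A)

    def test_sign_convention_dominant_element_positive(self, rng):
        A = rng.normal(size=(8, 6))
        r = decompose(A)
        for i in range(r.S.size):
            j = np.argmax(np.abs(r.U[:, i]))
            assert r.U[j, i] > 0

    def test_nonfinite_entries_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            decompose(np.array([[1.0, np.nan], [0.0, 1.0]]))


class TestLag1Autocorrelation:
    def test_linear_ramp_hand_value(self):
        # centered biased estimator on [1..5]: 4/10
        assert lag1_autocorrelation([1, 2, 3, 4, 5]) == pytest.approx(0.4)

    @given(a=st.floats(-50, 50).filter(lambda a: abs(a) > 1e-3),
           b=st.floats(-50, 50))
    @settings(deadline=None, derandomize=True)
    def test_affine_invariance(self, a, b):
        x = np.array([0.3, 1.7, 0.2, 2.2, 1.1, 0.5, 3.0])
        assert lag1_autocorrelation(a * x + b) == pytest.approx(
            lag1_autocorrelation(x), rel=1e-9, abs=1e-9)

    def test_white_noise_scores_near_zero(self):
        x = np.random.default_rng(77).normal(size=10_000)
        assert abs(lag1_autocorrelation(x)) < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            lag1_autocorrelation(np.ones(10))


class TestSelectRank:
    def test_noiseless_single_compartment_rank_one(self):
        r = decompose(ideal_waveform(separable_scenario(1)))
        assert select_rank(r) == 1

    def test_pure_noise_rank_zero(self):
        noise = np.random.default_rng(42).normal(size=(100, 60))
        r = decompose(noise)
        assert select_rank(r) == 0

    def test_healthy_scenario_selects_three_components(self, healthy_result):
        assert healthy_result.selected_rank == 3

    def test_diagnostics_table_complete(self, healthy_result):
        d = healthy_result.diagnostics
        assert list(d["component"]) == list(range(len(d)))
        assert d["retained"].sum() == 3
        assert (d["singular_value"].diff().dropna() <= 1e-9).all()

    @pytest.mark.parametrize("rank", [1, 2, 3, 4])
    def test_recovers_generating_rank_noiseless(self, rank):
        r = decompose(ideal_waveform(separable_scenario(rank)))
        assert select_rank(r) == rank


class TestReconstruct:
    def test_full_rank_recovers_input(self, healthy_result):
        A = healthy_result.matrix
        full = reconstruct(healthy_result, min(A.shape))
        assert np.linalg.norm(full - A) <= 1e-8 * np.linalg.norm(A)

    def test_rank_zero_is_zero_matrix(self, healthy_result):
        assert np.all(reconstruct(healthy_result, 0) == 0)

    def test_eckart_young_tail_error(self, rng):
        A = rng.normal(size=(8, 6))
        r = decompose(A)
        err = np.linalg.norm(reconstruct(r, 2) - A)
        assert err == pytest.approx(np.sqrt(np.sum(r.S[2:] ** 2)), rel=1e-8)

    def test_out_of_range_rank_rejected(self, healthy_result):
        with pytest.raises(ValueError, match="out of range"):
            reconstruct(healthy_result, 99)


class TestComponentReadouts:
    def test_rank_one_outer_product_reproduces_matrix(self):
        A = ideal_waveform(separable_scenario(1))
        r = decompose(A)
        select_rank(r)
        (ro,) = component_readouts(r)
        assert np.allclose(np.outer(ro.spatial_shape, ro.kinetic_amplitude), A,
                           atol=1e-10 * A.max())

    def test_readout_sum_equals_truncated_reconstruction(self, healthy_result):
        total = sum(np.outer(ro.spatial_shape, ro.kinetic_amplitude)
                    for ro in component_readouts(healthy_result))
        assert np.allclose(total,
                           reconstruct(healthy_result,
                                       healthy_result.selected_rank),
                           atol=1e-10)

    def test_time_permutation_equivariance(self, rng):
        A = rng.uniform(0.0, 1.0, size=(12, 9)) + np.outer(
            np.linspace(0, 2, 12), np.linspace(1, 3, 9))
        perm = rng.permutation(9)
        ra, rp = decompose(A), decompose(A[:, perm])
        k = 3
        for i in range(k):
            assert np.allclose(rp.U[:, i], ra.U[:, i], atol=1e-8)
            assert np.allclose(rp.S[i] * rp.V[:, i],
                               (ra.S[i] * ra.V[:, i])[perm], atol=1e-8)

    def test_empty_readout_when_nothing_retained(self):
        r = decompose(np.random.default_rng(0).normal(size=(30, 20)))
        select_rank(r)
        assert r.selected_rank == 0
        assert component_readouts(r) == []


class TestParameterRecovery:
    @pytest.mark.parametrize("rank", [1, 2, 3, 4])
    def test_spatial_shapes_match_generating_profiles(self, rank):
        scen = separable_scenario(rank)
        r = decompose(ideal_waveform(scen))
        select_rank(r)
        refs = compartment_spatial_profiles(scen)
        matches = match_components(r, refs)
        assert len(matches) == rank
        assert min(c for _, c in matches.values()) >= 0.9

    def test_inhibitor_abolishes_lysosome_component(self):
        refs = compartment_spatial_profiles(healthy_s1())
        rc = decompose(simulate_waveform(healthy_s1(seed=3)))
        select_rank(rc)
        re_ = decompose(simulate_waveform(e64_inhibited(seed=3)))
        select_rank(re_)
        e_ctrl = compartment_energies(rc, refs)["LYS"]
        e_inhib = compartment_energies(re_, refs)["LYS"]
        assert e_inhib < 0.1 * e_ctrl

    def test_retained_shapes_stable_across_seeds(self):
        results = []
        for seed in (101, 202, 303):
            r = decompose(simulate_waveform(healthy_s1(seed)))
            select_rank(r)
            results.append(r)
        ks = {r.selected_rank for r in results}
        assert ks == {3}
        for a, b in ((0, 1), (0, 2), (1, 2)):
            ra, rb = results[a], results[b]
            refs = {f"c{i}": rb.U[:, i] for i in range(rb.selected_rank)}
            matches = match_components(ra, refs)
            assert len(matches) == 3
            assert min(c for _, c in matches.values()) >= 0.8
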