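"""The MICA transform: reconstruction contract, projection, threshold choice."""

import json

import numpy as np
import pytest

import micasel as mcs
from micasel.exceptions import AlignmentError, ConvergenceError
from micasel.mica import (condition_number, ica_decompose, model_from_dict,
                          model_to_dict, resolve_optimal_tau)


class TestConditionNumber:
    def test_identity_is_one(self):
        assert condition_number(np.eye(3)) == pytest.approx(1.0)

    def test_diagonal_ratio(self):
        assert condition_number(np.diag([4.0, 2.0])) == pytest.approx(2.0)

    def test_matches_svd_oracle(self, rng):
        Z = rng.normal(size=(3, 10))
        s = np.linalg.svd(Z, compute_uv=False)  # independent recomputation
        assert condition_number(Z) == pytest.approx(s[0] / s[-1], abs=1e-9)

    def test_rank_deficient_returns_inf(self):
        Z = np.array([[1.0, 2.0], [2.0, 4.0]])  # exactly rank 1
        assert condition_number(Z) == np.inf


class TestFitContract:
    def test_tau_zero_meta_profile_is_identity(self, small_profile):
        _, meta = mcs.fit_mica(small_profile, level=4, tau=0, seed=1)
        assert np.abs(meta.values - small_profile.values).max() < 1e-8

    def test_nonconvergence_policy_raise(self, rng):
        """Pure Gaussian noise gives the ICA fixed point nothing to find;
        the strict policy reports that as a convergence error."""
        prof = mcs.ExpressionProfile(rng.normal(size=(12, 256)),
                                     [f"s{i}" for i in range(12)],
                                     [f"g{j}" for j in range(256)])
        with pytest.raises(ConvergenceError) as exc:
            mcs.fit_mica(prof, level=4, tau=0, seed=0, ica_restarts=2,
                         on_nonconvergence="raise")
        assert exc.value.n_iter == 400
        # default policy completes with the final rotation instead
        model, _ = mcs.fit_mica(prof, level=4, tau=0, seed=0, ica_restarts=2)
        assert model.k == 11

    def test_reconstruction_contract(self, fitted):
        model, meta = fitted
        err = np.linalg.norm(meta.values - model.offset - model.A @ model.Z)
        assert err / np.linalg.norm(meta.values) < 1e-6

    def test_delta_rederivable_from_Z(self, fitted):
        model, _ = fitted
        assert model.delta == pytest.approx(condition_number(model.Z), rel=1e-8)

    def test_component_sign_canonical(self, fitted):
        model, _ = fitted
        for row in model.Z:
            assert row[np.argmax(np.abs(row))] > 0

    def test_determinism_and_serialization_bytes(self, small_profile, fitted):
        model, _ = fitted
        again, _ = mcs.fit_mica(small_profile, level=4, tau=3, seed=1)
        b1 = json.dumps(model_to_dict(model), sort_keys=True).encode()
        b2 = json.dumps(model_to_dict(again), sort_keys=True).encode()
        assert b1 == b2

    def test_serialization_round_trip(self, fitted, tmp_path):
        model, _ = fitted
        path = tmp_path / "model.json"
        mcs.save_model(model, path)
        back = mcs.load_model(path)
        np.testing.assert_array_equal(back.Z, model.Z)
        np.testing.assert_array_equal(back.A, model.A)
        assert back.gene_ids == model.gene_ids

    def test_k_auto_is_rank_after_centering(self, small_profile, fitted):
        model, _ = fitted
        assert model.k == small_profile.n_samples - 1

    def test_too_few_samples_rejected(self, rng):
        prof = mcs.ExpressionProfile(rng.normal(size=(2, 128)),
                                     ["a", "b"], [f"g{i}" for i in range(128)])
        with pytest.raises(ValueError, match="3 samples"):
            mcs.fit_mica(prof, level=3)

    def test_sign_flip_before_canonicalization_is_invisible(self, rng):
        """Negating sources at the whitening stage cannot change the model."""
        # structured (non-Gaussian) sources so the fixed point has a target
        S = rng.laplace(size=(8, 200))
        M = rng.normal(size=(8, 8))
        X = M @ S
        offset, A, Z, _ = ica_decompose(X, "auto", seed=5)
        offset2, A2, Z2, _ = ica_decompose(X * 1.0, "auto", seed=5)
        np.testing.assert_array_equal(Z, Z2)
        # manual flip of a (row, column) pair then re-canonicalization
        Zf, Af = Z.copy(), A.copy()
        Zf[0], Af[:, 0] = -Zf[0], -Af[:, 0]
        i = np.argmax(np.abs(Zf[0]))
        if Zf[0, i] < 0:
            Zf[0], Af[:, 0] = -Zf[0], -Af[:, 0]
        np.testing.assert_allclose(Zf, Z, atol=1e-12)
        np.testing.assert_allclose(Af, A, atol=1e-12)


class TestMetaSamplesAndProjection:
    def test_meta_samples_shape_and_determinism(self, small_profile, fitted):
        model, _ = fitted
        A = mcs.meta_samples(model)
        assert A.shape == (small_profile.n_samples, model.k)
        np.testing.assert_array_equal(A, mcs.meta_samples(model))

    def test_meta_samples_match_normal_equations_oracle(self, fitted):
        model, meta = fitted
        centered = meta.values - model.offset
        # independently coded normal-equations solve
        oracle = centered @ model.Z.T @ np.linalg.inv(model.Z @ model.Z.T)
        assert np.abs(oracle - model.A).max() < 1e-5

    def test_projecting_training_profile_recovers_A(self, small_profile, fitted):
        model, _ = fitted
        P = mcs.project_samples(model, small_profile)
        assert np.abs(P - model.A).max() < 1e-5

    def test_orthonormal_Z_projection_is_inner_product(self, rng):
        model, _ = mcs.fit_mica(mcs.generate_two_class_profile(
            mcs.SyntheticSpec(p_per_class=5, n=128, seed=8)), level=3, tau=2,
            seed=2)
        Q, _ = np.linalg.qr(model.Z.T)
        model.Z = Q.T  # orthonormal rows
        x = rng.normal(size=(1, 128))
        prof = mcs.ExpressionProfile(x, ["new"], model.gene_ids)
        a = mcs.project_samples(model, prof)
        meta_x = mcs.mica.transform_meta_values(model, x)
        expected = (meta_x - model.offset) @ model.Z.T
        np.testing.assert_allclose(a, expected, atol=1e-8)

    def test_gene_mismatch_raises(self, fitted, rng):
        model, _ = fitted
        prof = mcs.ExpressionProfile(rng.normal(size=(1, len(model.gene_ids))),
                                     ["x"], ["wrong_" + g for g in model.gene_ids])
        with pytest.raises(AlignmentError):
            mcs.project_samples(model, prof)


class TestThresholdSelection:
    def test_unique_argmin(self):
        assert resolve_optimal_tau({2: 5.0, 3: 3.0, 4: 9.0}) == 3

    def test_tie_prefers_lowest_threshold_above_one(self):
        deltas = {t: 9.0 for t in range(1, 6)}
        deltas.update({t: 2.0 for t in range(6, 12)})
        deltas[1] = 5.0
        assert resolve_optimal_tau(deltas) == 6

    def test_tie_at_one_only_falls_back(self):
        assert resolve_optimal_tau({1: 2.0, 2: 9.0}) == 1

    def test_selection_matches_exhaustive_oracle(self, small_profile):
        candidates = [1, 2, 3]
        tau_star, deltas = mcs.select_level_threshold(
            small_profile, candidates, level=4, seed=7)
        # external loop re-fitting each candidate independently
        oracle = {t: mcs.fit_mica(small_profile, level=4, tau=t, seed=7)[0].delta
                  for t in candidates}
        assert deltas == pytest.approx(oracle)
        assert tau_star == min(oracle, key=lambda t: (oracle[t], t))
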