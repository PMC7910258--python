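"""Greedy compression: dominance tests, certificates, safety, baked export."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from voptx import (
    CompressionConfig,
    OverestimationModel,
    SARMatrixSet,
    bake_vops,
    bound_many,
    build_model,
    compress,
    dominance_test,
    precompute_vops,
    quadratic_form,
    random_unit_power_vectors,
    verify_certificates,
    worst_case_sar,
)
from voptx.evaluate import actual_max_sar
from conftest import random_psd_stack


def zero_model(n):
    return OverestimationModel("diag", 0.0, Z=np.zeros((n, n), complex))


class TestCompressStructure:
    def test_scaled_copies_collapse_to_one_vop(self):
        """(1 - alpha) S is PSD, so c = 1 on the top copy certifies all."""
        rng = np.random.default_rng(0)
        S = random_psd_stack(rng, 1, 4)[0]
        alphas = rng.uniform(0.05, 1.0, size=30)
        alphas[3] = 1.0
        mats = np.stack([a * S for a in alphas])
        s = SARMatrixSet(mats, global_matrix=S)
        with pytest.warns(UserWarning, match="epsilon_g = 0"):
            res = compress(s, zero_model(4), CompressionConfig(seed=0))
        assert res.n_vops == 1
        assert res.vop_indices[0] == 3

    def test_orthogonal_diagonals_both_kept(self):
        mats = np.stack([np.diag([1.0, 0.0]), np.diag([0.0, 1.0])]).astype(complex)
        s = SARMatrixSet(mats)
        with pytest.warns(UserWarning, match="epsilon_g = 0"):
            res = compress(s, zero_model(2), CompressionConfig(seed=0))
        assert res.n_vops == 2

    def test_first_voxel_is_largest_eigenvalue(self, small_set):
        model = build_model(small_set, "global", 0.1)
        res = compress(small_set, model, CompressionConfig(seed=0))
        lam = small_set.lambda_max()
        assert res.vop_positions[0] == int(np.argmax(lam))

    @pytest.mark.parametrize("rule", ["paper_random", "greedy_argmax"])
    def test_certificates_and_probes_confirm_discards(self, small_set, rule):
        """Every discarded voxel is PSD-certified and never beats the bound
        on random probes; every VOP is a member of the input set."""
        model = build_model(small_set, "global", 0.05)
        cfg = CompressionConfig(seed=1, coef_update_rule=rule, store_certificates=True)
        res = compress(small_set, model, cfg)
        assert 0 < res.n_vops < small_set.n_voxels
        assert set(res.vop_indices) <= set(small_set.voxel_ids.tolist())
        n_checked = verify_certificates(small_set, res)
        assert n_checked == small_set.n_voxels - res.n_vops

        vecs = random_unit_power_vectors(20_000, 4, seed=2)
        actual, _ = actual_max_sar(small_set, vecs)
        bound = bound_many(res, vecs)
        assert (bound >= actual * (1 - 1e-9)).all()

    def test_witness_pool_does_not_change_outcome(self, small_set):
        """The pooled pre-screen only skips work; decisions are identical."""
        model = build_model(small_set, "global", 0.05)
        base = CompressionConfig(seed=3, store_certificates=True)
        pooled = compress(small_set, model, base)
        unpooled = compress(
            small_set, model, dataclasses.replace(base, use_witness_pool=False)
        )
        assert np.array_equal(pooled.vop_indices, unpooled.vop_indices)
        assert set(pooled.certificates) == set(unpooled.certificates)

    def test_monotone_vop_count_in_epsilon(self, phantom_4ch):
        """Median VOP count over seeds is nonincreasing in epsilon_G."""
        counts = []
        for eps in [0.02, 0.1, 0.4]:
            per_seed = []
            for seed in range(3):
                model = build_model(phantom_4ch, "global", eps)
                cfg = CompressionConfig(seed=seed, coef_update_rule="greedy_argmax")
                res = compress(phantom_4ch, model, cfg)
                per_seed.append(res.n_vops)
            counts.append(np.median(per_seed))
        assert counts[0] >= counts[1] >= counts[2]

    def test_absolute_overestimation_bounded_by_eps_lambda_z(self, phantom_4ch):
        """baked bound - actual <= eps_G * lambda_max(Z) at unit power."""
        model = build_model(phantom_4ch, "diag", 0.1)
        cfg = CompressionConfig(seed=0, coef_update_rule="greedy_argmax")
        res = compress(phantom_4ch, model, cfg)
        vecs = random_unit_power_vectors(5000, 4, seed=4)
        actual, _ = actual_max_sar(phantom_4ch, vecs)
        bound = bound_many(res, vecs)
        cap = 0.1 * np.linalg.eigvalsh(model.Z)[-1]
        assert ((bound - actual) <= cap * (1 + 1e-9)).all()


class TestDominanceTest:
    def test_vop_member_bounded_by_one_hot(self):
        rng = np.random.default_rng(5)
        vops = random_psd_stack(rng, 3, 4)
        model = build_model(
            SARMatrixSet(vops), "global", 0.01
        )
        out = dominance_test(
            vops[1], vops, model, CompressionConfig(seed=0), np.random.default_rng(0)
        )
        assert out.status == "bounded"
        # the certificate concentrates on the duplicate member
        assert out.state.c_vop[1] > 0.9

    def test_dominant_eigenvalue_forces_unbounded(self):
        """lambda_max(S_v) above every bound ingredient admits no
        certificate; the top eigenvector witnesses the violation."""
        rng = np.random.default_rng(6)
        vops = random_psd_stack(rng, 4, 3)
        Z = random_psd_stack(rng, 1, 3)[0]
        model = OverestimationModel("global", 0.1, Z=Z)
        scale = 5 * (
            max(np.linalg.eigvalsh(m)[-1] for m in vops)
            + 0.1 * np.linalg.eigvalsh(Z)[-1]
        )
        S_v = scale * np.eye(3, dtype=complex)
        out = dominance_test(
            S_v, vops, model, CompressionConfig(seed=0), np.random.default_rng(0)
        )
        assert out.status == "unbounded"
        b = out.witness
        bound = max(quadratic_form(b, m) for m in vops) + model.term(b)
        assert quadratic_form(b, S_v) > bound

    def test_zero_iteration_cap_gives_inconclusive(self):
        rng = np.random.default_rng(7)
        vops = random_psd_stack(rng, 6, 4)
        # candidate inside the convex hull reach but not below the initial
        # equal-coefficient mixture: average of two members slightly shrunk
        S_v = 0.9 * (0.5 * vops[0] + 0.5 * vops[1])
        model = zero_model(4)
        cfg = CompressionConfig(seed=0, max_coef_iterations=0)
        out = dominance_test(S_v, vops, model, cfg, np.random.default_rng(0))
        assert out.status in ("bounded", "inconclusive")
        if out.status == "inconclusive":
            assert out.iterations == 0

    def test_coefficients_stay_normalized(self, small_set):
        model = build_model(small_set, "global", 0.05)
        cfg = CompressionConfig(seed=2, store_certificates=True)
        res = compress(small_set, model, cfg)
        for cert in res.certificates.values():
            c = cert["c_vop"]
            assert (c >= 0).all()
            assert c.sum() == pytest.approx(1.0, abs=1e-12)


class TestDoubleVop:
    def test_precompute_single_vop_for_scaled_copies(self):
        rng = np.random.default_rng(8)
        S = random_psd_stack(rng, 1, 3)[0]
        mats = np.stack([a * S for a in rng.uniform(0.1, 1, 20)])
        mats[0] = S
        s = SARMatrixSet(mats, global_matrix=S)
        pre, eps, trace = precompute_vops(s, 0.05)
        assert len(pre) == 1

    def test_huge_epsilon_gives_one_prevop(self, small_set):
        pre, eps, _ = precompute_vops(small_set, 1000.0)
        assert len(pre) == 1

    def test_auto_tune_reaches_target_and_count_monotone(self, phantom_4ch):
        pre, eps_used, trace = precompute_vops(
            phantom_4ch, 0.05, target_count=10, auto_tune=True,
            config=CompressionConfig(coef_update_rule="greedy_argmax"),
        )
        assert len(pre) <= 10
        assert eps_used >= 0.05
        counts = [c for _, c in trace]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_double_compression_safe(self, phantom_4ch):
        fast = CompressionConfig(seed=0, coef_update_rule="greedy_argmax")
        model = build_model(phantom_4ch, "double", 0.3, seed=0, config=fast)
        res = compress(phantom_4ch, model, fast)
        vecs = random_unit_power_vectors(10_000, 4, seed=5)
        actual, _ = actual_max_sar(phantom_4ch, vecs)
        bound = bound_many(res, vecs)
        assert (bound >= actual * (1 - 1e-9)).all()


class TestBakeVops:
    def test_diag_baked_matches_unbaked(self, small_set):
        model = build_model(small_set, "diag", 0.2)
        res = compress(small_set, model, CompressionConfig(seed=0))
        (baked,) = bake_vops(res)
        d = worst_case_sar(small_set)
        assert np.allclose(
            baked, res.vop_matrices + 0.2 * d * np.eye(4), atol=1e-12 * d
        )
        vecs = random_unit_power_vectors(100, 4, seed=6)
        direct = np.array(
            [
                max(quadratic_form(b, S) for S in res.vop_matrices) + model.term(b)
                for b in vecs
            ]
        )
        assert np.allclose(bound_many(res, vecs), direct, rtol=1e-12)

    def test_double_baked_equals_two_level_bound(self, phantom_4ch):
        fast = CompressionConfig(seed=1, coef_update_rule="greedy_argmax")
        model = build_model(phantom_4ch, "double", 0.25, seed=1, config=fast)
        res = compress(phantom_4ch, model, fast)
        a, b_stack = bake_vops(res)
        vecs = random_unit_power_vectors(2000, 4, seed=7)
        direct = np.array(
            [
                max(quadratic_form(bb, S) for S in res.vop_matrices) + model.term(bb)
                for bb in vecs
            ]
        )
        assert np.allclose(bound_many(res, vecs), direct, rtol=1e-12)
        assert len(a) == res.n_vops and len(b_stack) == res.n_pre_vops

    def test_baked_invariant_to_chunking(self, small_set):
        model = build_model(small_set, "global", 0.1)
        res = compress(small_set, model, CompressionConfig(seed=0))
        vecs = random_unit_power_vectors(1000, 4, seed=8)
        full = bound_many(res, vecs)
        parts = np.concatenate([bound_many(res, vecs[:300]), bound_many(res, vecs[300:])])
        assert np.array_equal(full, parts)


def test_bounded_stays_bounded_as_subset_grows(small_set):
    """Certificates stored mid-run stay valid against the FINAL VOP set
    (new coefficients default to zero), so discarded voxels never need
    re-checking."""
    model = build_model(small_set, "global", 0.08)
    cfg = CompressionConfig(seed=9, store_certificates=True)
    res = compress(small_set, model, cfg)
    assert verify_certificates(small_set, res, against_final=True) > 0
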