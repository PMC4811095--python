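"""ADMM updates, the spectral (u, p) solve, and end-to-end reconstruction."""

import numpy as np
import pytest

from patchtgv import dictlearn, patches, sampling, tgv
from patchtgv.dictlearn import DLParams
from patchtgv.metrics import psnr, shepp_logan
from patchtgv.patches import PatchConfig
from patchtgv.sampling import KSpaceData, forward_measure, make_mask
from patchtgv.solver import (ADMMState, ReconstructionModel, SolverParams,
                             objective, solve_up, update_duals, update_y,
                             update_z, _up_rhs)

from conftest import random_complex


def random_state(rng, n, cfg, dict_size=None):
    state = ADMMState.initial(random_complex(rng, (n, n)))
    state.p = random_complex(rng, (2, n, n))
    state.y = random_complex(rng, (2, n, n))
    state.z = random_complex(rng, (3, n, n))
    state.y_dual = random_complex(rng, (2, n, n))
    state.z_dual = random_complex(rng, (3, n, n))
    M = cfg.patch_len
    J = dict_size or 2 * M
    state.A = dictlearn.init_dictionary(M, J)
    state.codes = random_complex(rng, (J, n * n))
    return state


def apply_normal_matrix(v, n, mask, params, beta, cfg):
    """The (u, p) normal-equation operator, assembled from the quadratic's
    gradient via the package's primitive operators (independent of the
    spectral path)."""
    a1m2 = params.alpha1 * params.mu2
    a0m3 = params.alpha0 * params.mu3
    M = cfg.patch_len
    u = v[: n * n].reshape(n, n)
    p1 = v[n * n: 2 * n * n].reshape(n, n)
    p2 = v[2 * n * n:].reshape(n, n)
    ktk = sampling.adjoint_measure(forward_measure(u, mask))
    d1u, d2u = tgv.grad(u)
    e = tgv.sym_grad(np.stack([p1, p2]))
    out_u = (params.lambda0 * M * u + beta * ktk
             + a1m2 * (tgv._d1t(d1u - p1) + tgv._d2t(d2u - p2)))
    out_p1 = (a1m2 * (p1 - d1u)
              + a0m3 * (tgv._d1t(e[0]) + tgv._d2t(e[2])))
    out_p2 = (a1m2 * (p2 - d2u)
              + a0m3 * (tgv._d2t(e[1]) + tgv._d1t(e[2])))
    return np.concatenate([out_u.ravel(), out_p1.ravel(), out_p2.ravel()])


class TestInnerUpdates:
    def setup_method(self):
        self.params = SolverParams(mu2=1.0, mu3=1.0)

    def test_y_zero_argument(self, rng):
        n = 8
        state = ADMMState.initial(random_complex(rng, (n, n)))
        state.p = tgv.grad(state.u)  # Du - p = 0, duals zero
        assert np.all(update_y(state, self.params) == 0)

    def test_y_single_pixel_prox(self):
        n = 4
        state = ADMMState.initial(np.zeros((n, n)))
        state.p = np.zeros((2, n, n), dtype=complex)
        state.y_dual = np.zeros((2, n, n), dtype=complex)
        state.y_dual[0, 1, 1], state.y_dual[1, 1, 1] = 3.0, 4.0
        out = update_y(state, self.params)
        assert np.allclose([out[0, 1, 1], out[1, 1, 1]], [2.4, 3.2])

    def test_y_large_mu_limit(self, rng):
        n = 6
        state = ADMMState.initial(random_complex(rng, (n, n)))
        state.p = random_complex(rng, (2, n, n))
        state.y_dual = random_complex(rng, (2, n, n))
        arg = tgv.grad(state.u) - state.p + state.y_dual
        out = update_y(state, SolverParams(mu2=1e8))
        assert np.abs(out - arg).max() < 1e-7

    def test_z_zero_argument(self, rng):
        state = ADMMState.initial(random_complex(rng, (8, 8)))
        assert np.all(update_z(state, self.params) == 0)

    def test_z_large_mu_limit(self, rng):
        state = ADMMState.initial(random_complex(rng, (6, 6)))
        state.p = random_complex(rng, (2, 6, 6))
        state.z_dual = random_complex(rng, (3, 6, 6))
        arg = tgv.sym_grad(state.p) + state.z_dual
        out = update_z(state, SolverParams(mu3=1e8))
        assert np.abs(out - arg).max() < 1e-7

    def test_duals_fixed_on_feasibility(self, rng):
        state = ADMMState.initial(random_complex(rng, (8, 8)))
        state.p = random_complex(rng, (2, 8, 8))
        state.y = tgv.grad(state.u) - state.p
        state.z = tgv.sym_grad(state.p)
        yd, zd = update_duals(state, self.params)
        assert np.allclose(yd, state.y_dual) and np.allclose(zd, state.z_dual)

    def test_duals_zero_step(self, rng):
        state = ADMMState.initial(random_complex(rng, (8, 8)))
        state.y = random_complex(rng, (2, 8, 8))
        yd, zd = update_duals(state, SolverParams(mu=0.0))
        assert np.all(yd == 0) and np.all(zd == 0)

    def test_duals_one_step_equals_residual(self, rng):
        state = ADMMState.initial(random_complex(rng, (8, 8)))
        state.p = random_complex(rng, (2, 8, 8))
        state.y = random_complex(rng, (2, 8, 8))
        state.z = random_complex(rng, (3, 8, 8))
        yd, zd = update_duals(state, SolverParams(mu=0.7))
        assert np.allclose(yd, 0.7 * (tgv.grad(state.u) - state.p - state.y))
        assert np.allclose(zd, 0.7 * (tgv.sym_grad(state.p) - state.z))


class TestSolveUP:
    def test_matches_dense_oracle(self, rng):
        n = 8
        cfg = PatchConfig(side=3)
        mask = make_mask("random2d", n, 2, seed=3)
        params = SolverParams(beta=2.0, lambda0=0.6, alpha1=0.4, alpha0=0.2,
                              mu2=1.3, mu3=0.8)
        state = random_state(rng, n, cfg)
        b = KSpaceData(random_complex(rng, mask.num_kept), mask)
        u, p = solve_up(state, b, params, cfg)
        x = np.concatenate([u.ravel(), p[0].ravel(), p[1].ravel()])
        rhs = np.concatenate([r.ravel() for r in
                              _up_rhs(state, b, params.beta, params, cfg)])
        N = 3 * n * n
        L = np.zeros((N, N), dtype=complex)
        for i in range(N):
            e = np.zeros(N, dtype=complex)
            e[i] = 1.0
            L[:, i] = apply_normal_matrix(e, n, mask, params, params.beta, cfg)
        dense = np.linalg.solve(L, rhs)
        assert np.linalg.norm(x - dense) <= 1e-8 * np.linalg.norm(dense)

    def test_data_term_dominance_full_sampling(self, rng):
        """With beta huge and full sampling, u returns the true image."""
        n = 16
        cfg = PatchConfig(side=4)
        mask = make_mask("full", n)
        u_true = random_complex(rng, (n, n))
        b = forward_measure(u_true, mask)
        params = SolverParams(beta=1e6, lambda0=1e-6, alpha1=1e-8,
                              alpha0=1e-8, mu2=1.0, mu3=1.0)
        state = random_state(rng, n, cfg)
        u, _ = solve_up(state, b, params, cfg)
        assert np.linalg.norm(u - u_true) <= 1e-3 * np.linalg.norm(u_true)

    def test_dl_only_no_sampling_closed_form(self, rng):
        """alpha = 0, beta ~ 0: u = R^T(A Gamma) / M and p = 0."""
        n = 8
        cfg = PatchConfig(side=3)
        mask = make_mask("full", n)
        state = random_state(rng, n, cfg)
        b = KSpaceData(np.zeros(mask.num_kept, dtype=complex), mask)
        params = SolverParams(beta=1e-12, lambda0=0.9, alpha1=0.0, alpha0=0.0)
        u, p = solve_up(state, b, params, cfg)
        expected = patches.aggregate_patches(state.A @ state.codes, n,
                                             cfg) / cfg.patch_len
        assert np.allclose(u, expected, atol=1e-8)
        assert np.all(p == 0)

    def test_tgv_only_runs(self, rng):
        """lambda0 = 0 keeps the 3x3 solve well posed (DC is sampled)."""
        n = 8
        cfg = PatchConfig(side=3)
        mask = make_mask("random2d", n, 2, seed=1)
        state = random_state(rng, n, cfg)
        state.A = state.codes = None
        b = KSpaceData(random_complex(rng, mask.num_kept), mask)
        params = SolverParams(beta=10.0, lambda0=0.0, alpha1=0.5, alpha0=0.25,
                              mu2=1.0, mu3=1.0)
        u, p = solve_up(state, b, params, cfg)
        x = np.concatenate([u.ravel(), p[0].ravel(), p[1].ravel()])
        rhs = np.concatenate([r.ravel() for r in
                              _up_rhs(state, b, params.beta, params, cfg)])
        res = apply_normal_matrix(x, n, mask, params, params.beta, cfg) - rhs
        assert np.linalg.norm(res) <= 1e-8 * np.linalg.norm(rhs)

    def test_both_weights_zero_raises(self, rng):
        n = 8
        cfg = PatchConfig(side=3)
        mask = make_mask("full", n)
        state = random_state(rng, n, cfg)
        b = KSpaceData(np.zeros(mask.num_kept, dtype=complex), mask)
        with pytest.raises(ValueError):
            solve_up(state, b, SolverParams(beta=1e-30, lambda0=0.0), cfg,
                     beta=0.0)

    def test_strided_patches_rejected(self, rng):
        n = 8
        cfg = PatchConfig(side=2, stride=2)
        mask = make_mask("full", n)
        state = random_state(rng, n, PatchConfig(side=2, stride=2))
        b = KSpaceData(np.zeros(mask.num_kept, dtype=complex), mask)
        with pytest.raises(ValueError):
            solve_up(state, b, SolverParams(), cfg)


class TestObjective:
    def test_zero_state_zero_objective(self):
        n = 8
        cfg = PatchConfig(side=3)
        mask = make_mask("full", n)
        state = ADMMState.initial(np.zeros((n, n)))
        state.A = dictlearn.init_dictionary(9, 18)
        state.codes = np.zeros((18, n * n), dtype=complex)
        b = KSpaceData(np.zeros(mask.num_kept, dtype=complex), mask)
        assert objective(state, b, SolverParams(beta=1.0), cfg) == 0.0

    def test_terms_are_additive(self, rng):
        n = 8
        cfg = PatchConfig(side=3)
        mask = make_mask("random2d", n, 2, seed=2)
        state = random_state(rng, n, cfg)
        b = KSpaceData(random_complex(rng, mask.num_kept), mask)
        params = SolverParams(beta=1.7, lambda0=0.9, alpha1=0.2, alpha0=0.1)
        total = objective(state, b, params, cfg)
        data = 0.5 * params.beta * np.linalg.norm(
            forward_measure(state.u, mask).values - b.values) ** 2
        fit = 0.5 * params.lambda0 * np.linalg.norm(
            state.A @ state.codes - patches.extract_patches(state.u, cfg)) ** 2
        reg = tgv.tgv2_penalty(state.u, state.p, params.alpha0, params.alpha1)
        assert np.isclose(total, data + fit + reg, rtol=1e-12)


class TestReconstruction:
    def test_full_sampling_machine_precision(self):
        """Noiseless full sampling recovers the phantom almost exactly."""
        u = shepp_logan(64)
        model = ReconstructionModel.from_image(
            u, scheme="full", factor=1, sigma=0,
            params=SolverParams(outer_iters=2, admm_iters=3),
            dl_params=DLParams(ksvd_iters=2))
        res = model.fit()
        assert res.psnr() >= 100.0

    def test_deterministic_given_seed(self):
        u = shepp_logan(32)
        kwargs = dict(scheme="radial", factor=2, sigma=1.0, seed=4,
                      params=SolverParams(outer_iters=2, admm_iters=2),
                      dl_params=DLParams(ksvd_iters=1))
        h1 = ReconstructionModel.from_image(u, **kwargs).fit().history
        h2 = ReconstructionModel.from_image(u, **kwargs).fit().history
        assert h1.equals(h2)

    def test_history_and_summary(self):
        u = shepp_logan(32)
        model = ReconstructionModel.from_image(
            u, scheme="radial", factor=2, sigma=0, seed=0,
            params=SolverParams(outer_iters=2, admm_iters=2),
            dl_params=DLParams(ksvd_iters=1))
        res = model.fit()
        assert len(res.history) == res.n_iterations
        assert {"objective", "data_residual", "primal_res_y",
                "primal_res_z", "psnr"} <= set(res.history.columns)
        text = res.summary()
        assert "PSNR" in text and "radial" in text

    def test_primal_residuals_shrink(self):
        """Both splitting constraints tighten by >= 2 orders of magnitude
        within 200 inner iterations on the n=64 phantom problem."""
        u = shepp_logan(64)
        model = ReconstructionModel.from_image(
            u, scheme="radial", factor=3, sigma=0, seed=0,
            params=SolverParams(lambda0=0.0, outer_iters=20, admm_iters=10,
                                tol=0.0))
        res = model.fit()
        h = res.history
        assert h["primal_res_y"].iloc[-1] < 1e-2 * h["primal_res_y"].iloc[0]
        assert h["primal_res_z"].iloc[-1] < 1e-2 * h["primal_res_z"].iloc[0]

    def test_data_consistency_with_large_beta(self):
        """Noiseless sampled k-space entries are reproduced when beta is
        large."""
        u = shepp_logan(64)
        model = ReconstructionModel.from_image(
            u, scheme="radial", factor=3, sigma=0, seed=0,
            params=SolverParams(outer_iters=2, admm_iters=3),
            dl_params=DLParams(ksvd_iters=1))
        res = model.fit()
        b = model.kspace
        ku = forward_measure(res.image, b.mask).values
        rel = np.linalg.norm(ku - b.values) / np.linalg.norm(b.values)
        assert rel < 1e-4
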