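"""Helmholtz decomposition: operators, exact Lorenz form, fitting."""

import numpy as np
import pytest

from nesskit.helmholtz import (
    HelmholtzParams,
    correction_term,
    default_sample_grid,
    detect_sign_symmetries,
    exact_lorenz_decomposition,
    fit_decomposition,
    fit_operator,
    flat_q_index,
    flow_operator,
    kernel_potential_eval,
    KernelPotential,
    model_flow,
    params_from_gaussian,
    q_by_flat_index,
    solve_solenoidal_linear,
)
from nesskit.polybasis import enumerate_monomials
from nesskit.systems import lorenz


def _zero_params(n, Gamma=None, q=None, h=None):
    basis = enumerate_monomials(n, 2)
    return HelmholtzParams(
        basis=basis,
        h=np.zeros(basis.size) if h is None else h,
        q=q or {},
        Gamma=np.ones(n) if Gamma is None else np.asarray(Gamma, float),
    )


class TestFlowOperator:
    def test_pure_gamma(self):
        p = _zero_params(3, Gamma=[1, 1, 1])
        np.testing.assert_allclose(flow_operator(p, np.array([2.0, -1.0, 5.0])), -np.eye(3))

    def test_skew_structure_random(self, rng):
        basis = enumerate_monomials(3, 2)
        q = {(i, j): rng.normal(size=basis.size) for i in range(3) for j in range(i, 3)}
        p = HelmholtzParams(basis=basis, h=np.zeros(basis.size), q=q, Gamma=rng.uniform(0.1, 1, 3))
        pts = rng.uniform(-4, 4, (20, 3))
        Om = flow_operator(p, pts)
        # Omega + Omega^T = 2 diag(x.q_ii - Gamma_i): the skew part cancels
        sym = Om + Om.transpose(0, 2, 1)
        offdiag = sym - np.eye(3) * sym.diagonal(axis1=1, axis2=2)[:, :, None].transpose(0, 2, 1) * 0
        for k in range(3):
            sym[:, k, k] = 0.0
        assert np.max(np.abs(sym)) < 1e-12

    def test_exact_lorenz_omega22_entry(self):
        p = exact_lorenz_decomposition(10.0, 32.0, 8.0 / 3.0)
        x3 = 7.0
        Om = flow_operator(p, np.array([0.0, 0.0, x3]))
        q37 = q_by_flat_index(p, 37)
        assert np.isclose(Om[1, 1], q37 * x3 - p.Gamma[1])


class TestCorrectionTerm:
    def test_constant_operator_has_no_correction(self, rng):
        basis = enumerate_monomials(3, 2)
        q = {}
        for pair in [(0, 1), (0, 2), (1, 2)]:
            blk = np.zeros(basis.size)
            blk[0] = rng.normal()
            q[pair] = blk
        p = HelmholtzParams(basis=basis, h=np.zeros(basis.size), q=q, Gamma=np.ones(3))
        np.testing.assert_allclose(correction_term(p, rng.normal(size=(5, 3))), 0.0)

    def test_hand_differentiated_2d(self):
        # Q12 = x1 x2  ->  Lambda = (x1, -x2)
        basis = enumerate_monomials(2, 2)
        blk = np.zeros(basis.size)
        blk[basis.index_of((1, 1))] = 1.0
        p = HelmholtzParams(basis=basis, h=np.zeros(basis.size), q={(0, 1): blk}, Gamma=np.ones(2))
        lam = correction_term(p, np.array([3.0, 5.0]))
        np.testing.assert_allclose(lam, [3.0, -5.0])

    def test_matches_finite_difference_divergence(self, lorenz_laplace):
        p = lorenz_laplace.params
        rng = np.random.default_rng(5)
        pts = rng.uniform(-6, 6, (10, 3))
        lam = correction_term(p, pts)
        eps = 1e-6
        fd = np.zeros_like(lam)
        for j in range(3):
            d = np.zeros(3)
            d[j] = eps
            fd += (flow_operator(p, pts + d)[:, :, j] - flow_operator(p, pts - d)[:, :, j]) / (2 * eps)
        assert np.max(np.abs(lam - fd)) < 1e-8


class TestModelFlow:
    def test_zero_potential_zero_flow(self, rng):
        basis = enumerate_monomials(3, 2)
        blk = np.zeros(basis.size)
        blk[0] = 2.0
        p = HelmholtzParams(basis=basis, h=np.zeros(basis.size), q={(0, 1): blk}, Gamma=np.ones(3))
        f = model_flow(p, rng.normal(size=(6, 3)), jacobian=False)
        np.testing.assert_allclose(f, 0.0)

    def test_linear_case_constant_jacobian(self, rng):
        basis = enumerate_monomials(2, 2)
        H = np.array([[2.0, 0.5], [0.5, 1.0]])
        h = params_from_gaussian(basis, np.zeros(2), H)
        blk = np.zeros(basis.size)
        blk[0] = 0.7
        p = HelmholtzParams(basis=basis, h=h, q={(0, 1): blk}, Gamma=np.array([0.3, 0.4]))
        pts = rng.normal(size=(8, 2))
        f, J = model_flow(p, pts)
        Om = np.array([[-0.3, 0.7], [-0.7, -0.4]])
        np.testing.assert_allclose(J, np.broadcast_to(Om @ H, J.shape), atol=1e-12)
        np.testing.assert_allclose(f, pts @ (Om @ H).T, atol=1e-12)

    def test_jacobian_matches_finite_differences(self, coupled_laplace, rng):
        p = coupled_laplace.params
        pts = rng.uniform(-5, 5, (10, 6))
        _, J = model_flow(p, pts)
        eps = 1e-6
        for w in range(6):
            d = np.zeros(6)
            d[w] = eps
            fd = (model_flow(p, pts + d, jacobian=False) - model_flow(p, pts - d, jacobian=False)) / (2 * eps)
            assert np.max(np.abs(J[:, :, w] - fd)) < 1e-6


class TestSolenoidalLinear:
    def test_gradient_flow_gives_zero_Q(self):
        Q = solve_solenoidal_linear(-np.eye(3), np.ones(3))
        np.testing.assert_allclose(Q, 0.0, atol=1e-12)

    def test_random_stable_system_constraint(self, rng):
        A = rng.normal(size=(3, 3))
        J = -(A @ A.T) - 0.5 * np.eye(3) + 0.3 * (A - A.T)
        G = np.eye(3)
        Q = solve_solenoidal_linear(J, np.ones(3))
        resid = J @ Q + Q @ J.T - (G @ J.T - J @ G)
        assert np.max(np.abs(resid)) < 1e-10
        assert np.max(np.abs(Q + Q.T)) < 1e-12
        H = np.linalg.solve(Q - G, J)
        assert np.max(np.abs(H - H.T)) < 1e-8

    def test_degenerate_eigenpair_raises(self):
        J = np.diag([1.0, -1.0])  # eigenvalues sum to zero
        with pytest.raises(np.linalg.LinAlgError):
            solve_solenoidal_linear(J, np.ones(2))


class TestExactLorenz:
    def test_printed_parameter_relations(self):
        p = exact_lorenz_decomposition(10.0, 32.0, 8.0 / 3.0)
        h5 = p.h[p.basis.index_of((1, 1, 0))]
        h7 = p.h[p.basis.index_of((0, 0, 1))]
        assert np.isclose(-h5 * q_by_flat_index(p, 11), 10.0)
        assert np.isclose(-h7 * q_by_flat_index(p, 57), 8.0 / 3.0)
        assert np.isclose(-h5 * p.Gamma[1], 32.0)
        # exactly two nonzero potential coefficients
        nz = np.nonzero(np.abs(p.h) > 1e-12)[0]
        assert set(nz) == {p.basis.index_of((1, 1, 0)), p.basis.index_of((0, 0, 1))}

    def test_flow_reproduced_at_random_points(self, rng):
        p = exact_lorenz_decomposition(10.0, 32.0, 8.0 / 3.0)
        spec = lorenz(10.0, 32.0, 8.0 / 3.0)
        pts = rng.uniform(-20, 20, (100, 3))
        assert np.max(np.abs(model_flow(p, pts, jacobian=False) - spec.flow(pts))) < 1e-10

    def test_hessian_not_positive_definite(self):
        p = exact_lorenz_decomposition(10.0, 32.0, 8.0 / 3.0)
        H = p.potential_hessian(np.zeros(3))
        h5 = p.h[p.basis.index_of((1, 1, 0))]
        np.testing.assert_allclose(H, [[0, h5, 0], [h5, 0, 0], [0, 0, 0]])
        assert np.linalg.eigvalsh(H).min() < 0

    def test_other_gauges_also_exact(self, rng):
        p = exact_lorenz_decomposition(10.0, 28.0, 8.0 / 3.0, gauge=(2.0, -0.5))
        spec = lorenz(10.0, 28.0, 8.0 / 3.0)
        pts = rng.uniform(-15, 15, (50, 3))
        assert np.max(np.abs(model_flow(p, pts, jacobian=False) - spec.flow(pts))) < 1e-10

    def test_zero_gauge_rejected(self):
        with pytest.raises(ValueError):
            exact_lorenz_decomposition(10.0, 32.0, 8.0 / 3.0, gauge=(0.0, -1.0))


class TestFitting:
    def test_linear_flow_matches_closed_form(self):
        J = np.array([[-1.0, -4.0], [4.0, -1.0]])
        basis = enumerate_monomials(2, 2)
        pts = default_sample_grid(2, 4, 3.0, centre=[0, 0])
        p = fit_decomposition(lambda x: x @ J.T, pts, basis, Gamma=np.ones(2), fix_diagonal=True)
        assert p.fit_report.rms_residual < 1e-10
        Q = solve_solenoidal_linear(J, np.ones(2))
        H = np.linalg.solve(Q - np.eye(2), J)
        np.testing.assert_allclose(p.potential_hessian(np.zeros(2)), 0.5 * (H + H.T), atol=1e-8)

    def test_free_gamma_lorenz_fit_is_essentially_exact(self):
        """With free noise amplitudes the Lorenz flow admits an exact quadratic
        decomposition, so the fit residual collapses to numerical noise."""
        basis = enumerate_monomials(3, 2)
        grid = default_sample_grid(3, 4, 8.0)
        spec = lorenz()
        p = fit_decomposition(spec.flow, grid, basis, Gamma="free", fix_diagonal=False)
        flow_scale = float(np.sqrt(np.mean(spec.flow(grid) ** 2)))
        assert p.fit_report.rms_residual < 1e-6 * flow_scale

    def test_constrained_fit_highly_correlated_not_equal(self, lorenz_laplace):
        """The Laplace exemplar approximates but does not equal the target flow."""
        p = lorenz_laplace.params
        grid = default_sample_grid(3, 4, 8.0)
        spec = lorenz()
        target = spec.flow(grid) / 64.0
        fitted = model_flow(p, grid, jacobian=False)
        r = np.corrcoef(target.ravel(), fitted.ravel())[0, 1]
        assert r > 0.5
        assert np.max(np.abs(target - fitted)) > 1e-3

    def test_operator_refit_recovers_flow(self, lorenz_laplace):
        """Refitting the operator against the exemplar's own flow, with the
        same potential, reproduces that flow (fixed-potential idempotence)."""
        p = lorenz_laplace.params
        grid = default_sample_grid(3, 4, 8.0)
        own_flow = lambda x: model_flow(p, x, jacobian=False)
        p2 = fit_operator(own_flow, grid, p.basis, p.h, p.Gamma)
        assert p2.fit_report.rms_residual < 1e-8
        pts = np.random.default_rng(0).uniform(-8, 8, (40, 3))
        assert np.max(np.abs(model_flow(p2, pts, jacobian=False) - own_flow(pts))) < 1e-6

    def test_insufficient_sample_coordinates_rejected(self):
        basis = enumerate_monomials(2, 2)
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])  # one distinct x2
        with pytest.raises(ValueError):
            fit_decomposition(lambda x: -x, pts, basis, Gamma=np.ones(2))


class TestSymmetries:
    def test_lorenz_sign_symmetry_detected(self):
        syms = detect_sign_symmetries(lorenz().flow, 3)
        assert len(syms) == 1
        np.testing.assert_allclose(syms[0], [-1, -1, 1])

    def test_no_false_symmetries_for_generic_affine_flow(self, rng):
        J = rng.normal(size=(3, 3))
        c = rng.normal(size=3)
        assert detect_sign_symmetries(lambda x: x @ J.T + c, 3) == []


class TestKernelPotential:
    def test_identity_kernel(self):
        basis = enumerate_monomials(2, 2)
        k = {}
        for i in range(2):
            blk = np.zeros(basis.size)
            blk[0] = 1.0
            k[(i, i)] = blk
        kp = KernelPotential(basis=basis, mean=np.zeros(2), k=k)
        x = np.array([3.0, 4.0])
        val, grad, A = kernel_potential_eval(kp, x)
        assert np.isclose(val, 0.5 * 25.0)
        np.testing.assert_allclose(grad, x)
        np.testing.assert_allclose(A, np.eye(2))

    def test_state_dependent_kernel_stays_psd_with_quartic_terms(self, rng):
        basis = enumerate_monomials(2, 2)
        k = {}
        for (i, j) in [(0, 0), (0, 1), (1, 1)]:
            blk = np.zeros(basis.size)
            blk[0] = rng.normal()
            blk[basis.index_of((1, 0))] = rng.normal() * 0.3  # first-order entries
            blk[basis.index_of((0, 1))] = rng.normal() * 0.3
            k[(i, j)] = blk
        kp = KernelPotential(basis=basis, mean=np.zeros(2), k=k)
        pts = rng.uniform(-5, 5, (100, 2))
        val, grad, A = kernel_potential_eval(kp, pts)
        assert np.min(np.linalg.eigvalsh(A)) >= -1e-12
        # gradient against finite differences
        eps = 1e-6
        for i in range(2):
            d = np.zeros(2)
            d[i] = eps
            vp, _, _ = kernel_potential_eval(kp, pts + d)
            vm, _, _ = kernel_potential_eval(kp, pts - d)
            assert np.max(np.abs(grad[:, i] - (vp - vm) / (2 * eps))) < 1e-5

    def test_first_order_kernel_gives_quartic_potential(self):
        basis = enumerate_monomials(2, 2)
        k = {}
        for (i, j) in [(0, 0), (1, 1)]:
            blk = np.zeros(basis.size)
            blk[0] = 1.0
            blk[basis.index_of((1, 0))] = 0.5
            k[(i, j)] = blk
        kp = KernelPotential(basis=basis, mean=np.zeros(2), k=k)
        t = np.array([2.0, 4.0, 8.0])
        ray = np.outer(t, [1.0, 0.0])
        v, _, _ = kernel_potential_eval(kp, ray)
        # I = x1^2 (1 + x1/2)^2 / 2 along the ray: quartic growth
        np.testing.assert_allclose(v, [8.0, 72.0, 800.0], atol=1e-10)

    def test_asymmetric_specification_rejected(self):
        basis = enumerate_monomials(2, 2)
        blk = np.zeros(basis.size)
        with pytest.raises(ValueError):
            KernelPotential(basis=basis, mean=np.zeros(2), k={(1, 0): blk})


class TestFlatIndexing:
    def test_flat_indices_match_printed_examples(self):
        basis = enumerate_monomials(3, 2)
        assert flat_q_index(basis, 1, 2, 1) == 11   # constant of block (1,2)
        assert flat_q_index(basis, 2, 2, 7) == 37   # x3 term of block (2,2)
        assert flat_q_index(basis, 3, 3, 7) == 57   # x3 term of block (3,3)
        assert flat_q_index(basis, 2, 3, 4) == 44   # x2 term of block (2,3)


class TestStationarity:
    def test_fokker_planck_residual_adjudicates_housekeeping_sign(self, lorenz_laplace):
        """p ~ exp(-I) is exactly stationary under f = Omega grad I - Lambda;
        flipping the housekeeping sign breaks stationarity by orders of
        magnitude.  (Central differences are exact on the quadratic
        potential, so the correct-sign residual sits at round-off level.)"""
        from nesskit import densdyn
        from nesskit.helmholtz import correction_term

        p = lorenz_laplace.params
        for nodes in (17, 33):
            axes = [np.linspace(-12, 12, nodes), np.linspace(-12, 12, nodes),
                    np.linspace(16, 40, nodes)]
            fields = densdyn._SteadyFields(p, axes)
            gd = densdyn.GridDensity(axes=axes, surprisal=fields.I.copy())
            pts = densdyn._grid_points(axes)
            flow, J = model_flow(p, pts)
            shape = tuple(len(a) for a in axes)
            divf = np.trace(J, axis1=1, axis2=2).reshape(shape)
            fv = [flow[:, i].reshape(shape) for i in range(3)]
            rate = densdyn.generic_surprisal_rate(gd, fv, divf, p.Gamma)
            interior = (slice(2, -2),) * 3
            assert np.max(np.abs(rate[interior])) < 1e-9
            # opposite convention: f' = Omega grad I + Lambda
            lam = correction_term(p, pts)
            flow_bad = flow + 2.0 * lam
            # div f' = div f + 2 div Lambda = div f (Lambda is divergence-free
            # for skew Q), so only the advective part changes
            fv_bad = [flow_bad[:, i].reshape(shape) for i in range(3)]
            rate_bad = densdyn.generic_surprisal_rate(gd, fv_bad, divf, p.Gamma)
            assert np.max(np.abs(rate_bad[interior])) > 1e-3
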