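import numpy as np
import pytest

from tempodose.gene_model import GenePriors, fit_gaussian, hat_trace
from tempodose.spline_basis import (
    build_basis,
    expand_per_line,
    omega_half_inverse,
    orthogonalize,
    place_knots,
)


class TestPlaceKnots:
    @pytest.mark.parametrize(
        "times, K, expected",
        [
            (np.arange(1.0, 9.0), 2, [10 / 3, 17 / 3]),
            (np.arange(1.0, 9.0), 1, [4.5]),
            (np.array([0.0, 10.0, 5.0, 2.0]), 3, [2.5, 5.0, 7.5]),
        ],
    )
    def test_equally_spaced_interior(self, times, K, expected):
        np.testing.assert_allclose(place_knots(times, K), expected)

    def test_too_many_knots_rejected(self):
        with pytest.raises(ValueError, match="K <= "):
            place_knots(np.array([1.0, 2.0, 3.0]), 3)


class TestBuildBasis:
    def test_raw_basis_and_penalty_entries(self):
        times = np.arange(1.0, 9.0)
        knots = place_knots(times, 2)
        b = build_basis(times, knots)
        # row at a knot has a zero in that column
        np.testing.assert_allclose(np.abs(times[:, None] - knots) ** 3, b.Z_raw)
        assert np.all(np.diag(b.omega) == 0)
        np.testing.assert_allclose(b.omega, b.omega.T)
        np.testing.assert_allclose(b.omega[0, 1], (7 / 3) ** 3)

    def test_k1_uses_identity_penalty(self):
        times = np.arange(1.0, 9.0)
        b = build_basis(times, place_knots(times, 1))
        np.testing.assert_allclose(b.omega, [[1.0]])
        np.testing.assert_allclose(b.Z_reparam, b.Z_raw)

    def test_duplicate_knots_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            build_basis(np.arange(8.0), np.array([3.0, 3.0]))

    def test_time_translation_leaves_raw_basis_unchanged(self):
        times = np.arange(1.0, 9.0)
        knots = place_knots(times, 3)
        b1 = build_basis(times, knots)
        b2 = build_basis(times + 17.0, knots + 17.0)
        np.testing.assert_allclose(b1.Z_raw, b2.Z_raw)
        np.testing.assert_allclose(b1.omega, b2.omega)


class TestOmegaHalfInverse:
    def test_identity_and_diagonal(self):
        np.testing.assert_allclose(omega_half_inverse(np.eye(3)), np.eye(3))
        np.testing.assert_allclose(
            omega_half_inverse(np.diag([4.0, 9.0])), np.diag([0.5, 1 / 3]))

    def test_psd_matrix_whitens_on_retained_span(self, rng):
        A = rng.standard_normal((3, 3))
        omega = A @ A.T
        M = omega_half_inverse(omega)
        np.testing.assert_allclose(M.T @ omega @ M, np.eye(3), atol=1e-8)

    def test_small_singular_values_dropped_not_amplified(self):
        omega = np.diag([1.0, 1e-30])
        M = omega_half_inverse(omega)
        assert M[1, 1] == 0.0


class TestExpandPerLine:
    def test_single_line_unchanged(self, design_4x8):
        b = expand_per_line(design_4x8["basis"], 1)
        np.testing.assert_allclose(b.design, design_4x8["basis"].design)

    def test_block_diagonal_shape(self, design_4x8):
        b = expand_per_line(design_4x8["basis"], 4)
        assert b.design.shape == (32, 8)
        # rows of line i are zero outside block i
        Z = b.design
        for i in range(4):
            rows = slice(i * 8, (i + 1) * 8)
            mask = np.ones(8, bool)
            mask[i * 2:(i + 1) * 2] = False
            assert np.all(Z[rows][:, mask] == 0)

    def test_not_line_major_rejected(self, design_4x8):
        lines = np.tile(np.arange(4), 8)  # time-major ordering
        with pytest.raises(ValueError, match="line-major"):
            expand_per_line(design_4x8["basis"], 4, lines=lines)

    def test_identical_lines_reproduce_common_fit(self, design_4x8, rng):
        """Per-line spline on identical lines = common spline fit."""
        d = design_4x8
        curve = np.sin(np.linspace(0, np.pi, d["T"]))
        y = np.tile(curve, d["n"]) + rng.normal(0, 0.05, d["N"])
        y = np.tile(y[: d["T"]], d["n"])  # identical lines exactly
        pri = GenePriors(alpha_var=100.0, beta_pi0=1.0)
        # weak-shrinkage limit: both models reduce to least squares on the
        # same fitted subspace when the lines are identical
        fit_c = fit_gaussian(y, d["X"], basis=d["basis"], priors=pri,
                             variances=(1e5, 0.01))
        fit_p = fit_gaussian(y, d["X"], basis=expand_per_line(d["basis"], 4),
                             priors=pri, variances=(1e5, 0.01))
        np.testing.assert_allclose(fit_c.fitted, fit_p.fitted, atol=1e-6)


class TestOrthogonalize:
    def test_defining_property(self, design_4x8, rng):
        F = np.column_stack([design_4x8["X"], rng.standard_normal(32)])
        b = orthogonalize(design_4x8["basis"], F)
        assert np.abs(F.T @ b.design).max() < 1e-8

    def test_already_orthogonal_unchanged(self, design_4x8):
        basis = design_4x8["basis"]
        Q, _ = np.linalg.qr(basis.design)
        # a fixed design orthogonal to the spline columns by construction
        F = np.eye(32) - Q @ Q.T
        F = F[:, :3]
        b = orthogonalize(basis, F)
        np.testing.assert_allclose(b.design, basis.design, atol=1e-8)

    def test_spanning_design_absorbs_spline(self, design_4x8):
        basis = design_4x8["basis"]
        F = np.column_stack([basis.design, design_4x8["X"]])
        with pytest.warns(UserWarning, match="absorbed"):
            b = orthogonalize(basis, F)
        assert np.abs(b.design).max() < 1e-8

    def test_rank_deficient_rejected(self, design_4x8):
        X = design_4x8["X"]
        F = np.column_stack([X, X[:, 0]])
        with pytest.raises(ValueError, match="collinear"):
            orthogonalize(design_4x8["basis"], F)


class TestReparameterization:
    def test_correlated_prior_equals_iid_reparam(self, design_4x8, rng):
        """Raw basis + correlated prior and reparameterized basis + iid prior
        give identical fitted values (oracle: dense covariance algebra)."""
        d = design_4x8
        basis, X, N = d["basis"], d["X"], d["N"]
        for _ in range(5):
            y = rng.standard_normal(N)
            s2g, s2e, av = 0.8, 0.3, 50.0
            pri = GenePriors(alpha_var=av, beta_pi0=1.0)
            fit = fit_gaussian(y, X, basis=basis, priors=pri, variances=(s2g, s2e))
            M = omega_half_inverse(basis.omega)
            Cov = s2e * np.eye(N) + av * X @ X.T + s2g * basis.Z_raw @ M @ M.T @ basis.Z_raw.T
            fitted_oracle = (av * X @ X.T + s2g * basis.Z_raw @ M @ M.T @ basis.Z_raw.T) \
                @ np.linalg.solve(Cov, y)
            np.testing.assert_allclose(fit.fitted, fitted_oracle, atol=1e-6)

    def test_spline_flexibility_monotone_in_variance(self, design_4x8, rng):
        d = design_4x8
        y = rng.standard_normal(d["N"])
        pri = GenePriors(alpha_var=100.0, beta_pi0=1.0)
        traces = [
            hat_trace(fit_gaussian(y, d["X"], basis=d["basis"], priors=pri,
                                   variances=(s2g, 0.3)), "spline")
            for s2g in (1e-9, 1e-3, 1e-1, 1e1, 1e3)
        ]
        assert np.all(np.diff(traces) >= -1e-9)
        assert traces[0] < 1e-3  # shrunk flat
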