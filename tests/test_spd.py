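"""SPD calculus: closed forms, metric properties, and independent oracles.

The AIRM distance is checked against the generalized-eigenvalue formula
(sqrt of the summed squared log eigenvalues of A^{-1} B, computed with
scipy's generalized symmetric solver) and the matrix functions against
scipy.linalg's Schur-based logm/expm/sqrtm — routes algorithmically
independent of the eigendecomposition implementation under test.
"""

import numpy as np
import pytest
import scipy.linalg

from tanrec import spd
from tanrec.synthetic import generate_spd


def midpoint(a, b):
    """Closed-form geodesic midpoint A^1/2 (A^-1/2 B A^-1/2)^1/2 A^1/2
    via scipy (independent of the Karcher iteration)."""
    ah = scipy.linalg.sqrtm(a)
    ai = np.linalg.inv(ah)
    return ah @ scipy.linalg.sqrtm(ai @ b @ ai) @ ah


class TestRegularize:
    def test_identity_shift(self):
        out = spd.regularize(np.eye(2), 1.0)
        assert np.allclose(out.values, np.diag([2.0, 2.0]))

    def test_zero_lambda_keeps_spd_input(self, spd_pair):
        a, _ = spd_pair
        assert np.allclose(spd.regularize(a, 0.0).values, a.values)

    def test_eigenvalue_shift_on_singular_input(self):
        c = np.array([[1.0, 1.0], [1.0, 1.0]])  # rank-1 PSD
        out = spd.regularize(c, 1e-3)
        w = np.linalg.eigvalsh(out.values)
        assert w[0] == pytest.approx(1e-3, rel=1e-9)
        assert w[-1] == pytest.approx(2.0 + 1e-3, rel=1e-12)

    def test_zero_lambda_singular_errors_naming_eigenvalue(self):
        c = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(spd.NotSPDError, match="eigenvalue"):
            spd.regularize(c, 0.0)

    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError, match="symmetric"):
            spd.regularize(np.array([[1.0, 0.5], [0.2, 1.0]]), 0.1)

    def test_rejects_negative_lambda(self):
        with pytest.raises(ValueError):
            spd.regularize(np.eye(2), -0.1)


class TestMatrixFunction:
    def test_log_of_identity_is_zero(self):
        out = spd.matrix_function(np.eye(3), "log")
        assert np.allclose(out.values, 0.0)

    @pytest.mark.parametrize(
        "fn,diag,expected",
        [
            ("sqrt", [4.0, 9.0], [2.0, 3.0]),
            ("log", [1.0, np.e**2], [0.0, 2.0]),
            ("inv_sqrt", [4.0, 16.0], [0.5, 0.25]),
        ],
    )
    def test_diagonal_closed_forms(self, fn, diag, expected):
        out = spd.matrix_function(np.diag(diag), fn)
        assert np.allclose(out.values, np.diag(expected))

    def test_nonpositive_eigenvalue_errors(self):
        with pytest.raises(spd.NotSPDError):
            spd.matrix_function(np.diag([1.0, -0.5]), "log")

    def test_agrees_with_scipy_schur_routes(self):
        for m in generate_spd(6, 5, condition_number_cap=100, seed=3):
            log_ref = scipy.linalg.logm(m.values)
            sqrt_ref = scipy.linalg.sqrtm(m.values)
            assert np.allclose(spd.matrix_function(m, "log").values, log_ref, atol=1e-9)
            assert np.allclose(spd.matrix_function(m, "sqrt").values, sqrt_ref, atol=1e-9)

    def test_output_exactly_symmetric(self, spd_pair):
        out = spd.matrix_function(spd_pair[0], "log").values
        assert np.array_equal(out, out.T)

    def test_scalar_p1_matrix(self):
        out = spd.matrix_function(np.array([[4.0]]), "sqrt")
        assert out.values[0, 0] == pytest.approx(2.0)


class TestGeodesicDistance:
    def test_zero_self_distance_and_symmetry(self):
        mats = generate_spd(5, 10, condition_number_cap=100, seed=5)
        for i in range(0, 10, 2):
            a, b = mats[i], mats[i + 1]
            assert spd.geodesic_distance(a, a) == pytest.approx(0.0, abs=1e-10)
            assert spd.geodesic_distance(a, b) == pytest.approx(
                spd.geodesic_distance(b, a), rel=1e-10
            )

    def test_analytic_diagonal_cases(self):
        assert spd.geodesic_distance(np.eye(2), np.diag([np.e, np.e])) == pytest.approx(
            np.sqrt(2.0)
        )
        expected = np.hypot(np.log(4.0), np.log(9.0))
        assert spd.geodesic_distance(np.eye(2), np.diag([4.0, 9.0])) == pytest.approx(expected)

    def test_generalized_eigenvalue_oracle(self):
        """Matrix-log route equals sqrt(sum ln^2 lambda_i(A^-1 B))."""
        mats = generate_spd(7, 20, condition_number_cap=1e3, seed=11)
        for a, b in zip(mats[::2], mats[1::2]):
            d = spd.geodesic_distance(a, b)
            lam = scipy.linalg.eigh(b.values, a.values, eigvals_only=True)
            oracle = np.sqrt(np.sum(np.log(lam) ** 2))
            assert d == pytest.approx(oracle, rel=1e-10)

    def test_affine_invariance(self):
        """d(A, B) = d(MAM^T, MBM^T) for invertible M (100 random cases)."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            p = int(rng.integers(2, 11))
            a, b = generate_spd(p, 2, condition_number_cap=100, seed=int(rng.integers(1 << 30)))
            m = rng.normal(size=(p, p))
            while abs(np.linalg.det(m)) < 1e-3:
                m = rng.normal(size=(p, p))
            d0 = spd.geodesic_distance(a, b)
            d1 = spd.geodesic_distance(
                spd.SPDMatrix(m @ a.values @ m.T), spd.SPDMatrix(m @ b.values @ m.T)
            )
            assert abs(d0 - d1) <= 1e-8 * d0

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            spd.geodesic_distance(np.eye(2), np.eye(3))


class TestTangentMaps:
    def test_projecting_reference_gives_zero(self, spd_pair):
        a, _ = spd_pair
        t = spd.tangent_project(a, a)
        assert np.linalg.norm(t.values, "fro") <= 1e-8

    def test_identity_reference_is_matrix_log(self, spd_pair):
        a, _ = spd_pair
        t = spd.tangent_project(a, np.eye(a.p))
        assert np.allclose(t.values, scipy.linalg.logm(a.values), atol=1e-9)

    def test_diagonal_closed_form(self):
        t = spd.tangent_project(np.diag([4.0, 9.0]), np.eye(2))
        assert np.allclose(t.values, np.diag([np.log(4.0), np.log(9.0)]))

    def test_reference_id_recorded(self, spd_pair):
        a, b = spd_pair
        t = spd.tangent_project(a, b, reference_id="ref-7")
        assert t.reference_id == "ref-7"

    def test_retract_zero_recovers_reference(self, spd_pair):
        a, _ = spd_pair
        out = spd.tangent_retract(np.zeros((a.p, a.p)), a)
        assert np.allclose(out.values, a.values, atol=1e-12)

    def test_retract_diagonal_closed_form(self):
        out = spd.tangent_retract(np.diag([1.0, 2.0]), np.eye(2))
        assert np.allclose(out.values, np.diag([np.e, np.e**2]))

    def test_round_trip_identity(self):
        """retract(project(S)) = S within 1e-8 relative, 100 random matrices."""
        refs = generate_spd(6, 100, condition_number_cap=100, seed=21)
        mats = generate_spd(6, 100, condition_number_cap=100, seed=22)
        for ref, s in zip(refs, mats):
            t = spd.tangent_project(s, ref)
            back = spd.tangent_retract(t, ref)
            rel = np.linalg.norm(back.values - s.values, "fro") / np.linalg.norm(
                s.values, "fro"
            )
            assert rel <= 1e-8

    def test_first_order_flatness(self):
        """Near the reference, tangent Euclidean distance approximates the
        geodesic distance within 1%."""
        rng = np.random.default_rng(9)
        ref = generate_spd(6, 1, condition_number_cap=50, seed=33)[0]
        for _ in range(20):
            t1, t2 = rng.normal(size=(2, 6, 6))
            t1, t2 = 0.5 * (t1 + t1.T), 0.5 * (t2 + t2.T)
            t1 *= 0.01 / np.linalg.norm(t1, "fro")
            t2 *= 0.01 / np.linalg.norm(t2, "fro")
            s1 = spd.tangent_retract(t1, ref)
            s2 = spd.tangent_retract(t2, ref)
            assert spd.geodesic_distance(s1, ref) <= 0.0100001
            d_tan = np.linalg.norm(t1 - t2, "fro")
            d_geo = spd.geodesic_distance(s1, s2)
            assert d_tan == pytest.approx(d_geo, rel=0.01)


class TestRiemannMean:
    def test_single_and_repeated_element(self, spd_pair):
        a, _ = spd_pair
        assert np.allclose(spd.riemann_mean([a]).values, a.values, atol=1e-10)
        assert np.allclose(spd.riemann_mean([a, a]).values, a.values, atol=1e-10)

    def test_commuting_diagonal_geometric_mean(self):
        out = spd.riemann_mean([np.diag([1.0, 4.0]), np.diag([4.0, 1.0])])
        assert np.allclose(out.values, np.diag([2.0, 2.0]), atol=1e-8)

    def test_two_matrix_mean_is_geodesic_midpoint(self):
        mats = generate_spd(5, 20, condition_number_cap=100, seed=17)
        for a, b in zip(mats[::2], mats[1::2]):
            mean = spd.riemann_mean([a, b]).values
            mid = midpoint(a.values, b.values)
            assert np.linalg.norm(mean - mid, "fro") <= 1e-8 * np.linalg.norm(mid, "fro")

    def test_gradient_norm_below_tol_at_return(self):
        mats = generate_spd(6, 8, condition_number_cap=100, seed=29)
        mean = spd.riemann_mean(mats, tol=1e-8)
        r = spd.matrix_function(mean, "inv_sqrt").values
        grad = np.mean(
            [spd.matrix_function(r @ m.values @ r, "log").values for m in mats], axis=0
        )
        assert np.linalg.norm(grad, "fro") < 1e-8

    def test_nonconvergence_error_carries_gradient_norm(self):
        mats = generate_spd(5, 6, condition_number_cap=1e4, seed=31)
        with pytest.raises(spd.ConvergenceError) as err:
            spd.riemann_mean(mats, max_iter=1)
        assert err.value.gradient_norm > 0

    def test_empty_list_errors(self):
        with pytest.raises(ValueError, match="nonempty"):
            spd.riemann_mean([])

    def test_explicit_init_matrix(self, spd_pair):
        a, b = spd_pair
        via_init = spd.riemann_mean([a, b], init=a)
        via_arith = spd.riemann_mean([a, b])
        assert np.allclose(via_init.values, via_arith.values, atol=1e-7)


class TestIO:
    def test_round_trip_is_bit_stable(self, tmp_path, spd_pair):
        a, _ = spd_pair
        path = tmp_path / "m.tsv"
        spd.save_matrix(path, a.values)
        back, labels = spd.load_matrix(path)
        assert labels is None
        assert np.array_equal(back, a.values)

    def test_header_labels_round_trip(self, tmp_path):
        path = tmp_path / "m.tsv"
        spd.save_matrix(path, np.eye(3), labels=["r1", "r2", "r3"])
        back, labels = spd.load_matrix(path)
        assert labels == ["r1", "r2", "r3"]
        assert np.array_equal(back, np.eye(3))


class TestTypeInvariants:
    def test_spd_constructor_rejects_indefinite(self):
        with pytest.raises(spd.NotSPDError):
            spd.SPDMatrix(np.diag([1.0, -1.0]))

    def test_symmetric_constructor_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            spd.SymmetricMatrix(np.array([[np.nan, 0.0], [0.0, 1.0]]))

    def test_tangent_matrix_requires_symmetry(self):
        with pytest.raises(ValueError):
            spd.TangentMatrix(np.array([[0.0, 1.0], [0.5, 0.0]]))
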