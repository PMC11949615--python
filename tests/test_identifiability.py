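"""Correlation distance, identifiability matrices, fingerprinting rates,
reconfiguration vectors — checked against brute-force re-computation."""

import numpy as np
import pytest

from tanrec import identifiability as ident
from tanrec.connectivity import SEGMENTS, vectorize
from tanrec.spd import TangentMatrix


def random_tangents(rng, n, p, reference_id="ref"):
    out = []
    for i in range(n):
        m = rng.normal(size=(p, p))
        out.append(TangentMatrix(0.5 * (m + m.T), reference_id=reference_id, label=f"s{i}"))
    return out


class TestCorrelationDistance:
    def test_self_distance_zero(self):
        x = [1.0, 2.0, 5.0, 3.0]
        assert ident.correlation_distance(x, x) == pytest.approx(0.0)

    def test_anticorrelated_distance_two(self):
        x = np.array([1.0, 2.0, 5.0])
        assert ident.correlation_distance(x, -x + 7.0) == pytest.approx(2.0)

    def test_hand_computed_half(self):
        # r([1,2,3],[1,3,2]) = 0.5 by direct computation
        assert ident.correlation_distance([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError, match="constant"):
            ident.correlation_distance([1, 1, 1], [1, 2, 3])

    def test_range_bounds_on_random_pairs(self, rng):
        for _ in range(50):
            d = ident.correlation_distance(rng.normal(size=9), rng.normal(size=9))
            assert 0.0 <= d <= 2.0


class TestIdentifiabilityMatrix:
    def test_same_segment_zero_diagonal_symmetric(self, rng):
        tfcs = random_tangents(rng, 4, 5)
        idm = ident.identifiability_matrix(tfcs, tfcs, segment_pair=("A", "A"))
        assert np.allclose(np.diag(idm.values), 0.0, atol=1e-12)
        assert np.allclose(idm.values, idm.values.T)

    def test_entries_match_bruteforce_correlation_distance(self, rng):
        a = random_tangents(rng, 2, 4)
        b = random_tangents(rng, 2, 4)
        idm = ident.identifiability_matrix(a, b, segment_pair=("A", "B"))
        for i in range(2):
            for j in range(2):
                expected = ident.correlation_distance(vectorize(a[i]), vectorize(b[j]))
                assert idm.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_mixed_references_refused(self, rng):
        a = random_tangents(rng, 2, 4, reference_id="ref1")
        b = random_tangents(rng, 2, 4, reference_id="ref2")
        with pytest.raises(ValueError, match="reference"):
            ident.identifiability_matrix(a, b)

    def test_subject_permutation_equivariance(self, rng):
        a = random_tangents(rng, 4, 5)
        b = random_tangents(rng, 4, 5)
        idm = ident.identifiability_matrix(a, b, segment_pair=("A", "B"))
        perm = [2, 0, 3, 1]
        idm_p = ident.identifiability_matrix(
            [a[i] for i in perm], [b[j] for j in perm], segment_pair=("A", "B")
        )
        assert np.allclose(idm_p.values, idm.values[np.ix_(perm, perm)])


class TestMetaIdentifiability:
    def test_identical_tangents_give_all_zero_blocks(self, rng):
        one = random_tangents(rng, 1, 5)[0]
        tfcs = [one] * 3
        meta = ident.meta_identifiability({s: tfcs for s in SEGMENTS})
        for a in SEGMENTS:
            for b in SEGMENTS:
                assert np.allclose(meta.block(a, b).values, 0.0, atol=1e-10)

    def test_transpose_consistency_exact(self, rng):
        by_seg = {s: random_tangents(rng, 4, 5) for s in SEGMENTS}
        meta = ident.meta_identifiability(by_seg)
        for a in SEGMENTS:
            for b in SEGMENTS:
                assert np.array_equal(meta.block(a, b).values, meta.block(b, a).values.T)

    def test_missing_segment_errors(self, rng):
        by_seg = {s: random_tangents(rng, 3, 5) for s in SEGMENTS[:-1]}
        with pytest.raises(ValueError, match="missing"):
            ident.meta_identifiability(by_seg)

    def test_stacked_shape(self, rng):
        by_seg = {s: random_tangents(rng, 3, 5) for s in SEGMENTS}
        meta = ident.meta_identifiability(by_seg)
        assert meta.stacked().shape == (15, 15)


def brute_force_rate(values):
    """Independent re-count of the two-direction identification rate."""
    n = values.shape[0]
    hits = 0
    for m in (values, values.T):
        for i in range(n):
            mins = np.flatnonzero(m[i] == m[i].min())
            if mins.size == 1 and mins[0] == i:
                hits += 1
    return 100.0 * hits / (2 * n)


class TestIdentificationRate:
    def _idm(self, values):
        n = values.shape[0]
        return ident.IdentifiabilityMatrix(values, ("A", "B"), [f"s{i}" for i in range(n)])

    def test_dominant_diagonal_is_hundred(self):
        v = np.full((4, 4), 1.0)
        np.fill_diagonal(v, 0.1)
        assert ident.identification_rate(self._idm(v)) == 100.0

    def test_constructed_two_thirds_case(self):
        # subject 0 fails in both matching directions; subjects 1 and 2 succeed
        v = np.array([[0.5, 0.3, 0.9], [0.25, 0.2, 0.9], [0.9, 0.8, 0.1]])
        assert ident.identification_rate(self._idm(v)) == pytest.approx(
            brute_force_rate(v)
        )
        assert ident.identification_rate(self._idm(v)) == pytest.approx(200.0 / 3.0)

    def test_constant_matrix_all_ties_is_zero(self):
        assert ident.identification_rate(self._idm(np.ones((3, 3)))) == 0.0

    def test_matches_bruteforce_on_random_matrices(self, rng):
        for _ in range(20):
            v = rng.uniform(0, 2, size=(6, 6))
            assert ident.identification_rate(self._idm(v)) == pytest.approx(
                brute_force_rate(v)
            )

    def test_within_segment_refused(self):
        idm = ident.IdentifiabilityMatrix(np.zeros((3, 3)), ("A", "A"), list("abc"))
        with pytest.raises(ValueError, match="degenerate"):
            ident.identification_rate(idm)

    def test_monotone_subject_relabeling_invariance(self, rng):
        v = rng.uniform(0, 2, size=(5, 5))
        idm1 = self._idm(v)
        idm2 = ident.IdentifiabilityMatrix(v, ("A", "B"), [f"x{i}" for i in range(5)])
        assert ident.identification_rate(idm1) == ident.identification_rate(idm2)


class TestReconfigurationVector:
    def test_identical_sets_give_zeros(self, rng):
        tfcs = random_tangents(rng, 3, 5)
        idm = ident.identifiability_matrix(tfcs, tfcs, segment_pair=("A", "B"))
        vec = ident.reconfiguration_vector(idm)
        assert np.allclose(vec.values, 0.0, atol=1e-12)
        assert vec.n == 3

    def test_matches_entrywise_distance(self, rng):
        a = random_tangents(rng, 4, 5)
        b = random_tangents(rng, 4, 5)
        idm = ident.identifiability_matrix(a, b, segment_pair=("A", "B"))
        vec = ident.reconfiguration_vector(idm)
        for i in range(4):
            expected = ident.correlation_distance(vectorize(a[i]), vectorize(b[i]))
            assert vec.values[i] == pytest.approx(expected, abs=1e-12)

    def test_transition_labels_preserved(self, rng):
        a, b = random_tangents(rng, 3, 4), random_tangents(rng, 3, 4)
        idm = ident.identifiability_matrix(a, b, segment_pair=("R1.2", "SST"))
        assert ident.reconfiguration_vector(idm).transition == ("R1.2", "SST")


class TestCompareReconfigurations:
    def _vec(self, values, order=None):
        order = order or [f"s{i}" for i in range(len(values))]
        return ident.ReconfigurationVector(np.asarray(values, float), ("A", "B"), order)

    def test_identical_vectors(self):
        v = self._vec([0.1, 0.5, 0.9])
        out = ident.compare_reconfigurations(v, v)
        assert out.t == 0.0 and out.p == 1.0 and out.mean_difference == 0.0

    def test_constant_shift_degenerate(self):
        v1 = self._vec([0.1, 0.5, 0.9])
        v2 = self._vec([0.3, 0.7, 1.1])
        out = ident.compare_reconfigurations(v1, v2)
        assert out.mean_difference == pytest.approx(-0.2)
        assert np.isinf(out.t) and out.t < 0 and out.p == 0.0

    def test_matches_closed_form_t(self):
        v1 = self._vec([0.2, 0.5, 0.9, 1.1, 0.4])
        v2 = self._vec([0.1, 0.6, 0.7, 1.2, 0.2])
        out = ident.compare_reconfigurations(v1, v2)
        d = v1.values - v2.values
        t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        assert out.t == pytest.approx(t_expected)
        assert out.r == pytest.approx(np.corrcoef(v1.values, v2.values)[0, 1])

    def test_subject_mismatch_errors(self):
        v1 = self._vec([0.1, 0.5, 0.9])
        v2 = self._vec([0.1, 0.5, 0.9], order=["a", "b", "c"])
        with pytest.raises(ValueError, match="participants"):
            ident.compare_reconfigurations(v1, v2)
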