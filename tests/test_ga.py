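"""The G2 algebra layer: multiplication table, representations, embeddings."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gafuse import ga
from gafuse.ga import (
    ga_lstsq,
    ga_matvec,
    gp,
    left_matrix,
    magnitude,
    mv,
    real_embedding,
    reverse,
    to_real_matrix,
    unvec,
    vec,
)

from _oracles import gp_oracle

E0 = mv(e0=1)
E1 = mv(e1=1)
E2 = mv(e2=1)
E12 = mv(e12=1)
BASIS = [E0, E1, E2, E12]


finite_mv = st.tuples(*[st.floats(-10, 10) for _ in range(4)]).map(lambda t: np.array(t))


class TestGeometricProduct:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (E1, E1, E0),  # γ1² = 1
            (E2, E2, E0),  # γ2² = 1
            (E12, E12, -E0),  # γ12² = −1
            (E1, E2, E12),
            (E2, E1, -E12),
            (E1, E12, E2),
            (E12, E1, -E2),
            (E2, E12, -E1),
            (E12, E2, E1),
            (E1 + E2, E1, E0 - E12),  # expanded term-by-term: γ2γ1 = −γ12
        ],
    )
    def test_multiplication_table(self, a, b, expected):
        np.testing.assert_allclose(gp(a, b), expected, atol=1e-15)

    def test_identity_element(self, rng):
        b = rng.standard_normal(4)
        np.testing.assert_allclose(gp(E0, b), b)
        np.testing.assert_allclose(gp(b, E0), b)

    def test_matches_symbolic_blade_reduction(self, random_mv_pairs):
        for a, b in random_mv_pairs[:200]:
            np.testing.assert_allclose(gp(a, b), gp_oracle(a, b), atol=1e-12)

    def test_anticommutation_of_vector_generators(self):
        assert np.allclose(gp(E1, E2), -gp(E2, E1))

    @given(a=finite_mv, b=finite_mv, c=finite_mv)
    @settings(max_examples=200, deadline=None)
    def test_associative(self, a, b, c):
        np.testing.assert_allclose(gp(gp(a, b), c), gp(a, gp(b, c)), atol=1e-9)

    def test_bilinear(self, rng):
        a, b, c = rng.standard_normal((3, 4))
        np.testing.assert_allclose(gp(2.0 * a + b, c), 2.0 * gp(a, c) + gp(b, c), atol=1e-12)
        np.testing.assert_allclose(gp(c, 2.0 * a + b), 2.0 * gp(c, a) + gp(c, b), atol=1e-12)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            gp(mv(e0=np.nan), E0)

    def test_magnitude_submultiplicative_with_sqrt2_factor(self, random_mv_pairs):
        # G2 ≅ M2(R) has zero divisors, so the Euclidean magnitude is not
        # multiplicative; the sharp bound is |ab| ≤ √2·|a|·|b|.
        for a, b in random_mv_pairs:
            assert magnitude(gp(a, b)) <= np.sqrt(2) * magnitude(a) * magnitude(b) + 1e-9
        a = mv(e0=1, e1=1)
        assert np.isclose(magnitude(gp(a, a)), np.sqrt(2) * magnitude(a) ** 2)  # tight


class TestReverseAndMagnitude:
    def test_reversion_fixes_grades_0_1_flips_bivector(self):
        np.testing.assert_allclose(reverse(E12), -E12)
        np.testing.assert_allclose(reverse(E0 + E1), E0 + E1)

    def test_vector_grade_norm_via_reversion(self):
        a = E1 + 2 * E2
        assert np.isclose(gp(reverse(a), a)[0], 5.0)

    def test_magnitude_values(self):
        assert magnitude(mv()) == 0.0
        assert magnitude(E12) == 1.0
        assert np.isclose(magnitude(mv(1, 1, 1, 1)), 2.0)


class TestRealMatrixRepresentation:
    def test_scalar_maps_to_identity(self):
        np.testing.assert_allclose(to_real_matrix(E0), np.eye(4))

    def test_gamma1_matrix(self):
        expected = np.array([[0, 1, 0, 0], [1, 0, 0, 0], [0, 0, 0, -1], [0, 0, -1, 0]], dtype=float)
        np.testing.assert_allclose(to_real_matrix(E1), expected)

    def test_right_multiplication_orientation(self, rng):
        a, b = rng.standard_normal((2, 4))
        np.testing.assert_allclose(to_real_matrix(a) @ b, gp(b, a), atol=1e-12)
        np.testing.assert_allclose(left_matrix(a) @ b, gp(a, b), atol=1e-12)

    def test_anti_homomorphism_on_basis_example(self):
        np.testing.assert_allclose(
            to_real_matrix(E1) @ to_real_matrix(E2), to_real_matrix(gp(E2, E1))
        )
        np.testing.assert_allclose(to_real_matrix(gp(E2, E1)), to_real_matrix(-E12))

    def test_anti_homomorphism_random(self, random_mv_pairs):
        for a, b in random_mv_pairs:
            np.testing.assert_allclose(
                to_real_matrix(a) @ to_real_matrix(b), to_real_matrix(gp(b, a)), atol=1e-12
            )

    def test_linear(self, rng):
        a, b = rng.standard_normal((2, 4))
        np.testing.assert_allclose(
            to_real_matrix(0.3 * a + 1.7 * b),
            0.3 * to_real_matrix(a) + 1.7 * to_real_matrix(b),
            atol=1e-12,
        )


class TestMatvecAndLstsq:
    def test_matvec_trivial(self):
        D = E0.reshape(1, 1, 4)
        np.testing.assert_allclose(ga_matvec(D, E2.reshape(1, 4)), E2.reshape(1, 4))
        np.testing.assert_allclose(ga_matvec(D, np.zeros((1, 4))), np.zeros((1, 4)))

    def test_matvec_agrees_with_block_embedding(self, rng):
        D = rng.standard_normal((3, 2, 4))
        a = rng.standard_normal((2, 4))
        direct = ga_matvec(D, a)
        embedded = unvec(real_embedding(D) @ vec(a))
        np.testing.assert_allclose(direct, embedded, atol=1e-12)

    def test_matvec_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            ga_matvec(rng.standard_normal((3, 2, 4)), rng.standard_normal((3, 4)))

    def test_lstsq_exact_single_atom(self, rng):
        d = rng.standard_normal((5, 1, 4))
        d /= np.sqrt((d**2).sum())
        c = rng.standard_normal((1, 4))
        q = ga_matvec(d, c)
        sol = ga_lstsq(d, q)
        np.testing.assert_allclose(sol, c, atol=1e-10)
        np.testing.assert_allclose(ga_matvec(d, sol), q, atol=1e-10)

    def test_lstsq_zero_rhs(self, rng):
        d = rng.standard_normal((5, 2, 4))
        np.testing.assert_allclose(ga_lstsq(d, np.zeros((5, 4))), np.zeros((2, 4)), atol=1e-12)

    def test_lstsq_beats_random_candidates(self, rng):
        D = rng.standard_normal((6, 2, 4))
        q = rng.standard_normal((6, 4))
        sol = ga_lstsq(D, q)
        best = np.linalg.norm(vec(q - ga_matvec(D, sol)))
        for _ in range(100):
            cand = sol + 0.1 * rng.standard_normal((2, 4))
            assert np.linalg.norm(vec(q - ga_matvec(D, cand))) >= best - 1e-12
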