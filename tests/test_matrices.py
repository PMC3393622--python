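"""Matching polynomials, generalized Laplacian, distance matrices,
Faddeev-LeVerrier — all against independent oracles."""

import random
from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest
import sympy as sp

from treespectra.matrices import (GlapFingerprinter, bordered_charpolys,
                                  charpoly_leverrier_faddeev, distance_charpoly,
                                  distance_matrix, generalized_charpoly,
                                  matching_profile, root_distance_vector)
from treespectra.polynomial import ExactPolynomial, poly_eval
from treespectra.shapes import CHERRY, LEAF, enumerate_shapes, vertexize

from tests_oracles import bi_to_expr, cofactor_det, symbolic_glap_det, tri_to_expr

X, Y, Z = sp.symbols("x y z")


def brute_force_profile(T):
    """P_k/Q_k by literal enumeration of all matchings (edge subsets)."""
    from treespectra.polynomial import poly_add, poly_mul

    vt = vertexize(T)
    r = vt.n_vertices
    P, Q = {}, {}
    for k in range(0, r // 2 + 1):
        P[k] = {}
        Q[k] = {}
        for edges in combinations(vt.edges, k):
            verts = [v for e in edges for v in e]
            if len(set(verts)) < 2 * k:
                continue  # not a matching
            term = {(0, 0): 1}
            for i in range(r):
                if i not in verts:
                    term = poly_mul(term, {(1, 0): 1, (0, 1): -vt.degrees[i]})
            P[k] = poly_add(P[k], term)
            if 0 not in verts:
                Q[k] = poly_add(Q[k], term)
    return P, Q


class TestMatchingProfile:
    def test_cherry_exact(self):
        prof = matching_profile(CHERRY)
        assert sp.expand(bi_to_expr(prof.P[0]) - (X - Y)**2 * (X - 2*Y)) == 0
        assert sp.expand(bi_to_expr(prof.P[1]) - 2 * (X - Y)) == 0
        assert prof.Q[0] == prof.P[0]
        assert prof.Q[1] == {}

    def test_p0_is_degree_product(self):
        for n in range(2, 7):
            for T in enumerate_shapes(n):
                vt = vertexize(T)
                expect = sp.expand(sp.prod([X - Y * d for d in vt.degrees]))
                assert sp.expand(bi_to_expr(matching_profile(T).P[0]) - expect) == 0

    @pytest.mark.parametrize("n", range(2, 8))
    def test_against_matching_enumeration(self, n):
        for T in enumerate_shapes(n):
            prof = matching_profile(T)
            P, Q = brute_force_profile(T)
            for k in range(len(prof.P)):
                assert prof.P[k] == P.get(k, {})
                assert prof.Q[k] == Q.get(k, {})

    def test_root_factor_divides_q(self):
        # the root is never matched in Q_k, so (x - 2y) divides every Q_k
        for T in enumerate_shapes(6):
            for qk in matching_profile(T).Q:
                if qk:
                    quot, rem = sp.div(bi_to_expr(qk), X - 2*Y, X)
                    assert rem == 0

    def test_vanishing_beyond_max_matching(self):
        for T in enumerate_shapes(5):
            prof = matching_profile(T)
            assert len(prof.P) - 1 <= T.n_vertices // 2


class TestGeneralizedCharpoly:
    def test_cherry(self):
        cp = generalized_charpoly(CHERRY)
        target = sp.expand((X - Y)**2 * (X - 2*Y) - 2 * Z**2 * (X - Y))
        assert sp.expand(tri_to_expr(cp.tri) - target) == 0
        assert cp.adjacency() == ExactPolynomial([0, -2, 0, 1])  # x^3 - 2x

    @pytest.mark.parametrize("n", range(2, 8))
    def test_equals_symbolic_determinant(self, n):
        for T in enumerate_shapes(n):
            cp = generalized_charpoly(T)
            assert sp.expand(tri_to_expr(cp.tri) - symbolic_glap_det(T)) == 0

    def test_monic_and_even_z(self):
        for T in enumerate_shapes(6):
            cp = generalized_charpoly(T)
            r = cp.degree
            assert cp.tri[(r, 0, 0)] == 1
            assert all(k % 2 == 0 for (_, _, k) in cp.tri)

    def test_trace_identity(self):
        # coefficient of x^{r-1}: -y * sum(d_i) = -y (4n - 4)
        for n in range(2, 9):
            for T in enumerate_shapes(n):
                cp = generalized_charpoly(T)
                assert cp.coeff_x(cp.degree - 1) == {(1, 0): -(4 * n - 4)}

    def test_fingerprint_is_function_of_polynomial(self, rng):
        from treespectra.matrices import _root_pq
        fp = GlapFingerprinter(seed=11)
        for n in range(2, 7):
            for T in enumerate_shapes(n):
                p, q = _root_pq(T)
                for pt, (pv, qv) in zip(fp.points, fp.profile_fingerprint(T)):
                    assert poly_eval(p, pt) == pv
                    assert poly_eval(q, pt) == qv


class TestDistanceMatrix:
    def test_cherry(self):
        assert distance_matrix(CHERRY).array.tolist() == [[0, 2], [2, 0]]

    def test_three_leaf(self):
        D = distance_matrix(enumerate_shapes(3)[0]).array
        assert sorted(map(sorted, D.tolist())) == sorted(map(sorted, [
            [0, 2, 3], [2, 0, 3], [3, 3, 0]]))

    def test_balanced_four(self):
        from treespectra.shapes import parse_newick
        D = distance_matrix(parse_newick("((,),(,));")).array
        assert D[0, 1] == 2 and D[2, 3] == 2
        assert D[0, 2] == D[0, 3] == D[1, 2] == D[1, 3] == 4

    def test_root_distances(self):
        assert root_distance_vector(CHERRY) == [1, 1]
        assert sorted(root_distance_vector(enumerate_shapes(3)[0])) == [1, 2, 2]
        from treespectra.shapes import parse_newick
        assert root_distance_vector(parse_newick("((,),(,));")) == [2, 2, 2, 2]

    def test_symmetry_and_bounds(self):
        for n in range(2, 9):
            for T in enumerate_shapes(n):
                D = distance_matrix(T).array
                assert (D == D.T).all()
                assert (np.diag(D) == 0).all()
                off = D[~np.eye(n, dtype=bool)]
                assert (off >= 2).all()

    def test_four_point_condition(self):
        for n in range(4, 9):
            for T in enumerate_shapes(n):
                assert distance_matrix(T).satisfies_four_point()

    def test_rejects_single_leaf(self):
        with pytest.raises(ValueError):
            distance_matrix(LEAF)


class TestLeverrierFaddeev:
    def test_identity(self):
        assert charpoly_leverrier_faddeev(np.eye(2, dtype=np.int64)) == \
            ExactPolynomial([1, -2, 1])

    def test_cherry_distance(self):
        assert charpoly_leverrier_faddeev([[0, 2], [2, 0]]) == \
            ExactPolynomial([-4, 0, 1])

    def test_against_cofactor_oracle_random_5x5(self, rng):
        for _ in range(10):
            M = [[rng.randint(-9, 9) for _ in range(5)] for _ in range(5)]
            lf = charpoly_leverrier_faddeev(M)
            # compare coefficient-by-coefficient via evaluation of det(xI - M)
            for x0 in range(-6, 7):
                shifted = [[x0 * (i == j) - M[i][j] for j in range(5)]
                           for i in range(5)]
                assert lf(x0) == cofactor_det(shifted)

    def test_constant_term_is_det(self, rng):
        # det(xI - M) at x = 0 equals (-1)^n det(M)
        for _ in range(5):
            n = rng.randint(2, 6)
            M = [[rng.randint(-5, 5) for _ in range(n)] for _ in range(n)]
            cp = charpoly_leverrier_faddeev(M)
            assert cp(0) == (-1) ** n * cofactor_det(M)

    def test_fraction_entries(self):
        M = [[Fraction(1, 2), Fraction(0)], [Fraction(0), Fraction(1, 2)]]
        cp = charpoly_leverrier_faddeev(M)
        assert cp(Fraction(1, 2)) == 0

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            charpoly_leverrier_faddeev([[1, 2, 3], [4, 5, 6]])


class TestBorderedCharpolys:
    def test_cherry_first_polynomial(self):
        ps = bordered_charpolys(CHERRY)
        assert ps[0] == ExactPolynomial([-4, 0, 1])

    def test_degrees(self):
        for T in enumerate_shapes(4):
            n = T.n_leaves
            degs = [p.degree for p in bordered_charpolys(T)]
            assert degs == [n, n + 1, n + 1, n + 1]

    def test_schur_complement_identity_three_leaf(self):
        """The non-symmetric bordered matrix [[A, a], [1', 0]] has charpoly
        det(xI - A) * (x - 1'(xI - A)^{-1} a)."""
        T = enumerate_shapes(3)[0]
        A = sp.Matrix(distance_matrix(T).array.tolist())
        a = sp.Matrix(root_distance_vector(T))
        ones = sp.ones(3, 1)
        lhs_poly = bordered_charpolys(T)[2]
        lhs = sum(c * X**i for i, c in enumerate(lhs_poly.coeffs))
        xIA = X * sp.eye(3) - A
        rhs = sp.expand(xIA.det() * (X - (ones.T * xIA.inv() * a)[0, 0]))
        assert sp.simplify(lhs - rhs) == 0

    def test_distance_charpoly_consistency(self):
        for T in enumerate_shapes(5):
            assert bordered_charpolys(T)[0] == distance_charpoly(T)
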