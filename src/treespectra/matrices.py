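"""Exact matrix invariants of tree shapes.

Four matrix representations of a shape with ``r = 2n - 1`` vertices are
handled here:

* the adjacency matrix ``A``,
* the Laplacian ``L = A - D`` (``D`` = diagonal of vertex degrees),
* the generalized Laplacian ``yD + zA`` with symbolic weights ``(y, z)``,
  which specializes to both of the above,
* the leaf-to-leaf distance matrix (path length in edges).

The characteristic polynomial of ``x I - (yD + zA)`` for a tree admits a
matching expansion: only permutations that are products of disjoint
transpositions along edges survive the determinant sum, so

    charpoly = sum_k (-1)^k z^{2k} P_k(x, y),
    P_k(x, y) = sum over k-matchings p of  prod_{i not in p} (x - y d_i),

where ``d_i`` is the degree of vertex ``i``.  ``Q_k`` is the same sum
restricted to matchings that avoid the root; the pair family ``{P_k, Q_k}``
is the exchange fingerprint of a shape: two equal-size shapes with identical
families can be swapped below any host tree without changing the host's
generalized Laplacian spectrum.

Everything is exact: polynomial coefficients are arbitrary-precision
integers, and characteristic polynomials of integer matrices go through an
integer-preserving Faddeev-LeVerrier recurrence.  No floating point touches
any "same spectrum" decision.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .polynomial import ExactPolynomial, poly_add, poly_eval, poly_mul, poly_scale
from .shapes import TreeShape, leaf_depths

__all__ = [
    "MatchingProfile",
    "GeneralizedCharPoly",
    "DistanceMatrix",
    "matching_profile",
    "generalized_charpoly",
    "distance_matrix",
    "root_distance_vector",
    "distance_charpoly",
    "charpoly_leverrier_faddeev",
    "bordered_charpolys",
    "GlapFingerprinter",
    "default_points",
]

# ---------------------------------------------------------------------------
# Matching recursion (symbolic)
# ---------------------------------------------------------------------------
# Trivariate polynomials are dicts {(x_pow, y_pow, m_pow): int} where the
# third variable m marks one matched edge pair (it stands for -z^2 up to the
# sign handled at specialization).  For a subtree attached below an edge the
# root has degree 3; the recursion tracks
#   Ubar = sum over matchings leaving the subtree root unmatched, WITHOUT the
#          root's own (x - y d) factor,
#   C    = sum over matchings covering the subtree root (full product).

_X = {(1, 0, 0): 1}


def _deg_factor(d: int) -> dict:
    return {(1, 0, 0): 1, (0, 1, 0): -d}


_ATTACHED: dict[TreeShape, tuple[dict, dict]] = {}


def _attached(u: TreeShape) -> tuple[dict, dict]:
    """(Ubar, C) for a subtree whose root is attached (degree 3 if internal)."""
    got = _ATTACHED.get(u)
    if got is not None:
        return got
    if u.is_leaf:
        out = ({(0, 0, 0): 1}, {})
    else:
        ua, ca = _attached(u.left)
        ub, cb = _attached(u.right)
        fa = poly_add(poly_mul(_deg_factor(1 if u.left.is_leaf else 3), ua), ca)
        fb = poly_add(poly_mul(_deg_factor(1 if u.right.is_leaf else 3), ub), cb)
        ubar = poly_mul(fa, fb)
        c = poly_scale(poly_add(poly_mul(ua, fb), poly_mul(fa, ub)), 1,
                       extra=(0, 0, 1))
        out = (ubar, c)
    _ATTACHED[u] = out
    return out


def _root_pq(T: TreeShape) -> tuple[dict, dict]:
    """Trivariate (P, Q) of a standalone shape (root degree 2)."""
    if T.n_leaves < 2:
        raise ValueError("matrix invariants need n_leaves >= 2")
    ua, ca = _attached(T.left)
    ub, cb = _attached(T.right)
    fa = poly_add(poly_mul(_deg_factor(1 if T.left.is_leaf else 3), ua), ca)
    fb = poly_add(poly_mul(_deg_factor(1 if T.right.is_leaf else 3), ub), cb)
    root = _deg_factor(2)
    q = poly_mul(root, poly_mul(fa, fb))
    c = poly_scale(poly_add(poly_mul(ua, fb), poly_mul(fa, ub)), 1,
                   extra=(0, 0, 1))
    return poly_add(q, c), q


@dataclass(frozen=True)
class MatchingProfile:
    """The exchange fingerprint ``{P_k, Q_k}`` of a shape.

    ``P[k]`` / ``Q[k]`` are bivariate polynomials in ``(x, y)`` as dicts
    ``{(x_pow, y_pow): int}``; ``P_k`` sums over all k-matchings, ``Q_k``
    over the root-avoiding ones, each matching weighted by the product of
    ``(x - y d_i)`` over uncovered vertices (standalone degrees: root 2,
    leaves 1, other internal vertices 3).
    """

    n_leaves: int
    P: tuple[dict, ...]
    Q: tuple[dict, ...]

    @property
    def max_k(self) -> int:
        return len(self.P) - 1

    def __eq__(self, other):
        if not isinstance(other, MatchingProfile):
            return NotImplemented
        return self.P == other.P and self.Q == other.Q

    def __hash__(self):
        return hash(tuple(frozenset(p.items()) for p in self.P))


def _split_matchvar(tri: dict) -> tuple[dict, ...]:
    kmax = max((e[2] for e in tri), default=0)
    out: list[dict] = [dict() for _ in range(kmax + 1)]
    for (i, j, k), c in tri.items():
        out[k][(i, j)] = c
    return tuple(out)


def matching_profile(T: TreeShape) -> MatchingProfile:
    """Exact ``{P_k, Q_k}`` family of ``T`` via the subtree recursion.

    Matchings are never enumerated; the doubly-indexed recursion over child
    subtrees produces all ``P_k`` at once.
    """
    p, q = _root_pq(T)
    pk = _split_matchvar(p)
    qk = _split_matchvar(q)
    qk = qk + ({},) * (len(pk) - len(qk))
    return MatchingProfile(T.n_leaves, pk, qk)


class GeneralizedCharPoly:
    """Characteristic polynomial of ``x I - (y D + z A)``, exact in (x,y,z).

    Monic of degree ``r = 2n - 1`` in ``x``; only even powers of ``z`` occur.
    Specializing ``(y, z) = (0, 1)`` gives the adjacency characteristic
    polynomial, ``(y, z) = (-1, 1)`` that of the Laplacian ``A - D``.
    """

    __slots__ = ("n_leaves", "tri")

    def __init__(self, n_leaves: int, tri: dict):
        self.n_leaves = n_leaves
        self.tri = tri  # {(x_pow, y_pow, z_pow): int}

    @property
    def degree(self) -> int:
        return 2 * self.n_leaves - 1

    def coeff_x(self, j: int) -> dict:
        """Coefficient of ``x^j`` as a ``{(y_pow, z_pow): int}`` polynomial."""
        return {(e[1], e[2]): c for e, c in self.tri.items() if e[0] == j}

    def specialize(self, y, z) -> ExactPolynomial:
        """Exact univariate charpoly in ``x`` at integer ``(y, z)``."""
        r = self.degree
        cs = [0] * (r + 1)
        for (i, j, k), c in self.tri.items():
            cs[i] += c * y ** j * z ** k
        return ExactPolynomial(cs)

    def adjacency(self) -> ExactPolynomial:
        return self.specialize(0, 1)

    def laplacian(self) -> ExactPolynomial:
        return self.specialize(-1, 1)

    def __eq__(self, other):
        if not isinstance(other, GeneralizedCharPoly):
            return NotImplemented
        return self.tri == other.tri

    def __hash__(self):
        return hash(frozenset(self.tri.items()))

    def __repr__(self):
        return f"GeneralizedCharPoly(n_leaves={self.n_leaves}, terms={len(self.tri)})"


def generalized_charpoly(T: TreeShape) -> GeneralizedCharPoly:
    """``det(x I - y D - z A)`` via the matching expansion (chi = sgn)."""
    p, _ = _root_pq(T)
    tri: dict = {}
    for (i, j, k), c in p.items():
        tri[(i, j, 2 * k)] = c if k % 2 == 0 else -c
    return GeneralizedCharPoly(T.n_leaves, tri)


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------

_DIST: dict[TreeShape, np.ndarray] = {}
_DEPTH: dict[TreeShape, np.ndarray] = {}


def _dist_arrays(u: TreeShape) -> tuple[np.ndarray, np.ndarray]:
    """(leaf-to-leaf distance matrix, leaf depth vector) of a shape, memoized."""
    d = _DIST.get(u)
    if d is not None:
        return d, _DEPTH[u]
    if u.is_leaf:
        D = np.zeros((1, 1), dtype=np.int64)
        h = np.zeros(1, dtype=np.int64)
    else:
        Da, ha = _dist_arrays(u.left)
        Db, hb = _dist_arrays(u.right)
        na, nb = len(ha), len(hb)
        D = np.empty((na + nb, na + nb), dtype=np.int64)
        D[:na, :na] = Da
        D[na:, na:] = Db
        cross = (ha + 1)[:, None] + (hb + 1)[None, :]
        D[:na, na:] = cross
        D[na:, :na] = cross.T
        h = np.concatenate([ha + 1, hb + 1])
    _DIST[u] = D
    _DEPTH[u] = h
    return D, h


@dataclass(frozen=True)
class DistanceMatrix:
    """Exact integer leaf-to-leaf distance matrix in canonical leaf order.

    Symmetric with zero diagonal; entries count edges on the unique path, so
    every off-diagonal entry is at least 2.  As an unweighted tree metric it
    satisfies the four-point condition.
    """

    array: np.ndarray

    @property
    def n_leaves(self) -> int:
        return self.array.shape[0]

    def charpoly(self) -> ExactPolynomial:
        return charpoly_leverrier_faddeev(self.array)

    def satisfies_four_point(self) -> bool:
        """Check max of the three pair sums is attained at least twice on
        every leaf quadruple."""
        D = self.array
        n = D.shape[0]
        from itertools import combinations
        for i, j, k, l in combinations(range(n), 4):
            sums = sorted((int(D[i, j] + D[k, l]),
                           int(D[i, k] + D[j, l]),
                           int(D[i, l] + D[j, k])))
            if sums[1] != sums[2]:
                return False
        return True


def distance_matrix(T: TreeShape) -> DistanceMatrix:
    """Leaf-to-leaf path lengths of ``T`` (``n_leaves >= 2``)."""
    if T.n_leaves < 2:
        raise ValueError("distance matrix needs n_leaves >= 2")
    D, _ = _dist_arrays(T)
    return DistanceMatrix(D.copy())


def root_distance_vector(S: TreeShape) -> list[int]:
    """Edge distances from each leaf to the root, canonical leaf order."""
    return leaf_depths(S)


# ---------------------------------------------------------------------------
# Characteristic polynomials of exact matrices
# ---------------------------------------------------------------------------

def charpoly_leverrier_faddeev(M) -> ExactPolynomial:
    """Exact characteristic polynomial ``det(x I - M)`` by Faddeev-LeVerrier.

    ``M`` may be any square matrix of ints (or Fractions); non-symmetric
    matrices are fine.  The recurrence ``N_k = M N_{k-1} + c_{k-1} I``,
    ``c_k = -tr(M N_{k-1}) / k`` stays integral for integer input (each
    ``N_k`` is an integer polynomial in ``M``), so the trace division is
    exact and everything runs over plain Python ints.
    """
    A = [[_as_exact(v) for v in row] for row in np.asarray(M, dtype=object)]
    n = len(A)
    if any(len(row) != n for row in A):
        raise ValueError("matrix must be square")
    # coefficients c_0..c_n of x^n, x^{n-1}, ..., x^0 (c_0 = 1)
    cs = [1]
    N = [[1 if i == j else 0 for j in range(n)] for i in range(n)]
    for k in range(1, n + 1):
        AN = [[sum(A[i][l] * N[l][j] for l in range(n)) for j in range(n)]
              for i in range(n)]
        tr = sum(AN[i][i] for i in range(n))
        ck = -_exact_div(tr, k)
        cs.append(ck)
        if k < n:
            N = [[AN[i][j] + (ck if i == j else 0) for j in range(n)]
                 for i in range(n)]
    return ExactPolynomial(list(reversed(cs)))


def _as_exact(v):
    if isinstance(v, (int, np.integer)):
        return int(v)
    if isinstance(v, Fraction):
        return v
    raise TypeError(f"exact matrix entries must be int or Fraction, got {type(v)}")


def _exact_div(v, k: int):
    if isinstance(v, int):
        q, r = divmod(v, k)
        assert r == 0, "Faddeev-LeVerrier trace not divisible; non-integer input?"
        return q
    return v / k


def distance_charpoly(T: TreeShape) -> ExactPolynomial:
    """Exact charpoly of the leaf-to-leaf distance matrix of ``T``."""
    return charpoly_leverrier_faddeev(distance_matrix(T).array)


def bordered_charpolys(S: TreeShape) -> tuple[ExactPolynomial, ...]:
    """The four spectra entering the distance-matrix exchange criterion.

    For ``A`` = distance matrix of ``S``, ``a`` = leaf-to-root distances and
    ``1`` = all-ones, returns the exact characteristic polynomials of::

        A,   [[A, a], [a', 0]],   [[A, a], [1', 0]],   [[A, 1], [1', 0]]

    (the third is non-symmetric whenever ``a != 1``).  If all four agree
    between two equal-size shapes, swapping them below any common host leaves
    the host's distance spectrum unchanged.
    """
    A = distance_matrix(S).array
    a = np.array(root_distance_vector(S), dtype=np.int64)
    ones = np.ones(len(a), dtype=np.int64)

    def border(col, row):
        n = len(a)
        M = np.zeros((n + 1, n + 1), dtype=np.int64)
        M[:n, :n] = A
        M[:n, n] = col
        M[n, :n] = row
        return M

    return (charpoly_leverrier_faddeev(A),
            charpoly_leverrier_faddeev(border(a, a)),
            charpoly_leverrier_faddeev(border(a, ones)),
            charpoly_leverrier_faddeev(border(ones, ones)))


# ---------------------------------------------------------------------------
# Seeded exact fingerprints
# ---------------------------------------------------------------------------

def default_points(seed: int = 0, count: int = 3) -> tuple[tuple[int, int, int], ...]:
    """Seeded integer evaluation points ``(x0, y0, m0)`` for fingerprinting."""
    rng = random.Random(seed)
    pts = []
    for _ in range(count):
        pts.append((rng.randrange(5, 64), rng.randrange(3, 48),
                    rng.randrange(2, 32)))
    return tuple(pts)


class GlapFingerprinter:
    """Exact integer fingerprints of generalized-Laplacian invariants.

    Evaluates the trivariate ``P`` (and ``Q``) polynomials at fixed integer
    points via the same subtree recursion, memoized per shape — near-linear
    over a census because enumerated shapes share subtrees heavily.  A
    fingerprint is a function of the exact polynomial, so distinct
    fingerprints prove distinct polynomials; equal fingerprints are only ever
    trusted after exact confirmation by the caller.
    """

    def __init__(self, points=None, seed: int = 0):
        self.points = tuple(points) if points is not None else default_points(seed)
        self._memo: dict[TreeShape, tuple] = {}

    def _eval_attached(self, u: TreeShape) -> tuple:
        got = self._memo.get(u)
        if got is not None:
            return got
        if u.is_leaf:
            out = tuple((1, 0, x - y) for (x, y, m) in self.points)
        else:
            va = self._eval_attached(u.left)
            vb = self._eval_attached(u.right)
            out = []
            for (x, y, m), (ua, ca, fa), (ub, cb, fb) in zip(self.points, va, vb):
                ubar = fa * fb
                c = m * (ua * fb + fa * ub)
                f = (x - 3 * y) * ubar + c
                out.append((ubar, c, f))
            out = tuple(out)
        self._memo[u] = out
        return out

    def _root_values(self, T: TreeShape) -> tuple:
        if T.n_leaves < 2:
            raise ValueError("fingerprint needs n_leaves >= 2")
        va = self._eval_attached(T.left)
        vb = self._eval_attached(T.right)
        out = []
        for (x, y, m), (ua, ca, fa), (ub, cb, fb) in zip(self.points, va, vb):
            q = (x - 2 * y) * fa * fb
            p = q + m * (ua * fb + fa * ub)
            out.append((p, q))
        return tuple(out)

    def charpoly_fingerprint(self, T: TreeShape) -> tuple[int, ...]:
        """Fingerprint of the generalized-Laplacian characteristic polynomial."""
        return tuple(p for p, _ in self._root_values(T))

    def profile_fingerprint(self, T: TreeShape) -> tuple[tuple[int, int], ...]:
        """Fingerprint of the full ``{P_k, Q_k}`` exchange family."""
        return self._root_values(T)
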