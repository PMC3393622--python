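"""Symmetric-group characters and immanantal polynomials of tree matrices.

The immanant generalizes the determinant by replacing ``sgn`` with any
irreducible character ``chi_lambda`` of ``S_r``::

    I_chi(A) = sum_sigma chi(sigma) prod_i a_{i,sigma(i)}

and the immanantal polynomial is ``x -> I_chi(x I - M)``.  For the
generalized Laplacian of a tree only permutations that are products of
disjoint transpositions along edges contribute, so the immanantal polynomial
collapses to the matching expansion

    sum_k chi(C_k) z^{2k} P_k(x, y)

with ``C_k`` the conjugacy class of k disjoint transpositions and ``P_k``
the matching sums computed by :func:`treespectra.matrices.matching_profile`.
Since ``sgn(C_k) = (-1)^k`` is never zero, equal characteristic polynomials
force equal ``P_k`` for every k, hence equal immanantal polynomials for every
character: for these matrices the full immanantal family carries exactly the
same information as the spectrum.

Characters are evaluated with the Murnaghan-Nakayama rule (recursive
border-strip removal), memoized on ``(partition, remaining cycle type)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from math import factorial, prod

from .matrices import MatchingProfile, matching_profile
from .polynomial import ExactPolynomial
from .shapes import TreeShape, vertexize

__all__ = [
    "partitions",
    "murnaghan_nakayama",
    "character_on_transposition_class",
    "conjugacy_class_size",
    "ImmanantalPolynomial",
    "immanantal_polynomial",
    "brute_force_immanant",
    "symbolic_glap_matrix",
    "distance_immanantal_polynomial",
]


def partitions(r: int):
    """Integer partitions of ``r`` in reverse-lexicographic order.

    Yields non-increasing tuples; ``(r,)`` first, ``(1,)*r`` last.
    """
    if r == 0:
        yield ()
        return

    def rec(remaining: int, cap: int, prefix: tuple[int, ...]):
        if remaining == 0:
            yield prefix
            return
        for part in range(min(cap, remaining), 0, -1):
            yield from rec(remaining - part, part, prefix + (part,))

    yield from rec(r, r, ())


@lru_cache(maxsize=None)
def murnaghan_nakayama(lam: tuple[int, ...], rho: tuple[int, ...]) -> int:
    """Character value ``chi_lambda`` on the class of cycle type ``rho``.

    Both arguments are partitions of the same integer (``rho`` lists cycle
    lengths, fixed points included).  Recursive border-strip (rim hook)
    removal: for the first cycle length ``t``, sum ``(-1)^height`` over all
    ways to strip a length-``t`` border strip from ``lam``.
    """
    if sum(lam) != sum(rho):
        raise ValueError("partition and cycle type must have equal size")
    if not rho:
        return 1
    t, rest = rho[0], rho[1:]
    total = 0
    k = len(lam)
    # border strips correspond to beta-numbers: lam_i + (k - 1 - i); removing
    # a strip of size t means decreasing one beta-number by t, staying distinct
    beta = [lam[i] + (k - 1 - i) for i in range(k)]
    beta_set = set(beta)
    for i in range(k):
        nb = beta[i] - t
        if nb < 0 or nb in beta_set:
            continue
        new_beta = sorted((b for b in beta if b != beta[i]), reverse=True)
        # height = number of beta entries jumped over
        height = sum(1 for b in beta if nb < b < beta[i])
        new_beta.append(nb)
        new_beta.sort(reverse=True)
        m = len(new_beta)
        new_lam = tuple(new_beta[j] - (m - 1 - j) for j in range(m))
        new_lam = tuple(p for p in new_lam if p > 0)
        sign = -1 if height % 2 else 1
        total += sign * murnaghan_nakayama(new_lam, rest)
    return total


def character_on_transposition_class(lam, k: int) -> int:
    """``chi_lambda(C_k)``: the character on products of ``k`` disjoint
    transpositions (all other points fixed).

    Requires ``2k <= r`` where ``r = sum(lam)``.  ``lam = (1,)*r`` gives
    ``(-1)^k`` (sign character), ``lam = (r,)`` gives 1 (trivial).
    """
    lam = tuple(sorted(lam, reverse=True))
    r = sum(lam)
    if 2 * k > r:
        raise ValueError(f"C_{k} does not exist in S_{r}")
    rho = (2,) * k + (1,) * (r - 2 * k)
    return murnaghan_nakayama(lam, rho)


def conjugacy_class_size(rho: tuple[int, ...]) -> int:
    """Size of the conjugacy class of cycle type ``rho`` in ``S_sum(rho)``."""
    r = sum(rho)
    cent = 1
    from collections import Counter
    for length, mult in Counter(rho).items():
        cent *= length ** mult * factorial(mult)
    return factorial(r) // cent


@dataclass(frozen=True)
class ImmanantalPolynomial:
    """``I_chi(x I - (yD + zA))`` of a tree for character partition ``lam``.

    ``tri`` maps ``(x_pow, y_pow, z_pow)`` to integer coefficients; only even
    z-powers occur.  ``lam = (1,)*r`` reproduces the characteristic
    polynomial; ``lam = (r,)`` is the permanental analogue.
    """

    lam: tuple[int, ...]
    n_leaves: int
    tri: dict

    def specialize(self, y: int, z: int) -> ExactPolynomial:
        r = 2 * self.n_leaves - 1
        cs = [0] * (r + 1)
        for (i, j, k), c in self.tri.items():
            cs[i] += c * y ** j * z ** k
        return ExactPolynomial(cs)

    def __eq__(self, other):
        if not isinstance(other, ImmanantalPolynomial):
            return NotImplemented
        return self.lam == other.lam and self.tri == other.tri


def immanantal_polynomial(T: TreeShape, lam) -> ImmanantalPolynomial:
    """Generalized Laplacian immanantal polynomial of ``T`` for ``chi_lam``.

    ``sum(lam)`` must equal the vertex count ``2 n - 1``; the result reuses
    the matching profile, weighting ``P_k`` by ``chi_lam(C_k) z^{2k}``.
    """
    lam = tuple(sorted(lam, reverse=True))
    r = T.n_vertices
    if sum(lam) != r:
        raise ValueError(f"partition of {sum(lam)} does not match {r} vertices")
    prof = matching_profile(T)
    tri: dict = {}
    for k, pk in enumerate(prof.P):
        chi = character_on_transposition_class(lam, k)
        if chi == 0:
            continue
        for (i, j), c in pk.items():
            key = (i, j, 2 * k)
            v = tri.get(key, 0) + chi * c
            if v:
                tri[key] = v
            else:
                del tri[key]
    return ImmanantalPolynomial(lam, T.n_leaves, tri)


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def _cycle_type(perm: tuple[int, ...]) -> tuple[int, ...]:
    n = len(perm)
    seen = [False] * n
    lens = []
    for i in range(n):
        if seen[i]:
            continue
        l, j = 0, i
        while not seen[j]:
            seen[j] = True
            j = perm[j]
            l += 1
        lens.append(l)
    return tuple(sorted(lens, reverse=True))


def brute_force_immanant(M, lam, mul=None, add=None):
    """Literal permutation-sum immanant of a small square matrix.

    ``M`` is a nested sequence; entries may be ints or sparse polynomial
    dicts (see :mod:`treespectra.polynomial`), in which case ``mul``/``add``
    default to the dict polynomial operations.  Refuses dimensions above 8
    (factorial cost); this is a test oracle, not a production path.
    """
    n = len(M)
    if n > 8:
        raise ValueError("brute-force immanant limited to dimension <= 8")
    lam = tuple(sorted(lam, reverse=True))
    if sum(lam) != n:
        raise ValueError("partition size must equal matrix dimension")
    entries_are_ints = all(isinstance(M[i][j], int) for i in range(n) for j in range(n))
    if entries_are_ints:
        total = 0
        for perm in permutations(range(n)):
            term = prod(M[i][perm[i]] for i in range(n))
            if term:
                total += murnaghan_nakayama(lam, _cycle_type(perm)) * term
        return total
    from .polynomial import poly_add, poly_mul, poly_scale
    mul = mul or poly_mul
    add = add or poly_add
    total: dict = {}
    for perm in permutations(range(n)):
        term = None
        zero = False
        for i in range(n):
            e = M[i][perm[i]]
            if not e:
                zero = True
                break
            term = dict(e) if term is None else mul(term, e)
        if zero:
            continue
        chi = murnaghan_nakayama(lam, _cycle_type(perm))
        if chi:
            total = add(total, poly_scale(term, chi))
    return total


def symbolic_glap_matrix(T: TreeShape) -> list[list[dict]]:
    """``x I - (y D + z A)`` with sparse-dict entries in ``(x, y, z)``.

    Vertex order follows :func:`treespectra.shapes.vertexize`; intended as
    input to :func:`brute_force_immanant`.
    """
    vt = vertexize(T)
    r = vt.n_vertices
    M: list[list[dict]] = [[{} for _ in range(r)] for _ in range(r)]
    for i, d in enumerate(vt.degrees):
        M[i][i] = {(1, 0, 0): 1, (0, 1, 0): -d}
    for a, b in vt.edges:
        M[a][b] = {(0, 0, 1): -1}
        M[b][a] = {(0, 0, 1): -1}
    return M


def distance_immanantal_polynomial(T: TreeShape, lam) -> dict:
    """Exploratory: immanantal polynomial of the leaf-to-leaf distance matrix.

    Whether these add distinguishing power over the distance spectrum is an
    open question; this helper merely computes them (brute force, so only
    small trees).  Returns a sparse dict in the single variable ``x``.
    """
    from .matrices import distance_matrix

    D = distance_matrix(T).array
    n = len(D)
    if n > 8:
        raise ValueError("exploratory brute force limited to 8 leaves")
    M = [[({(1,): 1, (0,): -int(D[i][j])} if i == j else {(0,): -int(D[i][j])})
          if (i == j or D[i][j]) else {} for j in range(n)] for i in range(n)]
    # diagonal of x I - D is x (D has zero diagonal)
    for i in range(n):
        M[i][i] = {(1,): 1}
    return brute_force_immanant(M, lam)
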