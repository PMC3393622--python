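"""Exact counting of rooted binary tree shapes and their asymptotics.

The number of unlabeled rooted binary tree shapes with ``n`` leaves is the
Wedderburn-Etherington number ``t_n``.  Decomposing a shape into the two
subtrees hanging off the root gives the convolution recursion

    sum_{i=1}^{n-1} t_i t_{n-i} = 2 t_n - t_{n/2}        (t_{n/2} := 0, n odd)

which this module iterates with exact integers.  The same recursion, corrected
at a single index, counts shapes avoiding a fixed set of forbidden rooted
subtrees of one size: if ``m`` shapes of size ``a`` are forbidden, the avoider
counts ``s_n`` satisfy the identical convolution except ``s_a = t_a - m``
(a shape is a subtree of itself, so the forbidden shapes themselves drop out
at ``n = a``).  Remarkably ``s_n`` depends only on ``(a, m)``, not on which
shapes of size ``a`` are forbidden.

The generating function ``f(x) = sum t_n x^n`` has radius of convergence
``rho = 0.402698...``; writing ``g = 1 - f`` and ``h(x) = g(x)/x``, the
functional equation ``h(x^2) = 2 + h(x)^2`` yields ``1/rho`` as the limit of
the iterated maps

    q_n(0) = w_{n-1} o ... o w_0 (0),    w_k(u) = (2 + u^(2^k))^(2^-k),

and ``t_n ~ eta * rho^-n * n^(-3/2)`` with ``eta = 0.7916032...``.  For
avoiders the maps acquire a penalty term ``-2 xi^(2^k)`` with
``xi = rho_a^(a-1)``, turning the avoider radius ``rho_a`` into a fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache

import mpmath

__all__ = [
    "count_trees",
    "count_avoiders",
    "avoider_fraction",
    "radius_of_convergence",
    "avoider_radius",
    "eta_estimate",
    "AsymptoticConstants",
    "ConvergenceError",
]


class ConvergenceError(RuntimeError):
    """An iterative scheme failed to converge within its budget."""


# ---------------------------------------------------------------------------
# Exact integer sequences
# ---------------------------------------------------------------------------

def count_trees(n_max: int) -> list[int]:
    """Wedderburn-Etherington numbers ``[t_1, ..., t_n_max]`` (exact).

    ``t_n = (sum_{i=1}^{n-1} t_i t_{n-i} + t_{n/2}) / 2`` with the convention
    ``t_{n/2} = 0`` for odd ``n``.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    t = [0] * (n_max + 1)
    t[1] = 1
    for n in range(2, n_max + 1):
        # exploit symmetry of the convolution: sum_{i<n/2} 2 t_i t_{n-i} (+ t_{n/2}^2)
        conv2 = sum(t[i] * t[n - i] for i in range(1, (n + 1) // 2))  # half-sum
        if n % 2 == 0:
            total = 2 * conv2 + t[n // 2] * t[n // 2] + t[n // 2]
        else:
            total = 2 * conv2
        assert total % 2 == 0
        t[n] = total // 2
    return t[1:]


@lru_cache(maxsize=8)
def _cached_counts(n_max: int) -> tuple[int, ...]:
    return tuple(count_trees(n_max))


def n_shapes(n: int) -> int:
    """``t_n``, the number of shapes with ``n`` leaves."""
    return _cached_counts(max(n, 64))[n - 1]


def count_avoiders(n_max: int, a: int, m: int = 1) -> list[int]:
    """Counts ``[s_1, ..., s_n_max]`` of shapes avoiding forbidden subtrees.

    ``m`` distinct shapes of size ``a`` are forbidden; ``s_n`` counts the
    ``n``-leaf shapes containing none of them as a rooted subtree.  The
    convolution recursion for ``t_n`` carries over verbatim except at
    ``n = a`` where ``s_a = t_a - m``.

    Parameters
    ----------
    n_max : largest leaf count.
    a : leaf count of the forbidden shapes (``a >= 2``).
    m : how many shapes of size ``a`` are forbidden (``1 <= m <= t_a``).
    """
    if a < 2:
        raise ValueError("forbidden subtree size a must be >= 2")
    t_a = n_shapes(a) if a <= 64 else count_trees(a)[-1]
    if not 1 <= m <= t_a:
        raise ValueError(f"m must satisfy 1 <= m <= t_a = {t_a}")
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    s = [0] * (n_max + 1)
    if n_max >= 1:
        s[1] = 1
    for n in range(2, n_max + 1):
        conv = sum(s[i] * s[n - i] for i in range(1, n))
        half = s[n // 2] if n % 2 == 0 else 0
        total = conv + half
        assert total % 2 == 0
        s[n] = total // 2
        if n == a:
            s[n] -= m
    return s[1:]


def avoider_fraction(n_max: int, a: int, m: int = 1) -> list[Fraction]:
    """Exact fractions ``s_n / t_n`` for ``n = 1..n_max``.

    Equal to 1 below the forbidden size and monotonically decreasing beyond
    it; tends to zero, which is what makes shared spectra generic in large
    trees.
    """
    t = count_trees(n_max)
    s = count_avoiders(n_max, a, m)
    return [Fraction(sn, tn) for sn, tn in zip(s, t)]


# ---------------------------------------------------------------------------
# Asymptotic constants
# ---------------------------------------------------------------------------

@dataclass
class AsymptoticConstants:
    """High-precision asymptotic constants with iteration diagnostics."""

    rho: mpmath.mpf
    eta: mpmath.mpf | None = None
    rho_a: mpmath.mpf | None = None
    iterations: int = 0
    tolerance: float = 0.0


def _q_limit(xi, dps: int, tol, max_iter: int = 2000):
    """Limit of q_n(0) for the (possibly penalised) iterated maps.

    ``xi = 0`` gives the plain maps ``w_k(u) = (2 + u^(2^k))^(2^-k)`` whose
    limit is ``1/rho``; ``xi > 0`` gives ``w_{k,a,xi}`` with the ``-2 xi^(2^k)``
    penalty, whose limit is ``1/rho_a`` at the self-consistent ``xi``.
    """
    with mpmath.workdps(dps):
        u = mpmath.mpf(0)
        prev = None
        for k in range(max_iter):
            p = mpmath.mpf(2) ** k
            base = 2 - 2 * (xi ** p) + u ** p
            if base <= 0:
                raise ConvergenceError(
                    f"iterated map left its domain at k={k} (xi={xi})")
            u = base ** (1 / p)
            if prev is not None and abs(u - prev) < tol:
                return u, k + 1
            prev = u
        raise ConvergenceError(f"q_n(0) did not converge in {max_iter} steps")


def radius_of_convergence(n_iter: int | None = None, dps: int = 60,
                          tol: float | None = None) -> AsymptoticConstants:
    """Radius of convergence ``rho`` of ``sum t_n x^n`` via the q_n iteration.

    Returns ``1/lim q_n(0)``.  The iterates ``q_1(0) = 2, q_2(0) = sqrt(6),
    ...`` increase monotonically and converge doubly exponentially, so a few
    dozen steps give far more digits than double precision can hold; the
    default stops when successive iterates agree to ``10^-(dps-10)``.
    """
    with mpmath.workdps(dps):
        tol_ = mpmath.mpf(10) ** -(dps - 10) if tol is None else mpmath.mpf(tol)
        if n_iter is not None:
            u = mpmath.mpf(0)
            for k in range(n_iter):
                p = mpmath.mpf(2) ** k
                u = (2 + u ** p) ** (1 / p)
            return AsymptoticConstants(rho=1 / u, iterations=n_iter,
                                       tolerance=float(tol_))
        u, its = _q_limit(mpmath.mpf(0), dps, tol_)
        return AsymptoticConstants(rho=1 / u, iterations=its,
                                   tolerance=float(tol_))


def avoider_radius(a: int, dps: int = 60,
                   max_outer: int = 200) -> AsymptoticConstants:
    """Self-consistent radius ``rho_a`` for shapes avoiding one size-``a`` subtree.

    Solves the fixed point ``1/rho_a = lim q_{n,a,xi}(0)`` with
    ``xi = rho_a^(a-1)`` by a secant iteration on
    ``F(xi) = (1/q_lim(xi))^(a-1) - xi`` starting from ``xi = rho^(a-1)``
    (plain damped iteration contracts too slowly for small ``a``).
    ``rho_a > rho`` strictly, which is the engine of the vanishing avoider
    fraction.
    """
    if a < 2:
        raise ValueError("a must be >= 2")
    with mpmath.workdps(dps):
        tol = mpmath.mpf(10) ** -(dps - 15)
        rho = radius_of_convergence(dps=dps).rho

        def rho_a_of(xi):
            u, _ = _q_limit(xi, dps, tol)
            return 1 / u

        def F(xi):
            return rho_a_of(xi) ** (a - 1) - xi

        x0 = rho ** (a - 1)
        x1 = x0 * mpmath.mpf("1.01")
        f0, f1 = F(x0), F(x1)
        for outer in range(max_outer):
            if f1 == f0:
                break
            x2 = x1 - f1 * (x1 - x0) / (f1 - f0)
            x0, f0, x1 = x1, f1, x2
            f1 = F(x1)
            if abs(x1 - x0) < tol * max(abs(x1), 1):
                rho_a = rho_a_of(x1)
                if not rho < rho_a < 1:
                    raise ConvergenceError(
                        f"rho_a fixed point left (rho, 1): {rho_a}")
                return AsymptoticConstants(rho=rho, rho_a=rho_a,
                                           iterations=outer + 1,
                                           tolerance=float(tol))
        raise ConvergenceError(
            f"rho_a fixed point did not converge in {max_outer} secant steps")


def eta_estimate(n_max: int = 5000, dps: int = 60,
                 t: list[int] | None = None) -> AsymptoticConstants:
    """The growth constant ``eta`` of ``t_n ~ eta * n^(-3/2) * rho^(-(n-1))``.

    Computes exact ``t_n`` up to ``n_max``, forms
    ``a_n = n^(3/2) rho^(n-1) t_n`` in high precision, and removes the
    leading ``c/n`` correction by Richardson extrapolation ``2 a_{2n} - a_n``
    over the top of the range (one further level knocks out ``1/n^2``).
    The ``rho^(n-1)`` normalization is the one under which the literature
    value 0.7916032... of this constant is quoted; the limit of
    ``n^(3/2) rho^n t_n`` is ``eta * rho = 0.3187766...``.
    """
    if n_max < 100:
        raise ValueError("n_max must be >= 100 for a stable extrapolation")
    if t is None:
        t = count_trees(n_max)
    with mpmath.workdps(dps):
        rho = radius_of_convergence(dps=dps).rho

        def a(n: int):
            return mpmath.mpf(n) ** mpmath.mpf("1.5") * rho ** (n - 1) * t[n - 1]

        n = n_max
        a1, a2, a4 = a(n // 4), a(n // 2), a(n)
        r1 = 2 * a2 - a1          # kills the 1/n term
        r2 = 2 * a4 - a2
        eta = (4 * r2 - r1) / 3   # kills the 1/n^2 term
        return AsymptoticConstants(rho=rho, eta=eta, iterations=n_max)
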