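"""Minimal exact sparse polynomial arithmetic over the integers.

Multivariate polynomials are plain dicts mapping exponent tuples to nonzero
integer coefficients; the tiny function set below (add, multiply, scale,
evaluate) is all the matching recursions need, and keeping the representation
primitive keeps the hot loops fast.  Univariate polynomials with a public
face (characteristic polynomials) get the small :class:`ExactPolynomial`
wrapper with JSON export.
"""

from __future__ import annotations

from typing import Mapping

__all__ = ["poly_add", "poly_mul", "poly_scale", "poly_eval", "ExactPolynomial"]

Poly = dict  # exponent tuple -> int coefficient


def poly_add(p: Poly, q: Poly) -> Poly:
    out = dict(p)
    for e, c in q.items():
        s = out.get(e, 0) + c
        if s:
            out[e] = s
        else:
            out.pop(e, None)
    return out


def poly_mul(p: Poly, q: Poly) -> Poly:
    if len(p) > len(q):
        p, q = q, p
    out: Poly = {}
    get = out.get
    for e1, c1 in p.items():
        for e2, c2 in q.items():
            e = tuple(a + b for a, b in zip(e1, e2))
            s = get(e, 0) + c1 * c2
            if s:
                out[e] = s
            else:
                del out[e]
    return out


def poly_scale(p: Poly, c: int, extra: tuple[int, ...] | None = None) -> Poly:
    """``c * p``, optionally shifted by the monomial with exponents ``extra``."""
    if c == 0:
        return {}
    if extra is None:
        return {e: c * v for e, v in p.items()}
    return {tuple(a + b for a, b in zip(e, extra)): c * v for e, v in p.items()}


def poly_eval(p: Poly, point: tuple[int, ...]) -> int:
    """Exact evaluation at an integer point."""
    total = 0
    for e, c in p.items():
        term = c
        for exp, x in zip(e, point):
            if exp:
                term *= x ** exp
        total += term
    return total


class ExactPolynomial:
    """Univariate polynomial in ``x`` with exact integer coefficients.

    ``coeffs[i]`` is the coefficient of ``x^i``.  Characteristic polynomials
    produced by this package are monic of degree = matrix dimension.
    """

    __slots__ = ("coeffs",)

    def __init__(self, coeffs):
        cs = list(coeffs)
        while cs and cs[-1] == 0:
            cs.pop()
        self.coeffs = tuple(cs)

    @property
    def degree(self) -> int:
        return len(self.coeffs) - 1

    def __call__(self, x):
        acc = 0
        for c in reversed(self.coeffs):
            acc = acc * x + c
        return acc

    def __eq__(self, other):
        if isinstance(other, ExactPolynomial):
            return self.coeffs == other.coeffs
        return NotImplemented

    def __hash__(self):
        return hash(self.coeffs)

    def __repr__(self):
        terms = [f"{c}*x^{i}" for i, c in enumerate(self.coeffs) if c]
        return "ExactPolynomial(" + (" + ".join(reversed(terms)) or "0") + ")"

    def to_json(self) -> Mapping[str, int]:
        """``{power: coefficient}`` with zero coefficients omitted."""
        return {str(i): c for i, c in enumerate(self.coeffs) if c}

    @classmethod
    def from_json(cls, d: Mapping[str, int]) -> "ExactPolynomial":
        if not d:
            return cls([])
        n = max(int(k) for k in d)
        cs = [0] * (n + 1)
        for k, v in d.items():
            cs[int(k)] = v
        return cls(cs)
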