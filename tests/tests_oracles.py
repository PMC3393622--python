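"""Independent oracles shared across the test suite.

These deliberately avoid the package's own recursions: determinants come
from sympy's dense domain elimination or literal cofactor expansion, and
matching families from explicit edge-subset enumeration.
"""

import sympy as sp

from treespectra.shapes import vertexize

X, Y, Z = sp.symbols("x y z")


def tri_to_expr(tri):
    return sum(c * X**i * Y**j * Z**k for (i, j, k), c in tri.items())


def bi_to_expr(bi):
    return sum(c * X**i * Y**j for (i, j), c in bi.items())


def symbolic_glap_det(T):
    """det(x I - yD - zA) over ZZ[x,y,z] via sympy's DomainMatrix."""
    from sympy.polys.matrices import DomainMatrix

    vt = vertexize(T)
    r = vt.n_vertices
    M = sp.zeros(r)
    for i in range(r):
        M[i, i] = X - Y * vt.degrees[i]
    for a, b in vt.edges:
        M[a, b] = -Z
        M[b, a] = -Z
    return sp.expand(DomainMatrix.from_Matrix(M).det().as_expr())


def cofactor_det(M):
    """Literal first-row cofactor expansion (exact, exponential)."""
    n = len(M)
    if n == 1:
        return M[0][0]
    total = 0
    for j in range(n):
        if M[0][j] == 0:
            continue
        minor = [row[:j] + row[j + 1:] for row in M[1:]]
        total += (-1) ** j * M[0][j] * cofactor_det(minor)
    return total
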