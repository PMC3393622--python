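"""Exchange-property detection for subtree substitution.

Two equal-size shapes ``S1, S2`` have the *exchange property* for a matrix
representation when swapping ``S1`` for ``S2`` below any host tree preserves
the host's spectrum for that representation.  Two sufficient criteria are
implemented:

* generalized Laplacian: ``P_k(S1) = P_k(S2)`` and ``Q_k(S1) = Q_k(S2)`` for
  all k (matchings through the connecting edge and matchings avoiding it
  contribute identically);
* distance matrix: the four spectra of ``A``, ``[[A,a],[a',0]]``,
  ``[[A,a],[1',0]]`` and ``[[A,1],[1',0]]`` agree (``A`` = distance matrix,
  ``a`` = leaf-to-root distances), which by the bordered-determinant identity
  makes the host's distance characteristic polynomial insensitive to the swap.

"Same spectrum" is decided as exact equality of characteristic polynomials
throughout — equivalent for fixed-size matrices and free of numerics.

The smallest pair satisfying either criterion has 17 leaves, and it is the
same pair for both — an unexplained coincidence this module merely
re-verifies by exhaustive search.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from . import matrices as mx
from .matrices import (GlapFingerprinter, bordered_charpolys, default_points,
                       distance_charpoly, generalized_charpoly, matching_profile)
from .shapes import TreeShape, enumerate_shapes, glue_at_leaf

__all__ = [
    "MatrixKind",
    "lemma3_equal",
    "lemma4_equal",
    "verify_exchange",
    "smallest_exchange_pair",
    "ExchangePair",
]

MatrixKind = Literal["generalized_laplacian", "distance"]


def _check_same_size(S1: TreeShape, S2: TreeShape) -> None:
    if S1.n_leaves != S2.n_leaves:
        raise ValueError(
            f"shapes must have equal leaf counts ({S1.n_leaves} != {S2.n_leaves})")


def lemma3_equal(S1: TreeShape, S2: TreeShape) -> bool:
    """Exchange criterion for the generalized Laplacian: exact equality of
    the full ``{P_k, Q_k}`` matching-polynomial families."""
    _check_same_size(S1, S2)
    return matching_profile(S1) == matching_profile(S2)


def lemma4_equal(S1: TreeShape, S2: TreeShape) -> bool:
    """Exchange criterion for the distance matrix: exact equality of the
    four bordered characteristic polynomials."""
    _check_same_size(S1, S2)
    return bordered_charpolys(S1) == bordered_charpolys(S2)


def verify_exchange(S1: TreeShape, S2: TreeShape, R: TreeShape,
                    leaf_position: int, matrix_kind: MatrixKind) -> bool:
    """Direct substitution oracle, independent of the criteria above.

    Glues ``S1`` (resp. ``S2``) onto the given leaf of the host ``R`` and
    compares the two full trees' exact characteristic polynomials — the
    trivariate generalized-Laplacian polynomial or the distance-matrix
    polynomial.
    """
    _check_same_size(S1, S2)
    T1 = glue_at_leaf(R, leaf_position, S1)
    T2 = glue_at_leaf(R, leaf_position, S2)
    if matrix_kind == "generalized_laplacian":
        return generalized_charpoly(T1) == generalized_charpoly(T2)
    if matrix_kind == "distance":
        return distance_charpoly(T1) == distance_charpoly(T2)
    raise ValueError(f"unknown matrix kind: {matrix_kind}")


@dataclass(frozen=True)
class ExchangePair:
    """Result of an exchange-pair search."""

    n_leaves: int
    pair: tuple[TreeShape, TreeShape]


def smallest_exchange_pair(matrix_kind: MatrixKind, n_max: int,
                           seed: int = 0) -> Optional[ExchangePair]:
    """Exhaustive search for the smallest exchange pair with at most
    ``n_max`` leaves.

    Scans leaf counts in increasing order; within each, shapes are bucketed
    by a seeded exact fingerprint of the criterion data (the ``{P_k, Q_k}``
    family, or the four bordered polynomials) and every bucket with more
    than one member is re-verified by exact polynomial comparison.  Returns
    the first confirmed pair in canonical order, or ``None``.
    """
    if n_max < 2:
        raise ValueError("n_max must be >= 2")
    for n in range(2, n_max + 1):
        pair = _search_at_n(n, matrix_kind, seed)
        if pair is not None:
            return ExchangePair(n, pair)
    return None


def _search_at_n(n: int, matrix_kind: MatrixKind, seed: int):
    shapes = enumerate_shapes(n)
    if matrix_kind == "generalized_laplacian":
        fp = GlapFingerprinter(seed=seed)
        buckets: dict = {}
        for i, T in enumerate(shapes):
            buckets.setdefault(fp.profile_fingerprint(T), []).append(i)
        confirm = lambda T: matching_profile(T)
    elif matrix_kind == "distance":
        buckets = _distance_buckets(shapes, seed)
        confirm = lambda T: bordered_charpolys(T)
    else:
        raise ValueError(f"unknown matrix kind: {matrix_kind}")
    best = None
    for members in buckets.values():
        if len(members) < 2:
            continue
        exact: dict = {}
        for i in members:
            exact.setdefault(confirm(shapes[i]), []).append(i)
        for idxs in exact.values():
            if len(idxs) > 1:
                cand = tuple(sorted(idxs))[:2]
                if best is None or cand < best:
                    best = cand
    if best is None:
        return None
    return (shapes[best[0]], shapes[best[1]])


def _distance_buckets(shapes, seed: int) -> dict:
    """Fingerprint every shape's four bordered matrices by modular
    determinant evaluations (vectorized across shapes)."""
    from .census import _batched_det_points

    n = shapes[0].n_leaves
    N = len(shapes)
    A = np.empty((N, n, n), dtype=np.int64)
    a = np.empty((N, n), dtype=np.int64)
    for i, T in enumerate(shapes):
        D, h = mx._dist_arrays(T)
        A[i] = D
        a[i] = h
    ones = np.ones((N, n), dtype=np.int64)

    def bordered(col, row):
        M = np.zeros((N, n + 1, n + 1), dtype=np.int64)
        M[:, :n, :n] = A
        M[:, :n, n] = col
        M[:, n, :n] = row
        return M

    fps = [_batched_det_points(A, seed)]
    for col, row in ((a, a), (a, ones), (ones, ones)):
        fps.append(_batched_det_points(bordered(col, row), seed))
    keys = list(zip(*[list(zip(*f)) for f in fps]))
    buckets: dict = {}
    for i, k in enumerate(keys):
        buckets.setdefault(k, []).append(i)
    return buckets
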