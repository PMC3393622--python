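"""Canonical rooted binary tree shapes: representation, I/O, enumeration.

A *shape* is a rooted binary tree with no labels and no branch lengths;
isomorphic trees are identified.  Every shape is held in a canonical form in
which the two children of each internal node are ordered by
``(leaf count, canonical code)``, so structural equality of shapes reduces to
string equality of their codes.  Shapes are interned: a given shape exists
once per process, which lets downstream modules memoize expensive invariants
per shape object.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterator, Sequence

__all__ = [
    "TreeShape",
    "LEAF",
    "CHERRY",
    "node",
    "canonical_encode",
    "parse_newick",
    "write_newick",
    "enumerate_shapes",
    "shape_by_rank",
    "random_shape",
    "contains_subtree",
    "glue_at_leaf",
    "vertexize",
    "VertexizedTree",
    "MalformedTreeError",
    "NewickError",
]


class MalformedTreeError(ValueError):
    """Input tree is not strictly binary."""


class NewickError(ValueError):
    """Input string is not well-formed Newick for a binary shape."""


_INTERN: dict[str, "TreeShape"] = {}


class TreeShape:
    """An unlabeled rooted binary tree shape in canonical form.

    Attributes
    ----------
    left, right : TreeShape | None
        Canonically ordered children (``None`` for a leaf).  Ordering is by
        ``(n_leaves, canonical_code)``; the key is total on shapes, so the
        canonical form — hence the code — is unique per isomorphism class.
    n_leaves : int
    canonical_code : str
        ``"*"`` for a leaf, ``"(" + left.code + right.code + ")"`` otherwise.
    """

    __slots__ = ("left", "right", "n_leaves", "canonical_code")

    def __init__(self, left, right, n_leaves, canonical_code):
        self.left = left
        self.right = right
        self.n_leaves = n_leaves
        self.canonical_code = canonical_code

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    @property
    def n_vertices(self) -> int:
        return 2 * self.n_leaves - 1

    def _key(self) -> tuple[int, str]:
        return (self.n_leaves, self.canonical_code)

    def __eq__(self, other):
        if not isinstance(other, TreeShape):
            return NotImplemented
        return self.canonical_code == other.canonical_code

    def __hash__(self):
        return hash(self.canonical_code)

    def __lt__(self, other):
        return self._key() < other._key()

    def __repr__(self):
        return f"TreeShape({write_newick(self)!r})"

    def children(self) -> tuple["TreeShape", "TreeShape"]:
        if self.is_leaf:
            raise ValueError("a leaf has no children")
        return (self.left, self.right)


def _intern(left, right, n_leaves, code) -> TreeShape:
    shape = _INTERN.get(code)
    if shape is None:
        shape = TreeShape(left, right, n_leaves, code)
        _INTERN[code] = shape
    return shape


LEAF: TreeShape = _intern(None, None, 1, "*")


def node(a: TreeShape, b: TreeShape) -> TreeShape:
    """Join two shapes under a new root (canonically ordered)."""
    if b._key() < a._key():
        a, b = b, a
    return _intern(a, b, a.n_leaves + b.n_leaves,
                   "(" + a.canonical_code + b.canonical_code + ")")


CHERRY: TreeShape = node(LEAF, LEAF)


def canonical_encode(raw) -> TreeShape:
    """Canonicalize a raw nested-pair structure into a :class:`TreeShape`.

    A leaf may be written as ``None``, a string, or an existing leaf shape; an
    internal node is a 2-sequence of children.  Sibling order in the input is
    irrelevant (the output is the canonical form), and the map is idempotent
    on already-canonical shapes.
    """
    if isinstance(raw, TreeShape):
        return raw
    if raw is None or isinstance(raw, str):
        return LEAF
    if isinstance(raw, (tuple, list)):
        if len(raw) != 2:
            raise MalformedTreeError(
                f"internal node must have exactly 2 children, got {len(raw)}")
        return node(canonical_encode(raw[0]), canonical_encode(raw[1]))
    raise MalformedTreeError(f"unrecognized node: {raw!r}")


# ---------------------------------------------------------------------------
# Newick I/O (unlabeled-tolerant dialect)
# ---------------------------------------------------------------------------

def parse_newick(s: str) -> TreeShape:
    """Parse a Newick string into a shape.

    Labels and branch lengths are accepted and discarded; every internal node
    must be binary.  ``"((A,B),C);"`` and ``"((,),);"`` denote the same
    3-leaf shape.
    """
    s = s.strip()
    if s.endswith(";"):
        s = s[:-1]
    pos = 0

    def skip_label():
        nonlocal pos
        while pos < len(s) and s[pos] not in "(),;:":
            pos += 1
        if pos < len(s) and s[pos] == ":":  # branch length
            pos += 1
            while pos < len(s) and s[pos] not in "(),;":
                pos += 1

    def subtree() -> TreeShape:
        nonlocal pos
        if pos < len(s) and s[pos] == "(":
            pos += 1
            children = [subtree()]
            while pos < len(s) and s[pos] == ",":
                pos += 1
                children.append(subtree())
            if pos >= len(s) or s[pos] != ")":
                raise NewickError("unbalanced parentheses")
            pos += 1
            skip_label()
            if len(children) != 2:
                raise MalformedTreeError(
                    f"non-binary node with {len(children)} children")
            return node(children[0], children[1])
        skip_label()
        return LEAF

    out = subtree()
    if pos != len(s):
        raise NewickError(f"trailing characters at position {pos}: {s[pos:]!r}")
    return out


def write_newick(t: TreeShape) -> str:
    """Render a shape as unlabeled Newick, e.g. ``"((,),);"``."""

    def rec(u: TreeShape) -> str:
        if u.is_leaf:
            return ""
        return "(" + rec(u.left) + "," + rec(u.right) + ")"

    return rec(t) + ";"


# ---------------------------------------------------------------------------
# Exhaustive enumeration and uniform sampling
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def enumerate_shapes(n: int) -> tuple[TreeShape, ...]:
    """All shapes with ``n`` leaves, in a deterministic canonical order.

    The list has exactly ``t_n`` entries (Wedderburn-Etherington).  Order:
    root split sizes ``(i, n-i)`` with ``i = 1..n//2`` ascending, then
    lexicographic in the (recursively ordered) child indices; for the even
    middle split only unordered pairs ``a <= b`` are emitted.
    """
    if n < 1:
        raise ValueError("leaf count must be >= 1")
    if n == 1:
        return (LEAF,)
    out: list[TreeShape] = []
    for i in range(1, n // 2 + 1):
        small = enumerate_shapes(i)
        large = enumerate_shapes(n - i)
        if i < n - i:
            for a in small:
                for b in large:
                    out.append(node(a, b))
        else:  # i == n - i
            for ai, a in enumerate(small):
                for b in small[ai:]:
                    out.append(node(a, b))
    return tuple(out)


def shape_by_rank(n: int, rank: int) -> TreeShape:
    """The ``rank``-th shape (0-based) in :func:`enumerate_shapes` order.

    Computed arithmetically from the ``t_n`` counts, without materializing
    the enumeration; supports uniform sampling at leaf counts where the full
    list would be enormous.
    """
    from .counting import n_shapes

    if n == 1:
        if rank != 0:
            raise IndexError(rank)
        return LEAF
    if rank < 0:
        raise IndexError(rank)
    for i in range(1, n // 2 + 1):
        ti, tj = n_shapes(i), n_shapes(n - i)
        if i < n - i:
            block = ti * tj
            if rank < block:
                return node(shape_by_rank(i, rank // tj),
                            shape_by_rank(n - i, rank % tj))
            rank -= block
        else:
            block = ti * (ti + 1) // 2
            if rank < block:
                # unordered pair (a <= b), lexicographic
                a = 0
                while rank >= ti - a:
                    rank -= ti - a
                    a += 1
                return node(shape_by_rank(i, a), shape_by_rank(i, a + rank))
            rank -= block
    raise IndexError("rank out of range")


def random_shape(n: int, rng) -> TreeShape:
    """A uniformly random shape with ``n`` leaves (``rng``: numpy Generator
    or :class:`random.Random`)."""
    from .counting import n_shapes

    total = n_shapes(n)
    if hasattr(rng, "integers"):
        rank = int(rng.integers(0, total))
    else:
        rank = rng.randrange(total)
    return shape_by_rank(n, rank)


# ---------------------------------------------------------------------------
# Subtree operations
# ---------------------------------------------------------------------------

def contains_subtree(T: TreeShape, S: TreeShape) -> bool:
    """Whether ``S`` occurs as a rooted subtree of ``T``.

    A subtree hangs below an edge (detach the edge at its distal vertex); by
    convention the whole tree counts as a subtree of itself, which is what
    makes the avoider recursion's boundary ``s_a = t_a - m`` come out right.
    """
    if T.n_leaves < S.n_leaves:
        return False
    if T is S or T.canonical_code == S.canonical_code:
        return True
    if T.is_leaf:
        return False
    return contains_subtree(T.left, S) or contains_subtree(T.right, S)


def leaf_count_check(t: TreeShape) -> int:
    return t.n_leaves


def glue_at_leaf(R: TreeShape, leaf_position: int, S: TreeShape) -> TreeShape:
    """Identify the ``leaf_position``-th leaf of ``R`` (canonical DFS order)
    with the root of ``S``; returns the canonical form of the result.

    The glued tree has ``n(R) - 1 + n(S)`` leaves.
    """
    if not 0 <= leaf_position < R.n_leaves:
        raise IndexError(
            f"leaf_position {leaf_position} out of range for {R.n_leaves} leaves")

    def rec(u: TreeShape, pos: int) -> TreeShape:
        if u.is_leaf:
            return S
        if pos < u.left.n_leaves:
            return node(rec(u.left, pos), u.right)
        return node(u.left, rec(u.right, pos - u.left.n_leaves))

    return rec(R, leaf_position)


@dataclass(frozen=True)
class VertexizedTree:
    """A shape with a fixed vertex numbering, ready for matrix construction.

    Vertices are indexed in preorder (depth-first over the canonical form,
    root = 0, left child before right).  ``degrees[i]`` is the degree of
    vertex ``i``; the root has degree 2, leaves degree 1, all other internal
    vertices degree 3.
    """

    degrees: tuple[int, ...]
    edges: tuple[tuple[int, int], ...]
    root_index: int
    leaf_indices: tuple[int, ...]

    @property
    def n_vertices(self) -> int:
        return len(self.degrees)


def vertexize(T: TreeShape) -> VertexizedTree:
    """Deterministic vertex indexing of a shape (``n_leaves >= 2``)."""
    if T.n_leaves < 2:
        raise ValueError("vertexize requires at least 2 leaves (no edges otherwise)")
    degrees: list[int] = []
    edges: list[tuple[int, int]] = []
    leaves: list[int] = []

    def rec(u: TreeShape, parent: int) -> None:
        idx = len(degrees)
        if u.is_leaf:
            degrees.append(1)
            leaves.append(idx)
        else:
            degrees.append(2 if parent < 0 else 3)
        if parent >= 0:
            edges.append((parent, idx))
        if not u.is_leaf:
            rec(u.left, idx)
            rec(u.right, idx)

    rec(T, -1)
    return VertexizedTree(tuple(degrees), tuple(edges), 0, tuple(leaves))


def leaf_depths(T: TreeShape) -> list[int]:
    """Edge-distance of each leaf from the root, in canonical leaf order."""
    out: list[int] = []

    def rec(u: TreeShape, d: int) -> None:
        if u.is_leaf:
            out.append(d)
        else:
            rec(u.left, d + 1)
            rec(u.right, d + 1)

    rec(T, 0)
    return out


def iter_subtrees(T: TreeShape) -> Iterator[TreeShape]:
    """All rooted subtrees of ``T`` (including ``T`` itself), preorder,
    with repetition for repeated occurrences."""
    yield T
    if not T.is_leaf:
        yield from iter_subtrees(T.left)
        yield from iter_subtrees(T.right)
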