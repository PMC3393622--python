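"""Canonical form, Newick I/O, enumeration and subtree operations."""

import itertools
import random

import pytest
from hypothesis import given, settings, strategies as st

from treespectra.counting import count_trees
from treespectra.shapes import (CHERRY, LEAF, MalformedTreeError, NewickError,
                                TreeShape, canonical_encode, contains_subtree,
                                enumerate_shapes, glue_at_leaf, iter_subtrees,
                                parse_newick, random_shape, shape_by_rank,
                                vertexize, write_newick)


def raw_trees(max_leaves=10):
    """Hypothesis strategy for raw nested-pair structures."""
    return st.recursive(st.none(), lambda c: st.tuples(c, c), max_leaves=max_leaves)


class TestCanonicalEncode:
    def test_sibling_order_is_irrelevant(self):
        assert canonical_encode((None, (None, None))) == \
            canonical_encode(((None, None), None))

    def test_leaf(self):
        t = canonical_encode(None)
        assert t.is_leaf and t.n_leaves == 1 and t is LEAF

    def test_all_orderings_of_balanced_four_leaf_collapse(self):
        # brute force over every sibling permutation of ((a,b),(c,d))
        codes = set()
        for ab in [((None, None), (None, None))]:
            for l, r in itertools.permutations(ab):
                for ll in itertools.permutations(l):
                    for rr in itertools.permutations(r):
                        codes.add(canonical_encode((tuple(ll), tuple(rr))).canonical_code)
                        codes.add(canonical_encode((tuple(rr), tuple(ll))).canonical_code)
        assert len(codes) == 1

    def test_malformed(self):
        with pytest.raises(MalformedTreeError):
            canonical_encode((None, None, None))

    @given(raw_trees())
    @settings(max_examples=200, derandomize=True)
    def test_idempotent(self, raw):
        t = canonical_encode(raw)
        assert canonical_encode(t) is t

    def test_invariant_under_random_sibling_swaps(self):
        # 1000 seeded random trees; swapping children anywhere preserves code
        rng = random.Random(7)

        def rand_raw(n):
            if n == 1:
                return None
            i = rng.randint(1, n - 1)
            return (rand_raw(i), rand_raw(n - i))

        def swapped(raw):
            if raw is None:
                return None
            a, b = (swapped(c) for c in raw)
            return (b, a) if rng.random() < 0.5 else (a, b)

        for _ in range(1000):
            raw = rand_raw(rng.randint(2, 24))
            assert canonical_encode(raw) == canonical_encode(swapped(raw))


class TestEnumeration:
    @pytest.mark.parametrize("n,expected", [(2, 1), (5, 3), (8, 23)])
    def test_counts_match_published_census(self, n, expected):
        assert len(enumerate_shapes(n)) == expected

    def test_counts_match_recursion_up_to_14(self):
        t = count_trees(14)
        for n in range(1, 15):
            shapes = enumerate_shapes(n)
            assert len(shapes) == t[n - 1]
            assert len({s.canonical_code for s in shapes}) == t[n - 1]

    def test_domain_error(self):
        with pytest.raises(ValueError):
            enumerate_shapes(0)

    def test_shape_by_rank_matches_enumeration(self):
        for n in range(1, 9):
            shapes = enumerate_shapes(n)
            for i, s in enumerate(shapes):
                assert shape_by_rank(n, i) is s
        with pytest.raises(IndexError):
            shape_by_rank(5, 3)

    def test_random_shape_is_valid(self, rng):
        for _ in range(50):
            n = rng.randint(1, 40)
            assert random_shape(n, rng).n_leaves == n


class TestNewick:
    def test_labels_and_lengths_discarded(self):
        assert parse_newick("((A,B),C);") == parse_newick("((,),);")
        assert parse_newick("((A:0.1,B:0.2)ab:0.3,C:0.4);") == parse_newick("((,),);")

    def test_balanced_four(self):
        t = parse_newick("((,),(,));")
        assert t == canonical_encode(((None, None), (None, None)))

    def test_roundtrip_all_six_leaf_shapes(self):
        for s in enumerate_shapes(6):
            assert parse_newick(write_newick(s)) is s

    @given(raw_trees())
    @settings(max_examples=200, derandomize=True)
    def test_roundtrip_random(self, raw):
        t = canonical_encode(raw)
        assert parse_newick(write_newick(t)) == t

    def test_errors(self):
        with pytest.raises(MalformedTreeError):
            parse_newick("((,,),);")
        with pytest.raises(NewickError):
            parse_newick("((,);")
        with pytest.raises(NewickError):
            parse_newick("(,));")


class TestContainsSubtree:
    def test_self_containment(self):
        for n in range(1, 7):
            for T in enumerate_shapes(n):
                assert contains_subtree(T, T)

    def test_size_excludes(self):
        assert not contains_subtree(CHERRY, enumerate_shapes(3)[0])

    def test_four_leaf_avoiders_of_three_leaf(self):
        s3 = enumerate_shapes(3)[0]
        avoiders = [T for T in enumerate_shapes(4) if not contains_subtree(T, s3)]
        assert len(avoiders) == 1  # only the balanced shape

    def test_agrees_with_subtree_enumeration_oracle(self):
        all_small = [s for n in range(1, 9) for s in enumerate_shapes(n)]
        for n in range(1, 9):
            for T in enumerate_shapes(n):
                actual_subtrees = set(iter_subtrees(T))
                for S in all_small:
                    assert contains_subtree(T, S) == (S in actual_subtrees)


class TestGlue:
    def test_cherry_on_cherry_gives_caterpillar(self):
        assert glue_at_leaf(CHERRY, 0, CHERRY) == enumerate_shapes(3)[0]

    def test_leaf_count_arithmetic(self, rng):
        for _ in range(100):
            R = random_shape(rng.randint(2, 12), rng)
            S = random_shape(rng.randint(2, 12), rng)
            pos = rng.randrange(R.n_leaves)
            assert glue_at_leaf(R, pos, S).n_leaves == R.n_leaves + S.n_leaves - 1

    def test_non_equivalent_leaves_give_distinct_results(self):
        caterpillar4 = parse_newick("(((,),),);")
        S = CHERRY
        results = {glue_at_leaf(caterpillar4, p, S) for p in range(4)}
        assert len(results) > 1

    def test_invalid_position(self):
        with pytest.raises(IndexError):
            glue_at_leaf(CHERRY, 2, CHERRY)


class TestVertexize:
    def test_cherry(self):
        vt = vertexize(CHERRY)
        assert sorted(vt.degrees) == [1, 1, 2]
        assert vt.root_index == 0 and len(vt.leaf_indices) == 2

    def test_vertex_count_and_handshake(self):
        for n in range(2, 8):
            for T in enumerate_shapes(n):
                vt = vertexize(T)
                assert vt.n_vertices == 2 * n - 1
                assert sum(vt.degrees) == 2 * len(vt.edges)
                assert len(vt.edges) == 2 * n - 2

    def test_degree_multiset_eight_leaves(self):
        from collections import Counter
        for T in enumerate_shapes(8):
            assert Counter(vertexize(T).degrees) == {1: 8, 2: 1, 3: 6}

    def test_single_leaf_rejected(self):
        with pytest.raises(ValueError):
            vertexize(LEAF)
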