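# Methods

## Scope and objects

`treespectra` works with *tree shapes*: rooted, strictly bifurcating trees
with no leaf labels and no branch lengths, the combinatorial objects
underlying phylogenetic tree-shape statistics.  Isomorphic trees are
identified.  A shape with `n` leaves has `r = 2n - 1` vertices (root of
degree 2, leaves of degree 1, all other internal vertices of degree 3) and
`2n - 2` edges.  The number of shapes with `n` leaves is the
Wedderburn–Etherington number `t_n` (1, 1, 1, 2, 3, 6, 11, 23, ...).

Every shape is held in a canonical form: the two children of each internal
node are ordered by the key `(leaf count, canonical code)`, where the code of
a leaf is `*` and the code of a node is `(<left code><right code>)`.  The key
is a total order on shapes, so the canonical form — and hence the code — is
unique per isomorphism class, and shape equality is string equality.  Shapes
are interned (one object per class per process), which makes the heavy
per-shape memoization below sound and cheap.  Vertex indexing for matrix
construction is preorder over the canonical form (root = 0), and leaf order
is the canonical depth-first order.

Four matrix representations are supported: the adjacency matrix `A`, the
Laplacian `L = A - D` (sign convention: spectra are the negatives of the
`D - A` convention used elsewhere; census counts are unaffected), the
generalized Laplacian `yD + zA` with `(y, z)` symbolic, and the leaf-to-leaf
distance matrix (path lengths in edges).

## Matching expansion of the generalized Laplacian

For a tree, the only permutations that survive in `det(xI - yD - zA)` are
products of disjoint transpositions along edges — i.e. matchings.  With
`P_k(x, y)` the sum over k-matchings `p` of `prod_{i not covered by p}
(x - y d_i)`, the characteristic polynomial is
`sum_k (-1)^k z^{2k} P_k(x, y)`.  `Q_k` restricts the sum to matchings
avoiding the root.  The implementation never enumerates matchings: a
post-order recursion carries, per subtree, the pair (sum over matchings
leaving the subtree root unmatched, without the root's own factor; sum over
matchings covering the root), from which `P` and `Q` of the standalone tree
follow in one step.  Subtree degrees are the degrees in the final tree
(attached subtree roots have degree 3, the global root degree 2).  All
coefficients are arbitrary-precision integers; correctness is tested
exhaustively for `n <= 7` against a sympy symbolic determinant and against a
literal matching-enumeration oracle.

The same recursion evaluated at integer points `(x0, y0, m0)` (with `m0`
standing for the matched-pair marker) yields exact integer *fingerprints* of
the polynomials.  Because enumerated shapes share subtrees massively, the
memoized fingerprint of an entire census is near-linear in the number of
shapes.

## Immanantal polynomials and characters

The immanant replaces `sgn` in the determinant by an irreducible character
`chi_lambda` of `S_r`; the matching expansion carries over with weights
`chi_lambda(C_k)` on the class `C_k` of k disjoint transpositions.
Characters are computed by the Murnaghan–Nakayama rule on beta-numbers
(border-strip removal), memoized on `(partition, remaining cycle type)`.
The character code is validated against both orthogonality relations of the
full character table for `r <= 6`, closed forms for the sign, trivial and
standard representations, and a literal permutation-sum immanant for all
shapes with `r <= 7`.

Because `sgn(C_k) = (-1)^k` never vanishes, equal characteristic polynomials
force equal `P_k` for every `k`, hence equal immanantal polynomials for
*every* character; the converse is immediate.  The package verifies this
equivalence empirically on all same-size shape pairs with `n <= 8`.  The
argument specializes to any fixed `(y, z)`: in particular the smallest
adjacency-cospectral pair (8 leaves) has identical adjacency immanantal
polynomials for all 176 characters of `S_15`.  Immanantal polynomials of the
*distance* matrix are exposed only as an exploratory brute-force helper; no
distinguishing-power claim is made either way.

## Census semantics — what "GLS" means here

A census groups all shapes of a leaf count by exact characteristic
polynomial.  Counting is fingerprint-then-confirm: fingerprints (integer
evaluations for the matching-based kinds; `det(x0 I - D)` modulo two 31-bit
primes, vectorized across all shapes, for the distance kind) are functions
of the exact polynomial, so distinct fingerprints prove distinct spectra;
every bucket with more than one member is resolved by full exact polynomial
comparison before anything is counted.  Changing the fingerprint seed cannot
change any census count, only the amount of confirmation work.

An exact-arithmetic finding that shapes the interface: the published census
column labelled "generalized Laplacian spectra" (22 at n=8, 45 at n=9, ...,
24580 at n=17) coincides, row for row, with the **adjacency** census
(`y = 0, z = 1`), while the fully symbolic `(y, z)` census has *no*
collisions at those sizes (its count at n=8 is 23 = t_8, and its first
collisions are exactly the exchange pairs).  Moreover the 8-leaf
adjacency-cospectral pair does **not** share its Laplacian spectrum (exact
characteristic polynomials differ; the Laplacian census separates all shapes
through n=12 at least).  The package therefore exposes all four kinds
explicitly; `census_table` reproduces the published layout with the
adjacency kind in the GLS column, and the symbolic kind remains available as
`"generalized_laplacian"`.

## Exchange properties

Two equal-size shapes can be swapped below any host without changing the
host's generalized-Laplacian spectrum when their full `{P_k, Q_k}` families
agree (matchings through the connecting edge restrict to root-avoiding
matchings of the subtree; all others restrict to arbitrary ones).  For the
distance matrix the sufficient condition is equality of the four spectra of
`A`, `[[A,a],[a',0]]`, `[[A,a],[1',0]]`, `[[A,1],[1',0]]` (`a` = leaf-to-root
distances), via the bordered-determinant identity
`det(xI - [[A,g],[h',0]]) = det(xI - A) (x - h'(xI - A)^{-1} g)`.

"Same spectrum" is decided as exact equality of characteristic polynomials
throughout — equivalent for fixed-size matrices, and free of eigenvalue
numerics.  Characteristic polynomials of integer matrices (including the
non-symmetric bordered ones) use a Faddeev–LeVerrier recurrence kept over
plain integers: the auxiliary matrices are integer polynomials in the input,
so the trace division by `k` is exact and is asserted.

Exhaustive search (fingerprint bucketing with exact confirmation, sizes
scanned in increasing order) finds the smallest pair satisfying the
matching-family criterion at 17 leaves and none below; the same pair — and
no other — satisfies the distance criterion at 17, the coincidence the
analysis can only re-verify, not explain.  An independent substitution
oracle (`verify_exchange`) glues each shape of a pair onto random hosts
(uniformly sampled shapes via exact unranking of the enumeration order) and
compares full-tree polynomials; the suite runs it on 50 seeded hosts per
matrix kind.

## Counting and asymptotics

`t_n` satisfies the root-decomposition convolution
`sum_{i=1}^{n-1} t_i t_{n-i} = 2 t_n - t_{n/2}` (`t_{n/2} = 0` for odd `n`),
iterated with exact integers (the implementation halves the convolution by
symmetry).  Forbidding `m` of the `t_a` shapes of size `a` changes nothing
except `s_a = t_a - m`, because a shape is its own subtree; consequently the
avoider counts `s_n` depend only on `(a, m)` — verified against brute-force
subtree-avoidance counting for all configurations with `a <= 5, n <= 10`.

The radius of convergence of `f(x) = sum t_n x^n` comes from the iterated
maps `w_k(u) = (2 + u^(2^k))^(2^-k)`: `1/rho = lim q_n(0)`,
`q_n = w_{n-1} o ... o w_0`.  The iterates increase monotonically and
converge doubly exponentially; in 60-digit working precision eight
iterations reach the default stopping rule (successive iterates within
1e-50), giving `rho = 0.402697503...`.  For avoiders the maps acquire the
penalty `-2 xi^(2^k)` with `xi = rho_a^(a-1)`; the self-consistent `rho_a`
is found by a secant iteration on `xi` (plain damped fixed-point iteration
contracts too slowly for small `a`).  `rho_a > rho` strictly, decreasing
toward `rho` as `a` grows, and `1/rho_a` matches the empirical growth rate
`s_{n+1}/s_n` at `n = 2000` to better than 1e-3 — that strict gap is what
drives the avoider fraction `s_n/t_n` to zero, and with it the fraction of
shapes with a unique spectrum.

The growth constant is reported in the normalization
`t_n ~ eta * n^(-3/2) * rho^-(n-1)`, under which the literature value
`eta = 0.7916032...` is quoted; the limit of `n^(3/2) rho^n t_n` itself is
`eta * rho = 0.3187766...` (both statements are checked numerically — the
distinction matters and is easy to get wrong by one power of `rho`).  The
estimate computes exact `t_n` to `n = 5000`, forms
`a_n = n^(3/2) rho^(n-1) t_n` in 60-digit precision, and applies two levels
of Richardson extrapolation (`2 a_{2n} - a_n`, then the `1/n^2` level) over
`n_max/4, n_max/2, n_max`; at `n_max = 5000` the result is stable to ~5e-8.
The expansion of `a_n` in powers of `1/n` that justifies Richardson here is
standard for square-root singularities of this kind.  Exponential
sensitivity to `rho` (a 1% perturbation makes the sequence diverge) is
itself used as a test.

## Problem sizes, defaults, and numerical choices

* Census defaults in tests and the acceptance script: both matrix kinds for
  `n <= 14`, distance at `n = 17` (24 631 shapes, ~6 s); the published rows
  at `n = 18, 19` are reachable with the same code path but are left to the
  CLI user.
* Fingerprints: 3 integer points for matching-based kinds, 2 evaluation
  points x 2 primes (`2147483629`, `2147483587`) for the distance kind;
  seeded via `--seed`/function arguments, exact confirmation always on.
* High-precision work uses mpmath at 60 decimal digits; `rho` stops at
  1e-50, `rho_a`'s secant at 1e-45 relative.  Reported digits (6 for `rho`,
  7 for `eta`) are far inside what the precision certifies.
* `eta_estimate` uses `n_max = 5000` (exact `t_5000` has 1970 digits;
  ~20 s); `n_max = 1500` already gives 1e-6 agreement.
* Degenerate inputs: single-leaf trees are rejected by matrix constructors
  (no edges); `glue_at_leaf` accepts a leaf as the glued subtree and returns
  the host unchanged; non-binary input raises in both the raw-structure and
  Newick paths.

## Known limitations

* Censuses beyond ~19 leaves are out of practical reach of a single process
  (combinatorial growth); no parallel execution is provided.
* Weighted (branch-length) distance matrices, multifurcating trees, and
  leaf-labeled tree spaces are out of scope.
* The avoider growth constant `eta_a` (the analogue of `eta` for `s_n`) is
  not computed, and the complex-analytic uniqueness theory behind the
  functional equations is assumed, not re-proved.
* Minimality statements (smallest cospectral pair, smallest exchange pair)
  are exhaustive computational facts up to the stated sizes, not analytic
  theorems.
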