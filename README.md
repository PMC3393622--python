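# treespectra

Exact spectral invariants of unlabeled rooted binary tree shapes.

Tree-shape statistics summarize the branching structure of evolutionary
trees, and matrix spectra look like the canonical way to build such
statistics: encode a shape as its adjacency matrix `A`, Laplacian
`L = A − D`, generalized Laplacian `yD + zA`, or leaf-to-leaf distance
matrix, and take the eigenvalues (equivalently, the characteristic
polynomial), which are invariant under relabeling.  This package answers —
with exact integer arithmetic end to end — how well that works: it computes
the polynomials, runs censuses counting how many shapes share a spectrum at
each leaf count, searches for subtree pairs whose swap inside *any* host
tree preserves a spectrum (the *exchange property*), and computes the exact
counting sequences and asymptotic constants which show that, asymptotically,
almost every large shape shares its spectrum with another.

The mathematical core, in the field's standard notation:

* For a tree with vertex degrees `d_i`, the characteristic polynomial of the
  generalized Laplacian has the matching expansion
  `det(xI − yD − zA) = Σ_k (−1)^k z^{2k} P_k(x,y)` where
  `P_k = Σ_{k-matchings p} Π_{i∉p} (x − y d_i)`; `Q_k` is the same sum over
  root-avoiding matchings.  Equal `{P_k, Q_k}` families make two subtrees
  exchangeable for this matrix; replacing `(−1)^k` by irreducible characters
  `χ_λ(C_k)` of the symmetric group gives the immanantal polynomials, which
  carry exactly the same information as the spectrum.
* For the distance matrix, exchangeability follows from equality of four
  bordered spectra built from the distance matrix and the leaf-to-root
  distance vector.
* The shape counts `t_n` (Wedderburn–Etherington numbers) satisfy
  `Σ t_i t_{n−i} = 2 t_n − t_{n/2}`; their generating function has radius of
  convergence `ρ = 0.402698…` obtained from the iteration
  `w_k(u) = (2 + u^{2^k})^{2^{−k}}`, and `t_n ~ η n^{−3/2} ρ^{−(n−1)}` with
  `η = 0.7916032…`.  Shapes avoiding any fixed subtree have a strictly
  larger radius `ρ_a`, so the avoider fraction — and with it the fraction of
  shapes with a unique spectrum — vanishes as `n → ∞`.

All "same spectrum" decisions are exact polynomial equalities (big-integer
coefficients, fingerprint-then-confirm counting); no floating point touches
any census or search result.

## Worked example

```python
>>> import treespectra as ts
>>> c = ts.spectral_census(8, "adjacency")
>>> (c.n_trees, c.n_distinct, c.n_unique)
(23, 22, 21)
```

Among the 23 shapes with 8 leaves there are only 22 distinct adjacency
spectra: exactly one pair of shapes is cospectral (so 21 shapes have a
spectrum of their own) — the smallest cospectral pair for any of these
matrices.  The distance matrix still separates everything at this size
(`ts.spectral_census(8, "distance").n_distinct == 23`), and so does the
fully symbolic generalized Laplacian; its first collisions are the exchange
pairs below.

The same from the command line, with the published table layout:

```
$ treespectra census --max-leaves 8
leaves  trees   distinct_adjacency      unique_adjacency        distinct_distance       unique_distance
2       1       1       1       1       1
...
7       11      11      11      11      11
8       23      22      21      23      23
```

The smallest pair of subtrees that can be swapped below any host without
changing the host's generalized-Laplacian spectrum has 17 leaves, and the
very same pair is also the smallest exchange pair for the distance matrix:

```
$ treespectra exchange-search --matrix glap --max-leaves 17
((,((,),(,))),((,(,(,))),(,(,((,(,)),(,(,)))))));
(((,(,)),(,(,))),(,((,(,(,))),(,(,((,),(,)))))));
smallest glap exchange pair: n = 17
```

And the asymptotic constants:

```
$ treespectra rho --digits 8
rho   = 0.4026975   (8 iterations)
eta   = 0.7916032   (t_n up to n=5000)
```

`rho` is the radius of convergence of `Σ t_n x^n` — the reciprocal growth
rate of the number of shapes — and `eta` the constant in
`t_n ~ η n^{−3/2} ρ^{−(n−1)}`.

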