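# Methods

This note records the models, conventions and numerical choices behind
`ppinet`, and what the synthetic-data experiments do and do not show.

## Network representation

A network is an undirected simple graph over string node identifiers:
symmetric adjacency `c_ij = c_ji ∈ {0,1}` with `c_ii = 0`. Raw interaction
records are symmetrised (bait–prey orientation discarded), duplicates in
either orientation collapse to one edge, and self-interactions are dropped
with a counted warning. Isolated nodes are retained: `p(0)` is a
legitimate degree bin and changes `⟨k⟩ = 2E/N`, which matters for the
Poisson reference and for sub-sampled networks. Identifiers are kept
verbatim after whitespace trimming; accession mapping is dataset curation
and out of scope.

## Macroscopic characterisation

- `p(k)`: fraction of nodes with degree `k`, `k = 0..k_max`.
- `Π(k,k′)`: probability that a uniformly drawn edge, with both
  orientations counted, joins degrees `k` and `k′`. Exact identities,
  tested on every generated graph: `Σ p = 1`, `Σ Π = 1`,
  `Σ_{k′} Π(k,k′) = k p(k)/⟨k⟩`.
- `W(k,k′) = Π(k,k′) ⟨k⟩²/(k p(k) k′ p(k′))` for `k,k′ ≥ 1` on the support
  of `p`. Degree pairs *outside* the support are "no data" and stored as
  NaN; pairs inside the support with no observed edge are true zeros
  (suppression). The two mean different things in heat maps and in
  smoothed statistics. Degree-zero nodes never enter `Π` or `W`.
- Assortativity: Pearson correlation of the degree pair under `Π`. For a
  regular graph the edge-end marginal has zero variance and the value is
  reported as undefined (`None`), never as 0. Two independent routes
  (moments of `Π`; sums over `(p, W)`) agree to 1e−10 on exact statistics
  and both are exposed.

## Gaussian smoothening

KL-based quantities need strictly positive probabilities, while finite
networks have empty degree bins. We convolve `p` (over `0..k_max`) and `Π`
(over `1..k_max` on both axes) with a discrete Gaussian kernel
`K(i,j) ∝ exp(−(i−j)²/2σ²)` whose columns are renormalised where the
window is clipped at the range boundaries, so no probability mass leaks.
Smoothed `p` and `Π` are renormalised to sum exactly to 1, and `W` is then
re-formed from the smoothed pair using the smoothed mean degree — this
keeps the normalisation `Σ u u W = 1` (with `u(k) = k p(k)/⟨k⟩`) exact
after smoothing, and makes `d(A,A) = 0` hold identically. Default
`σ = 1` degree unit; `σ` is a parameter everywhere. Smoothening is applied
on the truncated degree range in use. Truncation of the degree axes
(`--kmax`, default 35 for matrix rendering) is an analysis option, not
part of the definitions: counts at large `k` are too thin to act as clean
probability estimators.

## Complexity

Per node, in nats (a `--bits` option divides by ln 2):

- degree complexity `Σ_k p(k) ln[p(k)/π_⟨k⟩(k)]`, the KL divergence from
  the Poisson distribution with the same mean degree;
- wiring complexity `(⟨k⟩/2) Σ Π ln W`, which equals `(⟨k⟩/2)` times the
  KL divergence of `Π` from its degree-uncorrelated counterpart
  `u(k)u(k′)`, and is identically zero when `W ≡ 1`.

Both are KL divergences, hence non-negative. "Per link" divides by
`⟨k⟩/2` (links per node), the unique conversion that makes the per-link
value independent of average degree; all per-link comparisons in the
package use this convention consistently. Exact (`σ = 0`) complexities
use the `0·ln 0 = 0` convention; the Poisson reference is truncated at the
grid cap with its tail mass reported (and a helper chooses a cap with
tail < 1e−9), bounding the truncation error of the KL.

## Network distance

The distance is the symmetrised KL divergence per node between the
maximum-entropy graph ensembles with the two networks' `(p, W, ⟨k⟩)`,
evaluated in the sparse large-`N` regime with the ensemble normalisation
at its leading value:

```
d(A,B) = ½ Σ_k [p_A ln(p_A/p_B) + p_B ln(p_B/p_A)]
         − ¼ (k̄_A − k̄_B) ln(k̄_A/k̄_B)
         + ¼ k̄_A Σ Π_A ln(W_A/W_B) + ¼ k̄_B Σ Π_B ln(W_B/W_A)
```

Consistency checks built into the construction and verified by tests:

- for two Erdős–Rényi ensembles it reduces to the directly computable
  `¼(k̄_A − k̄_B) ln(k̄_A/k̄_B)`;
- for equal degree statistics it equals `(k̄/4)` times the symmetrised KL
  divergence between the two edge-end joint laws, so it is zero iff the
  smoothed `(p, W, k̄)` coincide and positive when only the wiring
  differs;
- it is symmetric by construction and `d(A,A) = 0` exactly.

The last two lines carry all the DDC information; dropping them yields the
simplified degree-only distance, which is exactly zero for degree-matched
rewirings. Distances require both profiles smoothed with one `σ > 0` on a
shared grid covering both degree supports (the implementation enforces
this); exact `σ = 0` statistics are allowed only for complexities. One
caveat of the leading-order expression: for pathologically different
degree distributions (e.g. heavy point masses with very different means)
the mean-degree cross terms can undercut the degree KL term; for the
sparse, unimodal-ish distributions of real and generated interaction
networks all terms behave as distances.

## Null models

The null model is a uniform draw from all simple graphs with the observed
per-node degree sequence. Two chains are provided, both provably uniform
and both verified against exhaustive enumeration (labelled 4-cycle space
of size 3; perfect-matching spaces of sizes 15 and 105; chi-square
p > 0.01 on ≥ 1e5 sampled states):

- **hold_counting** (default; numba-compiled): proposals are drawn
  uniformly from the state-independent set {ordered pairs of distinct
  edges} × {2 orientations}; proposals that would create a self-loop or
  duplicate edge are executed as "stay" moves. The kernel is symmetric, so
  the stationary law is uniform. Only edge-changing moves count towards
  the equilibration target.
- **mobility_ratio** (pure Python, for small graphs): only executable
  swaps are proposed, uniformly among the `n(c)` moves of the current
  state, accepted with `min(1, n(c)/n(c′))`.

Equilibration: ≥ 100 accepted moves per link (configurable), plus an
observable trace (Hamming distance, assortativity, exact wiring
complexity) at a configurable interval so users can verify relaxation and
extend runs. A chain that cannot move (e.g. a star's degree sequence
admits a unique graph) returns the input unchanged with a warning.

The normalised Hamming distance is
`Δ(A,B) = |E_A △ E_B|/(|E_A| + |E_B|)`: 0 for identical graphs, and for
statistically independent degree-matched sparse graphs its expectation is
`1 − Σ_edges k_i k_j/(2E)² · E⁻¹`-close to 1 — the package exposes this
finite-`N` expectation (`expected_independent_hamming`) and the
equilibration tests compare against it rather than against the asymptotic
value 1, which no finite network can reach exactly.

## Generators and what the synthetic experiments show

The generators produce Erdős–Rényi graphs (independent edges at
`p = ⟨k⟩/(N−1)`), uniform configuration-model samples (Erdős–Gallai check,
Havel–Hakimi realisation, then the unbiased sampler), planted-correlation
graphs, and deterministic toys. Planted correlations steer
`S = Σ_edges k_i k_j` — affine in the assortativity once degrees are fixed
— towards a target by greedy degree-preserving swaps (tolerance band 0.02
in assortativity units; unreachable targets are reported with the achieved
value).

These graphs emulate the *statistical* structure the framework measures —
degree heterogeneity and pairwise degree correlations — and nothing else.
They do not model biological sampling biases (bait selection, spoke-model
expansion of complexes, false positives), modularity or motif structure.
Passing tests therefore demonstrate correctness of the measures and
samplers, not biological claims about real interactomes.

Study conditions used by the test suite and acceptance script (chosen as
realistic mid-size analogues of published interactomes): null-model
endpoints on ER graphs with `N = 2000`, `⟨k⟩ ≈ 5` over 10 seeds;
finite-size decay of null-model wiring complexity at
`N ∈ {500, 2000, 8000}` and fixed `⟨k⟩ = 5` (10 seeds each, exact `σ = 0`
estimator — the smoothed estimator has a small `N`-independent floor that
would mask the decay); sub-sampling ordering with `N = 3000`, `⟨k⟩ = 6`,
planted strength 0.35, 10 repeats, `σ = 1`; clustering recovery with six
networks at `N = 1500`, `⟨k⟩ = 6`, planted assortativity ±0.25.

## Known limitations

- At extreme sub-sampling (≥ 80% of nodes removed) the distance to the
  original is dominated by the collapsing degree distribution and its
  Monte-Carlo spread; the complexity ordering of sub-sampling curves is
  robust up to ~70% removal but can fluctuate beyond that. The acceptance
  script uses paired removal sets for the two networks being compared to
  sharpen the mean-difference estimate.
- The plug-in wiring complexity is upward-biased on finite samples
  (roughly populated-bins/4E nats); the null-model decay experiment
  measures exactly this bias shrinking with `N`.
- The distance is a leading-order sparse-ensemble expression (see caveat
  above); it is not a metric (no triangle-inequality guarantee), matching
  its role as a clustering dissimilarity.
- Dendrograms are exported as Newick with ultrametric branch lengths
  (leaf-to-root depth = merge height / 2); comparison against external
  reference taxonomies is left to external tools.
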