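# ppinet

Information-theoretic characterisation and comparison of protein–protein
interaction networks (PPINs) — or any undirected simple graph.

Interaction maps produced by different experimental techniques (yeast
two-hybrid, affinity-purification mass spectrometry, …) overlap only weakly
at the level of individual interactions, which makes naive edge-overlap
comparisons nearly meaningless. `ppinet` instead compares networks by their
*macroscopic* statistics: each network is reduced to its degree distribution
`p(k)` and its normalised degree–degree correlation (DDC) kernel `W(k, k′)`,
and all characterisation, complexity and comparison measures are exact
functionals of these two objects. The package is aimed at computational and
systems biologists who want to quantify topological information in sampled
interactomes, benchmark observations against rigorous null models, and
cluster collections of networks.

## What it computes

For a network with `N` nodes, `E` edges and mean degree `⟨k⟩ = 2E/N`:

- **Degree statistics** — `p(k)`, the edge-end joint law `Π(k, k′)` (the
  probability that a uniformly drawn interaction joins degrees `k` and
  `k′`), and the normalised DDC kernel

  `W(k, k′) = Π(k, k′) ⟨k⟩² / (k p(k) · k′ p(k′))`,

  the likelihood that nodes of degrees `k` and `k′` interact relative to a
  degree-matched uncorrelated random graph (`W ≡ 1` ⇔ no correlations
  beyond the degrees).
- **Assortativity** — the Pearson correlation of the degree pair under
  `Π`, computable equivalently from `Π` or from `(p, W)`.
- **Complexity** (nats; per node or per link) — degree complexity
  `Σ_k p(k) ln[p(k)/π_⟨k⟩(k)]` (KL divergence from the Poisson reference
  `π_⟨k⟩`) plus wiring complexity `(⟨k⟩/2) Σ Π ln W` (the information in
  the correlations; zero for degree-matched uncorrelated graphs).
- **Network distance** — the symmetrised Kullback–Leibler divergence, per
  node, between the maximum-entropy graph ensembles tailored to
  `(p_A, W_A)` and `(p_B, W_B)`:

  ```
  d(A,B) = ½ Σ_k [p_A ln(p_A/p_B) + p_B ln(p_B/p_A)]
           − ¼ (k̄_A − k̄_B) ln(k̄_A/k̄_B)
           + ¼ k̄_A Σ Π_A ln(W_A/W_B)
           + ¼ k̄_B Σ Π_B ln(W_B/W_A)
  ```

  with `k̄_X = Σ_k k p_X(k)`. Dropping the two `W` lines gives the
  simplified degree-only distance. A weak Gaussian smoothening of `p` and
  `Π` (width σ, default 1) keeps all probabilities strictly positive,
  which the KL terms require.
- **Null models** — uniform draws from all simple graphs with the observed
  degree sequence, generated by edge-swap MCMC with acceptance rules that
  make the sampling provably unbiased (hold-counting, or Metropolis with
  the mobility ratio), run to ≥ 100 accepted moves per link, with
  observable traces and the normalised Hamming distance
  `Δ = |E_A △ E_B| / (|E_A| + |E_B|)` (0 = identical, → 1 = independent).
- **Comparative tools** — pairwise distance matrices (triangular TSV),
  average-linkage dendrograms with Newick export, and node-removal
  sub-sampling robustness curves.
- **Generators** — Erdős–Rényi, uniform configuration-model, planted
  assortative/disassortative, and exact toy graphs, so every analysis is
  reproducible without downloading any dataset.

## Worked example

```python
import ppinet as pp

net = pp.planted_correlation(n=1500, mean_degree=5.0,
                             target_assortativity=-0.35, seed=3)
report = pp.null_model_report(net, pp.RandomisationConfig(seed=11))
print(report.result.hamming_to_original)
print(report.original_assortativity, report.null_assortativity)
```

Running `python examples/02_null_model.py` (the same computation with
commentary) prints:

```
accepted moves: 379900 (100 per link)
Hamming distance to original: 0.9963
  (expectation for a fully independent degree-matched graph: 0.9954)
assortativity: original -0.330 -> null -0.010
wiring complexity per node: original 0.1892 nats -> null 0.0317 nats
```

The randomisation kept every node degree, moved essentially every link
(Hamming ≈ 1), erased the planted degree correlations (assortativity
−0.33 → −0.01) and collapsed the wiring complexity to its finite-size
floor — the fingerprints of a correctly equilibrated, unbiased null model.
The other scripts in `examples/` walk through characterisation (`01`),
complexity (`03`), distances and clustering (`04`) and sub-sampling (`05`).

A thin CLI mirrors the library:

```bash
ppinet generate --family er --n 1000 --mean-degree 5 --seed 1 --out er.txt
ppinet stats er.txt
ppinet nullmodel er.txt --seed 7 --out null.txt --report run.json
ppinet cluster a.txt b.txt c.txt --newick tree.nwk
```

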