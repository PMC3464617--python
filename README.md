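# contactscales

Protein contact networks (PCNs) at different length scales and residue
classes.  `contactscales` builds normalized side-chain interaction
networks from atomic coordinates, slices them by sequence-separation
range and physico-chemical residue class, and analyzes how their largest
connected component collapses as the interaction threshold rises —
together with degree mixing, clustering, and a census of 3-clique
compositions.  It is aimed at structural bioinformaticians studying the
roles of short- vs long-range and hydrophobic vs hydrophilic vs charged
contacts in protein stability (e.g. thermophile/mesophile comparisons).

## The model

Residues are nodes.  For residues *i* and *j* the van der Waals contact
strength is the percentage

```
I_ij = n_ij / sqrt(N_i * N_j) * 100
```

where `n_ij` counts pairs of side-chain heavy atoms within 5 Å and `N_i`
is a per-residue-type normalization: the mean (over a reference set of
proteins) of the per-protein maximum number of atom-level interaction
pairs — main-chain *and* side-chain — made by a residue of that type.
An edge exists iff `I_ij > I_min`.  Three orthogonal filters slice the
network:

* range: ARN (`x = |i−j| > 0`), LRN (`x > 10`), SRN (`0 < x ≤ 10`);
* class: AN (all), BN (hydrophobic F M W I V L P A), IN (hydrophilic
  N C Q G S T Y), CN (charged R D E H K);
* threshold `I_min` from 0 to 10 %.

On this family of graphs the package computes:

* **Transition profiles** — normalized largest-connected-component (LCC)
  size vs `I_min`; **I_critical** (threshold at which the LCC halves,
  interpolated) and the **cooperativity index** CI = A/B (onset over
  breakdown threshold; sharp collapse ⇒ CI → 1);
* **Assortativity** r — Pearson correlation of endpoint degrees over
  edges (undefined, not zero, for degree-regular components);
* **Clustering** C_i = 2e_i / k_i(k_i−1);
* **3-clique census** — triangles classified by member classes
  (BBB … CCC), counts normalized by the combinatorially possible triples
  (C(n_B,3) for BBB, C(n_B,2)·n_I for BBI, n_B·n_I·n_C for BCI, …), plus
  sequence perimeters |a−b|+|b−c|+|a−c|;
* **Cohort aggregation** — per-(range, class) component statistics over
  components of ≥ 30 residues, assortative fractions, clique dominance
  distributions, composition counts.

A synthetic-structure generator (`synthetic_data`) emits valid PDB files
of chain-like extended chains (short-range dominated) and compact
lattice globules (long-range rich), with controllable residue-class
composition, contact density and planted 3-cliques, so the whole
pipeline is testable without downloading structures.

## Worked example

```python
from contactscales import *

# a synthetic study cohort: 20 chain-like + 20 globular structures
helices  = [generate_structure(GeneratorConfig(n_residues=100,
                topology="helix_chain", seed=s)) for s in range(20)]
globules = [generate_structure(GeneratorConfig(n_residues=100,
                topology="compact_globule", side_chain_mode="blob",
                seed=1000 + s)) for s in range(20)]

table = compute_normalization(helices + globules)   # N_i from the cohort
cm = build_contact_map(globules[0], table)

p = transition_profile(cm, "arn", "an")
print(round(i_critical(p), 2), round(cooperativity_index(p), 2))
# 3.62 0.38   <- the globule collapses gradually around I_min ~ 3.6 %

g = build_graph(cm, NetworkSpec("arn", "an", 0.0))
m = graph_metrics(g, min_component_size=30).per_component[0]
print(round(m.r, 2), round(m.mean_clustering, 2))
# 0.33 0.43   <- assortative and well clustered, like folded proteins

cen = census(g, class_counts=globules[0].class_counts())
print(cen.counts["BBB"], round(cen.normalized["BBB"], 4))
# 56 0.0037   <- 56 hydrophobic triangles; 0.37 % of the possible ones
```

The same profile on a chain-like structure collapses sharply at a much
lower threshold (I_critical ≈ 0.75, CI = 0.50 under the shared table) —
the short-range vs long-range cooperativity contrast the transition
analysis is built to expose.

A thin CLI mirrors the library: `contactscales simulate | validate |
contactmap | transition | cliques | cohort` (see `--help`).

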