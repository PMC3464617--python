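# Methods

## Network construction

A structure is a single protein chain; residues are renumbered
contiguously `1..L` in file order, so the sequence separation
`x = |i − j|` used by the range filters is independent of author
numbering and insertion codes.  Hydrogens, waters, ligands and all but
the highest-occupancy alternate location are discarded; multi-model
files contribute model 1 only.  Non-standard residues with a standard
parent (e.g. selenomethionine) are mapped to it; others are dropped.  A
gap in author numbering is treated as missing residues and rejected by
default (`strict=False` parses through), because distance-based network
parameters computed from incomplete chains are biased.

Contacts are purely distance-based (London–van der Waals): two heavy
atoms interact when their separation is at most 5 Å (closed comparison).
The pair count `n_ij` uses side-chain atoms only; glycine, which has no
heavy side-chain atom, is represented by its CA so that it can
participate in contacts and in hydrophilic subnetworks.  This surrogate
is a package choice — the underlying construction leaves glycine
unspecified — and is applied uniformly.

### Normalization factors

`N_i` for each of the 20 residue types is the mean over a reference
structure set of the per-protein maximum number of interaction pairs
(main-chain plus side-chain atoms, 5 Å rule, all other residues of the
chain) made by a residue of that type.  The asymmetry — all-atom counts
in the normalization, side-chain-only counts in the numerator — is
deliberate and follows the published construction.  The interaction
strength is

    I_ij = n_ij / sqrt(N_i · N_j) · 100 .

The geometric-mean denominator keeps strengths on the percent scale on
which the transition thresholds operate (grids to 10 %, critical
thresholds of a few percent); a plain product would push every strength
far below 1 % for realistically packed structures, since `N_i` bounds
any single pair count from above.  Scaling every `N_i` by `c` scales
every `I_ij` by `1/c`.

Because `N_i` requires each type to occur somewhere in the reference
set, single structures usually cannot self-normalize; cohorts compute
one table from the whole set (the reference-scale analysis uses one
table for all proteins), and every output records the table's
provenance, since all downstream numbers depend on it.  Tables can be
exchanged as two-column TSV.

## Subnetworks and metrics

A network slice is `(range, class, I_min)`: range keeps edges by
sequence separation (ARN `x>0`, LRN `x>10`, SRN `0<x≤10`), class keeps
*nodes* by residue class (both endpoints must survive), and an edge
exists iff `I_ij > I_min` strictly.  Isolated nodes are retained, and
normalized LCC sizes always divide by the full residue count `L` of the
protein — also in class-restricted slices — so profiles of different
slices of one protein are comparable.  SRN includes covalently adjacent
pairs (`x = 1`); users who want to exclude trivial neighbours can filter
the contact map's separation matrix before building graphs.

Assortativity is Newman's edge-wise Pearson degree correlation, each
edge counted once with its two endpoint degrees.  When all endpoint
degrees are equal the expression is 0/0; it is reported as NaN
("undefined") and excluded from cohort averages rather than coerced to
zero.  Clustering is `C_i = 2e_i / k_i(k_i−1)` with `C_i = 0` for
degree < 2.  Component statistics are computed per connected component,
defaulting to components of at least 30 nodes — below that, topology
statistics of subclusters are too noisy — and the assortative fraction
is the share of qualifying components with `r > 0`.

## Transition analysis

The LCC profile is evaluated on a grid of `I_min` values, default 0 to
10 % in steps of 0.5 (matching the half-percent resolution at which
critical thresholds are conventionally reported).  `i_critical` is the
threshold at which the LCC first falls to half its size at `I_min = 0`,
linearly interpolated between bracketing grid points to remove grid-step
bias in paired comparisons.  The cooperativity index is `CI = A/B` with
A the largest grid value at which the LCC still holds ≥ 95 % of its
initial size and B the smallest at which it is ≤ 10 %.  The 95 %/10 %
operationalization is a package choice (the onset and breakdown points
have no rigorous standard definition); both fractions are exposed as
parameters.  Profiles that never reach a level on the grid return a NaN
sentinel ("beyond grid"), which paired comparisons drop from averages.

## Clique census

Triangles are enumerated on all-residue (AN) graphs and classified by
the multiset of member classes into ten types.  Counts are normalized by
the number of composition-compatible triples the protein could form:
`C(n_X, 3)` for XXX, `C(n_X, 2)·n_Y` for XXY, `n_B·n_I·n_C` for BCI.
The mixed-type denominators generalize the published all-hydrophobic
example (939 BBB cliques / C(173, 3) = 0.0011), which is verified in the
tests.  Perimeter is the sum of pairwise sequence separations
(equivalently `2·(max − min)` for sorted members).  Dominant-type and
maximum-perimeter ties break deterministically in the fixed order BBB,
BBI, BBC, BII, BCI, BCC, III, CII, CCI, CCC.

## Synthetic structures

The generator emulates two contrasting regimes rather than protein
physics:

* `helix_chain`: an extended, gently waving chain (CA step 3.8 Å, full
  backbone N/CA/C/O, one CB pseudo-atom per residue pointing to the same
  side).  Side chains touch only sequence neighbours, so the contact
  graph is a chain, every edge is short-range, and with `n_ij = 1`
  everywhere the strength distribution is a narrow band — the regime of
  a sharp, cooperative collapse.
* `compact_globule`: the chain is folded onto a jittered boustrophedon
  walk through a near-cubic lattice (spacing `6.05 − 0.33·density` Å),
  with side-chain directions cycling perpendicular to the local chain so
  contacts form across the fold; at the default density about a third or
  more of contacts have `x > 10`.  In `"blob"` mode every residue
  carries two loosely scattered pseudo side-chain atoms (scatter 0.8 Å),
  so pair counts — and hence strengths — vary with packing geometry
  while staying independent of residue identity; the collapse is
  gradual.
* `planted_cliques`: a globule in which chosen residue triples receive
  prescribed classes and mutually touching side chains, giving
  ground-truth triangles for recovery tests.

Amino-acid identities are drawn from the configured class fractions
(default 0.45/0.33/0.22 hydrophobic/hydrophilic/charged, roughly the
composition of globular proteins) and uniformly within a class.  All
randomness flows from the config seed; a fixed config reproduces
identical PDB bytes.  `contact_density` maps approximately to side-chain
contacts per residue through the lattice spacing and is validated
against the geometric capacity of each topology (requests outside it
raise).

The transition **study conditions** pair 20 chain-like structures
(density 2, single-atom side chains) with 20 globules (density 5, blob
mode) of equal length 100 under one shared normalization table computed
from the combined cohort — mirroring the practice of computing one table
from the whole analyzed dataset.  Under these conditions the chain-like
cohort shows a higher cooperativity index and a lower `i_critical` than
the globular cohort, and raising the globule contact density to 6.5
(thermophile-like packing) shifts the long-range `i_critical` upward
against a density-5 baseline.  The generator reproduces the *mechanisms*
(chain-like vs cross-linked topology, homogeneous vs heterogeneous
contact strengths, density-driven long-range stabilization), not real
protein geometry: secondary-structure packing, residue-specific contact
propensities and realistic degree correlations are absent, so passing
tests demonstrate correctness of the analysis pipeline and the
qualitative mechanics, not quantitative agreement with experimental
structures.

## Numerical and design choices

* Distance comparisons are closed (`≤ 5 Å`), applied identically in pair
  counting and normalization.
* `i_critical` interpolation is linear; an exact grid hit returns the
  grid value.
* Assortativity uses a `1e-12` tolerance on the variance denominator
  before declaring the value undefined.
* Component order (for ranks and ties) is by decreasing size, then
  smallest member index.
* Cohort standard deviations are over components by default
  (`sd_over="proteins"` aggregates per protein first); whether published
  cohort spreads were taken over proteins or components is ambiguous, so
  both are available.
* The cohort pipeline excludes structures containing a residue with no
  atoms (reported, not silently dropped) and records the normalization
  provenance in its summary.

## Problem sizes

The shipped tests and the acceptance script run entirely on synthetic
cohorts: 20 + 20 structures of 100 residues for the transition contrast,
10 + 10 for the density shift, 200 random graphs (n ≤ 60) for the metric
oracles.  These sizes give stable means (standard errors well below the
contrasted differences) at desk-scale runtimes.

## Limitations

* Only London–van der Waals (distance) contacts: no electrostatics,
  hydrogen bonds or disulfides, by construction.
* Single chains: inter-chain contacts, symmetry mates and biological
  assemblies are out of scope, as is mmCIF input.
* Cohort-level reproduction of reference statistics (mean assortativity
  0.30 in all-range networks, 91 % assortative hydrophobic long-range
  subclusters, clique dominance percentages, …) requires the 495-chain
  reference set of experimentally determined structures, which cannot be
  bundled; the pipeline runs it when the chains and a `manifest.tsv` are
  placed under `data/reference_cohort/`.  Absolute strength scales also
  depend on the normalization table, which for real data must be
  computed from (or supplied for) the analyzed cohort.
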