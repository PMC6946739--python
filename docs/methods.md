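# Methods

## The model

The package treats each protein's gene tree as a realization of a simple
acquisition model: at some time in the past a gene entered the ancestor
of one or more Archaeplastida lineages (from cyanobacteria, other
bacteria, or the host's eukaryotic toolkit), the lineage later
diversified, and branch lengths accumulated at an approximately constant
rate. Under that clock assumption, the ratio of the stem length (from
the attachment point of a lineage's clade to its crown) to the typical
branch length inside the crown is proportional to the ratio of two
durations — acquisition-to-diversification over diversification-to-
present — and is therefore comparable across proteins regardless of each
protein's absolute rate. Relative stem lengths are dimensionless; all
branch lengths are substitutions/site.

Two lineages are measured independently: green (Viridiplantae, crowned
at the chlorophyte–streptophyte split, LVCA) and red (Rhodophyta,
crowned at the Cyanidiophytina–Rhodophytina split, LRCA). Glaucophytes
count as Archaeplastida when deciding whether a tree has a rootable
outgroup, but are never a measured lineage: with essentially one genome
available the stem of the whole Archaeplastida would hinge on a single
taxon, and many proteins are missing from one lineage anyway.

## Classification

A rooted, annotated tree is classified per lineage by the sister set at
the attachment of the Archaeplastida complex: starting from the lineage
crown, ancestors are ascended while the newly gained tips are all
Archaeplastida; the first ancestor gaining anything else defines the
sister set S. S entirely cyanobacterial and equal to the full
cyanobacterial tip set → type 2; a proper subset (cyanobacteria
paraphyletic) → type 1; at least the purity threshold (default 0.8) of S
other-bacterial → type 3; other-eukaryotic → type 4; otherwise the call
is `unresolved`, never forced. A tree without green/red/glaucophyte tips
is type 5 outright. A type-1/2 pattern in a tree whose only
non-Archaeplastida tips are cyanobacteria is downgraded to type 1c,
since no outgroup exists to root it; such trees are rooted by the
Gloeobacter-first convention (or MAD when no Gloeobacter tip exists).
The purity threshold tolerates sporadic horizontally transferred taxa in
an otherwise clean sister group without ever flipping a call between the
four concrete types.

Sub-origin within cyanobacteria (types 1/1c/2 only): `alpha` if every
cyanobacterial tip of S is α, `beta` if all β, `deep` if S contains any
basal taxon (Gloeobacter, Yellowstone *Synechococcus*, *Pseudanabaena*)
or mixes α and β. When green and red attach at different points each
lineage gets an independent call and the tree is flagged
`separated_lineages`; no combined Archaeplastida call is emitted.

Intruders inside a lineage crown: by default none are tolerated
(`k_intruders = 0`), because inputs are expected to be curated trees;
raising k marks the clade `tolerated` and lists the intruders rather
than silently absorbing them.

## Stem and leaf measurement

The stem origin is the nearest ancestor of the crown with at least one
descendant tip outside the lineage (tips flagged `rogue` are pruned
first, merging traversed branch lengths, so a stem may span several
former edges). S is the path length crown→origin. The leaf length L has
two readings, both implemented because "the median length of the clade"
is genuinely ambiguous:

* `clade_branches` (default): median of every branch strictly inside the
  crown clade, terminal and internal, excluding the stem edge. This
  follows the gloss "median of branch lengths in the respective
  subtree", and is invariant to rerooting above the crown.
* `tip_depth`: median crown-to-tip path length.

Even-count medians average the central pair. CL is measured the same way
(same mode as L, so CL/VL compares like with like) on the largest
all-cyanobacterial subclade among the siblings of the stem origin, after
dropping `cl_exclude`-flagged tips; it is missing — a value, not an
error — when no cyanobacterial neighbor exists (types 3/4) or fewer than
two branches survive exclusion. CL/RL is not reported: red-lineage taxon
sampling is typically too thin for a robust RL.

## Rooting

Three conventions, chosen per input (precedence in the batch driver:
explicit outgroup if configured, else MAD, else basal-taxon):

* **Outgroup**: root at the midpoint of the edge separating the smallest
  subtree containing all outgroup tips; a non-monophyletic outgroup
  roots at the best-separating edge with a warning. The midpoint choice
  only splits the root edge; it cannot affect any stem or leaf measured
  below the root.
* **MAD** (minimal ancestor deviation): for each candidate root position
  x on each edge, each tip pair (b, c) whose path crosses the root
  contributes the relative deviation r = |2(d_ib + x)/d_bc − 1|; pairs on
  one side keep their ordinary ancestor and a position-free deviation.
  The per-edge optimum has the closed form
  x\* = Σ d_bc⁻²(d_bc − 2 d_ib) / (2 Σ d_bc⁻²) over crossing pairs,
  clamped to the edge; the returned root minimizes the RMS deviation
  over all pairs. Ties below 1e-12 break to the earliest edge in
  post-order — a reproducibility choice among equivalent optima. Zero
  tip-pair distances make the deviation undefined and raise an error.
* **Basal taxon**: the named subgroup (default `gloeobacter`) is forced
  first-branching, for type 1c trees.

All three preserve pairwise tip distances exactly (they only insert a
root), verified to 1e-9 in tests.

## Aggregation and the reference point

Ratios are combined as geometric means — across methods per protein,
and across the reference set per axis — because they are ratios;
arithmetic means would weight the numerator scale. CL/VL is combined
only over methods where CL was measurable. The reference bands are
exp(mean ± SD) of the log values (sample SD, ddof = 1; a single-row
reference degenerates to a point). The log scale is a package choice:
all aggregation here is geometric, so the bands live on the same scale;
raw-scale SD bands would be asymmetric around a geometric center.
Timing calls are then: above the band `earlier`, below `later`, inside
`canonical`.

PhyloBayes-style third-opinion trees can be included or excluded from a
protein's method set explicitly in the batch configuration; nothing is
included implicitly.

## The simulator

`simulate_tree` builds an ultrametric time tree: every crown clade is a
pure-birth (Yule) tree conditioned on its tip count (generated by
dendropy's birth–death sampler, extended by one extra exponential
waiting time so the final cherry has positive terminal branches, then
rescaled to its configured crown depth). Default depths: green and red
crowns 1.0, Archaeplastida crown 1.3, stem duration s = 0.5, giving an
attachment age A = 1.8; cyanobacterial structure (α/β crowns and split,
basal ladder) is laid out as fixed multiples of A per archetype so the
attachment always lands on the intended edge; outgroup clades join 25%
older per step with crowns at 70% of their join age. Clade sizes default
to 3+3 green, 2+3 red (red sampling is deliberately thin, as in real
data), 4 α, 5 β, 3 basal (Gloeobacter, Yellowstone, *Pseudanabaena*,
deepest first), 3 + 3 outgroup tips — about 26 tips, the scale of a
curated single-protein tree. Rate noise multiplies every branch by an
independent lognormal factor with log-mean −σ²/2 and log-SD σ (unit
expectation); σ = 0 is exactly the identity.

Ground truth (type, sub-origin, per-lineage S, L, S/L, CL in both leaf
modes) is *measured* on the noiseless time tree with the same median
rules the estimator uses, not derived from formulas — so strict-clock
recovery is an exact round-trip test of the whole pipeline including
Newick serialization (written with 17 significant digits for lossless
float round-trips).

What the simulator does not emulate: phylogenetic reconstruction error
(trees are perturbed, never re-inferred from sequences), horizontal
transfer beyond the archetypes, gene duplication/loss, missing taxa, or
alignment artifacts. Passing recovery tests therefore demonstrates the
correctness of the measurement and classification logic under the
acquisition model, not robustness to tree-inference failure modes.

## Numerical choices and edge cases

* Branch lengths compared with absolute tolerance 1e-9 package-wide;
  ratio invariances asserted at 1e-12.
* Missing branch lengths parse as 0 with a recorded warning; negative
  lengths are an error; polytomies are legal everywhere and MRCAs are
  taken on the multifurcating tree as-is.
* Numeric internal-node labels are retained as support values, never
  taxa. Duplicate tip labels are an error naming the label.
* Geometric means reject empty and non-positive inputs; a crown at the
  tree root has no stem (`stem undefined` error); a zero leaf median is
  an error rather than an infinite ratio.
* The noise-robustness regression bound (median relative VS/VL error at
  σ = 0.25 over 200 fixed-seed replicates of the default T2
  configuration) was measured once at 0.179 and frozen at 0.25.

## Known limitations

Relative stem lengths are time proxies only under the clock assumption;
the CL/VL control flags rate shifts in the measured crown but cannot
correct them. Classification trusts the input topology: method
disagreement is reported per method with a consistency note in the run
log, never adjudicated. The reference-point bands describe dispersion of
the reference set, not confidence intervals for an individual protein.
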