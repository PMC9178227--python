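# Methods

This note documents the models, conventions and numerical choices behind
`orthodelta`, in the order the pipeline runs: tree handling → gene-family
decomposition → concordance → the Δ test → the simulators that everything
is validated against.

## Trees and conventions

Trees are `skbio.TreeNode` objects; Newick I/O accepts quoted labels,
internal-node labels (kept as annotations, never treated as taxa), missing
branch lengths and scientific notation. Leaf labels must be unique within
a tree; gene copies carry ids like `speciesA|g2`, and the default species
resolution takes the label prefix before the first `|` (an explicit
two-column table can override this; a label missing from a table is a hard
error, because silently dropping copies corrupts occupancy counts).

**Midpoint rooting** places the root halfway along the longest
leaf-to-leaf path. When several pairs attain the maximum, the
lexicographically smallest (leafA, leafB) name pair wins, making the
operation deterministic; when the midpoint coincides with a node, the
incident edge is subdivided at position zero rather than rerooting on the
node itself. A tree whose branch lengths are all zero has no midpoint; it
is rooted on the first internal edge in preorder with a warning. Missing
branch lengths are an error.

**Collapsing** contracts internal branches with length ≤ tol (default 0,
i.e. exact zeros — the tolerance is configurable because upstream tools
differ in how they write near-zero lengths) into polytomies. Terminal
branches are never collapsed: leaves must survive.

**Robinson–Foulds** distances count the symmetric difference of
non-trivial splits. The normalization divides by the number of non-trivial
splits actually present in the two trees, which is 2(n−3) for two binary
trees and degrades gracefully for polytomous ones.

## Decomposition

All trimming operates on midpoint-rooted trees (applied automatically when
the input is unrooted) and only ever removes leaves; `trim_lsd` and
`trim_tsd` are idempotent.

* **LSD.** A lineage-specific duplication is a maximal clade whose copies
  all belong to one species. The survivor is the copy whose ungapped
  sequence length is closest to the median length over *all* sequences in
  the family (lower median for even counts; distance ties broken by tree
  order). Tree-only inputs have no lengths; the fallback keeps the copy
  with the smallest root-to-tip distance (ties: lexicographic id) on the
  logic that runaway branches are the less trustworthy copies.
* **TSD.** A two-species duplication is a maximal clade whose copies come
  from exactly two species with at least three copies (a plain
  cross-species cherry contains no duplicate and is untouched). The
  surviving pair is the cross-species pair with the minimum patristic
  distance — the two copies most plausibly orthologous — with equal
  distances broken by the lexicographically smallest (copy, copy) pair.
* **SE** trims LSD and TSD, then emits every node whose subtree contains
  no species twice but whose parent's subtree does, in a single pass.
  These subtrees are leaf-disjoint and cover all post-trim leaves; the
  occupancy filter is applied afterwards.
* **MI** first cuts every branch (terminal or internal) longer than the
  cutoff and treats the resulting components separately. Each component is
  then processed iteratively: a duplicate-free tree is emitted whole;
  otherwise the duplicate-free clade with the most species is cut off and
  emitted and the remainder is pushed back for re-analysis. Ties among
  equally species-rich clades prefer the smaller total branch length, then
  postorder position. This remainder re-analysis is what distinguishes MI
  from SE in practice: at this package's default simulation conditions the
  two methods produce identical ortholog-set collections for roughly 85–90%
  of trimmed families, and every disagreement traces to a remainder that MI
  re-assembles into one larger set where SE's single pass reports separate
  maximal clades (or none above the occupancy threshold).
* **MO** requires at least one outgroup species, each outgroup species
  single-copy, and the outgroup copies monophyletic; otherwise the family
  is rejected. After rooting on the outgroup clade the ingroup is
  traversed root-to-tips; at any node whose child subtrees share a species
  (a duplication), the child with more species is kept — ties prefer the
  side with fewer gene copies, since extra copies suggest further hidden
  duplications, then tree order — and the rest is pruned. Polytomous
  duplication nodes are resolved by repeatedly pruning the weaker
  overlapping child.
* **ONE** samples one copy per species uniformly. The RNG stream is
  derived from (seed, family id), so a family's draw is independent of
  processing order.

The occupancy threshold counts distinct species and is applied after
extraction for every method.

## Concordance

Internal branches of the rooted binary species tree are enumerated in
preorder with stable ids; the two root-adjacent rooted edges map to a
single unrooted branch and are emitted once, with the C/D groups taken
from the sibling clade's children. Classification tests split presence on
the gene tree *viewed unrooted* (split presence is rooting-free), using
induced splits: a candidate split is present in the pruned gene tree iff
some bipartition of the full tree restricts to it with both sides
non-empty. At most one of the three candidate splits can be present
(conflicting splits are incompatible) and this is asserted on every
classification. Decisiveness requires at least one sampled species from
each of the four groups. Polytomies arising from zero-branch collapsing
are classified as-is: a region that resolves none of the three splits
yields PARAPHYLETIC, never an arbitrary resolution.

The discordant fraction used for test gating counts the two minor
topologies only, because those are the classes the Δ test consumes; the
complement-of-concordance alternative is available behind a flag.

## The Δ test

DF1/DF2 identities are fixed at their observed values and held fixed
across bootstrap replicates, so replicate Δ values are signed;
re-identifying DF1 per replicate would fold the null distribution and
bias Δ upward, and is available only as an explicit flag. Replicates
resample the full decisive classification list (concordant, both minors,
paraphyletic), so the discordant count varies per replicate exactly as it
would under gene-tree resampling; operationally this is a multinomial draw
over the observed class counts, which is equivalent to resampling the
label list and vectorizes. The Z-score divides the observed Δ by the
bootstrap standard deviation (ddof = 1) and the p-value is the two-sided
normal tail; a percentile alternative (two-sided tail of the centered
bootstrap distribution, floored at 1/B) is available behind a flag. A
degenerate bootstrap (sd = 0) reports p = 1 with a warning rather than a
spurious infinity.

Branches are tested only when their discordant fraction exceeds the gate
(default 5%); m for the Šidák correction counts the gated-in branches of
the current data set. The report always contains one row per internal
branch, with untested branches flagged and their statistics set to NaN.

Calibration, measured by the test suite: with equal minor-topology
probabilities the rejection rate at nominal 0.05 sits inside its 99%
binomial interval (slightly above nominal, as expected from the normal
approximation), and the family-wise false-positive rate of the full
simulate → classify → test pipeline stays at the corrected level.

## Simulators

One unit system throughout: species-tree branch lengths are coalescent
units, and duplication/loss rates are per copy per coalescent unit.

* **Species trees** are pure-birth (Yule) trees grown forward at rate 1
  per lineage until the target tip count, with one extra exponential
  waiting time so terminal branches are positive; they are ultrametric by
  construction.
* **MSC gene trees**: one lineage per species, pairwise coalescence at
  rate 1 within each branch, remaining lineages coalescing above the root.
  Correctness is checked against the closed-form triplet discordance
  (2/3)e^(−T) at T ∈ {0.5, 1, 2} and the equality of the two minor
  topologies.
* **Duplication–loss families** hang a birth–death process on the species
  tree: a single copy enters at the root, duplicates at rate λ (spawning
  an independent subtree) and dies at rate μ; survivors speciate at
  species-tree nodes. Internal nodes carry truth labels (D/S). The gene
  tree equals the locus tree — there is no within-locus coalescent
  layering — which suffices to exercise decomposition truth recovery;
  consequently these families contain no ILS, and passing decomposition
  tests says nothing about gene-tree estimation error either (no noise
  model). λ = μ = 0 reproduces the species tree exactly. Defaults
  (12 species, λ = μ = 0.3) give families averaging on the order of one
  copy per species with frequent multi-copy clades, comparable in
  duplication density to real vertebrate gene-family sets.
* **Triplet counts** draw n loci from the three-class multinomial in which
  a locus follows the species history with probability 1 − γ (concordant
  1 − (2/3)e^(−T), minors (1/3)e^(−T) each) and the introgressed history
  with probability γ, whose major class is the first minor topology (T′
  being the post-introgression branch length). This is the null/alternative
  generator for Δ calibration and power.
* **True ortholog groups** are the maximal clades containing no D node —
  the copies descending from a single ancestral copy without duplication.
  Recovery by SE is checked modulo the copies LSD/TSD trimming removes by
  design (the trimming survivor inside a mixed duplicate clade need not
  belong to a given group), and is exact in that sense.

All simulators are bit-reproducible given (seed, configuration); RNG
substreams are derived from SHA-256 of (seed, purpose, key) so adding
families or branches never perturbs other streams.

## Problem sizes and limitations

The statistical checks run at deliberately moderate sizes chosen for a
laptop-class machine: 1,000–1,100 duplication–loss families for the safety
and oracle studies, 100 replicate data sets of 300 loci for the
family-wise error study, 10,000 loci per branch length for the coalescent
closed-form checks, and 100 replicates per γ for the power study. These
are the package's study conditions, not tuning knobs.

Known limitations: no sequence-level operations (alignments, site
concordance factors, model selection are out of scope); concordance and Δ
require single-copy-per-species gene trees — multi-copy inputs are
rejected with a pointer to the decomposition methods rather than silently
resolved; the duplication–loss generator models neither ILS-aware
duplicate placement nor gene-tree error, so empirical gene trees — which
carry both — will behave more noisily than the synthetic test bed; and the
Δ test's normal approximation is mildly anticonservative for small minor
counts, which the >5% discordance gate largely screens out.
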