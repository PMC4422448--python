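# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `treetally`, in the spirit of the methods documentation of
mature simulation/inference packages.

## Segment extraction and naming

Proteins are split at caller-supplied residue coordinates (1-based,
inclusive at both ends); domain prediction is deliberately out of scope, so
the taxon table is the single source of segment boundaries, and the
invariant `seg1.end < seg2.start` is enforced at parse time.  Taxon codes
follow the 5-letter convention common in large phytochrome compilations:
three letters of the genus plus two of the epithet, an optional
strain-disambiguating character (caller-supplied, since no convention
dictates how it is chosen), then the protein abbreviation
(`Agrobacterium tumefaciens` + `Agp1` → `AgrTuAgp1`; a second strain →
`AgrTuFAgp1`).  Ambiguity codes (B, Z, U, O, J) collapse to X at read time
because every downstream model is 20-state.

## Alignment editing

* **Gap-column filter.** A column is removed iff its gap fraction is
  *strictly greater* than the threshold (default 0.5): a column with exactly
  50% gaps survives.  This literal "more than half" rule makes the boundary
  case well-defined and the operation idempotent.  Surviving columns carry a
  `column_keep_map` back to original coordinates.
* **Informative sites.** The standard parsimony-informative rule: at least
  two distinct states, each in at least two rows.  Gaps *and X* count as
  missing — an unknown residue cannot support a split.  The fraction is
  undefined below 4 rows (no column can then be informative for a split).
* **Overlap filter.** Rows with fewer than `min_overlap` non-gap columns
  (default 100) are dropped and reported.  Published deep alignments prune
  such rows by eye; the exact historical cutoffs are never stated, so the
  threshold is an explicit parameter here rather than a guess.
* **Bootstrap.** Replicate *r* draws its columns from
  `numpy.random.default_rng([seed, r])` — a named, versioned generator with
  a documented substream per replicate, so any single replicate can be
  regenerated in isolation.

## Distances

The default pairwise model is the Kimura protein correction
`d = −ln(1 − p − 0.2 p²)` over shared non-missing columns: a closed form
requiring no data files that tracks empirical-matrix distances well at the
divergences where trees are still estimable.  Per-pair maximum-likelihood
distances under any supplied reversible exchangeability matrix (PAML `.dat`
format) are available as the `empirical` model; no matrix file ships with
the package.  Rate-heterogeneity-corrected distances are deliberately not
offered — the classic distance-program setting these pipelines used is
"no gamma", and the simulator intentionally violates that assumption (see
Limitations).

Saturation: when `1 − p − 0.2 p² ≤ 0` (p ≳ 0.854) or the correction exceeds
the cap, the distance is set to a configurable maximum (default 10
substitutions/site) and a `SaturationWarning` is raised rather than an
error, because deep multi-kingdom datasets always contain saturated pairs
and a hard failure would make whole-matrix construction impossible.

## Tree building

* **Neighbor joining** is the standard agglomerative algorithm; on additive
  matrices it returns the generating topology with exact branch lengths
  (verified against brute-force least-squares over all 5-leaf topologies
  and on random trees up to 10 leaves).  Q-criterion ties break toward the
  lowest (i, j) index pair under the current label ordering — runs are
  bit-reproducible.  Negative length estimates clamp to zero.
* **Least-squares branch lengths** re-fit any fixed (possibly
  multifurcating) topology to a distance matrix by unweighted least squares
  (minimum-norm solution where edges are confounded, e.g. the two root
  edges of a rooted tree; negatives clamped to zero afterwards).  This is
  the in-repo stand-in for the classic "user tree" branch-length
  re-estimation step applied to consensus topologies.
* **Majority-rule consensus** includes exactly the nontrivial bipartitions
  present in strictly more than `threshold` (default 0.5) of the trees; a
  split in exactly half the trees is excluded.  Each consensus clade carries
  its occurrence fraction as support.  Splits above 50% are pairwise
  compatible, so the build is a laminar-family nesting.
* **Fitch parsimony** is a small-instance scoring oracle (bottom-up set
  pass, missing data contributes nothing); it is exact on binary trees,
  which is what the in-repo builders produce.
* **Ensembles.** The method axis is distance-model × bootstrap-consensus:
  for each model, 100 (configurable) bootstrap NJ trees are summarised by
  majority-rule consensus, then branch lengths are re-fit by least squares
  against the full-alignment matrix.  Model *m*, replicate *r* draws from
  `default_rng([seed, m, r])`.  External tree programs attach through an
  adapter (`command template with {in}/{out}` → Newick), keeping the
  ensemble open without re-implementing them.

## Topological hypotheses

All predicates operate on rooted trees; trees are midpoint-rooted by
default (outgroup rooting available), and every tally records which rooting
was used.  Midpoint rooting of a 2-leaf tree is special-cased (the wrapped
tree library degenerates there).

* `is_monophyletic(group, max_outliers)`: some clade contains all group
  leaves with at most `max_outliers` foreigners; the witness is the
  smallest such clade (witness clades containing a fixed leaf set are
  totally ordered on binary trees, so "smallest" is unique; on
  multifurcating consensus trees the first-found smallest in postorder is
  used).
* `sister_group` / `is_sister_of(A, B, mode)`: the sibling leaf set of the
  witness; `strict` requires the sister to consist entirely of B-leaves,
  `majority` requires strictly more than half.  A non-monophyletic group
  has no defined sister (an error; tallies count it as "does not hold").
* `is_basal(group)`: one child clade of the root consists of group members
  up to the outlier allowance.  Completeness of the group inside that child
  is *not* required — "a pure block of the group at the base" counts, which
  is the reading that matches how basal groups are scored in published
  tally tables; demand completeness by combining with `monophyly`.
* `placed_within(taxon, group)`: the taxon lies inside the smallest clade
  spanning the group ("X among Y", the intruder signature).  With the
  taxon's own group the taxon is first excluded from the group set, so the
  negation (`negate: true` in a hypothesis) expresses "X outside its own
  group".
* `are_adjacent(a, b, max_clade_size)`: smallest clade containing both has
  at most `max_clade_size` leaves; the default 2 is the strict cherry
  reading of "next to each other".
* `split_count(group)`: number of maximal all-group clades (1 ⇔ the group
  is monophyletic with zero outliers).

`tally_ensemble` evaluates each hypothesis on every tree of every ensemble
partition (e.g. seg1 vs seg2) and reports `count / denominator` per cell;
trees missing a hypothesis's subject taxa shrink that cell's denominator
rather than counting against it.

## Synthetic evolution

The generator emulates the structure of a two-segment photoreceptor family:

* **Species tree**: Yule (pure birth, no extinction — the simplest process
  with controllable depth), rescaled to a root-to-tip depth of 0.5 expected
  substitutions/site by default: deep enough that groups are distinct,
  shallow enough that distances are far from saturation ("moderate
  divergence").
* **Groups**: the subtrees obtained by cutting the earliest `n_groups − 1`
  divergences (default 4 groups), emulating taxonomy labels.  Event
  recipients keep their original label, so intruders are detectable.
* **Events**: each event has a time drawn in the (0.5, 0.9) fraction of
  tree depth — a transfer just after the root leaves no topological trace,
  so very early times are outside what the detection problem is about.
  HGT prunes the recipient lineage's subtree at the event time and regrafts
  it onto the donor lineage at the same time in *both* segment trees
  (replacing transfer: the recipient's original gene is lost).
  A rearrangement applies the same regraft to only the scoped segment's
  tree.  A duplication inserts a second copy (`<code>d`) on a pendant edge
  in both trees.  The sampler enforces: donor and recipient in different
  groups, event lineages pure for their own group, distinct groups across
  events where enough groups exist, and — critically — the donor edge must
  subtend a *strict subset* of the donor group.  Without that last
  condition a transfer can land on the group's stem lineage, making the
  recipient sister to the whole group instead of nested inside it, and the
  event would be undetectable as an intruder even with a perfect tree.
  Not every Yule tree can host such events (a group whose crown postdates
  the event window cannot donate), so the dataset generator redraws the
  species tree deterministically (substream `[seed+1, k]`) until placement
  succeeds.
* **Sequences**: 20-state uniform-exchangeability chain (protein
  Jukes–Cantor; any reversible matrix can be supplied) with per-column
  rates from a discrete gamma (4 categories, shape 1.0 — a conventional
  moderate-heterogeneity setting), plus Poisson indels (0.01 events/site
  per unit branch length, geometric lengths of mean 3) that open true gap
  columns.  Substitutions are applied along a branch before its indels;
  inserted columns start at stationarity.  The *true* alignment is emitted;
  aligner error is intentionally not simulated.
* **Seeding**: one master seed; species tree `seed+1`, events `seed+2`,
  segment *k* sequences `[seed+3, k]`.  Identical configs produce
  byte-identical files (sha256 manifest).

## What the recovery experiment shows — and what it does not

`recovery_experiment` simulates 12 taxa, 300 residues/segment, one HGT and
one seg2 rearrangement per replicate, runs the full pipeline (gap filter →
kimura+p × 100-bootstrap consensus ensembles → midpoint rooting →
`placed_within` tally) and scores: HGT detected in the majority of trees of
both segment ensembles; rearrangement flagged in the seg2 majority and not
the seg1 majority.

On the true gene trees the planted events are *always* detectable by
construction (verified exhaustively in the test suite).  On estimated
trees, each consensus tree misjudges the flag in roughly 2% of replicates —
the informative internal edge (group crown → regraft point) can be
genuinely short, and bootstrap consensus then collapses or confidently
flips it.  Because the scoring demands near-unanimity across the 2-model ×
2-segment consensus trees, the joint per-replicate success rate observed
over 60 replicates is ≈ 0.85–0.90 (HGT ≈ 0.93 and rearrangement asymmetry
≈ 0.92 separately).  This is a property of tree estimation at these data
sizes, not of the event planting or the predicates.

Passing tests on this synthetic data demonstrate the *logic* of the
multiple-tree approach on truth-known input.  They do not demonstrate
robustness to real-data complications the generator omits: alignment
error, compositional bias, rate variation across lineages, domain-internal
recombination, or taxon sampling artefacts.

## Numerical and degenerate-input choices

* Problem sizes throughout the test and acceptance machinery (12-taxon
  trees, 300-site segments, 100-replicate bootstraps, 20-replicate recovery
  runs, exhaustive predicate sweeps up to 7 leaves) were chosen as the
  smallest sizes at which each property is meaningfully exercised.
* Empirical-model ML distances use a bounded scalar optimiser on
  (10⁻⁹, max_distance); agreement to ~10⁻⁴ is the expected tolerance.
* All-equal distance matrices, zero-rate simulations, single-column
  bootstraps, 2-leaf midpoint rooting and gap-only rows are all defined
  behaviours with tests; an alignment losing every column to the gap filter
  or every row to the overlap filter is an error that names the parameter
  to change.
* Consensus thresholds are restricted to [0.5, 1): below one half the
  selected splits need not be compatible.
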