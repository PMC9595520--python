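# Methods

## Model and procedure

The package treats ortholog recovery as a tree-decomposition problem. A
gene family that is not globally single copy may still contain subtrees in
which every species, strain or organism is represented by exactly one
sequence once *species-specific inparalogs* — same-taxon tips that are
sisters or co-members of one polytomy, typically recent duplicates or
redundant transcripts — are reduced to a single representative. The
algorithm finds all maximal such subtrees subject to an occupancy floor.

The procedure, per family:

1. **Rooting.** Unless the caller declares the tree pre-rooted, it is
   midpoint rooted: the root is placed halfway along the longest
   leaf-to-leaf path. Midpoint rooting needs no outgroup, which is why it
   suits batch processing of thousands of families.
2. **Traversal.** Internal nodes are visited in preorder (root toward
   tips) with children ordered by their smallest descendant leaf label.
   Preorder makes the greedy acceptance deterministic and biases it toward
   *maximally inclusive* groups: an ancestor is always evaluated before
   its descendants, and acceptance blocks descent.
3. **Occupancy gate.** A candidate node must cover at least the occupancy
   threshold's worth of distinct taxa among all its descendant tips,
   counted before any trimming (trimming cannot change the distinct-taxon
   count). A node that fails still has its children visited, since
   occupancy only shrinks toward the tips and nested candidates of a
   *failed single-copy test* (below) may yet qualify.
4. **Support collapsing.** Within a working copy of the candidate subtree,
   internal branches with support strictly below the threshold are
   contracted into polytomies. The strict inequality means the default
   threshold of 80 keeps branches with support exactly 80. Nodes without a
   support value (e.g. previously collapsed polytomies) are never
   collapsed — absence of annotation is not evidence of low support. The
   collapse operates on a copy so that sibling and nested candidates are
   evaluated independently against the original supports.
5. **Inparalog trimming.** Same-taxon tips that are children of one node
   are reduced to a single survivor, then pass-through nodes are
   suppressed and the search repeats, because a survivor can become sister
   to another tip of its taxon. Iteration to a fixpoint handles arbitrary
   chains of nested duplicates.
6. **Acceptance.** If each remaining taxon has exactly one tip and no
   sequence of the subtree is already assigned, the survivors form a new
   group; *all* sequences of the subtree (trimmed inparalogs included) are
   marked assigned and traversal does not descend further there.

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| `occupancy` | 0.5 (fraction) | minimum distinct taxa per group; a fraction f resolves to ⌈f·n⌉ for n taxa ("at least half"), never below 2; an integer is used as-is |
| `support_threshold` | 80 | collapse branches with support < threshold; scaled for ultrafast-bootstrap-style percentages in [0, 100] |
| `rooted` | false | skip midpoint rooting when the input is already rooted |
| `inparalog_rule` | `longest_seq` | which same-taxon duplicate to keep: longest/shortest/median by non-gap sequence length, or by branch length (patristic distance from the set's most recent common ancestor) |
| `delimiter` | `\|` | separates taxon from gene in labels; split at the first occurrence so gene identifiers may contain the delimiter |

Sequence length counts non-gap residues, so aligned and unaligned input
rank inparalogs identically. Rank ties are broken by input FASTA order
(earlier record wins); the median over an even count takes the lower
central value, and ties at the median value fall back to FASTA order too.

## Numerical and representational choices

- **Newick dialect.** Supports are read from internal-node labels (the
  IQ-TREE/RAxML convention); a reader option accepts bracketed
  branch-comment dialects instead. Numeric internal labels outside
  [0, 100] are kept as plain names. If every support in a tree is ≤ 1 the
  values are taken as proportions and rescaled to percentages, with a
  logged warning — a heuristic, and deliberately visible as such.
- **Canonical output.** Children are serialized sorted by smallest
  descendant leaf label, so identical topologies produce identical bytes
  and reruns are byte-reproducible. Absent branch lengths are preserved as
  absent (they are treated as 0 only inside path computations).
- **Midpoint ties.** Among equally long leaf pairs the lexicographically
  smallest label pair wins; a midpoint falling exactly on a node (within
  1e-10) roots at that node. A tree whose branch lengths are all zero or
  absent has no midpoint; it is rooted on the branch to the smallest leaf
  label with a warning.
- **Collapsing and lengths.** Contracting a low-support branch discards
  that branch's length; children keep their own lengths. Contraction
  necessarily loses path information, and the traversal consumes only the
  topology of the collapsed copy, so no compensation scheme is applied.
- **Pruning.** Removing tips suppresses pass-through nodes with their two
  incident branch lengths summed, which preserves all patristic distances
  among kept leaves (asserted to < 1e-8 in tests, as is midpoint
  rooting's distance preservation).
- **Metrics.** DVMC uses the sample (n−1) standard deviation of
  root-to-tip distances. Robinson–Foulds prunes both trees to the shared
  leaf set, compares nontrivial bipartitions of the unrooted topologies,
  and normalizes by 2(n−3); polytomies contribute only the bipartitions
  they resolve, against the same normalization constant, so collapsed
  trees remain comparable. Saturation is the ordinary least-squares slope
  (free intercept) of pairwise uncorrected p-distances on patristic
  distances, reported untransformed so 1 reads as "no saturation";
  columns with a gap in either row are excluded per pair, and a pair with
  no comparable column is skipped. RCV and the parsimony-informative-site
  count exclude gap and ambiguity symbols from the state set; the
  alphabet is auto-detected (≥ 95% of non-gap residues in `ACGTUN` reads
  as nucleotide, in which case `N` is ambiguity rather than a state).

## What the generator emulates — and what it does not

`generate_family` plants k single-copy clades over overlapping taxon
subsets (each of at least ⌊n/2⌋+1 taxa, so any two groups share a taxon
and no union of groups can pass the single-copy test), joins them under a
caterpillar of duplication nodes — outparalogs in the classic sense — and
converts random tips into two-copy species-specific inparalog cherries at
the requested rate. Branch lengths are stratified: long stems and spine
segments (4–6 substitutions/site scale) against short within-group
branches (≤ 0.05), which pins the midpoint root onto the duplication spine
and keeps every planted clade monophyletic after rooting; for a single
planted group, one designated anchor tip carries the long branch instead.
Sequence lengths are drawn so every inparalog pair has a unique longest
member, recorded as the planted survivor. Supports are 100 everywhere by
default so the planted decomposition is exactly recoverable; a
low-support mode plants values below 80 to exercise collapsing, in which
case only the structural invariants — not a unique truth — are asserted.

The generator is **not** a sequence-evolution simulator: residues are
random amino-acid strings with controlled lengths, not evolved under a
substitution model, and branch lengths are not calibrated to any clock.
Passing the recovery grid therefore demonstrates the correctness of the
tree logic (occupancy gating, trimming, greedy assignment, rooting) under
clean topologies with known answers; it does not measure robustness to
misinferred gene trees, alignment error, or support miscalibration, which
real datasets exhibit and which only the collapse threshold addresses.

## Problem sizes in the test and acceptance runs

The oracle-equivalence suite compares the traversal against an
independent brute-force evaluation of the same predicate on 200 random
gene trees of 5–12 tips over 4–6 taxa; the recovery grid covers group
counts 1–5 × inparalog rates {0, 0.2, 0.5} with 50 seeded 8-taxon
families per cell (20 per cell in the acceptance script); rooting and
round-trip properties run on several hundred random trees of up to 30
tips. These sizes give exhaustive coverage of the branching logic while
keeping the whole suite in the seconds range.

## Known limitations

- Inparalog sets are recognized only among *leaf* children of a node; a
  same-taxon pair separated by a well-supported internal branch is not
  trimmed (by design — such copies are not "species-specific inparalogs"
  under the sister/polytomy definition) and will veto its candidate.
- Midpoint rooting on a family whose longest path runs through a genuine
  duplication can split an ortholog clade across the root; pre-rooted
  input (`rooted=true`) is the remedy when an outgroup is known.
- The support-proportion rescaling heuristic misreads a tree whose
  supports are genuinely all ≤ 1 percent; such inputs are vanishingly
  rare but the log warning exists for exactly this case.
- One tree/FASTA pair per run; batching over thousands of families is
  left to the caller's shell or workflow manager.
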