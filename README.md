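# snapog

**snapog** extracts single-copy ortholog groups that are nested inside
multi-copy gene-family phylogenies — so-called SNAP-OGs — by *s*plitting the
family tree and *p*runing species-specific inparalogs. It is aimed at
phylogenomics practitioners who build data matrices from orthology
inference output (OrthoFinder, OMA, BLAST/HMMER clusters, ...): most gene
families are discarded from such matrices because one or more species carry
multiple copies, even when perfectly good single-copy subgroups are hiding
inside the family. Recovering those subgroups can multiply the number of
usable gene markers, which matters most in clades with whole-genome
duplications, heavy gene turnover, or transcriptome-based proteomes.

The package also implements the nine alignment/tree information-content
properties commonly used to check that recovered groups are as
phylogenetically informative as conventional single-copy orthologs.

## The algorithm

Input is a gene-family tree (Newick) and the matching sequences (FASTA),
with every sequence named `taxon|gene` in both files. The tree is midpoint
rooted (unless declared pre-rooted), then internal nodes are visited from
the root toward the tips. A node with descendant tips covering at least
*t* distinct taxa — the **orthogroup occupancy** threshold, by default
⌈n/2⌉ for *n* taxa in the tree — is evaluated as a candidate:

1. branches inside the candidate subtree with bootstrap support < 80
   (configurable) are collapsed into polytomies, so weakly supported
   resolution cannot block or fabricate a group;
2. **species-specific inparalogs** — two or more tips of the same taxon
   that are sisters or co-members of one polytomy — are iteratively pruned
   to a single representative (by default the longest sequence; the
   shortest/median sequence or the longest/shortest/median branch are
   alternatives), repeating until no such set remains;
3. the candidate is accepted as a SNAP-OG if every remaining taxon is
   represented by exactly one sequence and none of the subtree's sequences
   already belong to an accepted group.

Acceptance consumes the entire subtree and stops descent, so maximally
inclusive groups win over nested ones; rejection keeps descending, because
a smaller subtree may still qualify. Output is one FASTA per group
(`<stem>.orthosnap.<i>.fa`, reference-tool naming) and optionally the
pruned subtree as Newick.

### Information-content metrics

For a gene with alignment *A* (n taxa × L sites) and tree *T*:
alignment length L; parsimony-informative sites (columns with ≥ 2 states
each in ≥ 2 rows); relative composition variability
RCV = Σᵢ Σₛ |cᵢₛ − c̄ₛ| / (nL); treeness = internal branch length / total
branch length; treeness/RCV; average bootstrap support; DVMC (sample
standard deviation of root-to-tip distances); saturation (OLS slope of
pairwise p-distance on patristic distance, 1 = unsaturated); and the
Robinson–Foulds distance to a reference tree, normalized by 2(n−3).

## Worked example

The bundled generator plants known single-copy clades and inparalog
cherries, so you can see the whole pipeline end to end:

```python
from snapog import generate_family
fam = generate_family(n_taxa=6, k_groups=2, inparalog_rate=0.3, seed=11)
fam.write(".", stem="demo")   # demo.fa, demo.nwk, demo.truth.tsv
```

```sh
$ snapog -f demo.fa -t demo.nwk --output-dir out
Arguments:
  fasta: demo.fa
  tree: demo.nwk
  support: 80.0
  occupancy: None
  rooted: False
  snap-trees: False
  inparalog-to-keep: longest_seq
  delimiter: |
  output-dir: out
SNAP-OGs identified: 2
  out/demo.orthosnap.0.fa
  out/demo.orthosnap.1.fa
```

The family contained two ortholog clades buried under a duplication node;
the run splits them apart and, inside each, keeps a single (longest)
sequence for every taxon that carried an inparalog pair — e.g. taxon `s04`
contributed `s04|g1-copy_0` and `s04|g1-copy_1` but only the longer copy
appears in `demo.orthosnap.0.fa`. `occupancy: None` in the echo means the
default (half of the taxa, rounded up) is in effect. The two output files
match `demo.truth.tsv`, the generator's ground-truth manifest, exactly.

The metric suite runs on an alignment plus tree (plus an optional
reference tree for the Robinson–Foulds column):

```sh
snapog metrics -a aln.fa -t gene.nwk --reference species.nwk
```

which prints a tab-separated header and one row with the nine properties.

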