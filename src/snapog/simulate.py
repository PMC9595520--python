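"""Deterministic generators of gene-family fixtures with planted truth.

``generate_family`` builds a gene-family tree containing a known set of
single-copy ortholog clades joined under deep duplication (outparalog)
nodes, optionally decorated with species-specific inparalog cherries, plus
matching placeholder sequences whose controlled lengths make the default
longest-sequence trimming rule unambiguous.  The planted groups are recorded
as machine-readable truth, so a correct extraction run must return exactly
those label sets.

The generator is not a sequence-evolution simulator: residues are random
characters with controlled lengths, and branch lengths are chosen so that
midpoint rooting always lands between the planted clades, never inside one.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

from .errors import ParameterError
from .phylo import GeneTree, Node, write_newick
from .seqio import SequenceRecord, write_fasta

_AMINO = "ACDEFGHIKLMNPQRSTVWY"

#: branch length from a planted group's root to the duplication spine;
#: large relative to within-group branches so the midpoint stays on the spine
_GROUP_STEM = 5.0
#: length of one spine segment between consecutive duplication nodes
_SPINE_SEGMENT = 2.0
#: terminal-branch length of the anchor tip used to pin the midpoint when
#: there is no spine (single planted group)
_ANCHOR_STEM = 6.0


@dataclass
class PlantedFamily:
    """One synthetic gene family with machine-readable ground truth."""

    tree: GeneTree
    records: list[SequenceRecord]
    truth: list[frozenset]
    inparalog_sets: list[frozenset]
    seed: int

    def record_map(self) -> dict[str, SequenceRecord]:
        return {r.full_label: r for r in self.records}

    def write(
        self, out_dir: Union[str, Path], stem: str = "family"
    ) -> tuple[Path, Path, Path]:
        """Emit FASTA + Newick + a plain-text truth manifest."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fasta = out_dir / f"{stem}.fa"
        newick = out_dir / f"{stem}.nwk"
        manifest = out_dir / f"{stem}.truth.tsv"
        write_fasta(self.records, fasta)
        with open(newick, "w") as fh:
            fh.write(write_newick(self.tree) + "\n")
        with open(manifest, "w") as fh:
            for group in self.truth:
                fh.write("\t".join(sorted(group)) + "\n")
        return fasta, newick, manifest


def _random_binary(
    leaves: list[Node], rng: random.Random, length_range=(0.01, 0.05),
    support: Optional[float] = 100.0,
) -> Node:
    """Join subtrees pairwise at random into a binary clade root."""
    pool = list(leaves)
    while len(pool) > 1:
        i = rng.randrange(len(pool))
        a = pool.pop(i)
        j = rng.randrange(len(pool))
        b = pool.pop(j)
        a.length = rng.uniform(*length_range)
        b.length = rng.uniform(*length_range)
        pool.append(Node(support=support, children=[a, b]))
    root = pool[0]
    return root


def _random_residues(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(_AMINO) for _ in range(length))


def generate_family(
    n_taxa: int,
    k_groups: int,
    inparalog_rate: float = 0.0,
    outparalog_depth: int = 1,
    seed: int = 0,
    min_group_size: Optional[int] = None,
    low_support_rate: float = 0.0,
    max_tips: Optional[int] = None,
) -> PlantedFamily:
    """Build a family of ``k_groups`` planted single-copy clades.

    Each group covers a random taxon subset of at least ``min_group_size``
    taxa (default ``n_taxa // 2 + 1``, which both satisfies the default
    occupancy threshold and guarantees every pair of groups shares a taxon,
    so no union of groups is ever single-copy).  Groups are joined under a
    caterpillar of duplication nodes whose branch lengths dwarf within-group
    branches; ``outparalog_depth`` scales the spine segment lengths, making
    the duplications arbitrarily deep.  With probability ``inparalog_rate``
    a tip is replaced by a two-copy species-specific inparalog cherry whose
    longer sequence is the planted survivor.

    All supports are 100 by default so the planted decomposition is exact;
    ``low_support_rate`` instead assigns within-group supports below 80 at
    the given rate, exercising collapse behaviour without a unique truth.
    """
    if n_taxa < 4:
        raise ParameterError("need at least 4 taxa")
    if k_groups < 1:
        raise ParameterError("need at least 1 group")
    if not 0.0 <= inparalog_rate <= 1.0:
        raise ParameterError("inparalog_rate must be in [0, 1]")
    if outparalog_depth < 1:
        raise ParameterError("outparalog_depth must be >= 1")
    min_size = min_group_size if min_group_size is not None else n_taxa // 2 + 1
    if min_size > n_taxa:
        raise ParameterError(
            f"minimum group size {min_size} exceeds {n_taxa} taxa"
        )
    if max_tips is not None and k_groups * min_size > max_tips:
        raise ParameterError(
            f"{k_groups} groups of >= {min_size} taxa exceed the "
            f"tip budget of {max_tips}"
        )

    rng = random.Random(seed)
    taxa = [f"s{i + 1:02d}" for i in range(n_taxa)]
    anchor_label: Optional[str] = None

    truth: list[frozenset] = []
    inparalog_sets: list[frozenset] = []
    records: list[SequenceRecord] = []
    group_roots: list[Node] = []

    for g in range(k_groups):
        size = rng.randint(min_size, n_taxa)
        members = sorted(rng.sample(taxa, size))
        gene = f"g{g + 1}"
        leaves: list[Node] = []
        survivors: list[str] = []
        for t_idx, taxon in enumerate(members):
            label = f"{taxon}|{gene}"
            is_anchor = k_groups == 1 and g == 0 and t_idx == 0
            base_len = rng.randint(120, 300)
            duplicate = (not is_anchor) and rng.random() < inparalog_rate
            if duplicate:
                lab0, lab1 = f"{label}-copy_0", f"{label}-copy_1"
                short_len = base_len - rng.randint(10, 40)
                if rng.random() < 0.5:
                    len0, len1 = base_len, short_len
                else:
                    len0, len1 = short_len, base_len
                c0 = Node(label=lab0, length=rng.uniform(0.005, 0.02))
                c1 = Node(label=lab1, length=rng.uniform(0.005, 0.02))
                cherry = Node(support=100.0, children=[c0, c1])
                leaves.append(cherry)
                winner = lab0 if len0 > len1 else lab1
                survivors.append(winner)
                inparalog_sets.append(frozenset((lab0, lab1)))
                for lab, ln in ((lab0, len0), (lab1, len1)):
                    taxon_part, _, gene_part = lab.partition("|")
                    records.append(
                        SequenceRecord(
                            full_label=lab,
                            taxon=taxon_part,
                            gene=gene_part,
                            residues=_random_residues(rng, ln),
                        )
                    )
            else:
                leaves.append(Node(label=label))
                survivors.append(label)
                records.append(
                    SequenceRecord(
                        full_label=label,
                        taxon=taxon,
                        gene=gene,
                        residues=_random_residues(rng, base_len),
                    )
                )
                if is_anchor:
                    anchor_label = label
        root = _random_binary(leaves, rng)
        if low_support_rate > 0.0:
            for nd in root.preorder():
                if not nd.is_leaf and rng.random() < low_support_rate:
                    nd.support = float(rng.randint(20, 79))
        group_roots.append(root)
        truth.append(frozenset(survivors))

    if k_groups == 1:
        tree_root = group_roots[0]
        if anchor_label is not None:
            for leaf in tree_root.leaves():
                if leaf.label == anchor_label:
                    leaf.length = _ANCHOR_STEM
        if tree_root.is_leaf:  # pragma: no cover - n_taxa >= 4 precludes this
            raise ParameterError("degenerate single-tip family")
    else:
        spine = group_roots[0]
        spine.length = _GROUP_STEM
        for g_root in group_roots[1:]:
            g_root.length = _GROUP_STEM
            spine = Node(support=100.0, children=[spine, g_root])
            spine.length = _SPINE_SEGMENT * outparalog_depth
        spine.length = None
        tree_root = spine

    records.sort(key=lambda r: r.full_label)
    tree = GeneTree(tree_root, rooted=False)
    return PlantedFamily(
        tree=tree,
        records=records,
        truth=truth,
        inparalog_sets=inparalog_sets,
        seed=seed,
    )


def generate_random_tree(
    n_tips: int,
    seed: int = 0,
    n_taxa: Optional[int] = None,
    mean_length: float = 0.2,
) -> GeneTree:
    """A random rooted binary tree with supports, for property testing.

    Topology comes from repeated random joins, branch lengths from an
    exponential distribution, supports are uniform integers in [0, 100].
    When ``n_taxa`` is given, tips are assigned random taxa (``tNN|gi``
    labels), emulating a multi-copy gene family; otherwise every tip is its
    own taxon.
    """
    if n_tips < 3:
        raise ParameterError("need at least 3 tips")
    rng = random.Random(seed)
    leaves = []
    for i in range(n_tips):
        if n_taxa is not None:
            taxon = f"t{rng.randrange(n_taxa) + 1:02d}"
        else:
            taxon = f"t{i + 1:02d}"
        leaves.append(Node(label=f"{taxon}|g{i + 1}"))
    root = _random_binary(
        leaves, rng, length_range=(0.0, 0.0), support=None
    )
    for nd in root.preorder():
        if nd is not root:
            nd.length = rng.expovariate(1.0 / mean_length)
        if not nd.is_leaf and nd is not root:
            nd.support = float(rng.randint(0, 100))
    return GeneTree(root, rooted=True)


def make_records(
    labels: list[str], seed: int = 0, delimiter: str = "|"
) -> list[SequenceRecord]:
    """Sequence records with distinct lengths for a set of tip labels.

    Lengths are a shuffled arithmetic progression so every sequence-length
    comparison has a unique winner.
    """
    rng = random.Random(seed)
    lengths = [100 + 3 * i for i in range(len(labels))]
    rng.shuffle(lengths)
    records = []
    for label, ln in zip(sorted(labels), lengths):
        taxon, _, gene = label.partition(delimiter)
        records.append(
            SequenceRecord(
                full_label=label,
                taxon=taxon,
                gene=gene,
                residues=_random_residues(rng, ln),
            )
        )
    return records
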