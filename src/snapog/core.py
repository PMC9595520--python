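"""Identification of single-copy ortholog groups nested in gene-family trees.

The algorithm walks a (midpoint-)rooted gene-family phylogeny from the root
toward the tips.  Each internal node whose descendant tips cover enough
distinct taxa (the orthogroup occupancy threshold) is evaluated as a
candidate: low-support branches inside the candidate subtree are collapsed,
species-specific inparalogs — same-taxon tips that are sisters or members of
one polytomy — are trimmed to a single representative, and the candidate is
accepted as a SNAP-OG when every remaining taxon is represented by exactly
one sequence and none of the subtree's sequences already belong to an
accepted group.  Acceptance consumes the whole subtree (including trimmed
inparalogs) and stops further descent, so maximally inclusive groups win
over nested ones.
"""

from __future__ import annotations

import logging
import math
import os
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

from .errors import ParameterError, ValidationError
from .phylo import (
    GeneTree,
    Node,
    collapse_low_support,
    midpoint_root,
    prune_to_tips,
    subtree_at,
    write_newick,
)
from .seqio import SequenceRecord, cross_validate, split_tip_label, write_fasta

_LOG = logging.getLogger(__name__)

INPARALOG_RULES = (
    "longest_seq",
    "shortest_seq",
    "median_seq",
    "longest_branch",
    "shortest_branch",
    "median_branch",
)


@dataclass
class SnapConfig:
    """Tunable parameters of a run.

    ``occupancy`` may be an integer (>= 2, minimum number of distinct taxa a
    group must cover) or a fraction in (0, 1] of the total taxa in the input
    tree (default 0.5, i.e. at least half, rounded up).  ``support_threshold``
    is the ultrafast-bootstrap-style percentage below which branches are
    collapsed before inparalog trimming.
    """

    occupancy: Union[int, float] = 0.5
    support_threshold: float = 80.0
    rooted: bool = False
    inparalog_rule: str = "longest_seq"
    delimiter: str = "|"
    emit_subtrees: bool = False
    strict: bool = False

    def __post_init__(self) -> None:
        if self.inparalog_rule not in INPARALOG_RULES:
            raise ParameterError(
                f"unknown inparalog rule {self.inparalog_rule!r}; "
                f"expected one of {', '.join(INPARALOG_RULES)}"
            )
        if not 0.0 <= self.support_threshold <= 100.0:
            raise ParameterError(
                f"support threshold must be in [0, 100], got {self.support_threshold}"
            )
        if len(self.delimiter) != 1:
            raise ParameterError("delimiter must be a single character")


@dataclass
class SnapOG:
    """One extracted single-copy ortholog group."""

    members: list[SequenceRecord]
    subtree: GeneTree
    index: int

    @property
    def labels(self) -> frozenset:
        return frozenset(r.full_label for r in self.members)

    @property
    def taxa(self) -> frozenset:
        return frozenset(r.taxon for r in self.members)


def compute_occupancy_threshold(n_taxa: int, config: SnapConfig) -> int:
    """Resolve the occupancy setting to an integer number of taxa.

    The fractional default means "at least that share of all taxa", hence
    the ceiling; the result is never below 2 (a group of one taxon is not an
    ortholog group).
    """
    if n_taxa < 2:
        raise ParameterError("need at least 2 distinct taxa")
    occ = config.occupancy
    if isinstance(occ, bool):
        raise ParameterError("occupancy must be a number")
    if isinstance(occ, int):
        if occ < 2:
            raise ParameterError(f"integer occupancy must be >= 2, got {occ}")
        if occ > n_taxa:
            raise ParameterError(
                f"occupancy {occ} exceeds the {n_taxa} taxa in the tree"
            )
        return occ
    if not 0.0 < occ <= 1.0:
        raise ParameterError(
            f"fractional occupancy must be in (0, 1], got {occ}"
        )
    return max(2, math.ceil(occ * n_taxa))


# ---------------------------------------------------------------------------
# Species-specific inparalog trimming
# ---------------------------------------------------------------------------

def _taxon_of(label: str, delimiter: str) -> str:
    return split_tip_label(label, delimiter)[0]


def _root_distances(root: Node) -> dict[int, float]:
    """Distance from ``root`` to every node in its clade (absent lengths = 0)."""
    dist = {id(root): 0.0}
    stack = [root]
    while stack:
        nd = stack.pop()
        for c in nd.children:
            dist[id(c)] = dist[id(nd)] + (c.length or 0.0)
            stack.append(c)
    return dist


def _rank_value(
    tip: Node,
    record: SequenceRecord,
    mrca_dist: dict[int, float],
    rule: str,
) -> float:
    if rule.endswith("_seq"):
        return float(record.length)
    return mrca_dist[id(tip)]


def _select_survivor(
    tips: Sequence[Node],
    records: dict[str, SequenceRecord],
    order: dict[str, int],
    mrca_dist: dict[int, float],
    rule: str,
) -> Node:
    """Pick the tip to keep from one same-taxon sister/polytomy set.

    Ranking is by non-gap sequence length (``*_seq`` rules) or by the
    patristic distance from the set's most recent common ancestor (``*_branch``
    rules).  Ties are broken by input FASTA order, earlier record first; for
    a median over an even count the lower-ranked central element is taken.
    """
    for tip in tips:
        if tip.label not in records:
            raise ValidationError(f"no sequence record for tip {tip.label!r}")
    keyed = sorted(
        tips,
        key=lambda t: (
            _rank_value(t, records[t.label], mrca_dist, rule),
            order[t.label],
        ),
    )
    if rule.startswith("longest"):
        # maximum value; among equals the earliest FASTA record
        best = _rank_value(keyed[-1], records[keyed[-1].label], mrca_dist, rule)
        winners = [
            t for t in keyed
            if _rank_value(t, records[t.label], mrca_dist, rule) == best
        ]
        return min(winners, key=lambda t: order[t.label])
    if rule.startswith("shortest"):
        return keyed[0]
    # median: lower central element of the sorted ranking; among equal
    # median values the earliest FASTA record wins
    med = keyed[(len(keyed) - 1) // 2]
    med_val = _rank_value(med, records[med.label], mrca_dist, rule)
    winners = [
        t for t in keyed
        if _rank_value(t, records[t.label], mrca_dist, rule) == med_val
    ]
    return min(winners, key=lambda t: order[t.label])


def trim_inparalogs(
    tips: Sequence[Node],
    records: dict[str, SequenceRecord],
    mrca: Node,
    rule: str,
    order: Optional[dict[str, int]] = None,
    delimiter: str = "|",
) -> str:
    """Return the label retained from one same-taxon tip set (>= 2 tips)."""
    if len(tips) < 2:
        raise ValidationError("an inparalog set has at least 2 tips")
    taxa = {_taxon_of(t.label, delimiter) for t in tips}
    if len(taxa) != 1:
        raise ValidationError(
            f"inparalog set spans multiple taxa: {', '.join(sorted(taxa))}"
        )
    if order is None:
        order = {lab: i for i, lab in enumerate(records)}
    mrca_dist = _root_distances(mrca)
    return _select_survivor(tips, records, order, mrca_dist, rule).label


def species_specific_inparalog_sets(
    node: Node, delimiter: str = "|"
) -> list[frozenset]:
    """Maximal same-taxon tip sets that collapse to a single representative.

    Two or more tips of one taxon form a species-specific inparalog set when
    they are children of one node (sisters, or co-members of a polytomy).
    Discovery iterates to a fixpoint: after a set is reduced to one survivor
    the survivor may become sister to another tip of the same taxon and join
    a new set.  The returned sets are the transitive unions over all rounds,
    so each set maps to exactly one surviving sequence.
    """
    work = node.copy()
    # map working tips back to original labels; union-find over merged groups
    group_of: dict[str, set[str]] = {}
    for leaf in work.leaves():
        group_of[leaf.label] = {leaf.label}

    changed = True
    while changed:
        changed = False
        for nd in list(work.postorder()):
            if nd.is_leaf:
                continue
            by_taxon: dict[str, list[Node]] = {}
            for child in nd.children:
                if child.is_leaf:
                    by_taxon.setdefault(
                        _taxon_of(child.label, delimiter), []
                    ).append(child)
            for taxon, tips in by_taxon.items():
                if len(tips) < 2:
                    continue
                survivor = tips[0]
                merged = set()
                for t in tips:
                    merged |= group_of.pop(t.label)
                group_of[survivor.label] = merged
                nd.children = [
                    c for c in nd.children if c is survivor or c not in tips
                ]
                changed = True
            if changed:
                break
        if changed:
            _suppress_unary(work)
    return [frozenset(g) for g in group_of.values() if len(g) > 1]


def _suppress_unary(root: Node) -> None:
    """Remove pass-through internal nodes in place (lengths summed)."""

    def rec(node: Node) -> Node:
        node.children = [rec(c) for c in node.children]
        if len(node.children) == 1 and not node.is_leaf:
            only = node.children[0]
            if only.length is None and node.length is None:
                merged = None
            else:
                merged = (node.length or 0.0) + (only.length or 0.0)
            only.length = merged
            return only
        return node

    root.children = [rec(c) for c in root.children]
    # a unary root is suppressed by the caller when needed


def _trim_subtree_inparalogs(
    sub: GeneTree,
    records: dict[str, SequenceRecord],
    order: dict[str, int],
    rule: str,
    delimiter: str,
) -> tuple[GeneTree, set[str]]:
    """Iteratively trim species-specific inparalogs from a working subtree.

    Per round, every set of same-taxon tips that are children of one node is
    reduced to the survivor chosen by ``rule``; pass-through nodes are then
    suppressed so survivors can join new sister sets.  Returns the trimmed
    tree and the labels removed.
    """
    work = sub.copy()
    removed: set[str] = set()
    while True:
        trimmed_this_round = False
        for nd in list(work.root.postorder()):
            if nd.is_leaf:
                continue
            by_taxon: dict[str, list[Node]] = {}
            for child in nd.children:
                if child.is_leaf:
                    by_taxon.setdefault(
                        _taxon_of(child.label, delimiter), []
                    ).append(child)
            for taxon, tips in sorted(by_taxon.items()):
                if len(tips) < 2:
                    continue
                mrca_dist = _root_distances(nd)
                survivor = _select_survivor(tips, records, order, mrca_dist, rule)
                drop = {id(t) for t in tips if t is not survivor}
                removed.update(t.label for t in tips if t is not survivor)
                nd.children = [c for c in nd.children if id(c) not in drop]
                trimmed_this_round = True
        if not trimmed_this_round:
            return work, removed
        _suppress_unary(work.root)
        while len(work.root.children) == 1 and not work.root.children[0].is_leaf:
            work.root = work.root.children[0]
            work.root.length = None


# ---------------------------------------------------------------------------
# Main traversal
# ---------------------------------------------------------------------------

def find_snap_ogs(
    tree: GeneTree,
    records: Sequence[SequenceRecord],
    config: Optional[SnapConfig] = None,
    progress: Optional[Callable[[int, int], None]] = None,
) -> list[SnapOG]:
    """Extract all SNAP-OGs from one gene-family tree.

    The tree is midpoint rooted first unless ``config.rooted`` declares it
    already rooted.  Internal nodes are visited root-to-tip (preorder with
    canonical child order); acceptance of a node consumes its entire subtree
    and blocks descent, while rejection does not (a smaller nested subtree
    may still qualify).  Returns groups in discovery order; an empty list is
    a valid outcome.

    ``progress``, when given, is called as ``progress(done, total)`` after
    each internal node is examined.
    """
    config = config or SnapConfig()
    record_map = cross_validate(tree, records, strict=config.strict)
    order = {r.full_label: i for i, r in enumerate(records)}

    work = tree if config.rooted else midpoint_root(tree)

    taxa = {
        _taxon_of(lab, config.delimiter) for lab in work.leaf_labels()
    }
    occ = compute_occupancy_threshold(len(taxa), config)

    internal_total = len(work.internal_nodes())
    examined = 0
    assigned: set[str] = set()
    snapogs: list[SnapOG] = []

    def min_leaf(node: Node) -> str:
        return min(node.leaf_labels())

    def visit(node: Node) -> None:
        nonlocal examined
        if node.is_leaf:
            return
        examined += 1
        if progress is not None:
            progress(examined, internal_total)
        labels = set(node.leaf_labels())
        node_taxa = {_taxon_of(lab, config.delimiter) for lab in labels}
        accepted = False
        if len(node_taxa) >= occ and not (labels & assigned):
            sub = subtree_at(node)
            sub = collapse_low_support(sub, config.support_threshold)
            trimmed, removed = _trim_subtree_inparalogs(
                sub, record_map, order, config.inparalog_rule, config.delimiter
            )
            survivors = trimmed.leaf_labels()
            surv_taxa = [
                _taxon_of(lab, config.delimiter) for lab in survivors
            ]
            if len(surv_taxa) == len(set(surv_taxa)):
                members = sorted(survivors, key=order.__getitem__)
                og_tree = prune_to_tips(subtree_at(node), members)
                snapogs.append(
                    SnapOG(
                        members=[record_map[lab] for lab in members],
                        subtree=og_tree,
                        index=len(snapogs),
                    )
                )
                assigned.update(labels)
                accepted = True
        if not accepted:
            for child in sorted(node.children, key=min_leaf):
                visit(child)

    visit(work.root)
    return snapogs


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def _atomic_write(path: Path, writer: Callable[[str], None]) -> None:
    fd, tmp = tempfile.mkstemp(dir=str(path.parent), prefix=path.name, suffix=".tmp")
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_snap_ogs(
    snapogs: Sequence[SnapOG],
    out_dir: Union[str, Path],
    stem: str,
    emit_subtrees: bool = False,
) -> list[Path]:
    """Write one FASTA (and optionally one Newick) per group.

    File naming follows the ``<stem>.orthosnap.<index>.fa`` convention of
    the reference tool, with the index in discovery order.  Writes are
    atomic (temp file + rename) so an interrupted run leaves no partial
    group files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for og in snapogs:
        fa = out_dir / f"{stem}.orthosnap.{og.index}.fa"
        _atomic_write(fa, lambda tmp, og=og: write_fasta(og.members, tmp))
        written.append(fa)
        if emit_subtrees:
            nwk = out_dir / f"{stem}.orthosnap.{og.index}.nwk"

            def write_tree(tmp: str, og=og) -> None:
                with open(tmp, "w") as fh:
                    fh.write(write_newick(og.subtree) + "\n")

            _atomic_write(nwk, write_tree)
            written.append(nwk)
    return written
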