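"""Alignment and tree information-content metrics.

Nine properties commonly used to judge the phylogenetic usefulness of a
gene: alignment length, parsimony-informative sites, relative composition
variability (RCV), treeness, treeness/RCV, average bootstrap support,
degree of violation of a molecular clock (DVMC), saturation, and the
(normalized) Robinson-Foulds distance to a reference tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .errors import UndefinedMetricError, ValidationError
from .phylo import (
    GeneTree,
    midpoint_root,
    nontrivial_splits,
    patristic_distances,
    prune_to_tips,
)
from .seqio import GAP_CHARS, SequenceRecord, read_fasta

#: symbols that are never character states, in any alphabet
_GAP_LIKE = frozenset("-?.*")
_NT_CHARS = frozenset("ACGTU")


@dataclass
class Alignment:
    """A multiple sequence alignment (equal-length rows)."""

    labels: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValidationError("alignment needs at least 2 rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValidationError("alignment rows differ in length")
        if len(self.labels) != len(self.rows):
            raise ValidationError("labels and rows differ in count")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("duplicate row labels in alignment")

    @property
    def n_sites(self) -> int:
        return len(self.rows[0])

    @property
    def n_taxa(self) -> int:
        return len(self.rows)

    @property
    def is_nucleotide(self) -> bool:
        """Alphabet auto-detection: >= 95% of non-gap residues in ACGTUN."""
        total = 0
        nt = 0
        for row in self.rows:
            for c in row.upper():
                if c in _GAP_LIKE:
                    continue
                total += 1
                if c in _NT_CHARS or c == "N":
                    nt += 1
        return total > 0 and nt / total >= 0.95

    @property
    def non_state_chars(self) -> frozenset:
        """Gap and ambiguity symbols excluded from composition counts."""
        extra = frozenset("XN") if self.is_nucleotide else frozenset("X")
        return _GAP_LIKE | extra

    def columns(self):
        return zip(*self.rows)

    def row(self, label: str) -> str:
        try:
            return self.rows[self.labels.index(label)]
        except ValueError:
            raise ValidationError(f"no alignment row for {label!r}") from None

    @classmethod
    def from_fasta(cls, path: Union[str, Path], delimiter: str = "|") -> "Alignment":
        records = read_fasta(path, delimiter=delimiter)
        return cls.from_records(records)

    @classmethod
    def from_records(cls, records: Sequence[SequenceRecord]) -> "Alignment":
        return cls(
            labels=[r.full_label for r in records],
            rows=[r.residues for r in records],
        )


@dataclass
class MetricReport:
    """Per-gene vector of the 9 information-content properties."""

    alignment_length: int
    pi_sites: int
    rcv: float
    treeness: float
    treeness_over_rcv: float
    abs_support: float
    dvmc: float
    saturation: float
    rf_normalized: Optional[float]

    FIELDS = (
        "alignment_length",
        "pi_sites",
        "rcv",
        "treeness",
        "treeness_over_rcv",
        "abs_support",
        "dvmc",
        "saturation",
        "rf_normalized",
    )

    def as_row(self) -> list[str]:
        out = []
        for name in self.FIELDS:
            val = getattr(self, name)
            if val is None:
                out.append("NA")
            elif isinstance(val, int):
                out.append(str(val))
            else:
                out.append(f"{val:.6g}")
        return out


# ---------------------------------------------------------------------------
# Tree-only metrics
# ---------------------------------------------------------------------------

def treeness(tree: GeneTree) -> float:
    """Fraction of total tree length on internal branches (in [0, 1]).

    High values indicate most divergence happened along internal branches —
    a signal-to-noise proxy.  Absent branch lengths count as 0.
    """
    internal = 0.0
    total = 0.0
    for node in tree.root.preorder():
        if node is tree.root:
            continue
        length = node.length or 0.0
        total += length
        if not node.is_leaf:
            internal += length
    if total == 0.0:
        raise UndefinedMetricError("treeness undefined: total tree length is 0")
    return internal / total


def average_bootstrap(tree: GeneTree) -> float:
    """Arithmetic mean of all internal-node support values present."""
    supports = [
        nd.support for nd in tree.internal_nodes() if nd.support is not None
    ]
    if not supports:
        raise UndefinedMetricError("tree carries no support values")
    return float(np.mean(supports))


def dvmc(tree: GeneTree) -> float:
    """Degree of violation of a molecular clock.

    Sample standard deviation (n-1 denominator) of root-to-tip distances;
    0 for an ultrametric tree.  Unrooted input is midpoint rooted first.
    """
    work = tree if tree.rooted else midpoint_root(tree)
    dist = {id(work.root): 0.0}
    stack = [work.root]
    tip_dists = []
    while stack:
        nd = stack.pop()
        for c in nd.children:
            dist[id(c)] = dist[id(nd)] + (c.length or 0.0)
            stack.append(c)
        if nd.is_leaf:
            tip_dists.append(dist[id(nd)])
    if len(tip_dists) < 2:
        raise UndefinedMetricError("DVMC needs at least 2 leaves")
    return float(np.std(tip_dists, ddof=1))


# ---------------------------------------------------------------------------
# Alignment-only metrics
# ---------------------------------------------------------------------------

def rcv(aln: Alignment) -> float:
    """Relative composition variability.

    Mean absolute deviation of each row's residue counts from the
    across-row mean count, summed over states and rows, divided by
    (n_taxa * n_sites).  Gap and ambiguity symbols are not states.
    0 means every row has identical composition.
    """
    if aln.n_sites == 0:
        raise UndefinedMetricError("RCV undefined for a zero-length alignment")
    excluded = aln.non_state_chars
    rows = [row.upper() for row in aln.rows]
    states = sorted({c for row in rows for c in row if c not in excluded})
    counts = np.array(
        [[row.count(s) for s in states] for row in rows], dtype=float
    )
    mean = counts.mean(axis=0)
    return float(np.abs(counts - mean).sum() / (aln.n_taxa * aln.n_sites))


def parsimony_informative_sites(aln: Alignment) -> int:
    """Columns with >= 2 distinct non-gap states each present in >= 2 rows."""
    excluded = aln.non_state_chars
    count = 0
    for col in aln.columns():
        tally: dict[str, int] = {}
        for c in col:
            c = c.upper()
            if c not in excluded:
                tally[c] = tally.get(c, 0) + 1
        if sum(1 for v in tally.values() if v >= 2) >= 2:
            count += 1
    return count


# ---------------------------------------------------------------------------
# Combined metrics
# ---------------------------------------------------------------------------

def treeness_over_rcv(tree: GeneTree, aln: Alignment) -> float:
    """Treeness divided by RCV; higher is more signal, less bias."""
    r = rcv(aln)
    if r == 0.0:
        raise UndefinedMetricError(
            "treeness/RCV undefined: alignment is compositionally homogeneous"
        )
    return treeness(tree) / r


def _p_distance(row_a: str, row_b: str) -> Optional[float]:
    """Uncorrected proportion of differing sites, skipping gapped columns."""
    used = 0
    diff = 0
    for a, b in zip(row_a.upper(), row_b.upper()):
        if a in GAP_CHARS or b in GAP_CHARS:
            continue
        used += 1
        if a != b:
            diff += 1
    if used == 0:
        return None
    return diff / used


def saturation(tree: GeneTree, aln: Alignment) -> float:
    """Slope of p-distance on patristic distance across all leaf pairs.

    A slope of 1 means observed divergence tracks inferred divergence (no
    saturation); smaller slopes mean multiple substitutions are hiding
    distance.  Ordinary least squares with a free intercept; pairs whose
    alignment rows share no ungapped column are skipped.
    """
    leaves = tree.leaf_labels()
    if len(leaves) < 3:
        raise UndefinedMetricError("saturation needs at least 3 leaves")
    missing = sorted(set(leaves) - set(aln.labels))
    if missing:
        raise ValidationError(
            f"tree leaves missing from alignment: {', '.join(missing)}"
        )
    labels, mat = patristic_distances(tree)
    idx = {lab: i for i, lab in enumerate(labels)}
    xs, ys = [], []
    for a, b in combinations(sorted(leaves), 2):
        p = _p_distance(aln.row(a), aln.row(b))
        if p is None:
            continue
        xs.append(mat[idx[a], idx[b]])
        ys.append(p)
    xs_arr = np.asarray(xs)
    ys_arr = np.asarray(ys)
    if len(xs_arr) < 2 or np.allclose(xs_arr, xs_arr[0]):
        raise UndefinedMetricError(
            "saturation undefined: no variance in patristic distances"
        )
    if np.allclose(ys_arr, ys_arr[0]):
        return 0.0
    result = stats.linregress(xs_arr, ys_arr)
    return float(result.slope)


def robinson_foulds(t1: GeneTree, t2: GeneTree) -> tuple[int, float]:
    """Robinson-Foulds distance between two trees, raw and normalized.

    Both trees are pruned to their shared leaf set (>= 4 leaves required),
    treated as unrooted, and compared on nontrivial bipartitions.  The raw
    distance is the size of the symmetric difference; the normalized value
    divides by 2(n-3), the maximum for two fully binary unrooted trees on n
    leaves (polytomies only contribute the bipartitions they resolve).
    """
    shared = set(t1.leaf_labels()) & set(t2.leaf_labels())
    if len(shared) < 4:
        raise ValidationError(
            f"Robinson-Foulds needs >= 4 shared leaves, got {len(shared)}"
        )
    a = t1 if set(t1.leaf_labels()) == shared else prune_to_tips(t1, shared)
    b = t2 if set(t2.leaf_labels()) == shared else prune_to_tips(t2, shared)
    sa = nontrivial_splits(a)
    sb = nontrivial_splits(b)
    raw = len(sa ^ sb)
    norm = raw / (2 * (len(shared) - 3))
    return raw, norm


def compute_report(
    aln: Alignment,
    tree: GeneTree,
    reference: Optional[GeneTree] = None,
) -> MetricReport:
    """All 9 properties for one gene.

    The Robinson-Foulds column is reported against ``reference`` (e.g. a
    species tree) and left as ``None`` when no reference is given.
    """
    rf_norm: Optional[float] = None
    if reference is not None:
        _, rf_norm = robinson_foulds(tree, reference)
    return MetricReport(
        alignment_length=aln.n_sites,
        pi_sites=parsimony_informative_sites(aln),
        rcv=rcv(aln),
        treeness=treeness(tree),
        treeness_over_rcv=treeness_over_rcv(tree, aln),
        abs_support=average_bootstrap(tree),
        dvmc=dvmc(tree),
        saturation=saturation(tree, aln),
        rf_normalized=rf_norm,
    )
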