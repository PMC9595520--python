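"""Phylogeny data model and tree operations.

A :class:`GeneTree` is a rooted hierarchy of :class:`Node` objects carrying
branch lengths (substitutions/site) and internal-node support values
(percentages in [0, 100], typically ultrafast bootstrap approximations).
Newick reading is delegated to dendropy; writing uses a canonical,
byte-reproducible serializer (children ordered by smallest descendant leaf
label).

Operations provided here are the tree-side primitives of the single-copy
ortholog extraction pipeline: midpoint rooting, support-based branch
collapsing, and pruning to a tip subset.  All operations are non-destructive
(they return new trees) and preserve the leaf set; midpoint rooting and
pruning additionally preserve patristic distances among the retained leaves.
"""

from __future__ import annotations

import logging
import re
from collections import deque
from typing import Iterable, Iterator, Optional, Sequence

import dendropy
import numpy as np

from .errors import NewickParseError, ValidationError

_LOG = logging.getLogger(__name__)

#: absolute tolerance used when a midpoint falls "exactly" on a node
_NODE_EPS = 1e-10


class Node:
    """One vertex of a rooted gene tree.

    ``label`` is set on leaves only.  ``length`` is the branch length to the
    parent (``None`` means *absent*, which is distinct from 0 and preserved
    on write).  ``support`` is the numeric support of the branch subtending
    this node; ``name`` stores a non-numeric internal-node label verbatim.
    """

    __slots__ = ("label", "length", "support", "name", "children")

    def __init__(
        self,
        label: Optional[str] = None,
        length: Optional[float] = None,
        support: Optional[float] = None,
        name: Optional[str] = None,
        children: Optional[list["Node"]] = None,
    ) -> None:
        self.label = label
        self.length = length
        self.support = support
        self.name = name
        self.children: list[Node] = children if children is not None else []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def copy(self) -> "Node":
        return Node(
            label=self.label,
            length=self.length,
            support=self.support,
            name=self.name,
            children=[c.copy() for c in self.children],
        )

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            nd = stack.pop()
            yield nd
            stack.extend(reversed(nd.children))

    def postorder(self) -> Iterator["Node"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def leaves(self) -> list["Node"]:
        return [nd for nd in self.preorder() if nd.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [nd.label for nd in self.leaves()]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        if self.is_leaf:
            return f"Leaf({self.label!r})"
        return f"Node(children={len(self.children)}, support={self.support})"


class GeneTree:
    """A rooted (or conventionally unrooted) gene-family phylogeny."""

    def __init__(self, root: Node, rooted: bool = True) -> None:
        self.root = root
        self.rooted = rooted

    # -- convenience -----------------------------------------------------
    def copy(self) -> "GeneTree":
        return GeneTree(self.root.copy(), rooted=self.rooted)

    def leaves(self) -> list[Node]:
        return self.root.leaves()

    def leaf_labels(self) -> list[str]:
        return self.root.leaf_labels()

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def internal_nodes(self) -> list[Node]:
        return [nd for nd in self.root.preorder() if not nd.is_leaf]

    def __repr__(self) -> str:  # pragma: no cover
        return f"GeneTree(n_leaves={self.n_leaves}, rooted={self.rooted})"


class Bipartition:
    """An unordered split of the leaf set into two disjoint, covering sides.

    Trivial splits (one side of size <= 1) are valid objects but are excluded
    from Robinson-Foulds computations by the caller.
    """

    __slots__ = ("sides",)

    def __init__(self, side_a: Iterable[str], side_b: Iterable[str]) -> None:
        a, b = frozenset(side_a), frozenset(side_b)
        if a & b:
            raise ValidationError("bipartition sides must be disjoint")
        if not a or not b:
            raise ValidationError("bipartition sides must be nonempty")
        self.sides = frozenset((a, b))

    @property
    def is_trivial(self) -> bool:
        return min(len(s) for s in self.sides) <= 1

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Bipartition) and self.sides == other.sides

    def __hash__(self) -> int:
        return hash(self.sides)

    def __repr__(self) -> str:  # pragma: no cover
        a, b = sorted(self.sides, key=lambda s: (len(s), sorted(s)))
        return f"Bipartition({sorted(a)} | {sorted(b)})"


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

_NUMERIC_RE = re.compile(r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?")


def _interpret_internal_label(raw: Optional[str]):
    """Split an internal-node label into (support, name).

    Numeric labels in [0, 100] are support values (IQ-TREE/RAxML dialect);
    anything else is kept verbatim as a name.
    """
    if raw is None or raw == "":
        return None, None
    try:
        val = float(raw)
    except ValueError:
        return None, raw
    if 0.0 <= val <= 100.0:
        return val, None
    return None, raw


def _support_from_comments(comments: Sequence[str]) -> Optional[float]:
    for comment in comments:
        m = _NUMERIC_RE.search(comment)
        if m:
            val = float(m.group(0))
            if 0.0 <= val <= 100.0:
                return val
    return None


def parse_newick(
    text: str,
    support_dialect: str = "label",
    rooted: Optional[bool] = None,
) -> GeneTree:
    """Parse a Newick string into a :class:`GeneTree`.

    Parameters
    ----------
    text:
        One Newick tree.  Internal-node labels that are numeric and within
        [0, 100] are interpreted as branch support values.
    support_dialect:
        ``"label"`` (default) reads supports from internal-node labels;
        ``"comment"`` reads them from bracketed branch comments such as
        ``[&support=87]`` or ``[87]``.
    rooted:
        Force the rooted flag; by default a bifurcating root is taken to
        mean the tree is rooted and a basal multifurcation to mean it is
        unrooted.

    Supports expressed as proportions are normalized: when every support in
    the tree is <= 1, all are multiplied by 100 (logged as a warning).
    """
    if support_dialect not in ("label", "comment"):
        raise ValidationError(f"unknown support dialect: {support_dialect!r}")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,
            preserve_underscores=True,
            extract_comment_metadata=False,
        )
    except Exception as exc:  # dendropy raises several reader subclasses
        line = getattr(exc, "line_num", None)
        col = getattr(exc, "col_num", None)
        loc = f" (line {line}, column {col})" if line is not None else ""
        raise NewickParseError(f"malformed Newick{loc}: {exc}") from exc

    def convert(dnode) -> Node:
        length = dnode.edge.length
        if dnode.is_leaf():
            if dnode.label is None:
                raise ValidationError("unlabelled leaf in Newick input")
            return Node(label=dnode.label, length=length)
        children = [convert(c) for c in dnode.child_nodes()]
        if support_dialect == "comment":
            support = _support_from_comments(dnode.comments)
            name = dnode.label
        else:
            support, name = _interpret_internal_label(dnode.label)
        return Node(length=length, support=support, name=name, children=children)

    root = convert(dtree.seed_node)
    tree = GeneTree(root, rooted=True)

    labels = tree.leaf_labels()
    if len(labels) < 2:
        raise ValidationError("tree must have at least 2 leaves")
    seen: set[str] = set()
    dupes = sorted({lab for lab in labels if lab in seen or seen.add(lab)})
    if dupes:
        raise ValidationError(f"duplicate leaf labels: {', '.join(dupes)}")

    supports = [nd.support for nd in tree.internal_nodes() if nd.support is not None]
    if supports and max(supports) <= 1.0:
        _LOG.warning(
            "all support values <= 1; interpreting them as proportions and "
            "rescaling to percentages"
        )
        for nd in tree.internal_nodes():
            if nd.support is not None:
                nd.support *= 100.0

    tree.rooted = rooted if rooted is not None else len(root.children) == 2
    return tree


_QUOTE_RE = re.compile(r"[\s()\[\]{}:;,']")


def _quote_label(label: str) -> str:
    if _QUOTE_RE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _fmt_number(x: float) -> str:
    if float(x) == int(x):
        return repr(float(x))  # "1.0" rather than "1" -- unambiguous round-trip
    return repr(float(x))


def _fmt_support(x: float) -> str:
    if float(x) == int(x):
        return str(int(x))
    return repr(float(x))


def write_newick(tree: GeneTree) -> str:
    """Serialize a tree to Newick with canonical child ordering.

    Children are sorted by their smallest descendant leaf label, so two
    topologically identical trees always serialize to identical bytes.
    Supports are written as internal-node labels; absent branch lengths are
    omitted (not written as 0).
    """
    min_leaf: dict[int, str] = {}

    def fill_min(node: Node) -> str:
        if node.is_leaf:
            min_leaf[id(node)] = node.label
        else:
            min_leaf[id(node)] = min(fill_min(c) for c in node.children)
        return min_leaf[id(node)]

    fill_min(tree.root)

    def serialize(node: Node) -> str:
        length = "" if node.length is None else f":{_fmt_number(node.length)}"
        if node.is_leaf:
            return f"{_quote_label(node.label)}{length}"
        inner = ",".join(
            serialize(c) for c in sorted(node.children, key=lambda c: min_leaf[id(c)])
        )
        if node.support is not None:
            lab = _fmt_support(node.support)
        elif node.name is not None:
            lab = _quote_label(node.name)
        else:
            lab = ""
        return f"({inner}){lab}{length}"

    root = tree.root
    out = serialize(root)
    # the root's own length is conventionally meaningless; keep it if present
    return out + ";"


# ---------------------------------------------------------------------------
# Patristic distances
# ---------------------------------------------------------------------------

def _adjacency(root: Node) -> dict[int, list[tuple[Node, float]]]:
    """Undirected adjacency over the rooted structure (lengths, None -> 0)."""
    adj: dict[int, list[tuple[Node, float]]] = {id(root): []}
    for node in root.preorder():
        adj.setdefault(id(node), [])
        for child in node.children:
            w = child.length if child.length is not None else 0.0
            adj[id(node)].append((child, w))
            adj.setdefault(id(child), []).append((node, w))
    return adj


def patristic_distances(tree: GeneTree) -> tuple[list[str], np.ndarray]:
    """All leaf-pair path-length distances.

    Returns the sorted leaf labels and the corresponding symmetric matrix.
    """
    leaves = sorted(tree.leaves(), key=lambda nd: nd.label)
    labels = [nd.label for nd in leaves]
    adj = _adjacency(tree.root)
    index = {id(nd): i for i, nd in enumerate(leaves)}
    n = len(leaves)
    mat = np.zeros((n, n))
    for i, src in enumerate(leaves):
        dist = {id(src): 0.0}
        queue = deque([src])
        while queue:
            nd = queue.popleft()
            for nbr, w in adj[id(nd)]:
                if id(nbr) not in dist:
                    dist[id(nbr)] = dist[id(nd)] + w
                    queue.append(nbr)
        for nd_id, d in dist.items():
            j = index.get(nd_id)
            if j is not None:
                mat[i, j] = d
    return labels, mat


# ---------------------------------------------------------------------------
# Midpoint rooting
# ---------------------------------------------------------------------------

class _Edge:
    """One undirected edge of the unrooted view of a tree."""

    __slots__ = ("a", "b", "length", "raw_length", "support", "name")

    def __init__(self, a, b, length, raw_length, support, name):
        self.a = a
        self.b = b
        self.length = length          # numeric, None treated as 0
        self.raw_length = raw_length  # None preserved
        self.support = support
        self.name = name

    def other(self, v):
        return self.b if v is self.a else self.a


def _build_unrooted(tree: GeneTree):
    """Undirected (vertex, edge) graph of the tree with a degree-2 root merged."""
    root = tree.root
    edges: list[_Edge] = []

    def add_subtree_edges(node: Node) -> None:
        for child in node.children:
            edges.append(
                _Edge(
                    node,
                    child,
                    child.length if child.length is not None else 0.0,
                    child.length,
                    child.support if not child.is_leaf else None,
                    child.name if not child.is_leaf else None,
                )
            )
            add_subtree_edges(child)

    if len(root.children) == 2:
        c1, c2 = root.children
        raw = (
            None
            if c1.length is None and c2.length is None
            else (c1.length or 0.0) + (c2.length or 0.0)
        )
        support = None
        name = None
        for c in (c1, c2):
            if not c.is_leaf:
                if support is None:
                    support = c.support
                if name is None:
                    name = c.name
        edges.append(_Edge(c1, c2, raw if raw is not None else 0.0, raw, support, name))
        add_subtree_edges(c1)
        add_subtree_edges(c2)
        vertices = [nd for nd in root.preorder() if nd is not root]
    else:
        add_subtree_edges(root)
        vertices = list(root.preorder())
    return vertices, edges


def _graph_adj(edges: list[_Edge]) -> dict[int, list[_Edge]]:
    adj: dict[int, list[_Edge]] = {}
    for e in edges:
        adj.setdefault(id(e.a), []).append(e)
        adj.setdefault(id(e.b), []).append(e)
    return adj


def midpoint_root(tree: GeneTree) -> GeneTree:
    """Root the tree at the midpoint of its longest leaf-to-leaf path.

    Patristic distances among leaves are unchanged.  Ties among equally long
    paths are broken by the lexicographically smallest endpoint label pair;
    a midpoint landing exactly on a node roots the tree at that node.  When
    every branch length is zero or absent the midpoint is undefined and the
    tree is instead rooted on the branch leading to the smallest leaf label
    (logged as a warning).
    """
    if tree.n_leaves < 2:
        raise ValidationError("midpoint rooting requires at least 2 leaves")
    vertices, edges = _build_unrooted(tree)
    adj = _graph_adj(edges)
    leaves = sorted(
        (nd for nd in vertices if nd.is_leaf), key=lambda nd: nd.label
    )

    # single-source shortest paths (trees: BFS) from every leaf
    def distances_from(src: Node) -> dict[int, float]:
        dist = {id(src): 0.0}
        queue = deque([src])
        while queue:
            nd = queue.popleft()
            for e in adj[id(nd)]:
                nbr = e.other(nd)
                if id(nbr) not in dist:
                    dist[id(nbr)] = dist[id(nd)] + e.length
                    queue.append(nbr)
        return dist

    leaf_dists = {id(nd): distances_from(nd) for nd in leaves}
    best = 0.0
    best_pair: Optional[tuple[Node, Node]] = None
    for i, u in enumerate(leaves):
        du = leaf_dists[id(u)]
        for v in leaves[i + 1:]:
            d = du[id(v)]
            if d > best + 1e-12:
                best, best_pair = d, (u, v)
            # ties: leaves are scanned in sorted order, so the first pair
            # reaching "best" is already the lexicographically smallest
    if best_pair is None or best <= 0.0:
        _LOG.warning(
            "all branch lengths zero or absent; midpoint undefined, rooting "
            "on the branch to the smallest leaf label"
        )
        anchor = leaves[0]
        edge = adj[id(anchor)][0]
        return _reroot_at_vertex(edge.other(anchor), adj, tree)

    u, v = best_pair
    # path u -> v via DFS parents
    parent: dict[int, tuple[Node, _Edge]] = {}
    stack = [u]
    seen = {id(u)}
    while stack:
        nd = stack.pop()
        if nd is v:
            break
        for e in adj[id(nd)]:
            nbr = e.other(nd)
            if id(nbr) not in seen:
                seen.add(id(nbr))
                parent[id(nbr)] = (nd, e)
                stack.append(nbr)
    path: list[tuple[Node, _Edge]] = []
    nd = v
    while nd is not u:
        prev, e = parent[id(nd)]
        path.append((nd, e))
        nd = prev
    path.reverse()  # edges from u toward v

    target = best / 2.0
    cum = 0.0
    for far_node, e in path:
        near_node = e.other(far_node)
        if cum + e.length >= target - _NODE_EPS:
            offset = target - cum  # distance from near_node along e
            if offset <= _NODE_EPS:
                return _reroot_at_vertex(near_node, adj, tree)
            if offset >= e.length - _NODE_EPS:
                return _reroot_at_vertex(far_node, adj, tree)
            return _reroot_on_edge(e, near_node, offset, adj, tree)
        cum += e.length
    # numerically we always return inside the loop
    raise AssertionError("midpoint not located")  # pragma: no cover


def _oriented_child(vertex: Node, come_from_edge: Optional[_Edge], adj) -> Node:
    """Rebuild the subtree hanging off ``vertex`` away from ``come_from_edge``."""
    if vertex.is_leaf:
        length = come_from_edge.raw_length if come_from_edge is not None else None
        return Node(label=vertex.label, length=length)
    children = []
    for e in adj[id(vertex)]:
        if e is come_from_edge:
            continue
        children.append(_oriented_child(e.other(vertex), e, adj))
    if come_from_edge is None:
        return Node(children=children)
    return Node(
        length=come_from_edge.raw_length,
        support=come_from_edge.support,
        name=come_from_edge.name,
        children=children,
    )


def _reroot_at_vertex(vertex: Node, adj, tree: GeneTree) -> GeneTree:
    if vertex.is_leaf:
        # cannot root at a leaf; root on its single incident edge instead
        e = adj[id(vertex)][0]
        return _reroot_on_edge(e, vertex, (e.length or 0.0) / 2.0, adj, tree)
    root = _oriented_child(vertex, None, adj)
    return GeneTree(root, rooted=True)


def _reroot_on_edge(e: _Edge, near: Node, offset: float, adj, tree: GeneTree) -> GeneTree:
    far = e.other(near)
    near_child = _oriented_child(near, e, adj)
    far_child = _oriented_child(far, e, adj)
    near_child.length = offset
    far_child.length = (e.length or 0.0) - offset
    root = Node(children=[near_child, far_child])
    return GeneTree(root, rooted=True)


# ---------------------------------------------------------------------------
# Support collapsing and pruning
# ---------------------------------------------------------------------------

def collapse_low_support(tree: GeneTree, threshold: float) -> GeneTree:
    """Contract internal branches whose support is strictly below ``threshold``.

    Children of a collapsed node are promoted to its parent, forming a
    polytomy; branches with support >= threshold, with no support value, and
    terminal branches are never touched.  The leaf set is preserved.
    """
    if not 0.0 <= threshold <= 100.0:
        raise ValidationError(
            f"support threshold must be in [0, 100], got {threshold}"
        )
    out = tree.copy()

    def process(node: Node) -> None:
        for child in node.children:
            process(child)
        new_children: list[Node] = []
        for child in node.children:
            if (
                not child.is_leaf
                and child.support is not None
                and child.support < threshold
            ):
                new_children.extend(child.children)
            else:
                new_children.append(child)
        node.children = new_children

    process(out.root)
    return out


def _sum_lengths(a: Optional[float], b: Optional[float]) -> Optional[float]:
    if a is None and b is None:
        return None
    return (a or 0.0) + (b or 0.0)


def prune_to_tips(tree: GeneTree, keep: Iterable[str]) -> GeneTree:
    """Restrict the tree to the given leaf labels.

    Unbranched internal nodes created by the pruning are suppressed with
    their two incident branch lengths summed, so patristic distances among
    kept leaves are unchanged.
    """
    keep_set = set(keep)
    labels = set(tree.leaf_labels())
    unknown = sorted(keep_set - labels)
    if unknown:
        raise ValidationError(f"unknown leaf labels: {', '.join(unknown)}")
    if len(keep_set) < 2:
        raise ValidationError("must keep at least 2 leaves")

    def rec(node: Node) -> Optional[Node]:
        if node.is_leaf:
            if node.label in keep_set:
                return Node(label=node.label, length=node.length)
            return None
        kids = [k for k in (rec(c) for c in node.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            only = kids[0]
            only.length = _sum_lengths(node.length, only.length)
            return only
        return Node(
            length=node.length,
            support=node.support,
            name=node.name,
            children=kids,
        )

    new_root = rec(tree.root)
    assert new_root is not None
    new_root.length = None
    new_root.support = None
    return GeneTree(new_root, rooted=tree.rooted)


def subtree_at(node: Node, rooted: bool = True) -> GeneTree:
    """A standalone copy of the clade below ``node`` (its own root)."""
    root = node.copy()
    root.length = None
    root.support = None
    return GeneTree(root, rooted=rooted)


# ---------------------------------------------------------------------------
# Bipartitions
# ---------------------------------------------------------------------------

def nontrivial_splits(tree: GeneTree) -> set[frozenset]:
    """Nontrivial bipartitions of the (unrooted view of the) tree.

    Each split is canonicalized as the side *not* containing the smallest
    leaf label, so rooted and unrooted encodings of the same topology yield
    identical sets.
    """
    all_leaves = frozenset(tree.leaf_labels())
    ref = min(all_leaves)
    splits: set[frozenset] = set()
    for node in tree.root.preorder():
        if node is tree.root or node.is_leaf:
            continue
        side = frozenset(node.leaf_labels())
        if len(side) < 2 or len(all_leaves) - len(side) < 2:
            continue
        canon = side if ref not in side else all_leaves - side
        splits.add(canon)
    return splits
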