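"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately written against its own minimal tree
representation (nested dicts parsed straight from Newick via dendropy) and
its own straightforward logic, so that agreement with the package is a real
cross-check rather than a tautology.
"""

from __future__ import annotations

import math

import dendropy

LEAF = "leaf"
INT = "int"


def ref_parse(newick: str):
    """Newick -> nested dicts: {'kind', 'label'|'support','children'}."""
    tree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        suppress_internal_node_taxa=True,
        suppress_leaf_node_taxa=True,
        preserve_underscores=True,
    )

    def conv(nd):
        if nd.is_leaf():
            return {"kind": LEAF, "label": nd.label}
        support = None
        if nd.label is not None:
            try:
                support = float(nd.label)
            except ValueError:
                support = None
        return {
            "kind": INT,
            "support": support,
            "children": [conv(c) for c in nd.child_nodes()],
        }

    return conv(tree.seed_node)


def ref_leaves(node) -> list:
    if node["kind"] == LEAF:
        return [node["label"]]
    out = []
    for c in node["children"]:
        out.extend(ref_leaves(c))
    return out


def ref_collapse(node, threshold: float):
    """Splice out internal children with support strictly below threshold."""
    if node["kind"] == LEAF:
        return dict(node)
    kids = [ref_collapse(c, threshold) for c in node["children"]]
    flat = []
    for k in kids:
        if (
            k["kind"] == INT
            and k["support"] is not None
            and k["support"] < threshold
        ):
            flat.extend(k["children"])
        else:
            flat.append(k)
    return {"kind": INT, "support": node["support"], "children": flat}


def _taxon(label: str) -> str:
    return label.split("|", 1)[0]


def ref_trim(node, seq_lengths: dict):
    """Iteratively prune same-taxon sister/polytomy tips, keeping the one
    with the longest sequence, until nothing changes."""

    def one_round(nd):
        """Returns (new_node_or_None, changed)."""
        if nd["kind"] == LEAF:
            return dict(nd), False
        changed = False
        new_children = []
        by_taxon = {}
        for c in nd["children"]:
            if c["kind"] == LEAF:
                by_taxon.setdefault(_taxon(c["label"]), []).append(c)
        dropped = set()
        for taxon, tips in by_taxon.items():
            if len(tips) >= 2:
                keep = max(tips, key=lambda t: seq_lengths[t["label"]])
                for t in tips:
                    if t is not keep:
                        dropped.add(t["label"])
                changed = True
        for c in nd["children"]:
            if c["kind"] == LEAF:
                if c["label"] not in dropped:
                    new_children.append(dict(c))
            else:
                sub, sub_changed = one_round(c)
                changed = changed or sub_changed
                if sub is not None:
                    new_children.append(sub)
        if not new_children:
            return None, changed
        if len(new_children) == 1:
            return new_children[0], True
        return {"kind": INT, "support": nd["support"], "children": new_children}, changed

    current = dict(node)
    while True:
        current, changed = one_round(current)
        if not changed:
            return current


def ref_predicate(node, seq_lengths, support_threshold: float):
    """Surviving labels if this subtree is single-copy after collapse+trim,
    else None."""
    collapsed = ref_collapse(node, support_threshold)
    trimmed = ref_trim(collapsed, seq_lengths)
    labels = ref_leaves(trimmed)
    taxa = [_taxon(lab) for lab in labels]
    if len(taxa) == len(set(taxa)):
        return frozenset(labels)
    return None


def ref_find_groups(newick: str, seq_lengths: dict, support_threshold=80.0,
                    occupancy=None):
    """Root-down greedy evaluation of every internal node (BFS order)."""
    root = ref_parse(newick)
    n_taxa = len({_taxon(lab) for lab in ref_leaves(root)})
    if occupancy is None:
        occupancy = max(2, math.ceil(0.5 * n_taxa))
    assigned = set()
    groups = []
    queue = [root]
    while queue:
        node = queue.pop(0)
        if node["kind"] == LEAF:
            continue
        tips = set(ref_leaves(node))
        taxa = {_taxon(lab) for lab in tips}
        if len(taxa) >= occupancy and not (tips & assigned):
            result = ref_predicate(node, seq_lengths, support_threshold)
            if result is not None:
                groups.append(result)
                assigned |= tips
                continue  # do not descend into an accepted subtree
        queue.extend(node.get("children", []))
    return groups


# ---------------------------------------------------------------------------
# Bipartition enumeration for Robinson-Foulds cross-checks
# ---------------------------------------------------------------------------

def ref_splits(newick: str) -> set:
    """Nontrivial bipartitions by direct enumeration over clades."""
    root = ref_parse(newick)
    all_leaves = frozenset(ref_leaves(root))
    ref_leaf = min(all_leaves)
    splits = set()

    def walk(node, is_root):
        if node["kind"] == LEAF:
            return
        for c in node["children"]:
            walk(c, False)
        if is_root:
            return
        side = frozenset(ref_leaves(node))
        if len(side) >= 2 and len(all_leaves - side) >= 2:
            canon = side if ref_leaf not in side else all_leaves - side
            splits.add(canon)

    walk(root, True)
    return splits


def ref_rf(newick_a: str, newick_b: str):
    sa, sb = ref_splits(newick_a), ref_splits(newick_b)
    raw = len(sa ^ sb)
    n = len(set(ref_leaves(ref_parse(newick_a))))
    return raw, raw / (2 * (n - 3))


def ref_pi_sites(rows: list) -> int:
    """Exhaustive per-column parsimony-informativeness check."""
    count = 0
    for col in zip(*rows):
        states = [c.upper() for c in col if c.upper() not in "-?.*X"]
        informative_states = 0
        for s in set(states):
            if states.count(s) >= 2:
                informative_states += 1
        if informative_states >= 2:
            count += 1
    return count
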