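"""The splitting-and-pruning algorithm itself."""

import pytest

from snapog import (
    ParameterError,
    SnapConfig,
    compute_occupancy_threshold,
    find_snap_ogs,
    parse_newick,
    species_specific_inparalog_sets,
    trim_inparalogs,
    write_newick,
    write_snap_ogs,
)
from snapog.core import _trim_subtree_inparalogs
from snapog.phylo import subtree_at
from snapog.seqio import SequenceRecord


def _rec(label, n):
    taxon, _, gene = label.partition("|")
    return SequenceRecord(full_label=label, taxon=taxon, gene=gene, residues="M" * n)


class TestOccupancyThreshold:
    @pytest.mark.parametrize(
        "n_taxa, occupancy, expected",
        [
            (24, 0.5, 12),
            (25, 0.5, 13),   # ceiling: "at least half"
            (20, 4, 4),
            (4, 0.5, 2),
            (3, 0.5, 2),     # floor of 2
        ],
    )
    def test_resolution(self, n_taxa, occupancy, expected):
        config = SnapConfig(occupancy=occupancy)
        assert compute_occupancy_threshold(n_taxa, config) == expected

    def test_integer_above_taxa_rejected(self):
        with pytest.raises(ParameterError):
            compute_occupancy_threshold(5, SnapConfig(occupancy=6))

    def test_integer_below_two_rejected(self):
        with pytest.raises(ParameterError):
            compute_occupancy_threshold(5, SnapConfig(occupancy=1))


class TestInparalogSets:
    def test_cherry(self):
        tree = parse_newick("(((A|x1:1,A|x2:1):1,B|y:1):1,C|z:1);")
        sets = species_specific_inparalog_sets(tree.root)
        assert sets == [frozenset({"A|x1", "A|x2"})]

    def test_polytomy_mixed_taxa(self):
        tree = parse_newick("((A|x1:1,A|x2:1,B|y:1):1,C|z:1);")
        sets = species_specific_inparalog_sets(tree.root)
        assert sets == [frozenset({"A|x1", "A|x2"})]

    def test_fixpoint_chains_same_taxon(self):
        # after the inner pair is reduced, its survivor becomes sister to A|x1
        tree = parse_newick("((A|x1:1,(A|x2:1,A|x3:1):1):1,B|y:1);")
        sets = species_specific_inparalog_sets(tree.root)
        assert sets == [frozenset({"A|x1", "A|x2", "A|x3"})]

    def test_non_sister_same_taxon_not_grouped(self):
        tree = parse_newick("((A|x1:1,(B|y:1,A|x2:1):1):1,C|z:1);")
        assert species_specific_inparalog_sets(tree.root) == []


class TestTrimRules:
    def _setup(self):
        tree = parse_newick(
            "((A|x1:0.1,A|x2:0.5,A|x3:0.9):1,B|y:1);"
        )
        node = tree.root.children[0]
        tips = [c for c in node.children if c.is_leaf]
        return node, tips

    def test_longest_seq(self):
        node, tips = self._setup()
        records = {"A|x1": _rec("A|x1", 300), "A|x2": _rec("A|x2", 250),
                   "A|x3": _rec("A|x3", 100)}
        assert trim_inparalogs(tips, records, node, "longest_seq") == "A|x1"

    def test_shortest_seq(self):
        node, tips = self._setup()
        records = {"A|x1": _rec("A|x1", 300), "A|x2": _rec("A|x2", 250),
                   "A|x3": _rec("A|x3", 100)}
        assert trim_inparalogs(tips, records, node, "shortest_seq") == "A|x3"

    def test_median_seq(self):
        node, tips = self._setup()
        records = {"A|x1": _rec("A|x1", 300), "A|x2": _rec("A|x2", 250),
                   "A|x3": _rec("A|x3", 100)}
        assert trim_inparalogs(tips, records, node, "median_seq") == "A|x2"

    def test_median_seq_even_count_takes_lower(self):
        tree = parse_newick("((A|x1:1,A|x2:1,A|x3:1,A|x4:1):1,B|y:1);")
        node = tree.root.children[0]
        tips = [c for c in node.children if c.is_leaf]
        records = {f"A|x{i}": _rec(f"A|x{i}", 100 + 10 * i) for i in range(1, 5)}
        # lengths 110,120,130,140 -> central pair (120,130) -> lower is 120
        assert trim_inparalogs(tips, records, node, "median_seq") == "A|x2"

    @pytest.mark.parametrize(
        "rule, expected",
        [
            ("longest_branch", "A|x3"),
            ("shortest_branch", "A|x1"),
            ("median_branch", "A|x2"),
        ],
    )
    def test_branch_rules(self, rule, expected):
        node, tips = self._setup()
        records = {lab: _rec(lab, 200) for lab in ("A|x1", "A|x2", "A|x3")}
        order = {"A|x1": 0, "A|x2": 1, "A|x3": 2}
        assert trim_inparalogs(tips, records, node, rule, order=order) == expected

    def test_sequence_tie_broken_by_fasta_order(self):
        tree = parse_newick("((A|x1:1,A|x2:1):1,B|y:1);")
        node = tree.root.children[0]
        tips = [c for c in node.children if c.is_leaf]
        records = {"A|x1": _rec("A|x1", 200), "A|x2": _rec("A|x2", 200)}
        order_fwd = {"A|x1": 0, "A|x2": 1}
        order_rev = {"A|x2": 0, "A|x1": 1}
        assert trim_inparalogs(tips, records, node, "longest_seq", order=order_fwd) == "A|x1"
        assert trim_inparalogs(tips, records, node, "longest_seq", order=order_rev) == "A|x2"

    def test_mixed_taxa_set_rejected(self):
        tree = parse_newick("((A|x1:1,B|y:1):1,C|z:1);")
        node = tree.root.children[0]
        tips = [c for c in node.children if c.is_leaf]
        records = {"A|x1": _rec("A|x1", 10), "B|y": _rec("B|y", 10)}
        from snapog import ValidationError

        with pytest.raises(ValidationError):
            trim_inparalogs(tips, records, node, "longest_seq")

    def test_fixpoint_trimming_of_nested_chain(self):
        tree = parse_newick("((A|x1:1,(A|x2:1,A|x3:1):1):1,B|y:1);")
        records = {
            "A|x1": _rec("A|x1", 150),
            "A|x2": _rec("A|x2", 100),
            "A|x3": _rec("A|x3", 200),
            "B|y": _rec("B|y", 120),
        }
        order = {lab: i for i, lab in enumerate(records)}
        sub = subtree_at(tree.root)
        trimmed, removed = _trim_subtree_inparalogs(
            sub, records, order, "longest_seq", "|"
        )
        assert sorted(trimmed.leaf_labels()) == ["A|x3", "B|y"]
        assert removed == {"A|x1", "A|x2"}


class TestFindSnapOGs:
    def test_single_copy_family_yields_itself(self):
        tree = parse_newick(
            "((A|g1:1,B|g1:1)100:1,(C|g1:1,D|g1:1)100:1);"
        )
        records = [_rec(f"{t}|g1", 100 + i) for i, t in enumerate("ABCD")]
        ogs = find_snap_ogs(tree, records)
        assert len(ogs) == 1
        assert ogs[0].labels == frozenset(tree.leaf_labels())

    def test_paralog_classes_family(self, paralog_classes_family):
        tree, records, expected = paralog_classes_family
        ogs = find_snap_ogs(tree, records, SnapConfig(rooted=True))
        assert [og.labels for og in ogs] == expected

    def test_paralog_classes_family_midpoint_rooted(self, paralog_classes_family):
        tree, records, expected = paralog_classes_family
        ogs = find_snap_ogs(tree, records)
        assert sorted(sorted(og.labels) for og in ogs) == sorted(sorted(g) for g in expected)

    def test_five_group_family(self, five_group_family):
        tree, records, expected = five_group_family
        ogs = find_snap_ogs(tree, records)
        assert sorted(sorted(og.labels) for og in ogs) == sorted(sorted(g) for g in expected)

    def test_no_qualifying_node_yields_empty(self):
        # every node with full occupancy has untrimmable duplicates and
        # every node below it covers too few taxa
        newick = (
            "((A|1:1,(B|1:1,(C|1:1,A|2:1):1):1):1,"
            "(D|1:1,(C|2:1,(B|2:1,D|2:1):1):1):1);"
        )
        tree = parse_newick(newick)
        records = [
            _rec(lab, 100 + i) for i, lab in enumerate(tree.leaf_labels())
        ]
        ogs = find_snap_ogs(tree, records, SnapConfig(occupancy=4, rooted=True))
        assert ogs == []

    def test_occupancy_blocks_small_groups(self, paralog_classes_family):
        tree, records, _ = paralog_classes_family
        ogs = find_snap_ogs(
            tree, records, SnapConfig(occupancy=4, rooted=True)
        )
        assert [og.labels for og in ogs] == [
            frozenset({"A|M", "B|M", "C|M", "D|M"}),
            frozenset({"A|N1", "B|N", "C|N", "D|N"}),
        ]

    def test_collapse_enables_polytomy_trimming(self):
        # the inparalog pair is split by a weakly supported node; collapsing
        # at the default threshold makes the pair a polytomy and trims it
        newick = (
            "(((A|x1:0.1,(A|x2:0.1,B|g:0.1)40:0.1)90:0.1,C|g:0.1)100:0.1,"
            "D|g:0.1);"
        )
        tree = parse_newick(newick)
        records = [
            _rec("A|x1", 300), _rec("A|x2", 200), _rec("B|g", 250),
            _rec("C|g", 240), _rec("D|g", 230),
        ]
        ogs = find_snap_ogs(tree, records, SnapConfig(rooted=True))
        assert len(ogs) == 1
        assert ogs[0].labels == frozenset({"A|x1", "B|g", "C|g", "D|g"})
        # without collapsing, taxon A keeps 2 non-sister copies, so only the
        # nested two-taxon cherry qualifies
        strict = find_snap_ogs(
            tree, records, SnapConfig(rooted=True, support_threshold=0)
        )
        assert [og.labels for og in strict] == [frozenset({"A|x2", "B|g"})]

    def test_members_one_per_taxon_and_disjoint(self, five_group_family):
        tree, records, _ = five_group_family
        ogs = find_snap_ogs(tree, records)
        seen = set()
        for og in ogs:
            taxa = [m.taxon for m in og.members]
            assert len(taxa) == len(set(taxa))
            assert not (og.labels & seen)
            seen |= og.labels

    def test_subtree_members_match(self, five_group_family):
        tree, records, _ = five_group_family
        ogs = find_snap_ogs(tree, records)
        for og in ogs:
            assert sorted(og.subtree.leaf_labels()) == sorted(og.labels)

    def test_deterministic_outputs(self, tmp_path, five_group_family):
        tree, records, _ = five_group_family
        outs = []
        for run in ("a", "b"):
            d = tmp_path / run
            ogs = find_snap_ogs(tree, records)
            written = write_snap_ogs(ogs, d, "fam", emit_subtrees=True)
            outs.append(b"".join(p.read_bytes() for p in sorted(written)))
        assert outs[0] == outs[1]

    def test_output_naming_convention(self, tmp_path, five_group_family):
        tree, records, _ = five_group_family
        ogs = find_snap_ogs(tree, records)
        written = write_snap_ogs(ogs, tmp_path, "fam", emit_subtrees=True)
        names = sorted(p.name for p in written)
        assert "fam.orthosnap.0.fa" in names
        assert "fam.orthosnap.0.nwk" in names
        assert len(names) == 2 * len(ogs)
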