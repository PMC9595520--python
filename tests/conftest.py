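"""Shared fixtures: worked-example gene families and helpers."""

from __future__ import annotations

import pytest

from snapog import SequenceRecord, parse_newick


def _records_from_lengths(lengths: dict) -> list:
    """Records with prescribed non-gap sequence lengths, in dict order."""
    out = []
    for label, n in lengths.items():
        taxon, _, gene = label.partition("|")
        out.append(
            SequenceRecord(
                full_label=label, taxon=taxon, gene=gene, residues="M" * n
            )
        )
    return out


@pytest.fixture
def paralog_classes_family():
    """A four-taxon family containing the three classic paralog classes.

    Genes M, N and O arose by duplications predating the speciation of taxa
    A-D (outparalogs).  Gene N carries a species-specific inparalog pair in
    taxon A; gene O duplicated into O1/O2 after the A/B/C split (inparalogs
    of D's single O, but not species-specific).  A correct decomposition
    under the default occupancy (half of 4 taxa = 2) yields four groups:
    M (4 taxa), N (4 taxa, A's pair trimmed), O1 (3 taxa), O2 (3 taxa).
    """
    newick = (
        "((((A|M:0.1,B|M:0.1)100:0.1,(C|M:0.1,D|M:0.1)100:0.1)100:1.0,"
        "(((A|N1:0.05,A|N2:0.05)100:0.1,B|N:0.1)100:0.1,"
        "(C|N:0.1,D|N:0.1)100:0.1)100:1.0)100:1.0,"
        "(((A|O1:0.1,(B|O1:0.1,C|O1:0.1)100:0.1)100:0.5,"
        "(A|O2:0.1,(B|O2:0.1,C|O2:0.1)100:0.1)100:0.5)100:0.5,"
        "D|O:0.6)100:1.0);"
    )
    tree = parse_newick(newick)
    lengths = {
        "A|M": 200, "B|M": 201, "C|M": 202, "D|M": 203,
        "A|N1": 250, "A|N2": 210, "B|N": 240, "C|N": 241, "D|N": 242,
        "A|O1": 150, "B|O1": 151, "C|O1": 152,
        "A|O2": 160, "B|O2": 161, "C|O2": 162,
        "D|O": 170,
    }
    records = _records_from_lengths(lengths)
    expected = [
        frozenset({"A|M", "B|M", "C|M", "D|M"}),
        frozenset({"A|N1", "B|N", "C|N", "D|N"}),
        frozenset({"A|O1", "B|O1", "C|O1"}),
        frozenset({"A|O2", "B|O2", "C|O2"}),
    ]
    return tree, records, expected


@pytest.fixture
def five_group_family():
    """A family of five nested single-copy groups over four species.

    Five ortholog clades (gene1..gene5) hang off a deep duplication spine;
    gene2 carries a species-specific inparalog pair in species2
    (``species2|gene2-copy_0`` / ``-copy_1``), of which copy_0 has the
    longer sequence and must be the retained representative.
    """
    g1 ="((species1|gene1:0.1,species2|gene1:0.1)100:0.1,(species3|gene1:0.1,species4|gene1:0.1)100:0.1)100"
    g2 = ("(((species2|gene2-copy_0:0.02,species2|gene2-copy_1:0.02)100:0.1,"
          "species1|gene2:0.1)100:0.1,(species3|gene2:0.1,species4|gene2:0.1)100:0.1)100")
    g3 = "((species1|gene3:0.1,species2|gene3:0.1)100:0.1,(species3|gene3:0.1,species4|gene3:0.1)100:0.1)100"
    g4 = "((species1|gene4:0.1,species2|gene4:0.1)100:0.1,(species3|gene4:0.1,species4|gene4:0.1)100:0.1)100"
    g5 = "((species1|gene5:0.1,species2|gene5:0.1)100:0.1,(species3|gene5:0.1,species4|gene5:0.1)100:0.1)100"
    newick = (
        f"(((({g1}:4.0,{g2}:4.0)100:2.0,{g3}:4.0)100:2.0,{g4}:4.0)100:2.0,"
        f"{g5}:4.0);"
    )
    tree = parse_newick(newick)
    lengths = {}
    for g in range(1, 6):
        for s in range(1, 5):
            lengths[f"species{s}|gene{g}"] = 200 + g + s
    del lengths["species2|gene2"]
    lengths["species2|gene2-copy_0"] = 260
    lengths["species2|gene2-copy_1"] = 220
    records = _records_from_lengths(lengths)
    expected = []
    for g in range(1, 6):
        group = {f"species{s}|gene{g}" for s in range(1, 5)}
        if g == 2:
            group.discard("species2|gene2")
            group.add("species2|gene2-copy_0")
        expected.append(frozenset(group))
    return tree, records, expected
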