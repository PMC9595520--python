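"""FASTA I/O and the ``taxon|gene`` naming convention.

Sequence headers and tree tip labels share one convention: the text before
the first ``|`` (configurable) identifies the species/strain/organism, the
remainder the gene.  Matching between a gene-family FASTA file and its tree
is by the exact full label (header token before the first whitespace).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .errors import NamingError, ValidationError
from .phylo import GeneTree

_LOG = logging.getLogger(__name__)

#: characters that do not count toward sequence length
GAP_CHARS = frozenset("-?")


def split_tip_label(label: str, delimiter: str = "|") -> tuple[str, str]:
    """Split ``taxon|gene`` at the FIRST delimiter occurrence.

    The gene part may itself contain the delimiter
    (``sp|a|b`` -> ``("sp", "a|b")``).
    """
    if delimiter not in label:
        raise NamingError(
            f"label {label!r} does not follow the taxon{delimiter}gene "
            f"naming convention (no {delimiter!r} found)"
        )
    taxon, _, gene = label.partition(delimiter)
    return taxon, gene


@dataclass
class SequenceRecord:
    """One FASTA entry tied to a tree tip by its full label."""

    full_label: str
    taxon: str
    gene: str
    residues: str
    description: str = ""  # header text after the first whitespace, verbatim

    @property
    def length(self) -> int:
        """Number of non-gap residues (alignment gaps excluded)."""
        return sum(1 for c in self.residues if c not in GAP_CHARS)

    @classmethod
    def from_header(
        cls, header: str, residues: str, delimiter: str = "|"
    ) -> "SequenceRecord":
        token, _, desc = header.partition(" ")
        taxon, gene = split_tip_label(token, delimiter)
        return cls(
            full_label=token,
            taxon=taxon,
            gene=gene,
            residues=residues,
            description=desc,
        )


def read_fasta(
    path: Union[str, Path], delimiter: str = "|"
) -> list[SequenceRecord]:
    """Read a FASTA file of ``taxon|gene``-named sequences, in file order."""
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        full = rec.id
        if full in seen:
            raise ValidationError(f"duplicate FASTA header: {full!r}")
        seen.add(full)
        taxon, gene = split_tip_label(full, delimiter)
        desc = rec.description.partition(" ")[2] if " " in rec.description else ""
        records.append(
            SequenceRecord(
                full_label=full,
                taxon=taxon,
                gene=gene,
                residues=str(rec.seq),
                description=desc,
            )
        )
    if not records:
        raise ValidationError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: Union[str, Path]) -> None:
    """Write records verbatim (60-column wrap), preserving descriptions."""
    if not records:
        raise ValidationError("refusing to write an empty FASTA file")
    bio = [
        _BioRecord(Seq(r.residues), id=r.full_label, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta")


def cross_validate(
    tree: GeneTree,
    records: Sequence[SequenceRecord],
    strict: bool = False,
) -> dict[str, SequenceRecord]:
    """Check that tree tips and FASTA records describe the same sequences.

    Tips missing from the FASTA are a hard error (the algorithm cannot rank
    inparalogs without their sequences).  FASTA records absent from the tree
    are ignored with a warning, or rejected when ``strict`` is set.

    Returns a mapping from tip label to its record.
    """
    by_label = {r.full_label: r for r in records}
    tips = set(tree.leaf_labels())
    missing = sorted(tips - by_label.keys())
    if missing:
        raise ValidationError(
            f"tree tips missing from FASTA: {', '.join(missing)}"
        )
    extra = sorted(by_label.keys() - tips)
    if extra:
        msg = f"FASTA records absent from tree: {', '.join(extra)}"
        if strict:
            raise ValidationError(msg)
        _LOG.warning("%s (ignored)", msg)
    return {lab: by_label[lab] for lab in tips}
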