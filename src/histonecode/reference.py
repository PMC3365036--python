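"""Histone reference sequences and residue-numbering conventions.

Mature histones lose their initiator methionine, and the literature numbers
residues in two ways: with the cleaved Met as residue 1 (UniProt-style) or
with the first residue *after* the Met as residue 1 (the convention of most
printed PTM maps, e.g. H4K16, H3K9).  The canonical convention throughout
this package is :attr:`NumberingOrigin.POST_MET_IS_1`; inputs using the
other convention are converted on ingest with :func:`renumber`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


class NumberingOrigin(enum.Enum):
    """Which residue is counted as 1."""

    MET_IS_1 = "met_is_1"
    POST_MET_IS_1 = "post_met_is_1"


class ReferenceError(ValueError):
    """Malformed reference sequence or failed sequence lookup."""


@dataclass(frozen=True)
class HistoneReference:
    """A named histone subtype sequence with its numbering convention.

    ``sequence`` is the mature chain (no initiator Met) when
    ``met_cleaved`` is true; residue ``i`` (1-based, post-Met numbering)
    is then ``sequence[i - 1]``.
    """

    name: str
    sequence: str
    met_cleaved: bool = True
    numbering_origin: NumberingOrigin = NumberingOrigin.POST_MET_IS_1

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ReferenceError(f"reference {self.name!r}: empty sequence")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ReferenceError(
                f"reference {self.name!r}: non-standard residues {sorted(bad)}"
            )
        if self.met_cleaved and self.numbering_origin is not NumberingOrigin.POST_MET_IS_1:
            raise ReferenceError(
                f"reference {self.name!r}: a Met-cleaved sequence must be numbered "
                "from the first post-Met residue"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue letter at a 1-based canonical (post-Met) position."""
        if not 1 <= position <= len(self.sequence):
            raise ReferenceError(
                f"position {position} outside {self.name} (1..{len(self.sequence)})"
            )
        return self.sequence[position - 1]


def read_reference_fasta(path: str | Path) -> dict[str, HistoneReference]:
    """Read histone references from a FASTA file.

    The first whitespace-separated header token becomes the reference name.
    Sequences are uppercased and assumed post-Met (mature chain) unless the
    caller renumbers them explicitly.

    Returns a name-keyed, insertion-ordered mapping.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    refs: dict[str, HistoneReference] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if not seq:
            raise ReferenceError(f"{path}: entry {record.id!r} has an empty sequence")
        if record.id in refs:
            raise ReferenceError(f"{path}: duplicate reference name {record.id!r}")
        refs[record.id] = HistoneReference(name=record.id, sequence=seq)
    return refs


def bundled_references() -> dict[str, HistoneReference]:
    """Core histone references (H4, H2A, H2B, H3) shipped with the package."""
    with resources.as_file(
        resources.files("histonecode").joinpath("data/histones.fasta")
    ) as p:
        return read_reference_fasta(p)


def renumber(
    position: int, from_origin: NumberingOrigin, to_origin: NumberingOrigin
) -> int:
    """Convert a residue index between the two numbering conventions.

    Met-is-1 numbering counts the (cleaved) initiator Met as residue 1, so a
    Met-is-1 index is one larger than the post-Met index of the same residue.
    Converting the Met itself (position 1, Met-is-1) has no post-Met image
    and raises.
    """
    if position < 1:
        raise ValueError(f"residue positions are 1-based, got {position}")
    if from_origin is to_origin:
        return position
    if from_origin is NumberingOrigin.MET_IS_1:
        result = position - 1
    else:
        result = position + 1
    if result < 1:
        raise ValueError(
            f"position {position} ({from_origin.value}) has no image in "
            f"{to_origin.value} numbering (it is the cleaved Met)"
        )
    return result


def renumber_all(
    positions: Iterable[int], from_origin: NumberingOrigin, to_origin: NumberingOrigin
) -> list[int]:
    return [renumber(p, from_origin, to_origin) for p in positions]
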