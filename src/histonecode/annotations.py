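"""Parsing and serialisation of annotated modified-peptide strings.

The text notation annotates a bare peptide sequence in place:

* ``ac-`` at the very start marks acetylation of the protein N-terminus
  (the free alpha-amino group), distinct from side-chain acetylation;
* a lowercase ``p`` immediately *before* S, T or Y marks phosphorylation;
* a lowercase tag immediately *after* a residue marks a side-chain PTM:
  ``ac`` acetylation (K/S/T/Y), ``me1``/``me2``/``me3`` mono-/di-/
  tri-methylation (K/R), ``pp`` propionylation, ``b`` butyrylation,
  ``cr`` crotonylation and ``gg`` the Gly-Gly ubiquitination remnant
  (K only);
* a parenthesised tag, e.g. ``(p)S`` or ``K(ac)``, marks a site whose
  exact residue assignment is ambiguous.

Example: ``ac-SGRGKacGGKacGLGKacGGAKacRHRKme2VLR`` is an H4 N-terminal
peptide with N-terminal acetylation, four acetyl-lysines and one
dimethyl-lysine.

Protein N-terminal acetylation is stored at pseudo-position 0 so that it
can enter co-occurrence analyses as an item of its own.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .reference import HistoneReference


class PeptideParseError(ValueError):
    """Annotated-sequence text that does not follow the notation."""


class PlacementError(ValueError):
    """Peptide sequence that cannot be placed uniquely on its reference."""


class PtmType(enum.Enum):
    NTERM_AC = "ntac"
    PHOS = "p"
    AC = "ac"
    ME1 = "me1"
    ME2 = "me2"
    ME3 = "me3"
    PROP = "pp"
    BUT = "b"
    CROT = "cr"
    UB_GG = "gg"


# chemically valid target residues per PTM type (side-chain PTMs only)
VALID_RESIDUES: Mapping[PtmType, frozenset[str]] = {
    PtmType.PHOS: frozenset("STY"),
    PtmType.AC: frozenset("KSTY"),
    PtmType.ME1: frozenset("KR"),
    PtmType.ME2: frozenset("KR"),
    PtmType.ME3: frozenset("KR"),
    PtmType.PROP: frozenset("K"),
    PtmType.BUT: frozenset("K"),
    PtmType.CROT: frozenset("K"),
    PtmType.UB_GG: frozenset("K"),
}

_SUFFIX_TAGS: Mapping[str, PtmType] = {
    "ac": PtmType.AC,
    "me1": PtmType.ME1,
    "me2": PtmType.ME2,
    "me3": PtmType.ME3,
    "pp": PtmType.PROP,
    "b": PtmType.BUT,
    "cr": PtmType.CROT,
    "gg": PtmType.UB_GG,
}
_TAG_FOR_PTM = {v: k for k, v in _SUFFIX_TAGS.items()}


@dataclass(frozen=True)
class SiteAnnotation:
    """One PTM at one residue position (canonical post-Met numbering).

    Position 0 with ``ptm == NTERM_AC`` denotes the protein N-terminus;
    its ``residue`` is the empty string.
    """

    position: int
    residue: str
    ptm: PtmType
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.ptm is PtmType.NTERM_AC:
            if self.position != 0 or self.residue != "":
                raise ValueError("N-terminal acetylation lives at pseudo-position 0")
        else:
            if self.position < 1:
                raise ValueError("side-chain PTM positions are 1-based")
            if self.residue not in VALID_RESIDUES[self.ptm]:
                raise PeptideParseError(
                    f"{self.ptm.name} is not chemically valid on residue "
                    f"{self.residue!r} (allowed: {sorted(VALID_RESIDUES[self.ptm])})"
                )


@dataclass(frozen=True)
class ModifiedPeptide:
    """An observed peptide instance placed on its reference.

    ``instance_count`` is the number of observations the row stands for;
    collapsed (distinct-pattern) lists use counts > 1, instance-level
    lists use 1 per row.
    """

    histone: str
    start: int
    end: int
    sequence: str
    annotations: tuple[SiteAnnotation, ...] = ()
    instance_count: int = 1

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("peptide span does not match sequence length")
        if self.instance_count < 1:
            raise ValueError("instance_count must be positive")
        seen: set[int] = set()
        for ann in self.annotations:
            if ann.position in seen:
                raise ValueError(
                    f"two PTMs at position {ann.position} on one peptide instance"
                )
            seen.add(ann.position)
            if ann.ptm is PtmType.NTERM_AC:
                if self.start != 1:
                    raise ValueError(
                        "N-terminal acetylation requires the peptide to start "
                        "at residue 1"
                    )
            elif not self.start <= ann.position <= self.end:
                raise ValueError(
                    f"annotation at {ann.position} outside peptide span "
                    f"[{self.start}, {self.end}]"
                )

    def covers(self, position: int) -> bool:
        """Whether the peptide's span includes a position (0 = N-terminus)."""
        if position == 0:
            return self.start == 1
        return self.start <= position <= self.end

    def annotation_at(self, position: int) -> SiteAnnotation | None:
        for ann in self.annotations:
            if ann.position == position:
                return ann
        return None

    def __len__(self) -> int:
        return len(self.sequence)


def locate_peptide(bare_sequence: str, reference: HistoneReference) -> int:
    """1-based start of the unique exact match of a peptide on a reference."""
    if not bare_sequence:
        raise PlacementError("empty peptide sequence")
    starts = []
    pos = reference.sequence.find(bare_sequence)
    while pos != -1:
        starts.append(pos + 1)
        pos = reference.sequence.find(bare_sequence, pos + 1)
    if not starts:
        raise PlacementError(
            f"peptide {bare_sequence!r} not found in reference {reference.name}"
        )
    if len(starts) > 1:
        raise PlacementError(
            f"peptide {bare_sequence!r} matches reference {reference.name} at "
            f"multiple starts {starts}"
        )
    return starts[0]


def _decompose_run(run: str, next_char: str | None) -> tuple[str | None, bool]:
    """Split a lowercase run into (suffix tag for the previous residue,
    phospho-prefix for the next residue).

    Returns (tag_or_None, has_phospho_prefix).  The only legal overlap is a
    trailing ``p`` acting as the phospho marker of a following S/T/Y.
    """
    candidates = []
    for pm in ("", "p"):
        if not run.endswith(pm):
            continue
        suffix = run[: len(run) - len(pm)]
        if suffix and suffix not in _SUFFIX_TAGS:
            continue
        if pm and (next_char is None or next_char not in "STY"):
            continue
        if not suffix and not pm:
            continue
        candidates.append((suffix or None, bool(pm)))
    if not candidates:
        raise PeptideParseError(f"unknown modification tag {run!r}")
    # prefer reading the whole run as a suffix tag; the overlap cases
    # ("pp" vs "p"+"p") are disjoint in the tag vocabulary so at most one
    # candidate survives in practice
    return candidates[0]


def _parse_units(text: str) -> tuple[bool, bool, list[dict]]:
    """Tokenise annotated text into per-residue units.

    Returns (nterm_ac, nterm_ambiguous, units); each unit is a dict with
    keys residue, phospho (None | 'plain' | 'ambiguous'), tag
    (None | (PtmType, ambiguous)).
    """
    nterm_ac = False
    nterm_ambig = False
    if text.startswith("(ac-)"):
        nterm_ac, nterm_ambig = True, True
        text = text[5:]
    elif text.startswith("ac-"):
        nterm_ac = True
        text = text[3:]
    units: list[dict] = []
    pending_phos: str | None = None  # 'plain' or 'ambiguous'
    i = 0
    n = len(text)
    while i < n:
        c = text[i]
        if c == "(":
            j = text.find(")", i)
            if j == -1:
                raise PeptideParseError(f"unbalanced parenthesis at offset {i}")
            inner = text[i + 1 : j]
            if inner == "p":
                if pending_phos is not None:
                    raise PeptideParseError("two phospho markers before one residue")
                pending_phos = "ambiguous"
            elif inner in _SUFFIX_TAGS:
                if not units:
                    raise PeptideParseError(
                        f"suffix tag ({inner}) before any residue"
                    )
                if units[-1]["tag"] is not None:
                    raise PeptideParseError(
                        f"residue {units[-1]['residue']!r} carries two tags"
                    )
                units[-1]["tag"] = (_SUFFIX_TAGS[inner], True)
            else:
                raise PeptideParseError(f"unknown modification tag ({inner!r})")
            i = j + 1
        elif c.isupper():
            units.append({"residue": c, "phospho": pending_phos, "tag": None})
            pending_phos = None
            i += 1
        elif c.islower() or c.isdigit():
            j = i
            while j < n and (text[j].islower() or text[j].isdigit()):
                j += 1
            run = text[i:j]
            next_char = text[j] if j < n else None
            if next_char == "(":
                next_char = None
            tag, phos_next = _decompose_run(run, next_char)
            if tag is not None:
                if not units:
                    raise PeptideParseError(f"suffix tag {tag!r} before any residue")
                if units[-1]["phospho"] is not None or units[-1]["tag"] is not None:
                    raise PeptideParseError(
                        f"residue {units[-1]['residue']!r} carries two modifications"
                    )
                units[-1]["tag"] = (_SUFFIX_TAGS[tag], False)
            if phos_next:
                pending_phos = "plain"
            i = j
        else:
            raise PeptideParseError(f"unexpected character {c!r} at offset {i}")
    if pending_phos is not None:
        raise PeptideParseError("dangling phospho marker at end of sequence")
    return nterm_ac, nterm_ambig, units


def parse_peptide(
    text: str,
    reference: HistoneReference,
    instance_count: int = 1,
    start: int | None = None,
) -> ModifiedPeptide:
    """Parse an annotated peptide string and place it on its reference.

    When ``start`` is given the peptide is placed there (after checking the
    sequence matches); otherwise a unique exact match is required.
    """
    text = text.strip()
    if not text:
        raise PeptideParseError("empty annotated sequence")
    nterm_ac, nterm_ambig, units = _parse_units(text)
    bare = "".join(u["residue"] for u in units)
    if start is not None:
        if reference.sequence[start - 1 : start - 1 + len(bare)] != bare:
            raise PlacementError(
                f"peptide {bare!r} does not match {reference.name} at "
                f"position {start}"
            )
    else:
        start = locate_peptide(bare, reference)
    if nterm_ac and start != 1:
        raise PeptideParseError(
            f"'ac-' N-terminal acetylation on a peptide starting at residue "
            f"{start} of {reference.name} (must start at 1)"
        )
    annotations: list[SiteAnnotation] = []
    if nterm_ac:
        annotations.append(
            SiteAnnotation(0, "", PtmType.NTERM_AC, ambiguous=nterm_ambig)
        )
    for offset, unit in enumerate(units):
        pos = start + offset
        if unit["phospho"] is not None and unit["tag"] is not None:
            raise PeptideParseError(
                f"residue {unit['residue']!r} at {pos} carries two modifications"
            )
        if unit["phospho"] is not None:
            annotations.append(
                SiteAnnotation(
                    pos,
                    unit["residue"],
                    PtmType.PHOS,
                    ambiguous=unit["phospho"] == "ambiguous",
                )
            )
        elif unit["tag"] is not None:
            ptm, ambig = unit["tag"]
            annotations.append(SiteAnnotation(pos, unit["residue"], ptm, ambig))
    return ModifiedPeptide(
        histone=reference.name,
        start=start,
        end=start + len(bare) - 1,
        sequence=bare,
        annotations=tuple(annotations),
        instance_count=instance_count,
    )


def serialise_peptide(p: ModifiedPeptide) -> str:
    """Render a peptide back to annotated text; inverse of :func:`parse_peptide`."""
    by_pos = {a.position: a for a in p.annotations if a.ptm is not PtmType.NTERM_AC}
    nterm = p.annotation_at(0)
    out: list[str] = []
    if nterm is not None:
        out.append("(ac-)" if nterm.ambiguous else "ac-")
    for offset, residue in enumerate(p.sequence):
        pos = p.start + offset
        ann = by_pos.get(pos)
        if ann is not None and ann.ptm is PtmType.PHOS:
            out.append("(p)" if ann.ambiguous else "p")
        out.append(residue)
        if ann is not None and ann.ptm is not PtmType.PHOS:
            tag = _TAG_FOR_PTM[ann.ptm]
            out.append(f"({tag})" if ann.ambiguous else tag)
    return "".join(out)


# ---------------------------------------------------------------------------
# TSV interchange: columns histone, annotated_sequence, instance_count
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ("histone", "annotated_sequence", "start", "instance_count")


def read_peptide_tsv(
    path: str | Path, references: Mapping[str, HistoneReference]
) -> list[ModifiedPeptide]:
    """Read peptides from a TSV of annotated sequences.

    Header row required.  ``instance_count`` (default 1) and ``start``
    (explicit placement, needed only for sequences that match the reference
    more than once) are optional columns.  Unicode dashes are normalised to
    ASCII hyphens.
    """
    path = Path(path)
    peptides: list[ModifiedPeptide] = []
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line:
            raise PeptideParseError(f"{path}: empty file (header row required)")
        header = header_line.rstrip("\n").split("\t")
        try:
            i_hist = header.index("histone")
            i_seq = header.index("annotated_sequence")
        except ValueError as exc:
            raise PeptideParseError(
                f"{path}: header must contain 'histone' and 'annotated_sequence'"
            ) from exc
        i_count = header.index("instance_count") if "instance_count" in header else None
        i_start = header.index("start") if "start" in header else None

        def field(fields: list[str], idx: int | None) -> str:
            if idx is None or idx >= len(fields):
                return ""
            return fields[idx].strip()

        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.replace("–", "-").replace("—", "-").split("\t")
            histone = field(fields, i_hist)
            if histone not in references:
                raise PlacementError(
                    f"{path}:{lineno}: unknown histone {histone!r}"
                )
            count = int(field(fields, i_count) or 1)
            start = int(field(fields, i_start)) if field(fields, i_start) else None
            try:
                peptides.append(
                    parse_peptide(
                        field(fields, i_seq),
                        references[histone],
                        instance_count=count,
                        start=start,
                    )
                )
            except (PeptideParseError, PlacementError) as exc:
                raise type(exc)(f"{path}:{lineno}: {exc}") from exc
    return peptides


def write_peptide_tsv(path: str | Path, peptides: Iterable[ModifiedPeptide]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for p in peptides:
            fh.write(
                f"{p.histone}\t{serialise_peptide(p)}\t{p.start}\t{p.instance_count}\n"
            )


def expand_instances(peptides: Iterable[ModifiedPeptide]) -> list[ModifiedPeptide]:
    """Split weighted rows into unit-count instances (occupancy-invariant)."""
    out = []
    for p in peptides:
        out.extend(replace(p, instance_count=1) for _ in range(p.instance_count))
    return out
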