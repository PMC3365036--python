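"""Per-residue modification-site occupancy and combinatorial code maps.

Occupancy of a (residue, PTM-type) pair is the number of peptide instances
on which the PTM was detected divided by the number of instances on which
the residue was observed at all — a spectral-count estimate of the relative
abundance of the modified form.  The denominator therefore depends on which
peptides enter the analysis: supplying unmodified peptides alongside the
modified ones gives abundance relative to *all* observations, while a
modified-only input gives abundance relative to modified peptides.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .annotations import ModifiedPeptide, PtmType, SiteAnnotation
from .reference import HistoneReference


def round_percent(fraction: float) -> int:
    """Round a fraction to integer percent, half-up (so 0.585 -> 59%)."""
    return int(
        (Decimal(str(fraction)) * 100).quantize(Decimal("1"), rounding=ROUND_HALF_UP)
    )


@dataclass(frozen=True)
class OccupancyTable:
    """Detected/observed instance counts per (position, PTM type).

    ``table`` columns: position, residue, ptm, detected, observed,
    occupancy.  Position 0 rows refer to the protein N-terminus.
    """

    histone: str
    table: pd.DataFrame
    modified_only: bool = False

    def occupancy(self, position: int, ptm: PtmType) -> float:
        rows = self.table[
            (self.table.position == position) & (self.table.ptm == ptm.name)
        ]
        if rows.empty:
            raise KeyError(f"no occupancy row for position {position}, {ptm.name}")
        return float(rows.iloc[0].occupancy)

    def percent(self, position: int, ptm: PtmType) -> int:
        return round_percent(self.occupancy(position, ptm))

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.insert(0, "histone", self.histone)
        out["occupancy_percent"] = [round_percent(x) for x in out.occupancy]
        out.to_csv(path, sep="\t", index=False)


def compute_occupancy(
    peptides: Sequence[ModifiedPeptide],
    reference: HistoneReference,
    include_ambiguous: bool = False,
    modified_only: bool | None = None,
) -> OccupancyTable:
    """Build the occupancy table for one histone.

    observed(position) sums instance counts of peptides covering the
    position; detected(position, ptm) sums instance counts of peptides
    carrying that PTM there.  Ambiguously-localised annotations are left
    out of the numerator unless ``include_ambiguous``.  The N-terminus
    (position 0) is observed only by peptides starting at residue 1.

    ``modified_only`` labels the denominator convention in the output; by
    default it is inferred (True when every input peptide carries a PTM).
    """
    peptides = [p for p in peptides if p.histone == reference.name]
    observed: dict[int, int] = {}
    detected: dict[tuple[int, str], int] = {}
    residues: dict[int, str] = {}
    for p in peptides:
        if p.start == 1:
            observed[0] = observed.get(0, 0) + p.instance_count
            residues.setdefault(0, "")
        for pos in range(p.start, p.end + 1):
            observed[pos] = observed.get(pos, 0) + p.instance_count
            residues.setdefault(pos, reference.residue(pos))
        for ann in p.annotations:
            if ann.ambiguous and not include_ambiguous:
                continue
            key = (ann.position, ann.ptm.name)
            detected[key] = detected.get(key, 0) + p.instance_count
    rows = []
    for (pos, ptm), det in sorted(detected.items()):
        rows.append(
            {
                "position": pos,
                "residue": residues[pos],
                "ptm": ptm,
                "detected": det,
                "observed": observed[pos],
                "occupancy": det / observed[pos],
            }
        )
    table = pd.DataFrame(
        rows, columns=["position", "residue", "ptm", "detected", "observed", "occupancy"]
    )
    if modified_only is None:
        modified_only = bool(peptides) and all(p.annotations for p in peptides)
    return OccupancyTable(histone=reference.name, table=table, modified_only=modified_only)


def conditional_occupancy(
    peptides: Sequence[ModifiedPeptide],
    condition: tuple[int, PtmType],
    target: tuple[int, PtmType],
) -> float:
    """P(target PTM | condition PTM), over instances covering both positions.

    Ambiguous annotations do not count as carrying a PTM.
    """
    cond_pos, cond_ptm = condition
    targ_pos, targ_ptm = target

    def has(p: ModifiedPeptide, pos: int, ptm: PtmType) -> bool:
        ann = p.annotation_at(pos)
        return ann is not None and ann.ptm is ptm and not ann.ambiguous

    n_cond = 0
    n_both = 0
    for p in peptides:
        if not (p.covers(cond_pos) and p.covers(targ_pos)):
            continue
        if has(p, cond_pos, cond_ptm):
            n_cond += p.instance_count
            if has(p, targ_pos, targ_ptm):
                n_both += p.instance_count
    if n_cond == 0:
        raise ValueError(
            f"no instance carries the conditioning PTM {cond_ptm.name}@{cond_pos}"
        )
    return n_both / n_cond


@dataclass(frozen=True)
class CodeMap:
    """One row per combinatorial modification pattern over a tail region.

    ``rows``: list of (pattern, multiplicity); a pattern maps position ->
    PtmType for every modified position (unmodified positions absent).
    """

    histone: str
    region: tuple[int, int]
    rows: tuple[tuple[tuple[tuple[int, PtmType], ...], int], ...]
    distinct: bool

    def to_frame(self, positions: Sequence[int] | None = None) -> pd.DataFrame:
        """Matrix view: rows = patterns, columns = positions, cells = tag names."""
        if positions is None:
            seen = sorted({pos for pattern, _ in self.rows for pos, _ in pattern})
            positions = seen
        data = []
        for pattern, mult in self.rows:
            lookup = dict(pattern)
            row = {str(pos): lookup[pos].value if pos in lookup else "" for pos in positions}
            row["multiplicity"] = mult
            data.append(row)
        return pd.DataFrame(data, columns=[str(p) for p in positions] + ["multiplicity"])


def build_code_map(
    peptides: Sequence[ModifiedPeptide],
    reference: HistoneReference,
    region: tuple[int, int],
    distinct: bool = True,
    include_ambiguous: bool = False,
) -> CodeMap:
    """Collect the modification patterns of peptides fully covering a region.

    Patterns are restricted to the region (N-terminal acetylation, position
    0, belongs to regions starting at 1).  With ``distinct``, identical
    patterns collapse to one row with their total multiplicity.  Rows sort
    by decreasing PTM count, then lexicographically by (position, tag).
    """
    start, end = region
    if start < 0 or end > len(reference) or start > end:
        raise ValueError(f"region {region} outside reference {reference.name}")
    patterns: list[tuple[tuple[tuple[int, PtmType], ...], int]] = []
    for p in peptides:
        if p.histone != reference.name:
            continue
        if not (p.start <= max(start, 1) and p.end >= end):
            continue
        pattern = tuple(
            sorted(
                (a.position, a.ptm)
                for a in p.annotations
                if (include_ambiguous or not a.ambiguous)
                and ((a.position == 0 and start <= 1) or start <= a.position <= end)
            )
        )
        patterns.append((pattern, p.instance_count))
    if distinct:
        merged: dict[tuple, int] = {}
        for pattern, mult in patterns:
            merged[pattern] = merged.get(pattern, 0) + mult
        patterns = list(merged.items())

    def sort_key(item):
        pattern, _ = item
        return (-len(pattern), tuple((pos, ptm.value) for pos, ptm in pattern))

    patterns.sort(key=sort_key)
    return CodeMap(
        histone=reference.name, region=region, rows=tuple(patterns), distinct=distinct
    )
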