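"""Frequent-itemset and association-rule mining over per-residue PTM states.

Each peptide instance becomes a *transaction*: one item per vocabulary
position, the item being either the unambiguous PTM observed there or an
explicit UNMODIFIED state.  Ambiguously-localised PTMs are treated as
unmodified, so every transaction assigns a state to every column of the
analysis region.  Frequent combinations of states are mined level-wise
(Apriori, with the anti-monotone pruning rule) and split into association
rules X -> Y scored by

    support(Z)     = (sum of weights of transactions containing Z) / total weight
    confidence     = support(X u Y) / support(X)

Support uses a *strict* threshold (kept are itemsets with support greater
than ``min_support``), and peptides shorter than ``min_peptide_length``
residues are dropped before mining so that only long-range combinatorial
patterns enter the transactions.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotations import ModifiedPeptide, PtmType
from .reference import HistoneReference

UNMODIFIED = "un"


@dataclass(frozen=True, order=True)
class Item:
    """A (position, state) pair; state is a PTM tag or the unmodified marker."""

    position: int
    state: str

    def __str__(self) -> str:
        return f"pos{self.position}:{self.state}"

    @classmethod
    def from_str(cls, text: str) -> "Item":
        pos, _, state = text.partition(":")
        if not pos.startswith("pos") or not state:
            raise ValueError(f"bad item string {text!r}")
        return cls(int(pos[3:]), state)

    @classmethod
    def modified(cls, position: int, ptm: PtmType) -> "Item":
        return cls(position, ptm.value)

    @classmethod
    def unmodified(cls, position: int) -> "Item":
        return cls(position, UNMODIFIED)


@dataclass(frozen=True)
class Transaction:
    items: frozenset[Item]
    weight: int = 1

    def __post_init__(self) -> None:
        if self.weight < 1:
            raise ValueError("transaction weight must be positive")
        positions = [it.position for it in self.items]
        if len(set(positions)) != len(positions):
            raise ValueError("a transaction holds one state per position")


@dataclass(frozen=True)
class FrequentItemset:
    items: frozenset[Item]
    support: float


@dataclass(frozen=True)
class AssociationRule:
    antecedent: frozenset[Item]
    consequent: frozenset[Item]
    support: float  # support of antecedent u consequent
    confidence: float

    def __str__(self) -> str:
        lhs = ",".join(str(i) for i in sorted(self.antecedent))
        rhs = ",".join(str(i) for i in sorted(self.consequent))
        return f"{lhs}=>{rhs}"


@dataclass(frozen=True)
class MiningConfig:
    """Region, vocabulary and thresholds for one mining run.

    ``region`` is a (start, end) residue span on the histone; a region
    starting at residue 1 implicitly includes the protein N-terminus
    (position 0).  ``vocabulary`` lists the positions that become matrix
    columns; when None it is derived from the data (positions modified at
    least once, unambiguously, plus position 0 for N-terminal regions).
    """

    region: tuple[int, int]
    min_support: float = 0.20
    min_peptide_length: int = 21
    vocabulary: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.min_support < 1:
            raise ValueError("min_support must lie in (0, 1)")
        if self.min_peptide_length < 1:
            raise ValueError("min_peptide_length must be >= 1")
        start, end = self.region
        if start < 1 or end < start:
            raise ValueError(f"bad region {self.region}")


def filter_peptides(
    peptides: Sequence[ModifiedPeptide], config: MiningConfig
) -> list[ModifiedPeptide]:
    """Keep peptides long enough and fully covering the analysis region."""
    start, end = config.region
    return [
        p
        for p in peptides
        if len(p) >= config.min_peptide_length and p.start <= start and p.end >= end
    ]


def derive_vocabulary(
    peptides: Sequence[ModifiedPeptide], config: MiningConfig
) -> tuple[int, ...]:
    """Positions in the region carrying at least one unambiguous PTM.

    Position 0 (protein N-terminus) is included whenever the region starts
    at residue 1; never-modified residues are left out so that their
    all-UNMODIFIED items do not flood the frequent sets.
    """
    start, end = config.region
    positions: set[int] = set()
    for p in peptides:
        for a in p.annotations:
            if a.ambiguous:
                continue
            if a.position == 0 or start <= a.position <= end:
                positions.add(a.position)
    if start == 1:
        positions.add(0)
    return tuple(sorted(positions))


def build_transactions(
    peptides: Sequence[ModifiedPeptide], config: MiningConfig
) -> list[Transaction]:
    """One transaction per peptide row, one item per vocabulary position."""
    start, end = config.region
    vocab = config.vocabulary
    if vocab is None:
        vocab = derive_vocabulary(peptides, config)
    for pos in vocab:
        if pos != 0 and not start <= pos <= end:
            raise ValueError(f"vocabulary position {pos} outside region {config.region}")
        if pos == 0 and start != 1:
            raise ValueError("position 0 requires a region starting at residue 1")
    transactions = []
    for p in peptides:
        items = []
        for pos in vocab:
            ann = p.annotation_at(pos)
            if ann is not None and not ann.ambiguous:
                items.append(Item.modified(pos, ann.ptm))
            else:
                items.append(Item.unmodified(pos))
        transactions.append(Transaction(frozenset(items), weight=p.instance_count))
    return transactions


def support_of(itemset: frozenset[Item], transactions: Sequence[Transaction]) -> float:
    """Weighted fraction of transactions containing the itemset."""
    total = sum(t.weight for t in transactions)
    if total == 0:
        return 0.0
    hit = sum(t.weight for t in transactions if itemset <= t.items)
    return hit / total


def apriori(
    transactions: Sequence[Transaction], min_support: float = 0.20
) -> list[FrequentItemset]:
    """All itemsets with support strictly greater than ``min_support``.

    Level-wise candidate generation: a size-k candidate is formed from two
    frequent size-(k-1) sets sharing their first k-2 items and kept only if
    all its size-(k-1) subsets are frequent (anti-monotonicity).
    """
    if not transactions:
        return []
    total = sum(t.weight for t in transactions)
    counts: dict[Item, int] = {}
    for t in transactions:
        for it in t.items:
            counts[it] = counts.get(it, 0) + t.weight
    current = {
        frozenset([it]): c / total
        for it, c in counts.items()
        if c / total > min_support
    }
    result: dict[frozenset[Item], float] = dict(current)
    k = 2
    while current:
        prev_sets = set(current)
        sorted_prev = sorted(tuple(sorted(s)) for s in current)
        candidates: set[frozenset[Item]] = set()
        for a, b in itertools.combinations(sorted_prev, 2):
            if a[:-1] == b[:-1]:
                cand = frozenset(a) | frozenset(b)
                if len(cand) == k and all(
                    cand - {it} in prev_sets for it in cand
                ):
                    candidates.add(cand)
        current = {}
        if candidates:
            tallies = {c: 0 for c in candidates}
            for t in transactions:
                for c in candidates:
                    if c <= t.items:
                        tallies[c] += t.weight
            for c, hit in tallies.items():
                supp = hit / total
                if supp > min_support:
                    current[c] = supp
        result.update(current)
        k += 1
    ordered = sorted(result.items(), key=lambda kv: (len(kv[0]), tuple(sorted(kv[0]))))
    return [FrequentItemset(items, supp) for items, supp in ordered]


def derive_rules(
    itemsets: Sequence[FrequentItemset],
    min_confidence: float = 0.0,
) -> list[AssociationRule]:
    """Split every frequent itemset of size >= 2 into all rules X -> Y.

    Supports are looked up from the frequent-itemset table (every subset of
    a frequent itemset is itself frequent, so the lookup never misses).
    Rules at or above ``min_confidence`` are returned, sorted by descending
    confidence then the deterministic itemset order.
    """
    lookup = {fs.items: fs.support for fs in itemsets}
    rules = []
    for fs in itemsets:
        if len(fs.items) < 2:
            continue
        items = sorted(fs.items)
        for r in range(1, len(items)):
            for x in itertools.combinations(items, r):
                antecedent = frozenset(x)
                if antecedent not in lookup:
                    raise RuntimeError(
                        f"support of {sorted(antecedent)} missing from frequent "
                        "itemsets; itemsets and rules must come from one run"
                    )
                confidence = fs.support / lookup[antecedent]
                if confidence >= min_confidence:
                    rules.append(
                        AssociationRule(
                            antecedent=antecedent,
                            consequent=fs.items - antecedent,
                            support=fs.support,
                            confidence=confidence,
                        )
                    )
    rules.sort(
        key=lambda r: (
            -r.confidence,
            len(r.antecedent) + len(r.consequent),
            tuple(sorted(r.antecedent)),
            tuple(sorted(r.consequent)),
        )
    )
    return rules


def rule_matrix(
    rules: Sequence[AssociationRule],
    antecedents: Sequence[Item | Iterable[Item]],
    consequents: Sequence[Item],
) -> pd.DataFrame:
    """Confidence matrix for a heat-plot: rows = conditions, columns = outcomes.

    Cell (i, j) is the confidence of antecedent_i -> consequent_j, looked up
    among single-consequent rules.  Cells whose rule was not derived (the
    antecedent or the pair fell below the support threshold) are missing
    (NaN), not zero.  A consequent contained in its own antecedent is the
    trivial diagonal and is set to 1.0.
    """
    norm_ante = [
        frozenset([a]) if isinstance(a, Item) else frozenset(a) for a in antecedents
    ]
    lookup = {
        (r.antecedent, next(iter(r.consequent))): r.confidence
        for r in rules
        if len(r.consequent) == 1
    }
    index = [",".join(str(i) for i in sorted(a)) for a in norm_ante]
    columns = [str(c) for c in consequents]
    data = []
    for ante in norm_ante:
        row = []
        for cons in consequents:
            if cons in ante:
                row.append(1.0)
            else:
                row.append(lookup.get((ante, cons), float("nan")))
        data.append(row)
    return pd.DataFrame(data, index=index, columns=columns)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def itemsets_to_frame(itemsets: Sequence[FrequentItemset]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "itemset": [",".join(str(i) for i in sorted(fs.items)) for fs in itemsets],
            "size": [len(fs.items) for fs in itemsets],
            "support": [fs.support for fs in itemsets],
        }
    )


def rules_to_frame(rules: Sequence[AssociationRule]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rule": [str(r) for r in rules],
            "support": [r.support for r in rules],
            "confidence": [r.confidence for r in rules],
        }
    )


def write_itemsets(path: str | Path, itemsets: Sequence[FrequentItemset]) -> None:
    itemsets_to_frame(itemsets).to_csv(path, sep="\t", index=False)


def write_rules(path: str | Path, rules: Sequence[AssociationRule]) -> None:
    rules_to_frame(rules).to_csv(path, sep="\t", index=False)


def write_rules_json(path: str | Path, rules: Sequence[AssociationRule]) -> None:
    payload = [
        {
            "antecedent": [str(i) for i in sorted(r.antecedent)],
            "consequent": [str(i) for i in sorted(r.consequent)],
            "support": r.support,
            "confidence": r.confidence,
        }
        for r in rules
    ]
    Path(path).write_text(json.dumps(payload, indent=2))
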