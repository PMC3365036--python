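"""Synthetic peptide populations with planted combinatorial PTM structure.

The generator emulates what a middle-down MS experiment delivers to the
downstream analysis: peptide instances drawn from an in-silico protease
digest of a histone reference, carrying PTMs whose co-occurrence follows
explicit planted rules —

* ``HIERARCHY`` — a zip-like chain (e.g. H4 K16 -> K12 -> K8 -> K5
  acetylation): the outermost site is modified with a marginal rate, and
  each inner site with a high probability when its predecessor is
  modified and a small leak rate when it is not;
* ``EXCLUDES`` — two marks that never co-occur on one molecule (e.g.
  N-terminal acetylation vs R3 trimethylation);
* ``IMPLIES`` — an antecedent mark that forces (with stated probability)
  a consequent mark.

Each planted annotation is independently flagged as ambiguously localised
with a configurable rate, mimicking sites that fragment spectra could not
pin to one residue.  :func:`expected_rule_table` gives the closed-form
supports and confidences these rules induce among peptides covering the
analysis region, for parameter-recovery checks against the miner.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .annotations import (
    ModifiedPeptide,
    PtmType,
    SiteAnnotation,
    VALID_RESIDUES,
)
from .mining import UNMODIFIED, Item
from .reference import HistoneReference


class Side(enum.Enum):
    N_TERMINAL = "N"
    C_TERMINAL = "C"


@dataclass(frozen=True)
class EnzymeRule:
    """A protease's cleavage specificity: cut N- or C-terminally of residues."""

    name: str
    cleavage: frozenset[tuple[str, Side]]


GLUC = EnzymeRule("GLUC", frozenset({("D", Side.C_TERMINAL), ("E", Side.C_TERMINAL)}))
ASPN = EnzymeRule("ASPN", frozenset({("D", Side.N_TERMINAL)}))
CHYMO = EnzymeRule(
    "CHYMO",
    frozenset(
        {("Y", Side.C_TERMINAL), ("F", Side.C_TERMINAL), ("W", Side.C_TERMINAL)}
    ),
)
TRYPSIN = EnzymeRule(
    "TRYPSIN", frozenset({("K", Side.C_TERMINAL), ("R", Side.C_TERMINAL)})
)
CNBR = EnzymeRule("CNBR", frozenset({("M", Side.C_TERMINAL)}))

ENZYMES: Mapping[str, EnzymeRule] = {
    e.name: e for e in (GLUC, ASPN, CHYMO, TRYPSIN, CNBR)
}


def insilico_digest(
    reference: HistoneReference, enzyme: EnzymeRule, missed_cleavages: int = 0
) -> list[tuple[int, int]]:
    """(start, end) spans of all digestion peptides, 1-based inclusive.

    Fully-cleaved fragments are the maximal runs between cut sites; with
    ``missed_cleavages`` = m, every concatenation of up to m+1 adjacent
    fragments is also produced.  The m = 0 fragments tile the sequence.
    """
    seq = reference.sequence
    cuts: set[int] = set()  # cut between residue i and i+1
    for i, aa in enumerate(seq, start=1):
        if (aa, Side.C_TERMINAL) in enzyme.cleavage and i < len(seq):
            cuts.add(i)
        if (aa, Side.N_TERMINAL) in enzyme.cleavage and i > 1:
            cuts.add(i - 1)
    boundaries = [0, *sorted(cuts), len(seq)]
    fragments = [
        (boundaries[i] + 1, boundaries[i + 1]) for i in range(len(boundaries) - 1)
    ]
    peptides = []
    for i in range(len(fragments)):
        for j in range(i, min(i + missed_cleavages + 1, len(fragments))):
            peptides.append((fragments[i][0], fragments[j][1]))
    return peptides


def parse_site(text: str) -> tuple[int, "PtmType"]:
    """Parse a ``position:tag`` site string, e.g. ``16:ac`` or ``0:ntac``."""
    pos_str, _, tag = text.partition(":")
    try:
        return int(pos_str), PtmType(tag)
    except ValueError as exc:
        raise ValueError(f"bad site string {text!r} (want e.g. '16:ac')") from exc


class RuleKind(enum.Enum):
    IMPLIES = "implies"
    EXCLUDES = "excludes"
    HIERARCHY = "hierarchy"


@dataclass(frozen=True)
class PlantedRule:
    """A planted co-occurrence rule over (position, PtmType) sites.

    Probability semantics per kind:

    * HIERARCHY: sites ordered outermost -> innermost;
      ``probs = (p_first, conditional, leak)`` — the first site's marginal
      rate, P(site_i | site_{i-1} modified) and P(site_i | site_{i-1}
      unmodified).
    * EXCLUDES: two sites; ``probs = (p_a, p_b_given_not_a)``.
    * IMPLIES: two sites (antecedent, consequent);
      ``probs = (p_antecedent, p_cons_given_ant, p_cons_given_not_ant)``.

    Position 0 with NTERM_AC denotes protein N-terminal acetylation.
    """

    kind: RuleKind
    sites: tuple[tuple[int, PtmType], ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(not 0.0 <= p <= 1.0 for p in self.probs):
            raise ValueError("rule probabilities must lie in [0, 1]")
        expected = {
            RuleKind.HIERARCHY: (2, None, 3),
            RuleKind.EXCLUDES: (2, 2, 2),
            RuleKind.IMPLIES: (2, 2, 3),
        }[self.kind]
        min_sites, max_sites, n_probs = expected
        if len(self.sites) < min_sites or (
            max_sites is not None and len(self.sites) > max_sites
        ):
            raise ValueError(f"{self.kind.name} rule needs >= {min_sites} sites")
        if len(self.probs) != n_probs:
            raise ValueError(
                f"{self.kind.name} rule needs {n_probs} probabilities, "
                f"got {len(self.probs)}"
            )


@dataclass(frozen=True)
class SimulationConfig:
    reference: HistoneReference
    n_instances: int
    rules: tuple[PlantedRule, ...] = ()
    ambiguity_rate: float = 0.0
    enzyme: EnzymeRule = GLUC
    missed_cleavages: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_instances < 1:
            raise ValueError("n_instances must be positive")
        if not 0.0 <= self.ambiguity_rate < 1.0:
            raise ValueError("ambiguity_rate must lie in [0, 1)")
        defined: set[tuple[int, PtmType]] = set()
        pairs: dict[frozenset, RuleKind] = {}
        for rule in self.rules:
            for i, site in enumerate(rule.sites):
                self._validate_site(site)
                if site in defined:
                    # a previously defined site may anchor a later rule (its
                    # state is inherited), but may not be re-defined
                    if i != 0:
                        raise ValueError(
                            f"site {site} is defined by more than one planted rule"
                        )
                else:
                    defined.add(site)
            if len(rule.sites) == 2:
                pair = frozenset(rule.sites)
                if pair in pairs and pairs[pair] is not rule.kind:
                    raise ValueError(f"contradictory rules on pair {sorted(pair)}")
                pairs[pair] = rule.kind

    def _validate_site(self, site: tuple[int, PtmType]) -> None:
        position, ptm = site
        if ptm is PtmType.NTERM_AC:
            if position != 0:
                raise ValueError("NTERM_AC must sit at pseudo-position 0")
            return
        residue = self.reference.residue(position)
        if residue not in VALID_RESIDUES[ptm]:
            raise ValueError(
                f"{ptm.name} invalid on {residue}{position} of {self.reference.name}"
            )


def _sample_rule_states(
    rule: PlantedRule,
    rng: np.random.Generator,
    states: dict[tuple[int, PtmType], bool],
) -> None:
    """Sample this rule's sites into ``states``; the first site's state is
    inherited when an earlier rule already defined it."""

    def anchor(p_default: float) -> bool:
        site = rule.sites[0]
        if site not in states:
            states[site] = bool(rng.random() < p_default)
        return states[site]

    if rule.kind is RuleKind.HIERARCHY:
        p_first, conditional, leak = rule.probs
        prev = anchor(p_first)
        for site in rule.sites[1:]:
            p = conditional if prev else leak
            prev = bool(rng.random() < p)
            states[site] = prev
    elif rule.kind is RuleKind.EXCLUDES:
        p_a, p_b_given_not_a = rule.probs
        a = anchor(p_a)
        states[rule.sites[1]] = False if a else bool(rng.random() < p_b_given_not_a)
    else:  # IMPLIES
        p_ant, p_given, p_not_given = rule.probs
        ant = anchor(p_ant)
        p = p_given if ant else p_not_given
        states[rule.sites[1]] = bool(rng.random() < p)


def generate_population(config: SimulationConfig) -> list[ModifiedPeptide]:
    """Draw ``n_instances`` modified-peptide instances under the planted rules.

    Each instance picks a digestion peptide (missed-cleavage count uniform
    over 0..max), samples the modification state of every planted site,
    keeps the sites its span covers, and flags each kept annotation as
    ambiguous with ``ambiguity_rate``.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(config.seed)
    by_mc: dict[int, list[tuple[int, int]]] = {}
    frag0 = {frag: i for i, frag in enumerate(insilico_digest(config.reference, config.enzyme, 0))}
    for start, end in insilico_digest(
        config.reference, config.enzyme, config.missed_cleavages
    ):
        # number of internal missed cuts = spanned 0-mc fragments - 1
        spanned = sum(1 for (s, e) in frag0 if start <= s and e <= end)
        by_mc.setdefault(spanned - 1, []).append((start, end))
    mc_levels = sorted(by_mc)
    ref = config.reference
    peptides = []
    for _ in range(config.n_instances):
        mc = mc_levels[rng.integers(len(mc_levels))]
        frags = by_mc[mc]
        start, end = frags[rng.integers(len(frags))]
        states: dict[tuple[int, PtmType], bool] = {}
        for rule in config.rules:
            _sample_rule_states(rule, rng, states)
        annotations: list[SiteAnnotation] = []
        for (position, ptm), modified in states.items():
            if not modified:
                continue
            if position == 0:
                if start != 1:
                    continue
                residue = ""
            elif start <= position <= end:
                residue = ref.residue(position)
            else:
                continue
            ambiguous = bool(rng.random() < config.ambiguity_rate)
            annotations.append(SiteAnnotation(position, residue, ptm, ambiguous))
        annotations.sort(key=lambda a: a.position)
        peptides.append(
            ModifiedPeptide(
                histone=ref.name,
                start=start,
                end=end,
                sequence=ref.sequence[start - 1 : end],
                annotations=tuple(annotations),
                instance_count=1,
            )
        )
    return peptides


@dataclass(frozen=True)
class ExpectedRule:
    """Closed-form expectation for one mined rule on region-covering peptides."""

    antecedent: Item
    consequent: Item
    confidence: float
    joint_support: float


def expected_rule_table(config: SimulationConfig) -> list[ExpectedRule]:
    """Expected pairwise supports/confidences under the generative model.

    Expectations hold among transactions whose peptides cover all involved
    positions (the miner's region filter guarantees this).  An annotation
    enters a transaction as modified only if it was kept unambiguous, so
    observed marginals carry a factor q = 1 - ambiguity_rate.
    """
    q = 1.0 - config.ambiguity_rate
    out: list[ExpectedRule] = []
    known_marginals: dict[tuple[int, PtmType], float] = {}
    for rule in config.rules:
        items = [Item.modified(pos, ptm) for pos, ptm in rule.sites]
        if rule.kind is RuleKind.HIERARCHY:
            p_first, conditional, leak = rule.probs
            marginals = [known_marginals.get(rule.sites[0], p_first)]
            for _ in rule.sites[1:]:
                prev = marginals[-1]
                marginals.append(prev * conditional + (1 - prev) * leak)
            for i in range(1, len(items)):
                joint = marginals[i - 1] * conditional
                # inner site predicts its outer neighbour
                if marginals[i] > 0:
                    out.append(
                        ExpectedRule(
                            antecedent=items[i],
                            consequent=items[i - 1],
                            confidence=q * joint / marginals[i],
                            joint_support=q * q * joint,
                        )
                    )
                # outer site predicts its inner neighbour
                if marginals[i - 1] > 0:
                    out.append(
                        ExpectedRule(
                            antecedent=items[i - 1],
                            consequent=items[i],
                            confidence=q * conditional,
                            joint_support=q * q * joint,
                        )
                    )
            for site, m in zip(rule.sites, marginals):
                known_marginals.setdefault(site, m)
        elif rule.kind is RuleKind.EXCLUDES:
            p_a, p_b_given_not_a = rule.probs
            p_a = known_marginals.get(rule.sites[0], p_a)
            p_b = (1 - p_a) * p_b_given_not_a
            known_marginals.setdefault(rule.sites[0], p_a)
            known_marginals.setdefault(rule.sites[1], p_b)
            a_item, b_item = items
            # the modified marks never co-occur
            out.append(ExpectedRule(a_item, b_item, 0.0, 0.0))
            out.append(ExpectedRule(b_item, a_item, 0.0, 0.0))
            # each mark perfectly predicts the other's absence
            if p_a > 0:
                out.append(
                    ExpectedRule(
                        a_item,
                        Item(b_item.position, UNMODIFIED),
                        1.0,
                        q * p_a,
                    )
                )
            if p_b > 0:
                out.append(
                    ExpectedRule(
                        b_item,
                        Item(a_item.position, UNMODIFIED),
                        1.0,
                        q * p_b,
                    )
                )
        else:  # IMPLIES
            p_ant, p_given, p_not_given = rule.probs
            p_ant = known_marginals.get(rule.sites[0], p_ant)
            ant, cons = items
            p_cons = p_ant * p_given + (1 - p_ant) * p_not_given
            joint = p_ant * p_given
            known_marginals.setdefault(rule.sites[0], p_ant)
            known_marginals.setdefault(rule.sites[1], p_cons)
            if p_ant > 0:
                out.append(ExpectedRule(ant, cons, q * p_given, q * q * joint))
            if p_cons > 0:
                out.append(
                    ExpectedRule(cons, ant, q * joint / p_cons, q * q * joint)
                )
    return out


def h2a_triad_config(
    reference: HistoneReference,
    n_instances: int = 5000,
    p_nterm_ac: float = 0.88,
    p_r3me3_given_no_nterm: float = 1.0,
    p_k5ac_given_nterm: float = 0.205,
    ambiguity_rate: float = 0.0,
    seed: int = 0,
) -> SimulationConfig:
    """The H2A tail triad: abundant N-terminal acetylation (88% of modified
    peptides), R3 trimethylation mutually exclusive with it, and K5
    acetylation only on N-terminally acetylated molecules (marginal ~18%)."""
    exclusion = PlantedRule(
        RuleKind.EXCLUDES,
        sites=((0, PtmType.NTERM_AC), (3, PtmType.ME3)),
        probs=(p_nterm_ac, p_r3me3_given_no_nterm),
    )
    k5_gate = PlantedRule(
        RuleKind.IMPLIES,
        sites=((0, PtmType.NTERM_AC), (5, PtmType.AC)),
        probs=(p_nterm_ac, p_k5ac_given_nterm, 0.0),
    )
    return SimulationConfig(
        reference=reference,
        n_instances=n_instances,
        rules=(exclusion, k5_gate),
        ambiguity_rate=ambiguity_rate,
        enzyme=GLUC,
        missed_cleavages=0,
        seed=seed,
    )


def h4_zip_config(
    reference: HistoneReference,
    n_instances: int = 5000,
    conditional: float = 1.0,
    leak: float = 0.0,
    p_k16: float = 0.5,
    ambiguity_rate: float = 0.0,
    seed: int = 0,
) -> SimulationConfig:
    """Zip-model acetylation on the H4 tail: K16 -> K12 -> K8 -> K5."""
    zip_rule = PlantedRule(
        RuleKind.HIERARCHY,
        sites=(
            (16, PtmType.AC),
            (12, PtmType.AC),
            (8, PtmType.AC),
            (5, PtmType.AC),
        ),
        probs=(p_k16, conditional, leak),
    )
    return SimulationConfig(
        reference=reference,
        n_instances=n_instances,
        rules=(zip_rule,),
        ambiguity_rate=ambiguity_rate,
        enzyme=GLUC,
        missed_cleavages=1,
        seed=seed,
    )


def load_simulation_config(
    path, references: Mapping[str, HistoneReference], seed: int | None = None
) -> SimulationConfig:
    """Load a simulation config from a YAML file.

    Expected layout::

        reference: H4
        n_instances: 5000
        ambiguity_rate: 0.05
        enzyme: GLUC
        missed_cleavages: 1
        seed: 7
        rules:
          - kind: hierarchy
            sites: ["16:ac", "12:ac", "8:ac", "5:ac"]
            probs: [0.5, 1.0, 0.0]

    A ``seed`` argument overrides the file's seed.
    """
    import yaml

    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    ref_name = raw["reference"]
    if ref_name not in references:
        raise ValueError(f"unknown reference {ref_name!r}")
    rules = tuple(
        PlantedRule(
            kind=RuleKind(block["kind"].lower()),
            sites=tuple(parse_site(s) for s in block["sites"]),
            probs=tuple(float(p) for p in block["probs"]),
        )
        for block in raw.get("rules", [])
    )
    return SimulationConfig(
        reference=references[ref_name],
        n_instances=int(raw["n_instances"]),
        rules=rules,
        ambiguity_rate=float(raw.get("ambiguity_rate", 0.0)),
        enzyme=ENZYMES[raw.get("enzyme", "GLUC").upper()],
        missed_cleavages=int(raw.get("missed_cleavages", 0)),
        seed=int(seed if seed is not None else raw.get("seed", 0)),
    )
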