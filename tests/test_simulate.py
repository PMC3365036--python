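import math

import numpy as np
import pytest

from histonecode import (
    Item,
    MiningConfig,
    PtmType,
    apriori,
    build_transactions,
    derive_rules,
    expected_rule_table,
    filter_peptides,
    generate_population,
    h2a_triad_config,
    h4_zip_config,
    support_of,
)
from histonecode.mining import UNMODIFIED
from histonecode.reference import HistoneReference
from histonecode.simulate import (
    ASPN,
    CHYMO,
    GLUC,
    PlantedRule,
    RuleKind,
    SimulationConfig,
    insilico_digest,
)


def frag_sequences(ref, enzyme, mc=0):
    return [ref.sequence[s - 1 : e] for s, e in insilico_digest(ref, enzyme, mc)]


class TestInsilicoDigest:
    def test_gluc_cuts_cterminal_of_d_and_e(self):
        ref = HistoneReference("toy", "AEKDG")
        assert frag_sequences(ref, GLUC) == ["AE", "KD", "G"]

    def test_aspn_cuts_nterminal_of_d(self):
        ref = HistoneReference("toy", "AKDGD")
        assert frag_sequences(ref, ASPN) == ["AK", "DG", "D"]

    def test_chymotrypsin_cuts_after_aromatics(self):
        ref = HistoneReference("toy", "AGYLKF")
        assert frag_sequences(ref, CHYMO) == ["AGY", "LKF"]

    def test_zero_missed_cleavage_fragments_tile_the_protein(self, refs):
        for ref in refs.values():
            for enzyme in (GLUC, ASPN, CHYMO):
                assert "".join(frag_sequences(ref, enzyme)) == ref.sequence

    def test_missed_cleavages_concatenate_adjacent_fragments(self):
        ref = HistoneReference("toy", "AEKDG")
        assert set(frag_sequences(ref, GLUC, 1)) == {
            "AE", "KD", "G", "AEKD", "KDG",
        }

    def test_gluc_mean_length_on_histones_in_middle_down_range(self, refs):
        # among MS-detectable peptides (>= 6 aa, up to 2 missed cleavages)
        # GluC digestion of the core histones yields middle-down-sized
        # peptides averaging in the mid-20s
        lengths = [
            e - s + 1
            for ref in refs.values()
            for s, e in insilico_digest(ref, GLUC, 2)
            if e - s + 1 >= 6
        ]
        assert 20 <= np.mean(lengths) <= 30


class TestGeneratePopulation:
    def test_same_seed_same_population(self, h4):
        cfg = h4_zip_config(h4, n_instances=200, seed=5)
        assert generate_population(cfg) == generate_population(cfg)

    def test_different_seed_differs(self, h4):
        a = generate_population(h4_zip_config(h4, n_instances=200, seed=5))
        b = generate_population(h4_zip_config(h4, n_instances=200, seed=6))
        assert a != b

    def test_deterministic_zip_forces_full_chain(self, h4):
        cfg = h4_zip_config(h4, n_instances=100, conditional=1.0, leak=0.0, seed=1)
        pop = generate_population(cfg)
        for p in pop:
            mods = {(a.position, a.ptm) for a in p.annotations}
            if (5, PtmType.AC) in mods:
                for pos in (8, 12, 16):
                    if p.covers(pos):
                        assert (pos, PtmType.AC) in mods

    def test_excludes_never_co_occur(self, h2a):
        cfg = h2a_triad_config(h2a, n_instances=2000, seed=2)
        pop = generate_population(cfg)
        for p in pop:
            mods = {(a.position, a.ptm) for a in p.annotations}
            assert not ({(0, PtmType.NTERM_AC), (3, PtmType.ME3)} <= mods)
            # K5ac only on N-terminally acetylated molecules
            if (5, PtmType.AC) in mods and p.start == 1:
                assert (0, PtmType.NTERM_AC) in mods

    def test_contradictory_rules_rejected(self, h4):
        excl = PlantedRule(
            RuleKind.EXCLUDES, ((0, PtmType.NTERM_AC), (3, PtmType.ME3)), (0.5, 0.5)
        )
        impl = PlantedRule(
            RuleKind.IMPLIES, ((0, PtmType.NTERM_AC), (3, PtmType.ME3)), (0.5, 1.0, 0.0)
        )
        with pytest.raises(ValueError):
            SimulationConfig(reference=h4, n_instances=10, rules=(excl, impl))

    def test_site_redefinition_rejected(self, h4):
        r1 = PlantedRule(
            RuleKind.IMPLIES, ((0, PtmType.NTERM_AC), (16, PtmType.AC)), (0.5, 1.0, 0.0)
        )
        r2 = PlantedRule(
            RuleKind.IMPLIES, ((5, PtmType.AC), (16, PtmType.AC)), (0.5, 1.0, 0.0)
        )
        with pytest.raises(ValueError):
            SimulationConfig(reference=h4, n_instances=10, rules=(r1, r2))

    def test_chemically_invalid_planted_site_rejected(self, h4):
        rule = PlantedRule(
            RuleKind.IMPLIES, ((2, PtmType.AC), (16, PtmType.AC)), (0.5, 1.0, 0.0)
        )  # G2 cannot be acetylated
        with pytest.raises(ValueError):
            SimulationConfig(reference=h4, n_instances=10, rules=(rule,))

    def test_ambiguity_rate_flags_annotations(self, h4):
        cfg = h4_zip_config(h4, n_instances=1000, ambiguity_rate=0.3, seed=4)
        pop = generate_population(cfg)
        anns = [a for p in pop for a in p.annotations]
        frac = sum(a.ambiguous for a in anns) / len(anns)
        assert 0.25 < frac < 0.35


class TestExpectedRuleTable:
    def test_forced_implication_has_confidence_one(self, h4):
        rule = PlantedRule(
            RuleKind.IMPLIES, ((5, PtmType.AC), (16, PtmType.AC)), (0.4, 1.0, 0.0)
        )
        cfg = SimulationConfig(reference=h4, n_instances=10, rules=(rule,))
        table = expected_rule_table(cfg)
        fwd = next(
            r for r in table if r.antecedent == Item(5, "ac") and r.consequent == Item(16, "ac")
        )
        assert fwd.confidence == 1.0

    def test_excludes_pair_has_zero_joint_support(self, h2a):
        cfg = h2a_triad_config(h2a, n_instances=10)
        table = expected_rule_table(cfg)
        joint = next(
            r
            for r in table
            if r.antecedent == Item(0, "ntac") and r.consequent == Item(3, "me3")
        )
        assert joint.joint_support == 0.0 and joint.confidence == 0.0
        absence = next(
            r
            for r in table
            if r.antecedent == Item(3, "me3")
            and r.consequent == Item(0, UNMODIFIED)
        )
        assert absence.confidence == 1.0

    def test_hierarchy_expectations_match_monte_carlo(self, h4):
        cfg = h4_zip_config(
            h4, n_instances=100_000, conditional=0.9, leak=0.1, seed=17
        )
        pop = generate_population(cfg)
        covering = [p for p in pop if p.start <= 1 and p.end >= 24]
        n = len(covering)

        def marginal(item):
            return (
                sum(
                    1
                    for p in covering
                    if any(
                        a.position == item.position
                        and a.ptm.value == item.state
                        and not a.ambiguous
                        for a in p.annotations
                    )
                )
                / n
            )

        for er in expected_rule_table(cfg):
            m_ant = marginal(er.antecedent)
            joint = (
                sum(
                    1
                    for p in covering
                    if all(
                        any(
                            a.position == it.position
                            and a.ptm.value == it.state
                            and not a.ambiguous
                            for a in p.annotations
                        )
                        for it in (er.antecedent, er.consequent)
                    )
                )
                / n
            )
            mc_conf = joint / m_ant
            se = math.sqrt(er.confidence * (1 - er.confidence) / (m_ant * n))
            assert abs(mc_conf - er.confidence) <= 4 * se + 1e-12
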