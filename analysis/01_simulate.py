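"""Generate the synthetic peptide populations used by the downstream steps.

Two populations over the bundled references:

* H4: zip-model acetylation K16 -> K12 -> K8 -> K5 plus mutual exclusion of
  N-terminal acetylation and R3me3, GluC digestion with one missed cleavage;
* H2A: the N-terminal triad (abundant N-terminal acetylation, R3me3
  mutually exclusive with it, K5ac only on N-terminally acetylated
  molecules).

Writes pipeline-ready TSVs under results/.
"""

import sys
from pathlib import Path

from histonecode import (
    PtmType,
    bundled_references,
    generate_population,
    h2a_triad_config,
    h4_zip_config,
    write_peptide_tsv,
)
from histonecode.simulate import PlantedRule, RuleKind, SimulationConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    refs = bundled_references()

    zip_cfg = h4_zip_config(refs["H4"], n_instances=5000, conditional=1.0, leak=0.0, seed=SEED)
    exclusion = PlantedRule(
        RuleKind.EXCLUDES, ((0, PtmType.NTERM_AC), (3, PtmType.ME3)), (0.55, 0.6)
    )
    h4_cfg = SimulationConfig(
        reference=refs["H4"],
        n_instances=5000,
        rules=zip_cfg.rules + (exclusion,),
        enzyme=zip_cfg.enzyme,
        missed_cleavages=1,
        seed=SEED,
    )
    h4_pop = generate_population(h4_cfg)
    write_peptide_tsv(RESULTS / "h4_population.tsv", h4_pop)
    print(f"H4 population: {len(h4_pop)} instances -> results/h4_population.tsv")

    h2a_cfg = h2a_triad_config(refs["H2A"], n_instances=5000, seed=SEED + 1)
    h2a_pop = generate_population(h2a_cfg)
    write_peptide_tsv(RESULTS / "h2a_population.tsv", h2a_pop)
    print(f"H2A population: {len(h2a_pop)} instances -> results/h2a_population.tsv")


if __name__ == "__main__":
    main()
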