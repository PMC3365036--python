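"""Per-residue occupancy tables and combinatorial code maps.

Reads the simulated populations, computes detected/observed ratios per
(residue, PTM) and the distinct modification patterns on the H4 and H2A
N-terminal tails, and prints the headline percentages.
"""

from pathlib import Path

from histonecode import (
    PtmType,
    build_code_map,
    bundled_references,
    compute_occupancy,
    read_peptide_tsv,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    refs = bundled_references()
    for histone, region in (("H4", (1, 24)), ("H2A", (1, 41))):
        peptides = read_peptide_tsv(
            RESULTS / f"{histone.lower()}_population.tsv", refs
        )
        modified = [p for p in peptides if p.annotations]
        table = compute_occupancy(modified, refs[histone])
        table.to_tsv(RESULTS / f"occupancy_{histone}.tsv")
        cm = build_code_map(modified, refs[histone], region, distinct=True)
        cm.to_frame().to_csv(
            RESULTS / f"codemap_{histone}_{region[0]}-{region[1]}.tsv",
            sep="\t",
            index=False,
        )
        print(
            f"{histone}: {len(modified)} modified instances, "
            f"{len(cm.rows)} distinct patterns on {region[0]}-{region[1]}"
        )
        for pos, ptm in sorted(
            {(a.position, a.ptm) for p in modified for a in p.annotations}
        ):
            pct = table.percent(pos, ptm)
            label = "N-term" if pos == 0 else f"{refs[histone].residue(pos)}{pos}"
            print(f"  {label} {ptm.name}: {pct}% of modified peptides covering it")


if __name__ == "__main__":
    main()
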