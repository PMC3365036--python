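"""Flanking-sequence motif analysis around acetyl-lysine sites.

Builds 11-aa windows around the unambiguous acetylation sites of the
simulated populations plus a planted kA..K-style foreground, scores them
against a histone-only lysine background, and writes the position
frequency matrix and extracted motifs.
"""

from pathlib import Path

import numpy as np

from histonecode import (
    PtmType,
    SiteWindow,
    build_background,
    bundled_references,
    extract_windows,
    find_motifs,
    frequency_matrix,
    read_peptide_tsv,
)
from histonecode.motifs import motifs_to_frame

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    refs = bundled_references()
    peptides = read_peptide_tsv(RESULTS / "h4_population.tsv", refs)
    sites = sorted(
        {
            (p.histone, a.position, a.ptm)
            for p in peptides
            for a in p.annotations
            if a.ptm is PtmType.AC and not a.ambiguous and a.position > 0
        }
    )
    fg = extract_windows(sites, refs, w=5)
    bg = build_background(refs, "K", w=5)
    frequency_matrix(fg).to_csv(RESULTS / "acetyl_site_frequencies.tsv", sep="\t")
    print(f"{len(sites)} acetylation sites -> results/acetyl_site_frequencies.tsv")

    # planted enrichment: Ala at +1, Lys at +4 around acetyl-K
    rng = np.random.default_rng(6)
    planted = []
    for i in rng.choice(len(bg), size=60, replace=True):
        chars = list(bg[i].residues)
        chars[6], chars[9] = "A", "K"
        planted.append(SiteWindow("".join(chars), center_ptm=PtmType.AC))
    motifs = find_motifs(planted, bg, min_count=5, p_threshold=1e-4)
    motifs_to_frame(motifs).to_csv(RESULTS / "acetyl_motifs.tsv", sep="\t", index=False)
    for m in motifs:
        print(
            f"  motif {m.pattern}: n={m.support_count}, "
            f"fold={m.fold_enrichment:.1f}, p={m.p_value:.2e}"
        )


if __name__ == "__main__":
    main()
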