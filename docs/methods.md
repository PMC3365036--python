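# Methods

## Problem and scope

Middle-down mass spectrometry of histones yields long peptides (>20 aa)
on which several post-translational modifications (PTMs) co-occur on the
same molecule. This package implements the downstream combinatorial
analysis of such data: parsing annotated peptide lists, per-residue
modification-site occupancy, frequent-itemset / association-rule mining
of co-occurring marks ("histone code" rules), and flanking-sequence
motif enrichment. Wet-lab and instrument-level steps (enrichment,
acquisition, database search, FDR control) are out of scope; the input
is a list of annotated peptide observations.

## Numbering conventions

Mature histones lack the initiator Met. The canonical convention here
numbers the first post-Met residue as 1 (so H4K16, H3K9 carry their
familiar names); UniProt-style Met-is-1 inputs are shifted by one on
ingest (`renumber`). Acetylation of the protein's free alpha-amino
terminus is a mark of its own, distinct from side-chain acetylation of
residue 1; it is held at pseudo-position 0 so it can enter occupancy
tables and itemsets like any residue.

## Peptide notation

Peptides are written as their bare sequence with in-line tags: `ac-`
prefix for N-terminal acetylation, `p` before S/T/Y for
phosphorylation, and suffix tags `ac`, `me1|me2|me3`, `pp`
(propionyl), `b` (butyryl), `cr` (crotonyl), `gg` (ubiquitination
remnant) after the modified residue. Parenthesised tags (`(p)S`,
`K(ac)`) mark ambiguous site assignment. The grammar is closed: `me`
without a digit and unknown tags are rejected, as are chemically
impossible placements (phospho on K, methyl on G, ...). A lowercase
run between residues is resolved by preferring a whole-run suffix tag
and otherwise splitting a trailing `p` off as the next residue's
phospho marker (`KpppS` → propionyl-K, phospho-S). Parsing and
serialisation are exact inverses, property-tested over randomly
generated peptides.

Each input row is a peptide *instance*; `instance_count` lets
collapsed (distinct-pattern) lists behave identically to instance-level
lists everywhere (occupancy and mining are invariant under splitting a
count-k row into k rows — both properties are tested).

## Occupancy

Occupancy of (residue, PTM) = detected instances / observed instances,
where a peptide "observes" every residue its span covers and the
N-terminus is observed only by peptides starting at residue 1.
Ambiguous annotations are excluded from numerators by default (they
count as unmodified, mirroring the mining rule). The denominator
convention follows the input: with unmodified peptides supplied,
occupancy is relative to all observations; from a modified-only list it
is "of modified peptides" (the table records which). Percentages round
half-up to integer percent. No uncertainty is attached to occupancy
ratios.

## Transactions and mining

An analysis is scoped to a region (e.g. H4 residues 1–24). Peptides
shorter than 21 aa, or not fully covering the region, are dropped —
long-range combinatorial claims need every column defined on every row.
The item vocabulary is the set of region positions carrying at least
one unambiguous PTM in the data (plus position 0 for N-terminal
regions); never-modified residues are omitted so their all-unmodified
items do not flood the frequent sets. Each peptide instance becomes a
transaction with exactly one item per vocabulary position: the
unambiguous PTM observed there, else an explicit UNMODIFIED state
(ambiguous annotations are deliberately demoted to unmodified).

Frequent itemsets are mined level-wise (Apriori): size-k candidates are
joined from size-(k-1) frequent sets and pruned by anti-monotonicity;
an itemset is frequent iff its weighted support is *strictly greater*
than `min_support` (default 0.20). Every frequent itemset of size ≥ 2
is split into all rules X → Y with confidence supp(X∪Y)/supp(X),
supports looked up from the itemset table (all subsets of a frequent
itemset are frequent, so the lookup is total). No confidence threshold
is applied by default; rules are reported sorted by confidence with
deterministic tie-breaks (itemset size, then position/state order).
Lift and other interest measures are intentionally absent. The
confidence matrix view (conditions × outcomes) reports underivable
cells as missing, never zero, and trivially sets antecedent-contains-
consequent cells to 1.

Correctness is checked against an independent brute-force oracle
(per-transaction subset enumeration) on hundreds of random weighted
transaction sets, and the confidence of every derived rule is
re-verified from raw support scans.

## Motif analysis

Windows of 2w+1 residues (default 11) are cut around modified sites,
padded with `-` at chain ends; pads are excluded from numerators and
denominators of the position-frequency matrix, whose columns each sum
to 1. Because histones are K/R-rich, enrichment is always scored
against a histone-only background: one window per occurrence of the
centre residue across the reference set.

Motif extraction is greedy, motif-x style: among all (offset, residue)
pairs, pick the smallest binomial tail probability P[X ≥ k] with
k = foreground count, n = foreground size, p = background frequency at
that offset; fix it, filter both sets to matching windows, repeat until
no pair passes `p_threshold` (default 1e-6) with at least `min_count`
(default 5) supporting windows; then remove the matched foreground
windows and restart for the next motif, so motif supports are disjoint.
Defaults are exposed as parameters since the analysis offers no single
canonical choice. Note the step-wise p-values need not decrease
monotonically: re-filtering conditions the background, which can make a
later fix less significant; the reported p-value is the final step's.
Patterns serialise with dot wildcards and a lowercase centre
(`.....kA..K.`).

## Synthetic populations

The generator stands in for the experiment's peptide lists. A
peptide instance is drawn from an in-silico digest of the reference
(enzyme specificities: GluC C-terminal of D/E, AspN N-terminal of D,
chymotrypsin C-terminal of Y/F/W, trypsin C-terminal of K/R, CNBr
C-terminal of M), with the missed-cleavage count uniform on 0..max (no
distribution is otherwise implied). PTMs are assigned by planted rules:

- HIERARCHY (zip model): outermost site at marginal `p_first`; each
  inner site with probability `conditional` when its predecessor is
  modified, `leak` otherwise — the C→N acetylation zip of the H4 tail.
- EXCLUDES: P(a) = `p_a`; b occurs only when a is absent — the
  N-terminal-acetylation / R3me3 exclusion.
- IMPLIES: consequent probability depends on the antecedent state.

A site defined by one rule may anchor a later rule (its state is
inherited), which expresses e.g. the H2A triad: N-terminal acetylation
at 0.88, R3me3 certain in its absence (marginal 0.12), K5ac at 0.205
given N-terminal acetylation (marginal ~0.18). Re-defining a site, or
putting EXCLUDES and IMPLIES on the same pair, is a config error.
Annotations are independently flagged ambiguous at `ambiguity_rate`.
All randomness flows through one seeded NumPy generator; identical
seeds give identical populations.

`expected_rule_table` gives closed-form supports and confidences of the
planted pairwise rules among region-covering peptides. With
q = 1 − ambiguity_rate, hierarchy marginals follow
m_i = m_{i−1}·conditional + (1 − m_{i−1})·leak, and the mined
(observed-state) confidences are q·conditional (outer→inner) and
q·m_{i−1}·conditional/m_i (inner→outer). Mined confidences on
populations of 5,000 instances are required to sit within three
binomial standard errors of these values, and the expectations are
themselves validated against a 100,000-instance Monte-Carlo run.

What the generator does not emulate: spectral noise, charge states,
retention behaviour, search-engine scoring, co-eluting isobaric forms,
inter-histone crosstalk, or abundance biases between peptide species —
so passing recovery tests show the *analysis* is correct under the
assumed sampling model, not that real spectra would be interpreted
correctly upstream.

## Problem sizes and numerical choices

Recovery studies use 5,000 instances (of which roughly 650 survive the
region/length filter on the H4 tail), miner-vs-oracle equivalence uses
200 random transaction sets of up to 64 weighted transactions over ≤ 12
items, and motif recovery uses 60 planted windows over the ~100-lysine
histone background; the full suite and the acceptance run each finish
in a few seconds. The mean detectable GluC peptide length (~24 aa) is
computed over fragments ≥ 6 aa with up to 2 missed cleavages, since
shorter fragments are not observable in this kind of experiment. Exact
rational arithmetic is avoided: supports are floats, and oracle
comparisons use relative tolerances ~1e-12; the strict `>` on
min_support is applied to the float ratio, matching the definition
"greater than 20%" rather than any rounding of it.

## Known limitations

- Cross-isoform site equivalence (e.g. linker-histone variants sharing
  a site) is not modelled; references are independent sequences.
- Single-residue digestion fragments cannot be re-placed by sequence
  alone; the TSV dialect carries an optional `start` column for them.
- The motif extractor is a faithful greedy binomial procedure, not a
  re-implementation of any particular web service's corrections; motif
  results on real data should be treated as candidate patterns.
- Occupancy from modified-only inputs over-estimates abundance relative
  to all molecules; supply unmodified peptide lists when available.
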