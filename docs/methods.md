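# Methods

## Problem and scope

`talscan` implements a desk-scale survey of tail-associated lysins (TALs)
in annotated phage and prophage genomes. Inputs are genomes that already
carry gene annotations (GenBank features with products and translations);
gene calling, prophage boundary prediction and live domain-database queries
are explicitly out of scope — the conclusions of such external analyses are
encoded as static, packaged metadata (motif patterns, residue rules, class
vocabularies). Prophage regions are treated exactly like phage genomes; no
boundary re-prediction is attempted.

## Module partitioning and the tail unit

Gene products are mapped to functional-module categories by
case-insensitive substring matching against a priority-ordered keyword
vocabulary (lysogeny > packaging > head > tail > lysis > DNA metabolism;
first match wins). The priority order resolves composite annotations
deterministically. The genome is then segmented greedily left-to-right:
consecutive genes of one category merge, and runs of hypothetical/other
genes flanked by the same category on both sides are absorbed — Dit
proteins in particular are frequently annotated only as small hypothetical
proteins, and absorption keeps them inside the tail segment.

The tail module is taken as the tail-category genes strictly between the
*last* head segment and the *first* subsequent lysis segment (mosaic
genomes can carry several of each). If no tail-category segment lies there
but unannotated genes do, those genes become the candidate tail module with
the conformity flag down. Within the module, the TMP is the gene with a
tape-measure keyword, falling back to the longest CDS above 800 aa (ties go
to the first in genomic order); Dit is the gene immediately after the TMP
(distal-tail keyword preferred, small hypothetical accepted) and Tal the
gene after Dit. Short-tailed podovirus-style genomes — no keyword, no long
gene — leave the TMP unset; lysin scanning still covers the whole module.
Tail length is estimated as 0.15 nm per TMP residue.

Temperate genomes are flagged from integrase/recombinase or repressor
annotations; "anti-repressor" alone deliberately does not count.

## Motif library and domain scanning

Domain detection uses packaged position-constrained patterns rather than
live Pfam/CDD scans. Each pattern is a per-column set of allowed residues
(the consensus residue widened one step to BLOSUM-positive neighbours); a
sliding window scores the fraction of matching columns, windows at or above
the motif's threshold become hits, and overlapping same-motif hits merge
keeping the best score. Scanning is O(n·m·L) for protein length n, m
motifs of pattern length L, vectorised with numpy.

The consensus backbones are *synthetic*: only the residues fixed by
published domain knowledge are meaningful — the GH23 lytic transglycosylase
motifs I–IV and the six family-1P extra columns, the GDPD catalytic
His/His + Glu/Glu/Asp, the NLPC/P60 Cys…His dyad. All other columns were
filled once with seeded random residues and frozen. An external domain-hit
TSV (gene_id, motif_name, start_aa, end_aa, score) can bypass the scanner
per gene, so profile-HMM results can be dropped in without code changes.

Score thresholds default to 0.8 (0.9 for the low-complexity hydrophobic
membrane pattern) and were calibrated against a seeded shuffle null so that
under 1% of length-matched uniform-composition decoys produce any hit;
`talscan.lysins.shuffle_null_fpr` recomputes this rate (1,000 decoys of
500 aa by default). Proteins shorter than 30 aa are not scanned.

Region constraints are fractional terciles of the protein (N-terminal,
central, C-terminal), not fixed residue counts, because TAL protein lengths
span roughly 240–2,254 aa. A hit records both its observed tercile and
whether that satisfies the motif's declared region; violations are
reported, never silently dropped.

## Classification

Class priority is a total order — TMP-LT (only for the TMP gene itself),
then TAEP, NLPC/P60, GDPD, pectinesterase — so every scanned protein
receives exactly one class; losing domain families are kept as secondary
classes, preserving co-occurrence reports (e.g. GDPD alongside a TAEP)
while the census counts each protein once. DA-group assignment considers
only the domain families that define the class's architectures, which keeps
a stray accessory hit from another family from corrupting the DA label.

GH23 family assignment aligns the LT hit region to the packaged class
consensus (global Gotoh alignment) and checks motifs I–IV in the alignment
frame; family 1P additionally requires the six extra columns, making 1P a
strict refinement of 1A. Family 1E is reserved for N-terminal LTs in
non-TMP proteins matching the packaged 1E signature at ≥0.7 aligned
identity. The 1P column labels (T46 etc.) refer to the packaged reference
alignment frame, not absolute protein coordinates — the published labels
are alignment-relative, and anchoring them to our own reference is an
assumption. Catalytic verification maps the class residue rules through
the same alignment; a failed alignment verifies as False with a logged
reason.

## Alignment, profiles, trees

Pairwise alignment is global Needleman–Wunsch with affine gaps (Gotoh),
BLOSUM62, gap open 11 charged on the first gapped column and extend 1
thereafter; tie breaks are fixed (diagonal > up > left) for determinism.
Multiple alignment is progressive over a UPGMA guide tree of pairwise
identity distances with profile–profile Gotoh at internal nodes; permuting
the input order can move gap columns but not the induced pairwise
identities beyond tie-break effects.

Consensus profiles use the 20-letter alphabet with a uniform background
(WebLogo-style): information content is log2(20) minus the gap-excluded
column entropy, so bits lie in [0, log2 20] with identical columns at the
ceiling. Gaps are tracked as a 21st symbol but excluded from the entropy
denominator; majority-gap columns (>50%) never count as conserved.
The conservation threshold defaults to 0.9 (top-residue frequency) —
the source analyses mark "highly conserved" positions without a number,
so the threshold is configurable.

Trees are classical neighbor joining (Q-matrix selection, Studier–Keppler
update, lowest-index tie break, negative branch estimates clamped to zero
with the clamped amount logged). Classical NJ replaces approximate-ML
tree building deliberately: the claim under test is a two-group leaf
bipartition, which NJ supports exactly and deterministically — on additive
matrices NJ reconstructs the generating tree to numerical precision, which
the tests verify against a four-point-condition quartet oracle. Two-group
separation holds iff some tree edge induces exactly the given bipartition.

## Landscape summaries

Census percentages are printed to one decimal with ties rounding to even,
which reproduces all five published class percentages (in particular
34/544 = 6.25% printing as 6.2). Size groups follow the published ranges
(<30.5 kb, 31–43, 55–86, ≥130) with the gaps between ranges left
unclassified rather than snapped to a neighbour, and a known morphology
hint overriding size (a 16.9 kb siphovirus belongs with siphovirus group 1,
not the podoviruses). Arrangement percentages are reported under both
denominators — all genomes with a located tail module, and only those with
at least one TAL — because the published percentages leave the denominator
ambiguous. Correlations are Spearman (the published scatters are monotone,
not claimed linear) with a seeded two-sided permutation p-value (10,000
permutations by default, computed on the rank scale).

## Synthetic cohort

The generator emulates the study conditions: morphotype mix 18% podo /
40% sipho group 1 / 24% sipho group 2 / 18% myo (the study set is 18%
podoviruses, 64% siphoviruses, 18% myoviruses; the group-1/group-2 split
within siphoviruses is not published and was fixed once at 40/24), genome
sizes uniform within each morphotype's published range (17.9–30.5,
21–43, 55–86, 130.9–156.5 kb), temperate fraction 16%, intergenic GC
0.35 (near the reported cohort average), TMP-LT lengths uniform on
1180–2254 aa, bare-GDPD proteins at 240 aa. Arrangements follow the
published per-morphotype patterns (sipho1: TMP-LT + Tal-TAEP; sipho2:
TAEP only; myo: TMP-LT + adjacent NLPC/P60; podo: NLPC/P60 tailspike-like
near the head, no TMP-Dit-Tal). TAEP DA groups are drawn with DA1 at
60.5% and the remainder spread evenly over DA2–DA5; GDPD and
pectinesterase extras are planted in siphovirus tails at per-TAEP odds
22/383 and 7/383, tying the planted class proportions to the published
census. Non-motif protein sequence is uniform-random; coding DNA is a
seeded reverse translation (table 11); annotation noise (hypothetical
renaming, product shuffling among genes, Dit dropping) touches only
annotations, never sequences, because misannotation is the failure mode
the partitioner must tolerate.

What the generator does **not** emulate: real residue composition and
phylogenetic correlation of sequences, mosaicism/recombination, codon
bias, overlapping genes, reverse-strand gene order, or partially degraded
prophages. Passing the recovery tests therefore demonstrates the
pipeline's logic (partitioning, role resolution, scanning, classification,
aggregation) under controlled conditions, not detection power on diverged
natural sequences — on real data, sensitivity is bounded by the motif
library or the external hit tables supplied.

## Problem sizes and numerical choices

Tests and the acceptance script run on deliberately small problems chosen
as adequate for the properties asserted: a 50-genome zero-noise cohort for
recovery scoring, 1,000 decoys for the scanner null, 100 random short
pairs for the alignment oracle, 30 random additive matrices (n ≤ 6) for
NJ, 20 seeded replicates for the null-correlation property. Percentages
use decimal rounding (ties to even); alignment and NJ comparisons use
1e-6/1e-9 absolute tolerances; degenerate inputs (empty census, constant
correlation variables, tail modules with <3 genes, missing head or lysis
modules) return flagged results rather than raising, except where the
contract requires an error (empty motif library, <2 profile sequences,
<3 NJ taxa).

## Known limitations

- The packaged motif backbones are synthetic stand-ins; real-data use
  should supply external domain-hit tables from a profile-HMM scan.
- Genomes with non-canonical module organisation get `conforms=false`
  layouts and best-effort scanning; no manual curation is attempted.
- NLPC/P60 subgroup boundaries below the two-group split are reported
  descriptively, not tested as claims.
- Circular-genome origin-spanning genes are represented unwrapped
  (end > genome length) and are not exercised by the generator.
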