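# Methods

This note records the models, conventions and numerical choices behind
`mitocomp`, in the order the pipeline runs.

## Data model and coordinates

Genomes are held as a sequence plus an ordered feature list over a fixed
canonical vocabulary (13 PCGs, 2 rRNAs, 22 tRNAs, `AT_rich` control
region). Coordinates are 0-based half-open internally; GenBank I/O
converts at the boundary, so gap/overlap arithmetic is plain subtraction.
Strands are J (majority, '+') and N (minority, '−'); a feature's sequence
is always reported in coding orientation. Origin-spanning features are two
intervals (tail, head) concatenated 5'→3'.

Leu/Ser tRNA paralogs follow the standard convention — trnL1 decodes CUN
(anticodon UAG), trnL2 decodes UUR (UAA), trnS1 decodes AGN (GCU/UCU),
trnS2 decodes UCN (UGA). Annotations lacking an anticodon are resolved by
their gene neighbourhood against the ancestral arrangement and flagged
`inferred`. Duplicate annotations keep the longest copy; unsequenced genes
are represented as absent, never imputed.

## Composition and skews

AT-skew = (A − T)/(A + T) and GC-skew = (G − C)/(G + C), computed on
percentages over the unambiguous (ACGT) total; ambiguity codes are
excluded from numerator and denominator, and a zero denominator yields an
explicit undefined flag rather than 0. PCG-region statistics concatenate
each gene's sense strand (a flag allows all-J-strand computation); this
convention reproduces the characteristic T- and C-rich PCG pattern of
insect mitogenomes. Report rounding is decimal half-up: 2 dp for contents,
3 dp for skews, matching the precision of published tables.

## Codon usage

The genetic code is fixed to translation table 5 (ATA=Met, AGA/AGG=Ser,
TGA=Trp; stops TAA/TAG); no per-genome override in v1. Codons are read in
frame 0; terminal complete stops go to a separate tally and a trailing
1–2 nt remainder is dropped as an incomplete stop. RSCU is k·n_c/Σn over
each synonymous family; zero-usage families are undefined rather than 0,
and the missing-codon report covers sense codons only. Incomplete stop
calls (T/TA) additionally require the downstream feature, in gene
orientation, to abut or overlap the CDS tail — the geometry under which
polyadenylation completes the stop.

## NG86 Ka/Ks

The counting method is Nei–Gojobori (1986) with equal pathway weighting
and Jukes–Cantor correction; the synonymous-site fraction of a codon
counts changes to stops as nonsynonymous alternatives. Multi-difference
codons average syn/nonsyn steps over all substitution orderings, excluding
orderings that pass through a stop; if every ordering is blocked the
differences are split in proportion to the codon pair's site counts (a
documented fallback, exercised only by unusual codon pairs). Codons with
gaps, ambiguity, or an in-sequence stop in either sequence are excluded
pairwise. Ks = −(3/4)·ln(1 − (4/3)·pS) and likewise Ka; the ratio is
undefined — flagged, never printed as 0 — when Ks = 0 or a log argument is
non-positive (saturation). Overlapping PCG nucleotides (the atp8/atp6
7 bp) are counted in both genes, matching per-gene extraction. Per-gene
and concatenated results are both emitted, since published rate summaries
do not always state which was used.

## Gene order

Arrangements are circular signed permutations. Comparison against the
ancestral insect arrangement first projects the ancestor onto the observed
gene set, so partially sequenced genomes never report missing genes as
rearranged. In-place genes are a maximum-length common circular signed
subsequence (computed exactly by anchoring each shared gene and running an
LIS-based LCS, O(n² log n)); leftover genes are classified translocated
(same sign), inverted in place (sign flip, position conserved in the
unsigned common subsequence) or remote-inverted (moved + flipped). The
narrative is a heuristic "at least N events" statement, not a provably
minimal scenario: single events and disjoint event pairs are recovered
exactly whenever they are identifiable — a move of ≥3 circular positions.
Moves of 1–2 positions admit multiple equally parsimonious explanations
(an adjacent swap can be attributed to either gene), so tests and the
acceptance script enumerate the identifiable cases.

Breakpoints are signed circular adjacencies of the observed order absent
from the projected ancestor, with (x→y) identified with (−y→−x); under
this convention a full mirror reversal has distance 0. The control region
participates in ordering but is excluded from breakpoint counting (its
boundaries are unreliable in partial genomes).

## tRNA structures and junctions

Dot-bracket input is parsed by nesting: the stem holding the outermost
pair closes the cloverleaf (AA stem) and the hairpins in 5'→3' order are
DHU, AC, TΨC; two hairpins mean a degenerate D-arm (loop in place of the
stem), as in many metazoan mitochondrial tRNAs. The built-in folder is a
deterministic constrained search, not a thermodynamic model: the anticodon
is centred in a 7-nt loop, stems are chosen within configured ranges
(AA 6–8, AC 4–6, DHU 0–4, TΨC 3–5 pairs) to maximise a simple score
(+2 canonical pair, +1 G-U, −1 mismatch), ties resolved toward the
5'-most anchor and the longest stems. Mismatches are stem pairs outside
{A-U, U-A, G-C, C-G, G-U, U-G}; the wobble is canonical by default
(published mismatch tables list U-U/A-C/A-A only) and the set is
configurable. T pairs as U; loop positions are never counted.

The junction census walks consecutive features in genomic order (wrapping
for circular genomes): signed length = next start − current end, positive
gap / zero abutting / negative overlap. Nested features are excluded from
the walk. The control region is a feature — its flanks are junctions — but
its own span never counts as intergenic sequence. Conservation law on
complete circular genomes: Σ gene lengths + Σ gaps − Σ overlaps = genome
length, held exactly. Published spacer counts for the same genome can
differ by counting rule (e.g. whether the incomplete control region or the
pre-trnY spacer is itself a "spacer"); we count gaps ≥ 1 bp as locations
and do not tune to any particular published total.

## Supermatrices and saturation

Codon alignments are split by position (columns 0,3,6,… → pos1, …);
variants: P123 (all PCG positions), P123R (+ rRNA and tRNA partitions),
P12T (P123R minus a named exclusion list — in the motivating study the
partitions carrying all third positions and both rRNAs), AA (translated
PCGs). Missing taxa are gap-filled; charsets tile [0, n_sites) and
n_sites(P123) = 3·n_sites(AA) structurally. Published absolute site counts
depend on the original alignment runs and are not reproduced; only the 3×
identity is asserted. Alignment itself (MAFFT) and partition-scheme search
(PartitionFinder) are external; the scheme is consumed as configuration.

Saturation screening fixes a documented heuristic (scatter-plot inspection
is not machine-checkable): per taxon pair, p-distance with pairwise
deletion, transition/transversion proportions, and the K80 distance
d = ½·ln 1/(1−2P−Q) + ¼·ln 1/(1−2Q). The least-squares slope of p on d
across pairs is ≈1 when substitutions are rare and falls as multiple hits
accumulate; a partition is flagged when slope < 0.6 (exposed threshold) or
>10% of pairs have undefined corrected distances.

## Synthetic data

The generator emits the study conditions: gene order defaulting to the
ancestral arrangement (events injectable), PCG lengths totalling ~11.2 kb,
sense-strand PCG composition target (A,C,G,T) = (35.2, 10.4, 10.3, 44.1)%
— the published PCG percentages of the newly sequenced cimbicid — rRNA and
control targets at ~84–85% A+T, an incomplete stop (T) planted on nad5,
ten spacers (1–20 bp, with the ATTATAA motif on the N strand of the
nad4/nad4l gap) and four overlaps (1–7 bp including atp8/atp6 ATGATAA,
which is constructed so the shared 7 bp are simultaneously atp6's
ATG start and atp8's TGA-TAA tail), and 20 tRNAs with planted cloverleafs:
two D-arm-less (trnV, trnS1) and five planted mismatches per genome,
mirroring published mismatch tables.

CDS bases are drawn i.i.d. from the target; in-frame stops are repaired by
swapping their first two bases (TAA→ATA, TAG→ATG), which preserves
composition exactly, so realised composition of ≥1 kb regions stays within
±1.5 percentage points of target by binomial sampling alone. tRNA loops
and spacers inside a tRNA draw from {A,C}, which cannot pair internally;
each candidate is refolded and redrawn until the planted structure is
recovered exactly, making structural ground truth verifiable by
construction. Overlaps keep the upstream gene's bases and are only
permitted where the downstream feature is content-free (rRNA/control),
apart from the explicit atp8/atp6 construction — so planted PCG/tRNA
truths stay exact. One integer seed drives everything; per-gene substreams
come from fixed gene indices, so output is independent of generation
order.

Codon pairs evolve by per-site Poisson(t) proposals with transition bias
κ/(κ+2); stop-creating proposals are rejected (a small, documented
composition bias at desk scale) and nonsynonymous proposals are accepted
with probability min(1, ω). The K80 alignment simulator places tips of a
star tree at depths spanning [0.6, 1.4]·t/2, giving the saturation
regression leverage across pairs.

What the generator does not emulate: indels (so no real alignment step is
exercised), among-site rate variation, strand-asymmetric mutation
pressure, duplicated or fragmented control regions, and sequencing error.
Passing tests therefore demonstrate correctness of the statistics and
censuses on clean annotations, not robustness to annotation noise.

## Problem sizes and tolerances

Acceptance-level runs use: 2000-codon pairs × 50 seeds per ω for rate
recovery (mean Ka/Ks within ±0.05 of an independent recount, monotone in
ω); exhaustive 64×64 single-codon and 300 seeded two-codon NG86 oracle
sweeps (counts to 1e-12, hand-worked JC values to 1e-9); ~2,500
identifiable single rearrangement events plus 100 disjoint pairs and 100
random 10-gene breakpoint instances; 8-taxon, 2000-site K80 alignments ×
20 seeds for saturation (slope ∈ [0.9, 1.0] at t = 0.05; lower and flagged
at t = 2.0). Skew recomputation from published percentages is exact at the
printed 3 dp for all 14 species. Reproducing deposited-record region
lengths requires the GenBank records themselves, which are not bundled;
the corresponding check runs only when they are supplied locally.
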