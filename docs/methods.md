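# Methods

This note documents the models and procedures implemented in `drrbs`, the
parameter choices that matter, and what the simulation-based tests do and
do not demonstrate.

## Restriction digestion model

An enzyme is a recognition motif over the 15-letter IUPAC alphabet plus a
cut offset (caret notation, `C^CGG`).  The overhang length — the number of
bases filled in during end repair and masked downstream — is derived as
`len(site) − 2·offset`, which models 5′-overhang and blunt cutters.  The
geometry is footprint-symmetric: a site found on the bottom strand yields
the same top-strand cut position arithmetic as a top-strand site, so both
orientations of a non-palindromic motif are scanned and merged.  Scanning
uses overlapping regex lookahead; `N` in the genome never matches any motif
code, including `N` in the motif — an intentionally conservative choice so
assembly gaps never create fragments.

Digestion is complete and combined: cut sets of all enzymes are merged, and
fragments are the partition of each contig between adjacent cuts.  This
matches a sequential double digestion run to completion, where order is
irrelevant.  Partial digestion, star activity and methylation-sensitive
cutting are out of scope.  Four enzymes of the shipped panel (HpyCH4III,
BanII, SphI, KpnI) are 3′-overhang cutters whose chemistry the model cannot
express; they are approximated by mid-site cuts (boundary error ≤ 2 bp, no
fill-in), since 3′ extensions are removed rather than filled during end
repair.  Users can override the derived overhang with a third table column
for non-palindromic sites.

End repair extends each fragment's right end by the right enzyme's
overhang (`filled_end = end + overhang`, clamped).  Both daughter fragments
of an internal cut therefore carry a copy of the overhang bases; this is
deliberate — each physical fragment really does gain those bases — and it
means filled fragments of one contig overlap by `overhang` bases at cuts.

Size selection is inclusive on both ends and operates on fragment
(insert) length by default; adapters are never modelled.  Gel windows
quoted for adapter-ligated material map to insert windows by subtracting
the adapter contribution (~120 bp).

## Genomic elements

CpG islands follow the composition definition: length strictly > 200 bp,
GC fraction strictly > 0.5 and observed/expected CpG ratio strictly > 0.6,
with `O/E = (#CG · length)/(#C · #G)`.  Detection slides a 200 bp window at
step 1, merges overlapping qualifying windows, and re-validates every
merged region on its final extent; a merged region that fails is trimmed
greedily one base at a time from whichever end best improves the weaker
criterion, and discarded if it shrinks to ≤ 200 bp.  The choice of a
200 bp window with merge-then-revalidate is the classic sliding-window
formulation consistent with the stated thresholds; no single "correct"
algorithm exists, so re-validation of the final extent is the contract the
tests enforce.

Promoters span 2200 bp upstream to 500 bp downstream of the TSS (strand
reflected for minus-strand genes, clamped at contig ends).  Shores are the
2 kb flanks of each island with any island overlap subtracted and abutting
pieces merged, so shores never overlap islands and contribute ≤ 4 kb per
island.  Element assignment is multi-label — a CpG inside both a promoter
and an island counts toward both classes — so per-class coverage
percentages deliberately do not sum to 100%.

## Coverage prediction

For a selected fragment of filled length F and read length L, the covered
footprint is `[0, min(L, F))` for single-end and the union with
`[max(0, F−L), F)` for paired-end layouts.  A CpG counts as interrogated
when either base of the dinucleotide lies in an unmasked footprint; the
predicted depth of a CpG counts fragments (× a read multiplicity, default
1 — design mode predicts relative, not absolute, depth).  With fill-in
masking on, the right-end overhang bases of each fragment are excluded
from its footprints.  "Reads per informative CpG" divides aligned read
*pairs* by CpGs at or above a depth threshold; pairs-vs-mates is a
convention choice, documented here and configurable by the caller.
Per-element reports bin the summed per-CpG depth ("individual CpG
measurements") with default edges 0 / 1–5 / 6–15 / 16–25 / >25; the top
bin is fixed, the inner edges are configurable.

Coverage of a double digest is *not* a strict superset of the single
digest: extra cuts can split an in-window fragment into pieces below the
window minimum, losing the CpGs of the sub-minimum piece.  On the default
synthetic genome this affects ~9% of the single-digest CpG set while the
double digest covers ~1.5–2× more CpGs overall and strictly more in every
element class.  Read-length widening (PE50 → PE90) and window widening
(40–220 → 40–300) on a fixed fragment set are genuine supersets, and
masking only ever removes coverage.

## Synthetic data generator

The generator defines the study conditions under which the analysis chain
is validated.

* **Genome** — a single 500 kb contig (default) of iid bases at a target
  background GC of 0.40, with CpG dinucleotides retained at rate 0.25
  (background O/E ≈ 0.25; the initial GC is analytically inflated so the
  realized GC lands within ±0.02 of the request).  Forty 600 bp island
  segments (GC 0.65, CpG retention 0.90) are embedded at jittered,
  non-overlapping positions; these compositions make MspI sites dense
  inside islands (~1 per 100 bp) and sparse outside (~1 per 2.5 kb), while
  ApeKI (no CpG in its site) cuts the background about every kilobase —
  the exact density contrast that motivates the double-enzyme design.
  Gene models (three 200 bp exons, 800 bp introns) place half their TSSs at
  island centres, mirroring real promoter–CGI association, so promoter,
  intron and downstream element classes are populated.
* **Methylome** — per-CpG methylation probabilities drawn per class:
  Beta(2, 18) (mean 0.1) inside islands, Beta(8, 2) (mean 0.8) elsewhere;
  the bimodality matches mammalian methylomes.  The lambda-like spike
  contig (48.5 kb, GC 0.5, no CpG depletion, labelled `lambda_spike`) is
  exactly unmethylated.  It is a generated surrogate, not the phage
  sequence.
* **Reads** — per selected fragment, Poisson(depth, default 20) molecules,
  each from the top or bottom original strand with equal probability
  (directional protocol).  Per molecule, each cytosine on its strand is
  methylated by an independent Bernoulli draw of the CpG's truth
  probability (non-CpG cytosines are unmethylated); unmethylated cytosines
  convert C→T with probability equal to the conversion rate (default
  0.995), methylated cytosines never convert.  The end-repair artifact is
  simulated on the strand that physically receives filled bases: the
  right-end top-strand extension for top molecules and the left-end
  bottom-strand extension for bottom molecules, always unmethylated
  regardless of truth.  Uniform sequencing error (default 0.001) is applied
  last; qualities are constant Q35 with a configurable low-quality
  fraction to exercise the QC filter.  The spike contig is digested with
  the same enzymes and window — the spike is added before digestion in the
  protocol being modelled — and down-sampled so spiked pairs are ~5% of
  output; this is what lets spiked reads pass the enzyme-end filter.
* Everything derives from one integer seed through fixed-offset seed
  sequences; identical configs reproduce byte-identical outputs.

Not emulated: PCR duplicates and amplification bias, indels, adapter
read-through, base-caller error profiles, non-uniform gel recovery, CHH/CHG
methylation.  Tests passing on this generator therefore demonstrate the
correctness of the analysis logic under idealized error models, not
robustness to every artifact of real libraries.

## Methylation calling

QC drops a pair when either mate has strictly more than 30% `N`s or
strictly more than 10% of bases under Q20 (Phred+33 by default).

The built-in mapper implements three-letter alignment: two reference forms
(all C→T and all G→A) are indexed by exact 20-mers; a pair is tested under
the top-strand hypothesis (C→T-transformed forward read and reverse-
complemented reverse read against the C→T form) and the bottom-strand
hypothesis (G→A transforms against the G→A form).  Placements are
full-length and ungapped, verified at ≤ 2 mismatches per mate (default),
and a pair is reported only when exactly one best-scoring consistent
placement exists — ties are discarded, making output independent of input
order.  Three staggered seeds per read guarantee (by pigeonhole) that ≤ 2
mismatches cannot hide all seeds for reads ≥ 60 bp, and make misses
vanishingly rare at 50 bp.  The mapper targets simulated and small real
genomes; for scale, alignments from an external bisulfite aligner can be
imported from SAM/BAM (`load_sam_pairs`), using the `XG` tag or read-1
orientation for strand of origin.

A pair is retained when its genome-left coordinate equals a cut site or
its genome-right coordinate equals a cut site plus that enzyme's overhang
(tolerance 0 bp) — "a digestion site at the ends".  For retained pairs the
reverse read's 5′-end bases covering the fill-in region are masked (2 for
an MspI boundary, 3 for ApeKI) and excluded from all counting.  Masking
removes the end-repair bias at fragment-boundary CpGs almost entirely; a
small residue (|mean bias| < 0.02 under default conditions) remains because
the *forward* read of a fragment whose filled length is at most the read
length also reads through the right-end fill, and the masking rule —
deliberately restricted to the reverse read's 5′ end — cannot see it.

Calls pool both strands of a CpG: top-strand reads vote at the C
(C = methylated, T = unmethylated), bottom-strand reads at the G
(G = methylated, A = unmethylated), and `level = M/(M+U)`.  The pooled
dinucleotide record is the default because CpG methylation is mostly
symmetric; the per-cytosine counting convention `M/(M+U)` is declared, not
derived.  Non-CpG contexts are not called.  The conversion rate is
`T/(C+T)` over all cytosine positions of the spike contig, both strands,
all contexts, after filtering and masking; with no spike coverage the
estimate is undefined (NaN) rather than silently wrong.

## Differential statistics

Region counts sum methylated/unmethylated votes over the CpGs inside a
region.  The DMR test is a Pearson chi-square (df = 1) on
`[[M_A, U_A], [M_B, U_B]]` without continuity correction (a Yates flag
exists); degenerate tables (a zero marginal) return statistic 0, p 1.  A
region is a DMR only when p < 0.01 **and** |level_A − level_B| > 0.20, both
strict; the difference rule is interpreted on the level scale (percentage
points).  The chi-square null is slightly conservative for discrete
counts, so null simulations sit at ≈ 0.8–1.2% rejections at p < 0.01, and
the Δ rule drives null DMR calls to essentially zero.  Raw p-values are
thresholded by default (an optional BH correction over regions is
available to callers via the DGE machinery).

The Audic–Claverie probability `p(y|x)` is the negative binomial
NB(x+1, N1/(N1+N2)) in y, computed in log space via `gammaln` so large
counts cannot overflow.  The two-sided p doubles the smaller of the two
point-inclusive tails evaluated once in each orientation,
`p = min(1, 2·min(P(K ≥ y | x; N1,N2), P(K ≥ x | y; N2,N1)))`.  The two
tails sum to `1 + p(y|x)`, so the test is exactly symmetric under swapping
the samples and caps at 1 for equal evidence; a naive doubled single-
orientation tail is not symmetric, which is why this form was chosen.
Genes are differentially expressed at Benjamini–Hochberg FDR < 0.01 with a
TPM fold change ≥ 2, where fold change uses a pseudocount of one read per
library to stabilise zeros (`TPM = count/library·10⁶`).

## Numerical and procedural choices

* Coordinates are 0-based half-open everywhere internally; BED is native,
  GTF converted on read.
* CGI re-validation trims deterministically (ties trim the left end);
  island detection on contigs shorter than the window is skipped with a
  log notice.
* When two enzymes cut the same coordinate, the alphabetically first name
  labels the boundary (deterministic, affects labels only).
* Pearson correlation over shared CpGs requires depth ≥ 5 in *both*
  samples (the concordance convention for single-CpG comparisons).
* Reported problem sizes: the default validation simulations use a 500 kb
  genome at 20× target depth (parameter recovery, masking), 60 kb at 8×
  (pipeline determinism), and 2,500 regions at depth 400 (null
  calibration) — sizes at which every sampling check has comfortable
  Monte-Carlo margins.

## Known limitations

* The built-in mapper is exact-seeded and ungapped; indel-containing reads
  are unmappable by construction (import external alignments for real
  libraries).
* 3′-overhang enzymes are positionally approximated (≤ 2 bp) and carry no
  fill-in mask.
* The simulator's error model is uniform and context-free; M-bias beyond
  the fill-in artifact, duplicates and adapter contamination are absent,
  so QC/masking performance on real data will differ in degree.
* Double-digest coverage is not a superset of single-digest coverage (see
  above); design comparisons should use the per-class counts the report
  produces, not set inclusion.
* The DMR chi-square treats reads as independent Bernoulli trials;
  overdispersion from clonal reads in real libraries would inflate the
  statistic.
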