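# Methods

`esimir` re-implements, as a tested library, the computational arm of a
two-library (female vs male) insect small-RNA sequencing study: read cleanup
and accounting, known / known-candidate / novel miRNA identification, star
strand and isomiR classification, hairpin-based novel prediction, exact
two-library count statistics with Bonferroni correction, and 2^-ddCt qPCR
validation. Because raw libraries of such studies are often not deposited,
every stage is exercised against a synthetic-data generator whose reads carry
a complete ground-truth table.

## Synthetic libraries

The generator emulates the statistical structure of a real small-RNA
experiment rather than its base-level error process (no base-call errors,
quality simulation, or paired ends):

* **References.** Mature miRNAs are 21–23 nt with the first 5' base drawn as
  U/A with probability 0.815, the strong first-base preference reported for
  mature miRNA catalogs. Each precursor is `leader(3) + mature + loop(9–13) +
  star + trailer(3)`, where the star arm is the reverse complement of the
  mature with 1–2 interior substitutions; every precursor is folded at
  generation time and must reach ΔG ≤ −15 kcal/mol under the default engine
  (planted loci are discoverable by construction). Known precursors are
  planted at recorded coordinates (either strand) in a uniform-random proxy
  genome; the "KC" (known-candidate) subset has precursors in the reference
  set but *not* in the genome; novel loci are planted hairpins whose matures
  are absent from the mature reference set. Planting fails with a capacity
  error when loci cannot be placed without overlap.
* **Reads.** Each library draws `depth` reads over four classes —
  contaminant (exact substrings of ncRNA references, default fraction 0.15),
  novel-locus matures (0.02), junk (0.45; a mix of random 10–30-nt inserts,
  homopolymers and N-containing reads that emulates both filter-failing
  material and the unannotated small RNAs that dominate real libraries), and
  miRNA reads. miRNA identities follow a sorted log-normal abundance law
  (μ=0, σ=1.5), giving the heavy-tailed few-miRNAs-dominate profile seen in
  real top-20 tables. Star strands are emitted at probability
  `star_ratio/(1+star_ratio)` so the expected star/mature count ratio equals
  `star_ratio` (default 0.05). IsomiR variation is applied independently per
  mature read: 5'-end shift/extension (0.05), substitution at positions 9–15
  (0.05), and 3'-end addition/trimming (0.15, the most frequent class in
  real data). Inserts get the 3' adapter appended (default: the standard
  Illumina TruSeq small-RNA adapter; the study kit's adapter is unknown, so
  it is a free parameter) and constant Phred-40 qualities, which the
  pipeline never uses beyond presence.
* **Differential expression.** The default DE subset is 10 miRNAs, 8 down-
  and 2 up-regulated (male/female), mirroring the ~80%/20% split such
  studies report. In the male library each miRNA's per-read probability is
  its female probability times its fold change, and the junk class absorbs
  the aggregate mass difference. Consequently the expected male/female raw
  count ratio of **every** miRNA equals its fold change exactly — null
  miRNAs keep identical expected composition — at the price of a slightly
  different junk share between libraries (a realistic feature: real library
  pairs never have identical composition).

Reruns with the same configuration and seed are byte-identical. Read IDs
index the truth table, so truth joining never depends on sequence
uniqueness.

What passing tests on these libraries does **not** show: robustness to
sequencing error, adapter chemistry variants, cross-mapping between
paralogous miRNA families, or real genome repeat structure. The generator's
genome is uniform-random, which makes exact contaminant/genome matching
cleaner than reality.

## Preprocessing

Adapter trimming takes the insert upstream of the leftmost full adapter
occurrence, or a ≥ `min_overlap` (default 6) adapter prefix at the read's 3'
end; reads without adapter evidence are rejected. The length window is 15–26
nt inclusive. "Junk" is operationalized (the term is never defined in such
studies' methods) as any non-ACGT symbol or a single base occupying ≥ 80% of
positions. Collapsing produces one tag per distinct sequence with
per-library counts, sorted by total count descending with lexicographic
tie-break; collapse conserves per-library read counts exactly. Contaminant
subtraction is exact substring matching on both strands — conservative and
fully testable, since no mismatch tolerance is published for this screen.
"Mappable reads" are the tags surviving all filters and contaminant
subtraction; they are the denominator of the accounting table and of CPM
normalization.

## Annotation

Matching to mature references is ungapped: a placement with ≤ 3 nt 5'/3'
overhang, overlap ≥ 15 nt and Hamming distance ≤ 1 over the overlap. The
"one mismatch" convention is read as substitution-only; indel-like variants
surface as 5'/3' length variation instead. Ties resolve to fewest
mismatches, then longest overlap, then the lexicographically first
reference name. A 7-mer exact-seed prefilter accelerates the scan (any
≤1-mismatch, ≥15-overlap match shares an exact 7-mer, so the prefilter is
lossless). A matched miRNA is **known** when its precursor occurs exactly
(either strand) in the proxy genome and **KC** otherwise ("KC-" name
prefix); a missing precursor record also demotes to KC with a warning.

Star strands are unmatched tags that place (≤ 1 mismatch, ungapped, ± 3 nt
slack) on the arm opposite an observed mature of the same precursor;
star/mature count ratios above 1 are flagged "dominant-star". Variation
classes use 1-based mature coordinates with seed = positions 2–8:
5'-terminus changes (including a substitution at position 1) are
`five_prime_end`; substitutions at 9–15 are `seed_adjacent`; 3'-terminus
changes or substitutions past position 15 are `three_prime_end`; more than
one category is `mixed`; and a substitution strictly inside the seed with
identical termini is reported as the flagged class `seed_variant`, since the
seed is expected to be conserved. Per-miRNA count rows take the variant
with the most reads as representative (lexicographic tie-break) and sum
counts over all grouped variants. The 5' first-base composition is
read-weighted by default; `weighted=False` gives the per-catalog
composition.

## Novel miRNA prediction

Unassigned tags are mapped exactly to both genome strands; tags with more
than 10 placements are discarded as repetitive. Around each locus two
candidate windows are cut — 70 nt upstream (+15 downstream) and 70 nt
downstream (+15 upstream), clipped at contig bounds, reverse-complemented
for minus-strand loci so the tag reads 5'→3' — and folded.

The default folding engine is a dynamic program over non-crossing pairings
that scores only *stacked* pairs: a pair contributes −3.0 (GC), −2.0 (AU)
or −1.0 (GU) kcal/mol when its inner neighbour is also paired; hairpin
loops are ≥ 3 nt and isolated pairs carry zero energy and are never emitted.
This model is deliberately simple enough to verify against brute-force
enumeration and an independently written DP, while preserving the ranking
behaviour needed for hairpin screening; its absolute energies run more
negative than nearest-neighbour thermodynamics. The engine is pluggable —
`vienna_fold` wraps the RNAfold executable behind the same
`(sequence) -> (dot-bracket, ΔG)` signature for thermodynamic fidelity.

A window is ACCEPTed when, in order: (1) ΔG ≤ −15 kcal/mol; (2) the window's
longest helix anchors a single stem-loop — formally, it lies on a maximal
non-branching chain of nested pairs ending in a hairpin loop; a longest
helix sitting above a branch point is a multiloop rejection, while enclosing
pairs *outside* the chain (flank artifacts) are ignored; (3) the tag lies
entirely within one arm (neither touching the loop interior nor crossing to
the opposite arm; an unpaired overhang outside the stem is allowed);
(4) ≥ 14 tag bases are paired and at least that many of their partners fall
inside one window of tag length + 10 nt — a compact mature:star-style duplex
that tolerates a couple of stray long-range pairs. Criterion (4)'s
compactness clause is what separates genuine hairpins from the long but
scattered pairings that random flanks form under the permissive energy
model; shuffling a window's flanks while keeping the tag in place (the
negative control in `shuffle_controls`) drops the acceptance rate from
~100% to ≤ 10%. All thresholds are keyword-exposed.

Accepted calls merge at ≥ 50% reciprocal locus overlap, keep the
lowest-energy call, and are named `esi-novel-N` in genome order.

## Differential expression

Normalized expression is `(count / total mappable) × 1e6` (CPM). miRNAs are
partitioned into female-specific / male-specific / co-expressed; only
co-expressed miRNAs are tested, and the Bonferroni multiplicity m is the
number of co-expressed miRNAs.

The Audic–Claverie posterior-predictive distribution
`P(y|x) = (N2/N1)^y (x+y)! / (x! y! (1+N2/N1)^(x+y+1))` is the negative
binomial NB(r = x+1, p = N1/(N1+N2)), so tails are computed with stable
log-space negative-binomial sums rather than explicit summation. The
two-sided p-value is defined symmetrically in the libraries:
`p = min over both orientations of 2·min(P(Y≤y), P(Y≥y))`, capped at 1.
(The naive one-orientation two-sided value is not invariant under swapping
the libraries for a discrete test; the symmetric definition keeps
exchanging the libraries a pure relabelling — direction flips, p-values
unchanged.) Fisher's exact test runs on the 2×2 table
`[[x, N1−x], [y, N2−y]]`, and the Pearson chi-squared statistic (1 df, no
continuity correction) abstains (`None`) when any expected cell is below 1.

A co-expressed miRNA is significant when **all** non-abstaining
Bonferroni-corrected p-values fall below α = 1e-4 (the conservative reading
of running three tests jointly; switchable to `any`). α applies to the
corrected values. Direction is up/down for male relative to female by CPM.
Under a 1e4-replicate Poisson null at N1 = N2 = 1e6 the uncorrected AC test
rejects at 0.05 within ±0.01, and a planted 4-fold change at base CPM 100 is
detected with sensitivity ≥ 0.95.

## qPCR (2^-ddCt)

Per replicate, dCt = Ct(target) − Ct(reference gene); ddCt is the sample
mean dCt minus the calibrator (default female, configurable) mean; fold =
2^−ddCt. Replicate spread is summarized as the SD of dCt and mapped through
2^−x as asymmetric bounds (fold at ddCt ± SD) — the standard visual
error-bar convention, made explicit. Fold changes are invariant to adding a
constant to all Ct values, and identical target/reference Cts give fold 1.
Concordance with sequencing compares the sign of log fold with the sign of
the log CPM ratio per target. Amplification-efficiency correction (Pfaffl)
and melt-curve analysis are out of scope.

## Reporting and orchestration

Printed percentages round half-up to 2 decimals; category percentages are
taken of mappable reads, and published accounting tables are reproduced to
|Δ| ≤ 0.01 (one row of the reference table carries a 0.01 upstream rounding
artifact). The pipeline runs simulate → preprocess → annotate → novel →
accounting → diffexp → qpcr, asserts read-count conservation at every stage
(raw = rejected + filtered; mappable = filtered − contaminants; categories
sum exactly to mappable), writes plain TSV tables plus a JSON manifest, and
halts with the failing stage's name on error. All outputs except the
manifest timestamp are byte-reproducible for a fixed seed. Star reads are
accounted under conserved miRNA candidates; accepted novel tags under
specific miRNA candidates; everything else mappable is unknown small RNAs.

## Problem sizes and defaults

Default study conditions: 30 known + 10 KC matures, 10 novel loci, 20
contaminant references, a 30 kb single-contig genome, and 1e5 reads per
library. These desk-scale sizes keep an end-to-end run under half a minute
on one CPU while leaving every per-category count in the hundreds-to-
thousands range where the statistical checks are meaningful; all sizes are
constructor arguments.

## Known limitations

* The default energy model is not thermodynamic; absolute ΔG values are
  comparable only within the model (use the RNAfold backend for real data).
* Contaminant and genome matching are exact; a single sequencing error
  defeats them (no mutation process is simulated for those classes).
* Annotation assumes substitution-only variation within a ±3 nt window;
  larger editing events fall through to "unknown".
* Dispersion-aware DE models (negative binomial with biological replicates)
  are out of scope — the design is the classic one-library-per-condition
  count comparison with Bonferroni control, not an FDR workflow.
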