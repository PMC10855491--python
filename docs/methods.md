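# Methods

## Coordinate conventions

All in-memory coordinates are 0-based half-open `[start, end)`. GTF/GFF3
input (1-based closed) is converted at the I/O boundary; BED is half-open
already and passes through. Converting once at the boundary removes every
off-by-one ambiguity from the containment tests, which is where such errors
would silently change counts. An optional `chr`-prefix-stripping toggle lets
annotations and BED files with mismatched naming be combined; the consensus
step refuses outright disjoint chromosome namespaces, which almost always
indicate such a mismatch.

## Promoters

The transcription start site is taken as the 5′ end of the annotated gene
span (start on `+`, end on `−`) — the only transcript-free definition when a
single promoter per gene is wanted. Gene-level analysis deliberately ignores
alternative transcripts with distinct promoters; that is a known limitation,
not an oversight. The promoter is the `window` bp (default 1000,
configurable) directly upstream of the TSS. Promoters running past a
chromosome edge are clipped and flagged; promoters clipping to zero length
are dropped and the affected gene ids reported. Promoters are *not* masked
against neighboring genes: adjacent-gene overlap is left intact, and an OQ
contained in two overlapping regions counts for each, which keeps every
region's count independent of the rest of the region set.

## Consensus catalog

The OQ catalog used downstream is the set of structure calls supported by
both stabilizer conditions. Geometry: coordinate intersection of every
overlapping (≥1 bp) K⁺/PDS pair, then merging of overlapping or bookended
results, sorted output. This is conservative, deterministic, and symmetric
in the two conditions. Because interval widths (and therefore containment
counts) depend on this choice, an alternative `kplus_anchored` mode keeps
the whole K⁺ interval whenever any PDS overlap exists.

OQ strand is ignored during assignment by default — G4-Seq reports
per-strand calls, but promoters are regulatory regions where either strand's
structure can act, and no strand filter is obviously right; a
`strand_policy="match"` toggle restricts to same-strand OQs.

## Containment counting

Strict containment (`oq.start ≥ region.start and oq.end ≤ region.end`,
same chromosome) is evaluated with a per-chromosome sorted-array bisection
on OQ starts followed by an end-bound check, which is near-linear at
genome scale (~4 × 10⁵ OQs). The quadratic all-pairs scan survives as the
test oracle: the indexed path must reproduce it exactly on randomized
instances.

## DE stratification

A gene is DE when `padj < α` (default 0.05). Rows with missing adjusted
p-values (DESeq2 independent filtering) are kept as non-DE rather than
dropped, so the analysis universe remains the full annotation; the non-DE
background is the set complement of the DE calls within that universe,
untested genes included. Fold tiers are inclusive: tier *k* means
|log₂FC| ≥ log₂ k, so a gene at exactly 2-fold belongs to the 2-fold tier.
Fold changes are taken from the input column as-is; no shrinkage or
re-estimation is performed.

## Statistics

**Presence enrichment.** Hypergeometric upper tail with N = all regions of
the class, K = regions containing ≥1 consensus OQ, n = group size,
k = group regions with ≥1 OQ. The tail is accumulated in log space
(`logsumexp` over the pmf) so the result stays meaningful far below double
underflow; the result carries both `p` (floored at the smallest positive
double) and an exact `log10_p`.

**Count comparison.** Wilcoxon rank-sum on per-region OQ counts, by default
restricted to OQ-containing regions in each group — the reported group
means are per OQ-containing region, so the test matches the summary it
accompanies; `include_zeros` lifts the restriction. W is the first-sample
Mann–Whitney U (rank sum minus n₁(n₁+1)/2, range [0, n₁n₂]); the first
sample is the DE group. Dispatch: exact permutation null when the pooled
sample is tie-free and n₁+n₂ ≤ 20, otherwise the normal approximation with
tie-corrected variance n₁n₂/12 · [(N+1) − Σ(t³−t)/(N(N−1))] and a 0.5
continuity correction. Two-sided p-values are the default (the conservative
choice when sidedness is not prescribed); one-sided alternatives are
available. Exhaustive checking over every achievable W at sample sizes
8–10 shows the one-sided approximation within 0.01 of the exact tail
(worst 0.0055); the two-sided p is twice the smaller tail, so its
deviation is exactly double.

**Length confound.** Longer genes accumulate more OQs by chance, so the
gene-body comparison is accompanied by a rank-sum test on gene lengths
among OQ-containing genes, with group mean lengths reported.

**Over-representation.** Per-term hypergeometric upper tail against a gene
universe, Benjamini–Hochberg step-up adjustment (via statsmodels), terms
reconciled to the universe first. Term databases are user-supplied; none
are bundled.

**Report rounding.** Percentages are reported at 1 decimal and means at 2
decimals (matching the precision at which such results are conventionally
printed); full-precision values are always present alongside in the
machine-readable report.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, with
exact bookkeeping so recovery can demand equality rather than tolerance:

- **Genome.** 4 chromosomes × 30 Mb, 5000 genes by default. Gene lengths
  are log-normal (median 10 kb, σ_log = 1) clipped to 1–100 kb — the span
  of typical human gene lengths; strands equiprobable; ~46% protein-coding.
- **Placement.** Each gene occupies one *block* (promoter + body). Blocks
  are placed uniformly without overlap per chromosome (sorted-uniform gap
  construction), so promoter OQs can never fall inside a gene body or
  another promoter, keeping planted per-region counts exact.
- **OQs.** Per-region counts are Poisson with mean λ₀·len/1000 (λ₀ = 0.5
  OQs/kb, the order of genome-wide G4-Seq density) times ρ (default 3) for
  regions of the designated DE genes. Intervals are 15–50 bp, placed
  uniformly inside the region with a 6 bp edge margin and ≥12 bp mutual
  separation. Draws that cannot fit are truncated; the recorded truth is
  the realized count.
- **Condition BEDs.** Every planted OQ appears in both files, extended ≤5 bp
  leftward in the K⁺ file and ≤5 bp rightward in the PDS file. Because the
  extensions are shorter than half the inter-OQ pad and the edge margin,
  the pairwise intersection reproduces each OQ exactly and no two consensus
  intervals can touch or merge. Condition-private decoys (density 0.1/kb
  per condition) are placed in intergenic gaps, mutually non-overlapping,
  so they exercise the intersection and are guaranteed to vanish in it.
- **DE table.** 15% of genes are DE (`padj` uniform below 0.05, the rest at
  or above it, with 2% of non-DE rows given missing `padj` to exercise the
  independent-filtering rule). DE |log₂FC| mass across the <2× / 2–5× /
  5–10× / ≥10× bins is (84.8, 13.2, 1.55, 0.45)% and 54.3% of DE genes are
  up — the proportions observed in DHX36-knockout-style experiments.
  Non-DE fold changes are N(0, 0.2).
- **Determinism.** One `numpy` Generator keyed by the seed; fixed write
  order and formats make outputs byte-identical per seed. Every file
  carries the seed in a header comment; `truth.json` records realized
  per-region counts, group memberships, and input checksums binding truth
  to its files.

What the generator does **not** emulate: real G4 sequence composition and
its GC-content covariates, clustered/CpG-island promoter architecture,
correlated OQ placement between neighboring genes, overlapping genes and
alternative promoters, and any dependence of DE status on expression level.
Passing tests therefore demonstrate the correctness of the counting and the
calibration of the statistics under the stated sampling model — not that
real enrichment of this size will be detected in any particular real
dataset.

`recover_truth` demands exact count equality and, where an enrichment was
actually planted (ρ ≥ 2), a significant promoter presence test. The
decision check is promoter-only by design: gene bodies are long enough
(λ ≈ 7.5 per region) that presence saturates in both groups on small
simulations, so a non-significant gene-body presence test is the correct
outcome there, not a failure.

## Numerical and edge-case choices

- Hypergeometric parameter violations (k outside its support, K > N, ...)
  raise before any computation; p is clamped into (0, 1] only against
  floating-point rounding above 1.
- Identical-sample rank-sum input (all values tied) takes the normal path;
  midranks make W = n₁n₂/2 and p ≈ 1.
- Empty OQ sets are valid (all-zero counts); empty condition sets are not.
- BED records are validated line-by-line with line numbers in errors;
  `start ≥ end` is rejected rather than silently dropped.
- Duplicate gene ids are an error; identical coordinates under distinct ids
  are legitimate and kept.
- Chromosome sizes may be supplied (two-column TSV); when absent, each
  chromosome is bounded by max(gene end) + window, which only disables
  far-end clipping.
- Reports contain no timestamps and record input *basenames* + MD5
  checksums rather than absolute paths, so reruns on identical inputs are
  byte-identical wherever they are run from.

## Problem sizes in the checks

The statistical property checks run at the defaults: 200 seeds for the
null-calibration sweep (ρ = 1, rejection rate at α = 0.05 inside the
binomial 95% interval) and 100 seeds for power/recovery (ρ = 3: presence
p < 0.01 and count-ratio recovery of ρ within 15% in ≥95% of seeds); the
acceptance script uses 50 power seeds. Unit fixtures use a 240-gene,
2-chromosome genome, which exercises every code path (both strands, decoys,
clipping guards) in milliseconds.

## Known limitations

- One promoter per gene; no transcript-level analysis.
- No sequence-level modeling: OQs are opaque intervals, not motifs; no
  GC/length matching of the background beyond the explicit length test.
- The gene-length confound is reported, not corrected for; a
  length-matched resampling test would be the natural extension.
- Tallies against transcription-factor/oncogene/helicase lists depend
  entirely on the user-supplied lists and alias map; no database content is
  bundled.
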