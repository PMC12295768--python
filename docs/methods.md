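# Methods

This note records the models, conventions and numerical choices behind
`g4reg`, in the spirit of the methods documentation of packages like
statsmodels or msprime: enough detail to reproduce or audit every
computation without reading the source.

## Coordinates and gene models

All coordinates are 0-based half-open (BED convention); GTF input is
converted on read (1-based inclusive → half-open). One gene model is kept
per gene: when a GTF carries several transcripts the longest (by summed
exon length) is used, which maximizes intron coverage. Introns are exactly
the gaps between consecutive exons and are numbered 1..n in *transcription*
direction, so intron 1 of a minus-strand gene is the genomically last gap.
The promoter is `promoter_window` (default 1000) bases immediately upstream
of the TSS, strand-aware; it is clipped at the chromosome start (position 0)
— clipping at the right edge requires chromosome sizes, which BED-style
inputs do not carry, so minus-strand promoters near a contig end are the
caller's responsibility.

The midpoint of an interval is `floor((start+end)/2)` throughout — the
single-label annotation rule, the TF binding-site rule, and the
site-in-region overlap rule all use it. Single-label annotation resolves
ties by a priority order (promoter > 5'UTR > 3'UTR > exon > intron >
intergenic) and, within a priority level, by the lexicographically smallest
gene id, which makes annotation deterministic for overlapping genes.
Expression and TF region classification use any-overlap (≥ 1 bp) instead of
the midpoint, matching the behaviour of `bedtools annotate`.

## Interval operations

`merge_intervals` joins intervals that overlap **or abut** (distance 0),
strand-agnostically — the `bedtools merge` default — and conserves covered
bases exactly. `shuffle_intervals` re-places each interval, length
preserved, uniformly over all legal start positions across the universe
segments: a segment of length S contributes `max(S - L + 1, 0)` start
positions for an interval of length L, and segments are chosen with
probability proportional to that weight. Shuffled intervals may overlap
each other (again the bedtools default). An interval longer than every
universe segment is an error.

## First-intron permutation test

The observed statistic is the fraction of intronic peaks whose *midpoint*
lies in a first intron. Midpoint membership (rather than any-overlap) is a
deliberate divergence from counting overlaps: it prevents a peak spanning
an exon boundary from being counted in two introns, so the proportions sum
to one. Each permutation re-places all intronic peaks over the union of all
introns by the shuffle law above (the implementation vectorizes the
placement on a flattened coordinate line; the placement distribution is
identical to `shuffle_intervals`). The p-value is the add-one estimator
`(#{null ≥ observed} + 1) / (m + 1)`, which can never be zero; with the
10,000 permutations used at full scale the smallest reportable p is ~1e-4.

## Statistics

**Fisher's exact test (two-sided)** uses the minimum-likelihood convention:
the p-value sums hypergeometric point probabilities of all tables with the
observed margins whose probability does not exceed the observed table's by
more than a relative tolerance of 1e-7 (the convention of R's
`fisher.test`). Log-space point probabilities (`hypergeom.logpmf` +
log-sum-exp) keep p-values of order 1e-100 exact. For tables whose two row
totals are equal the null pmf is symmetric and this convention provably
coincides with tail doubling; the test suite asserts that equivalence.

**Wilcoxon rank-sum** uses the exact null distribution when the combined
sample size is ≤ 50 and the data are tie-free, and otherwise the normal
approximation with tie-corrected variance and a 0.5 continuity correction —
the switching behaviour of R's `wilcox.test`. Full enumeration under ties
at n = 50 is computationally out of reach (C(50,25) ≈ 1.3e14 assignments),
so ties always take the asymptotic path; with hundreds of samples per
group, as in the DE setting this package targets, the approximation error
is negligible. Degenerate data (all values identical) returns p = 1.

**Spearman correlation** is the Pearson correlation of average ranks with
the t-approximation on n−2 degrees of freedom. **Benjamini–Hochberg**
adjustment is the standard step-up with cumulative-minimum monotonicity.

## Differential expression

TMM normalization follows the trimmed-mean-of-M-values definition: the
reference sample is the one whose 75th-percentile count fraction is closest
to the mean of those fractions; for each sample vs the reference, genes
zero in either are dropped; M (log2 ratio of library-scaled counts) is
trimmed 30% two-sidedly and A (average log abundance) 5% two-sidedly by
average ranks; the factor is 2^(weighted mean of kept M) with
delta-method inverse variances `(N−x)/(Nx)` as weights; factors are
rescaled to geometric mean 1. The implementation is validated against an
independently coded, loop-level clean-room implementation to 1e-10.

CPM divides by effective library size (library × factor) × 1e-6; log-CPM
uses `log2(cpm + prior)` with prior 1. DE testing pre-filters to genes with
CPM > 1 in at least `min(|A|,|B|)` samples (the "very low counts" filter,
fixed here as a concrete rule), applies the per-gene two-sided rank-sum
test on CPM, BH-adjusts across tested genes, and calls up/down at
FDR < 0.01 with |log2FC| ≥ 2 (≥ 4-fold). The fold change is computed from
group mean CPM with prior 1 added to both numerator and denominator; the
prior is configurable.

## TF binding and co-localization

A TF is assigned to a G4 region iff at least one of its peak midpoints lies
inside the region. Regions are classified promoter / intron 1 / downstream
intron by any-overlap with the owning gene's features, with promoter
winning over intron 1 over downstream introns. Complementarity statistics
are computed per gene over the union of TF sets of its regions in each
class; genes with both a promoter and a first-intron G4 enter the Spearman
correlation, and those with ≥ 1 first-intron TF enter the shared-fraction
histogram.

Co-localization sites partition the genome at all peak boundaries and emit
maximal segments covered by ≥ 2 distinct TFs with their protein set
(`bedtools multiinter` semantics); site classes "≥ k" are nested by
construction. Enrichment of class-≥k site midpoints inside G4 regions is
tested against a *single* seeded length-preserving shuffle of the G4
regions (the published analyses report one control column of the same
denominator), with the two-tailed exact Fisher test; the TF-level
enrichment routine instead averages the control count over `n_perm`
shuffles (default 100) before the same test. The control universe is
configurable; promoter space is the natural choice when the query regions
are promoter G4s.

## pG4 scanning and SNV effects

The scanner finds, at each position, the leftmost motif with **minimal
loops and maximal G-tracts** (greedy G-runs, lazy loops, with
backtracking), emits it, and resumes after its end — motifs are therefore
non-overlapping per strand. The minus strand is scanned on the reverse
complement and mapped back; `N` never matches. Maximal G-runs were chosen
over a strictly-shortest match because they give the biologically canonical
tract/loop decomposition used downstream; the difference only shows when a
terminal G-run exceeds the minimum tract length. Scoring engines that rank
overlapping candidates (e.g. pqsfinder) will produce different motif
counts; parity with them is not claimed.

SNVs are classified g_tract / loop / outside against the scanned motif map;
when overlapping motifs disagree, g_tract wins (a G-tract hit is the more
consequential call). Substitution types are expressed on the G-rich motif
strand so that a genomic C>T under a minus-strand motif aggregates as G>A.
The built-in stability scorer averages per-base G-run/C-run scores
(+/−min(run, 4)) over the window; it is sign-inverted relative to a folding
energy (higher = more stable), monotone in G-tract integrity, and
deliberately simple — an adapter slot accepts any `str -> float` scorer
obeying the same contract (an external folding engine plugs in by negating
its minimum free energy). The neutral-call tolerance is 0 by default: any
nonzero delta is a call. Gain/loss detection rescans the ±30-nt window
(clipped at contig edges) around the SNV in REF and ALT, on both strands,
and compares motif sets keyed by coordinates + strand.

## Synthetic data generator

The generator exists to give every pipeline stage a known ground truth; its
defaults are the package's study conditions. A single integer seed feeds a
named substream per generator (SeedSequence spawn keys), so adding a
generator never perturbs the others and all text outputs are byte-stable.

- **Genome/genes**: 2 chromosomes × 2 Mb of random sequence at GC 0.41;
  300 genes placed sequentially with random strands; intron counts are
  geometric with mean 7.6 (so every gene has ≥ 1 intron); exon lengths are
  log-normal around 150 bp; downstream introns log-normal with median
  400 bp and the first intron log-normal with median 1200 bp (≈ 3×).
- **G4 placement**: Poisson numbers of canonical motifs (tracts 3–4, loops
  1–7 over {A,C,T}) per feature — expected 0.6 per promoter, 1.35 per first
  intron, 0.15 per downstream intron. Because first introns are ~3× longer,
  the first-intron *per-base* motif density is ~3× the downstream density:
  that — not the per-feature count — is the planted enrichment the
  permutation test must detect. First-intron positions follow Beta(1, 4)
  from the intron's 5' end; other placements are uniform. Placements that
  would overwrite an earlier motif are skipped, so the truth record equals
  what is actually in the sequence. Peaks are motif coordinates jittered
  ±10 bp plus 10% random decoy peaks.
- **Expression**: negative-binomial counts (dispersion 0.2) around
  log-normal per-gene baselines (median 100), 30 tumor + 30 normal-adjacent
  samples with ±30% library-size variation; genes carrying a promoter or
  first-intron G4 get a +1 log2 mean shift in tumor. A separate calibration
  generator plants a configurable number of shifted genes in an otherwise
  null matrix for DE sensitivity/FDR studies (8-fold shifts by default,
  matching the ≥ 4-fold DEG threshold with headroom).
- **TF peaks**: 20 TFs. Per gene, promoter and first-intron binding
  propensities are drawn from a Gaussian copula with rank correlation ρ
  (default −0.5) and mapped to [0.05, 0.6]; each TF binds at the gene level
  with those propensities and its peak midpoint lands inside one randomly
  chosen G4 of that class, so per-gene TF counts are Binomial(20, p) by
  construction. Downstream-intron G4s are bound at a flat 0.08 rate, and
  each TF gets 50 background peaks. Binomial sampling attenuates the
  recovered count-level Spearman correlation below |ρ| (to roughly −0.3 for
  ρ = −0.5); the recovery tests check the attenuated value, not ρ itself.
- **SNVs**: 5000 by default — 50% placed on G-tract bases (of motifs
  scanned from the realized genome, so labels are exact), 35% on loop bases
  restricted to A/T references (an A/T base can never sit in a G-tract on
  either strand, making the label unambiguous), the rest background outside
  motifs. Tract SNVs substitute G>A with probability 0.6 (else G>C/G>T,
  equally), expressed on the motif strand. Separately, isolated
  gain/loss constructs are written into intergenic space, padded by 8 T's
  so no loop (≤ 7 nt) can bridge them to surrounding sequence: a gain site
  is a motif with its fourth tract broken at the middle G (the SNV restores
  it), a loss site a full motif whose second tract the SNV breaks.

What the generator does **not** emulate: chromatin context, mutational
signatures beyond the single G>A dial, overlapping genes and alternative
transcripts, batch effects, or realistic cohort library-size distributions.
Passing tests therefore demonstrate correctness of the computations and
recoverability of planted effects, not performance on real tumor data.

## Problem sizes and tolerances

The default synthetic world (2 × 2 Mb, 300 genes, 20 TFs, 5000 SNVs) runs
end-to-end in seconds; permutation tests use 1000 permutations in the
bundled acceptance script and 199–10,000 in tests depending on the
property being checked; calibration studies use 20 seeds (complementarity),
50 runs × 2000 genes (DE false-discovery control), 200 runs (permutation-p
uniformity), 50 random matrices (TMM), and 100 random 10-kb sequences
(scanner oracle). Numerical tolerances: TMM vs clean-room oracle 1e-10;
Spearman vs rank oracle 1e-12; Fisher vs exact-rational enumeration 1e-12
relative; calibrated error rates are asserted within 3σ binomial bands or
at KS α = 0.01.
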