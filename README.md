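# g4reg

Analysis toolkit for the regulatory landscape of DNA **G-quadruplexes (G4s)**
in gene promoters and first introns, with an emphasis on the patterns seen in
breast-cancer G4 ChIP data: where experimentally mapped G4 peaks fall in gene
architecture, whether their concentration in first introns exceeds what intron
length alone predicts, how promoter/first-intron G4s relate to expression, how
transcription factors (TFs) distribute complementarily between promoter and
first-intron G4s, how multi-TF co-localization concentrates in promoter G4
regions, and how somatic single-nucleotide variants (SNVs) destabilize,
create, or destroy G4 motifs.

It is written for computational biologists who have peak files (BED), gene
models (GTF or a simple TSV), count matrices, TF ChIP peaks, SNV tables and a
genome FASTA — or who want a fully seeded synthetic version of all of those
with known planted effects, which the package also generates.

## Methods at a glance

- **Canonical pG4 motif**: `G_x N_{1-7} G_x N_{1-7} G_x N_{1-7} G_x` with
  x ≥ 3; the scanner emits non-overlapping motifs per strand with an explicit
  G-tract/loop map, scanning both strands.
- **First-intron permutation test**: intronic peaks are re-placed
  length-preserved, uniformly over all legal start positions across the
  intron universe (bedtools-shuffle semantics); the add-one empirical
  p-value compares the observed first-intron proportion with the
  permutation null.
- **Differential expression**: TMM normalization (trimmed mean of M-values),
  CPM transformation, per-gene two-sided Wilcoxon rank-sum tests,
  Benjamini–Hochberg FDR; DEG = FDR < 0.01 and ≥ 4-fold change.
- **Exact Fisher tests**: two-sided by the minimum-likelihood convention
  (the R `fisher.test` convention), computed with log-space hypergeometric
  point probabilities so p-values of order 1e-100 are exact.
- **TF binding**: a TF binds a G4 region when one of its ChIP-peak midpoints
  lies inside the region; complementarity is the per-gene Spearman
  correlation between promoter and first-intron TF counts, plus the shared
  fraction |TF_prom ∩ TF_int1| / |TF_int1|.
- **Multi-TF co-localization**: maximal genome segments covered by ≥ 2
  distinct TFs (multiinter semantics), tested for enrichment inside G4
  regions against a length-preserving shuffled control with a two-tailed
  Fisher test.
- **SNV effects**: classification into G-tract vs loop hits, 12-type
  substitution spectra expressed on the G-rich strand, a G-run stability
  score (each base in a G-run of length k scores +min(k, 4), C-runs score
  negatively; higher = more stable) with pluggable external scorers, ±30-nt
  gain/loss rescanning, and the region enrichment score
  `(N_G4,region / N_G4,total) / (N_BC,region / N_BC,total)`.

## Worked example

Generate a seeded synthetic dataset and run the landscape and SNV analyses:

```bash
g4reg synth --seed 3 --out demo
g4reg landscape --peaks demo/g4_peaks.bed --genes demo/genes.tsv \
    --n-perm 200 --seed 7 --out demo/perm.tsv
g4reg snv --snvs demo/snvs.tsv --fasta demo/genome.fa --out demo/snv.tsv
```

which prints:

```
observed first-intron proportion 0.546, p = 0.00498
5000 SNVs: 294 gain a motif, 1961 lose one
```

The first line says 54.6% of intronic G4 peaks sit in first introns while
the permutation null (uniform placement over all introns, length preserved)
centers near 30% — the planted 3× per-base first-intron density is detected
at the smallest p the 200-permutation add-one estimator can produce. The
second line counts SNVs whose ±30-nt window gains or loses a canonical G4
motif; losses dominate because half the synthetic SNVs are planted inside
G-tracts, where a single G substitution usually destroys the motif.

The same stages are available as library calls (`g4reg.landscape`,
`g4reg.expression`, `g4reg.tf`, `g4reg.variants`), which is the recommended
interface for anything beyond one-off runs.

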