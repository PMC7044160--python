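# Methods

`silencerscan` implements a genome-wide strategy for discovering and
characterizing silencer elements — distal cis-regulatory elements (CREs)
that repress transcription. The strategy has four stages: (1) candidate
pool definition by subtraction, (2) functional quantification by massively
parallel reporter assay (MPRA), (3) sequence-based generalization with a
gapped k-mer support vector machine, and (4) downstream characterization
(methylation, conservation, chromatin state, 3D contacts, disease
variants). A synthetic-data generator with planted ground truth makes the
whole analysis runnable and testable offline.

## Coordinate model

All coordinates are 0-based half-open (BED convention) throughout —
readers, writers and arithmetic alike. Interval subtraction is
*whole-record*: a DNase hypersensitive site (DHS) peak sharing even one
base with a subtraction track is removed in full, never clipped. A
base-clipping variant is deliberately not provided; the candidate pool is
defined in units of peaks, not base pairs. Chromosome names are matched by
exact string equality, and operations warn when two inputs share no
chromosome names (the classic `chr1` vs `1` mismatch).

## Stage 1 — subtractive candidate calling (SSA)

Open chromatin (DHS peaks) per cell type is filtered against tracks with
known regulatory identity:

- enhancers: H3K4me1 peaks;
- promoters: H3K4me3 peaks plus strand-aware TSS windows spanning 2000 bp
  upstream to 500 bp downstream of each annotated TSS (clipped at the
  chromosome origin);
- candidate insulators: CTCF sites pooled across cell types (CTCF binding
  is largely cell-type invariant).

DHS records untouched by every track are "uncharacterized CREs" — the
pool expected to contain silencers. The output is provably invariant to
the order the tracks are applied (each filter is an intersection-
complement), and adding records to any subtraction track can only shrink
it. Whether H3K4me3 peaks outside TSS windows count as promoters is
genuinely ambiguous; both are subtracted here, which is the conservative
choice for a candidate pool meant to exclude everything already
characterized.

## Stage 2 — MPRA activity and silencer calling

For element e and replicate r with plasmid count > 0, the normalized
ratio is

    ratio_er = (RNA_er / rna_lib_r) / (plasmid_er / plasmid_lib_r)

with library sizes fixed at the full-table column totals (filtering a
table does not change the sequencing depth it was measured at). Activity
is the mean ratio over valid replicates divided by the mean ratio of the
control-random elements, so control-random activity is exactly 1 and the
measure is invariant to rescaling any library. Zero-RNA replicates yield
ratio 0 and are valid observations for the activity mean; no pseudocounts
are added anywhere.

Elements are retained only if detected (count > 0) in at least three
replicates in both the RNA and plasmid libraries. Each retained tested
element is then compared against the pooled per-replicate ratios of all
control-random elements with a one-tailed two-sample t test (alternative:
element below controls) on log2 ratios. Two numerical choices matter
here:

- **Log scale.** Ratios are right-skewed; log2 stabilizes the variance.
  Zero ratios have no logarithm and are excluded from the *test* sample
  (they still enter the activity estimate); with the default count model
  they are rare. The raw-scale test remains available via
  `log_scale=False`.
- **Pooled variance (default) vs Welch.** Both groups draw from the same
  count model, so their log-scale variances are comparable and pooling is
  statistically justified. It is also decisive in practice: with 5
  element replicates against ~335 pooled control ratios, Welch's
  effective degrees of freedom collapse to ~4, and in simulation at the
  default study conditions detection power drops from 1.0 (pooled) to
  ~0.67 (Welch) after FDR correction, while both variants control the
  null at well under the nominal 5%. Welch remains available via
  `equal_var=False`.

P-values are Benjamini–Hochberg adjusted (step-up, q(i) = min over j >= i
of m·p(j)/j, capped at 1) across tested elements only. A silencer call
requires both activity (fold change) < 1 and q < 0.05. Degenerate tests
(zero variance in both groups at equal means) yield p = 1 with a log
message, never an exception.

qPCR utilities implement the delta-delta-Ct convention: dCt = Ct_target −
Ct_ref (single reference or the mean of two internal references), ddCt
relative to the control-group mean, fold change 2^(−ddCt), with a
one-tailed t test between groups on dCt.

## Stage 3 — gapped k-mer SVM

A gapped k-mer is a length-l word with k informative positions and l−k
wildcards. Every length-l window contributes one count to each of the
C(l,k) position choices; windows are skipped for a position choice only
when an N falls on an informative position. With reverse-complement
collapsing (default), a gapped word and its reverse complement share one
canonical feature, making the featurization strand-symmetric. Feature
counts conserve mass: an N-free sequence of length L yields exactly
(L−l+1)·C(l,k) total counts.

This explicit featurization is a transparent stand-in for the
string-kernel formulation of gapped k-mer SVMs: the feature map is
enumerable, testable against brute-force window/subset enumeration, and
feeds an ordinary linear SVM (scikit-learn `LinearSVC`, C = 1 by
default). Feature vectors are L2-normalized per sequence so that score
scale does not depend on sequence length. Defaults l = 10, k = 6 follow
the published tool lineage; tests and the end-to-end run use the l = 6,
k = 4 preset, which keeps the feature space at C(6,4)·4^4 = 3840 columns
and trains in seconds at a few thousand sequences.

Training sets are the activity extremes of the MPRA screen: the
n-lowest-activity tested elements as positives (silencer-like) and the
n-highest as negatives, boundary ties broken by element id for
determinism. The split is stratified 80/20 with an explicit seed; AUROC
(trapezoidal, half credit for ties — identical to the Mann–Whitney pair
statistic) and AUPRC (step-wise precision-recall integral) are computed
on the held-out scores, where the classification threshold is chosen at
maximum accuracy (rule: positive if score >= t; ties resolved to the
lowest qualifying cutoff). The threshold is chosen once, on held-out
data, and reused for genome-wide prediction, never refit per cell type.

A note on achievable discrimination: when positives carry a planted
consensus at rate p+ and negatives at rate p−, a perfect motif detector's
AUROC is bounded by p+(1−p−) + ½(p+p− + (1−p+)(1−p−)); at the default
0.9/0.1 rates this ceiling is exactly 0.90, and realized held-out AUROC
on the synthetic screen is ~0.83–0.89 — the same range as reporter-assay
classifiers on real screens. Passing tests therefore demonstrate that
the classifier extracts essentially all the signal the generator plants,
not that real silencers are this predictable.

## Stage 4 — characterization statistics

**Permutation overlap test.** For a target set against a feature track,
observed = number of target records overlapping >= 1 feature. Each of N
permutations draws |target| records from a designated universe (random
DHS or random enhancers) without replacement and recounts. The empirical
probability is P = (Σn + 1)/(N + 1) with Σn the permutations whose null
count strictly exceeds the observed; the add-one makes the estimate valid
and floors it at 1/(N+1). Null draws are not length- or GC-matched — the
universe is assumed comparable by construction.

**GWAS-trait enrichment.** Lead SNPs are expanded with linkage-
disequilibrium proxies at r² >= 0.8 (proxies inherit their lead's trait;
deduplicated by SNP-trait pair). For each cell type and trait, with M
distinct catalog SNPs, K of the trait, n inside the cell's silencers and
k of the trait inside, the upper-tail hypergeometric P[X >= k] tests the
trait against the rest of the catalog. BH adjustment runs across the full
cell × trait matrix (per-cell adjustment is config-exposed); enrichment
is called at q < 0.01. SNP membership is point-in-half-open-interval.

**Binomial motif enrichment** is the arithmetic only: upper-tail
P[X >= k] for X ~ Binomial(n, background rate), with the rate-zero edge
handled explicitly.

**Chromatin states.** Each element is assigned the 15-state segmentation
state covering most of its bases, ties resolved by the canonical state
ordering (TssA … Quies); uncovered elements are reported separately as
NA, and fractions over assigned elements sum to 1. An optional baseline
repeats the assignment over B = 1000 random draws from a universe and
reports mean fractions.

**Promoter-capture Hi-C.** Interactions are kept when the edge-to-edge
gap between bait (promoter fragment) and other-end fragment is at least
10 kb — removing close-proximity ligation noise; trans interactions pass
trivially. The 10 kb anchor is measured fragment-edge to fragment-edge
(midpoint anchoring is a config choice away). Each element overlapping a
retained other end by >= 1 bp is paired with every bait gene,
many-to-many preserved. Target-gene expression is binned as RPKM = 0,
(0,2], (2,10], (10,∞) — right-closed, so RPKM = 2.0 is "lowly expressed"
— and silencer- vs enhancer-contacted gene expression is compared with a
one-tailed Wilcoxon rank-sum test: midranks for ties, exact enumeration
of rank assignments when the pooled sample has <= 12 observations,
otherwise the normal approximation with tie-corrected variance and
continuity correction.

**Value tracks.** Per-element means weight every covered base equally.
Sparse tracks (per-cytosine WGBS methylation) divide by covered bases and
leave uncovered elements undefined; dense tracks (phastCons-style
conservation) treat absent positions as 0 and divide by element length.
Coverage weighting of methylation calls is deliberately not modeled.

**Active enhancers** are DHS overlapping both H3K4me1 and H3K27ac.
Silencer-to-enhancer switching is the fraction of one cell type's
silencers overlapping the union of all *other* cell types' active
enhancers. The genomic-context annotator uses a fixed priority —
promoter > exon > intron > repeat > intergenic — and does not replicate
any published annotation suite's precedence bit-for-bit.

## Synthetic data: what it emulates and what it does not

The generator plants every truth the pipeline is asked to recover, on a
deliberately scaled-down genome. Default study conditions (all
config-exposed; randomness flows from one master seed through named
substreams, so every fixture is independently reproducible):

| parameter | default | rationale |
|---|---|---|
| genome | 1 chromosome × 2 Mb | desk-scale stand-in for a 3 Gb genome |
| cell types | 3 | minimum for pooling/switching analyses |
| tested elements | 2000, 200 nt | oligo-scale screen |
| controls | 67 random / 20 enhancer / 20 silencer | the screen's control design |
| replicates | 5 | biological replicate count of the screen |
| counts | negative binomial, mean 200, dispersion 0.1 | overdispersed sequencing counts |
| true silencer activity | 0.3 | a strong repressive fold change |
| planted silencer fraction | 0.4 | the observed hit rate of such screens |
| consensus plant rate | 0.9 in silencers vs 0.1 elsewhere | imperfect motif-activity coupling |
| methylation Beta means | 0.70 silencers / 0.40 enhancers | hyper- vs hypo-methylated contrast |
| SNP enrichment factor | 10× for one (trait, cell) pair | a clearly detectable disease signal |

Construction guarantees worth knowing: subtraction tracks are laid down
first and planted uncharacterized CREs are placed in the uncovered
complement, so SSA recovers the planted set *exactly* — that test
validates the subtraction logic, not placement luck. Decoy p-CHiC
interactions are generated strictly below the 10 kb gap and everything
else at or above it, so the distance filter's behaviour is checkable
exactly.

Not emulated: chromatin-state spatial autocorrelation, haplotype-based
LD structure, GC/length-matched null regions, WGBS coverage variation,
sequence evolution, and any real motif biology (the planted consensus is
positional truth, not a factor's binding site). Passing tests therefore
demonstrate correctness of the statistics and plumbing under a known
model — not that real genomes behave this way.

## Problem sizes and runtime

The default end-to-end run (3 × 2000 CREs, 2000-element screen, l=6/k=4
classifier at 500 per class, 24 trait-cell enrichment tests) completes in
well under a minute on one CPU; the full test suite, including the
200-table FDR/power simulations and the exhaustive tail-probability
enumerations, runs in about a minute. These sizes were chosen so that
every statistical check rests on enough replication to be stable while
the whole suite stays interactive.

## Known limitations

- The explicit gapped k-mer featurization approximates, and does not
  numerically replicate, string-kernel gapped k-mer SVM scores.
- Whole-record subtraction makes the candidate pool sensitive to peak
  fragmentation in the input tracks.
- The permutation null draws records without matching length or GC.
- The hypergeometric universe is the whole SNP catalog; a per-cell
  universe is an option, not the default.
- qPCR statistics assume approximately normal dCt values within groups.
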