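# silencerscan

Genome-wide discovery and characterization of **silencer elements** —
distal cis-regulatory elements that repress transcription. Enhancers have
well-known chromatin signatures; silencers do not, so this package
implements a subtraction-first strategy for anyone analyzing
open-chromatin, histone-mark, reporter-assay and 3D-contact data:

1. **Subtractive candidate calling (SSA).** Per cell type, remove from
   DNase hypersensitive sites (DHS) everything with a known identity —
   enhancers (H3K4me1), promoters (H3K4me3 plus −2000/+500 TSS windows)
   and insulators (pooled CTCF) — leaving *uncharacterized CREs*.
2. **MPRA silencer calling.** From RNA/plasmid count tables, per-replicate
   library-normalized ratios give each element an activity (fold change)
   normalized to control-random regions; a one-tailed t test on log2
   ratios against the pooled controls with Benjamini–Hochberg correction
   calls silencers at activity < 1 and q < 0.05.
3. **Sequence classifier.** A gapped k-mer featurization (length-l words
   with k informative positions, reverse-complement collapsed, explicit
   sparse counts) plus a linear SVM trained on the screen's activity
   extremes generalizes silencer calls to untested elements; performance
   is reported as held-out AUROC/AUPRC and candidates are called at the
   maximum-accuracy score threshold.
4. **Characterization.** Permutation overlap tests (P = (Σn+1)/(N+1)),
   hypergeometric GWAS-trait enrichment with LD expansion (r² ≥ 0.8),
   chromHMM state composition with permuted baselines, methylation and
   conservation averaging over value tracks, promoter-capture Hi-C target
   assignment (≥ 10 kb bait/other-end gap) with expression binning and
   one-tailed Wilcoxon comparisons, silencer-to-enhancer switching and
   footprint density.

A synthetic-data generator (`silencerscan.synth`) produces every input
class — peak tracks, sequences, count tables, interactions, SNP catalogs,
value tracks, segmentations — with planted ground truth, so the entire
pipeline runs and is tested offline. See `docs/methods.md` for the model
and its assumptions.

## Worked example

```python
from silencerscan import SynthConfig, run_pipeline

report = run_pipeline(SynthConfig(seed=1))
print(report.summary())
```

prints

```
silencerscan end-to-end report
----------------------------------
uncharacterized CREs: cell_0: 2000, cell_1: 2000, cell_2: 2000
MPRA silencers: 862 (43.1% of tested)
  realized FDR 0.072, power 1.000
classifier held-out AUROC 0.886, AUPRC 0.871
  candidate fraction among scored elements 48.0%
methylation means: silencers 0.701, enhancers 0.403
conservation means: silencers 0.201, enhancers 0.190
top chromHMM states: Quies 0.63, ReprPCWk 0.18, TxWk 0.10
p-CHiC: 95.7% of silencer-contacted genes at RPKM <= 2 (silencer-vs-enhancer Wilcoxon p = 0.00e+00)
enriched trait/cell pairs (q < 0.01): [('cell_0', 'trait_0')]
silencer-to-enhancer switching: aggregate 5.8%
footprints per element: silencers 1.10 vs enhancers 4.40 (p = 0.00e+00)
```

Reading the numbers: the subtractive step recovers exactly the 2000
planted uncharacterized CREs per cell type; 43.1% of tested elements are
called silencers at 5% FDR (the generator plants 40% true silencers at
activity 0.3, and the realized false-discovery rate against the planted
truth is 0.072); the sequence classifier separates activity extremes at
held-out AUROC 0.886; silencers are hypermethylated (70%) relative to
active enhancers (40%); silencer-contacted genes are overwhelmingly
inactive or lowly expressed; and the one SNP-enriched (trait, cell) pair
planted by the generator is the one recovered.

The same stages are available as a CLI for file-based workflows:

```bash
silencerscan synth --seed 1 --out data/
silencerscan ssa --config ssa.yaml --out ucres/
silencerscan mpra --rna data/mpra_rna.tsv --plasmid data/mpra_plasmid.tsv --out activity.tsv
silencerscan gkm train --fasta data/elements.fa --activity activity.tsv --model-out model.npz
silencerscan enrich gwas --snps data/gwas_leads.tsv --proxies data/ld_proxies.tsv \
    --silencers cell_0 silencers.bed --out traits.tsv
```

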