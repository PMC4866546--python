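# fragile-exon

Where in a gene's exon architecture do pathogenic point mutations
fall, and how much of that placement points at splicing?

Pathogenic SNPs - including synonymous ones - frequently act by
disrupting splicing rather than (only) by changing protein sequence.
Because exonic splicing enhancers (ESEs) cluster near exon ends, the
positions of disease mutations relative to exon junctions, flanking
introns, boundary phases and splice-site tetranucleotides carry a
splicing signal. `fragile-exon` is a toolkit for geneticists and
molecular evolution researchers that quantifies that signal on any
gene annotation + variant table:

* **Domain enrichment** - observed vs length-expected SNP counts over
  splice-site (d <= 3 bp), exon-end (3 < d <= 69 bp) and exon-core
  (d > 69 bp) domains of internal exons, with fo/fe ratios and a
  goodness-of-fit chi-squared; per-exon-half variants and exon-class
  (symmetric (0,0) phase, AGgt/agGT splice-site) enrichments.
* **Splice-affecting fraction** - a background-removal estimator: the
  SNP rate in deep exon cores (central 100 bp of exons > 300 bp) is
  the splice-unrelated background N/L; the flank excess
  Q - M·N/L, divided by all internal-exon SNPs S, estimates the
  fraction of pathogenic SNPs acting through splicing (conservative
  mode), with a liberal mode that allows a share of core mutations to
  be splice-related, and a 50-100 bp cutoff robustness sweep.
* **Matched-nucleotide randomization** - gene-half, flanking-intron-
  size and exon-class tests against a null that re-places each SNP
  uniformly over same-gene positions carrying the same nucleotide,
  with empirical p = (n+1)/(m+1).
* **Density correlations** - per-exon pathogenic SNP density
  (Dpi = SNPs/exon length) against flanking intron size and against
  ESE hexamer density at exon ends (Spearman and Goodman-Kruskal
  gamma), plus a within-gene sign test on half-exon densities.
* **Cross-species cis-motif usage** - codon/amino-acid usage gradients
  near exon junctions, phase-zero splice-site proportions, genome
  architecture parameters (X, N, M) and a trait-table export for
  phylogenetic regression.
* **Synthetic data** - a generator of human-like gene models with
  planted SNP-placement effects and exact ground truth, used by the
  test suite for end-to-end parameter recovery and null calibration.

## Worked example

The background-removal arithmetic on a dataset's printed totals
(124 core SNPs in 70,700 core bp; 2,734,972 flank bp; 6,774 flank
SNPs of 8,250 internal-exon SNPs):

```python
import fragile_exon as fx

res = fx.estimate_from_counts(N=124, L=70_700, S=8_250,
                              M=2_734_972, Q=6_774, mode="conservative")
print(f"core rate N/L      : {res.core_rate:.6f} SNPs/bp")
print(f"expected flank SNPs: {res.P:.0f}")
print(f"splice fraction    : {res.fraction:.2%}")
```

```
core rate N/L      : 0.001754 SNPs/bp
expected flank SNPs: 4797
splice fraction    : 23.97%
```

About 24% of these pathogenic SNPs sit at exon ends in excess of the
core background - the conservative estimate of the splice-affecting
share. The same pipeline on a synthetic genome with planted
end-enrichment (domain multipliers 8/4/1) and a 1.5-fold 3'-gene-half
bias:

```python
cfg = fx.SimulationConfig(n_genes=60)
models, genome = fx.simulate_genes(cfg, rng=101)
truth = fx.SyntheticTruth(domain_multipliers=(8.0, 4.0, 1.0), gene_half_bias=1.5)
variants, realized = fx.plant_pathogenic_snps(models, truth, 2500, rng=102,
                                              hexamers=cfg.hexamers)
records = fx.annotate_all(fx.raw_variants_from_frame(variants), models,
                          include_nonsense=True)
enr = fx.domain_enrichment(records, models)
gh = fx.gene_half_test(records, models, m=100, rng=7)
```

```
fo/fe splice_site : 2.79
fo/fe end         : 1.31
fo/fe core        : 0.32
chi2 = 682.3, df = 2, p = 6.93e-149
3'/5' ratio = 1.58, p = 0.0099
```

The planted ordering (splice-site > end > 1 > core) is recovered, and
the gene-half randomization hits its floor p-value (no null replicate
among 100 reaches the observed 3'/5' ratio).

A CLI mirrors the main entry points:

```bash
fragile-exon simulate --out fixtures --n-genes 60 --n-snps 2500 --seed 1
fragile-exon enrich --genes fixtures/genes.genePred.tsv \
    --genome fixtures/genome.fa --variants fixtures/variants.tsv
fragile-exon splice-fraction ... --mode conservative --cutoffs 50:100:5
fragile-exon randomize ... --test gene-half --m 100 --seed 17
```

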