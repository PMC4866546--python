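# Methods

This note documents the models, statistics and numerical choices behind
`fragile-exon`, in the spirit of the methods documentation of packages
such as statsmodels or msprime: what is computed, under what
assumptions, and what the synthetic validation does and does not show.

## Gene models and coordinates

A gene is represented by its coding portion only: exons are clipped to
the annotated CDS (ATG through the stop codon), UTR-only exons are
dropped, and everything is strand-normalized so exon 1 is the 5'-most
exon of the transcript and all sequences read in transcript
orientation. External inputs follow their format conventions (genePred
and BED12 are 0-based half-open, VCF is 1-based); internal coordinates
are 0-based half-open, and all reported positional statistics are
1-based in transcript orientation.

Validity filters remove genes whose CDS is not a codon multiple, does
not start with ATG, does not end with a stop codon, contains an
internal in-frame stop or an ambiguous nucleotide, or has no intron.
The rule order is fixed (frame, start, stop, internal stop, ambiguity,
intronless) so removal reports are deterministic; each gene is charged
to the first rule it fails. The frame rule is listed first because all
codon-level statistics presuppose an in-frame CDS.

Per-exon architecture: the 5'/3' boundary phases are the cumulative CDS
length modulo 3 (phase 0 = boundary between codons; a "symmetric (0,0)
exon" has phase 0 at both ends); junction tetranucleotides follow the
exon-uppercase / intron-lowercase convention, so an exon ending `...AG`
before an intron starting `gt...` has donor class `AGgt`, and an exon
starting `GT...` after `...ag` has acceptor class `agGT`.

## Exon domains

Each exon position p (1-based) is assigned a distance to the nearest
junction, d = min(p, length - p + 1), and a domain: splice-site
(d <= 3), exon end (3 < d <= 69), exon core (d > 69). The boundaries
are inclusive as written, which makes the three classes a partition for
any exon length; exons too short for two full domains are handled by
the same min-distance rule with no special case. The 3 bp and 69 bp
cutoffs are the analysis defaults and are configurable (`DomainSpec`).
In the per-half variant each exon is split at ceil(length/2) and
distances are measured to that half's own junction only.

## Enrichment statistics

The expected domain distribution is length-based: over the SNP-bearing
internal exons, the bp of each domain is summed and divided by the
total bp. Observed SNP counts are tested against it with a plain
Pearson goodness-of-fit chi-squared (df = labels - 1, no continuity
correction), and per-label preference is reported as fo/fe = observed
proportion / expected proportion. The same machinery serves two-class
enrichments (donor-AGgt exons, symmetric (0,0) exons) with the class's
bp share as the expectation.

**Caveat found during validation:** conditioning the expected
distribution on SNP-bearing exons biases the null when SNPs are sparse.
A short exon enters the expected set only if it was hit, and short
exons are flank-dominated, so even uniformly placed SNPs show a mild
apparent end enrichment. The bias vanishes as per-exon coverage
approaches 1; the null-calibration fixtures are therefore generated
dense enough that essentially every internal exon carries a SNP. Users
comparing sparse datasets should keep this conditioning in mind.

The gene-level exon-count comparison regresses exon count on CDS length
with lowess over the pooled disease + non-disease genes and compares
group residuals with a two-sided Mann-Whitney U test. The lowess
smoother is local-linear with span 0.75 by default (configurable); a
rank test on residuals is insensitive to the local polynomial degree at
these sample sizes.

## Background-removal estimator of the splice-affecting fraction

Core regions are the central 100 bp of internal exons longer than
300 bp; their SNP rate N/L estimates the splice-unrelated background.
Conservative mode extrapolates that rate over the flank bp M (every
internal-exon position with d <= cutoff, splice-site bp included),
predicts P = M N/L flank SNPs, and attributes the excess to splicing:
fraction = (Q - P)/S with S all internal-exon SNPs. Liberal mode
assumes a fraction (default 0.25) of core mutations also act through
splicing, deflates the background to (1 - 0.25) N/L, and spreads it
over all internal-exon bp T: fraction = (S - T rate)/S. Negative
excesses clamp to zero with a warning. A cutoff sweep (50..100 bp by 5)
recomputes M and Q per cutoff.

Two deliberate conventions: the conservative denominator is S, the
internal-exon SNP total (an alternative N + Q denominator is exposed
via `denominator="methods"`), and a `printed_rounding` switch truncates
the liberal background rate to 4 significant figures and the expected
count to an integer, reproducing fixed-precision hand arithmetic
exactly; the default keeps full precision.

## Matched-nucleotide randomization

All three randomization tests share one null: for each real SNP, each
replicate draws one pseudo SNP uniformly from the positions of the SAME
gene (all coding-exon positions for the gene-half test; internal-exon
positions for the intron-size and exon-class tests) that carry the SAME
reference nucleotide. This conditions on gene identity and nucleotide
composition, removing expression-level and base-content confounds. One
pseudo SNP per real SNP per replicate makes the replicate statistic
directly comparable to the observed one. The empirical p-value is
(n + 1)/(m + 1) over m replicates (default 100, floor p = 0.0099), with
n the replicates at least as extreme in the stated direction.
Replicates use deterministic child streams of a single seed, so results
are exactly reproducible; SNPs whose gene has no matching-base position
in the region are skipped with a warning.

The intron-size test compares, per replicate and per SNP, the pseudo
flanking intron with the real one (the flanking intron is the one
nearest the SNP; the longer of the two at an exact tie). A counts
pseudo-larger pairs, B pseudo-smaller; exact ties are excluded from
both, the standard sign-test convention - counting ties into A (a
pseudo SNP frequently lands in the same exon as its real SNP) would
inflate A under the null and destroy Type-I calibration. Each replicate
gets an exact two-sided binomial test on (A, A + B) (minimum-likelihood
two-sidedness, as implemented by scipy); the overall empirical p counts
replicates with A <= B.

The within-gene Dpi sign test uses half-exon densities
(5'-Dpi = SNPs in the 5' half / (length/2), and likewise 3') paired
with the adjacent flanking intron, two points per internal exon, for
genes with at least five SNP-bearing internal exons; the sign of the
per-gene Spearman rho is tallied (zero or undefined rho excluded) and
an exact one-sided binomial tests for an excess of negative genes at
p0 = 0.5. Note that for a 136-negative vs 99-positive split this
standard test gives p ~ 9.4e-3; published analyses sometimes quote
other variants (e.g. two-sided or normal-approximate values), so exact
agreement with any particular quoted p should not be expected. All
internal exons of qualifying genes enter by default (zero-Dpi halves
included); a SNP-bearing-only mode is provided.

## Densities and rank association

Dpi = SNP count / exon length (0 for unhit exons). ESE density of a
window is the fraction of hexamer start positions (window length - 5,
overlapping matches counted) whose 6-mer belongs to the ESE set; this
normalization bounds the density in [0, 1]. An exon's end density is
the mean over its two terminal 69 bp windows, or one whole-exon window
below 138 bp. For exon-level Dpi vs intron-size correlations the
exon's flanking intron is the one nearest its median SNP position
(longer at a tie), or the shorter flanking intron for unhit exons;
logs of intron size are natural logs, immaterial to rank statistics.
Goodman-Kruskal gamma is (C - D)/(C + D) over all pairs with ties
excluded, p from the large-sample normal approximation
z = gamma sqrt((C + D)/(n(1 - gamma^2))); gamma is preferred alongside
Spearman because zero-Dpi exons create heavy ties.

The ESE hexamer list is a plain-text input (one uppercase 6-mer per
line), matching published hexamer collections. The bundled default is
a synthetic stand-in built from purine-rich non-stop codon pairs
(GAR-like), chosen so the generator can implant motifs codon-aligned
without ever creating a stop codon; it is not a curated ESE set and is
labelled accordingly.

## Cross-species cis-motif usage

Codon (61 sense codons) or amino-acid (20) usage in internal exons is
tabulated as a function of the distance in codons from each junction,
distances 2..34; codons adjacent to either boundary are excluded, and a
codon spanning a junction belongs to the exon holding two of its three
bases. Per item and per end, a two-tailed Spearman correlation of
proportional usage against distance is computed; an item counts toward
the species metric if it clears a Bonferroni threshold (alpha divided
by the item-family size, applied per end - the family size and a
joint-ends variant are configurable) at BOTH ends. A seeded fixed-n
exon subsample makes species with different exon counts comparable.
Species-level architecture parameters are the proportion of phase-zero
internal junctions, X = mean CDS/gene length, N = introns per kb exon,
M = mean intron size. The trait-table exporter writes a headerless
species-by-trait TSV checked against the newick tree's tip set, ready
for external continuous-trait phylogenetic regression (running such
MCMC analyses is outside this package's scope).

## Synthetic data generator

The generator emulates the architecture features the pipeline measures,
not real human sequence. Defaults: exon counts 3 + NB(mean 6), exon
lengths 50 + NB(mean 120, dispersion 0.5) bp (overall mean ~170 bp
with a heavy tail, so that a realistic share of internal exons exceeds
the 300 bp core-region threshold and the background-rate estimate is
well determined), intron lengths log-normal (median ~1.3 kb), GC 0.45,
junction phases drawn from (0.47, 0.30, 0.23), AGgt donors at rate
0.35 (optionally phase-0 boosted) and agGT acceptors at 0.20 against
invariant gt..ag introns. The CDS is built from non-stop codons with
ATG start and a single terminal stop; forced junction dinucleotides and
codon-aligned ESE implants resolve any incidental stop by mutating an
unconstrained base, so every generated gene passes the validity
filters by construction.

SNPs are planted with per-position probability proportional to a
product of truth multipliers: exon domain (splice-site/end/core), gene
half, flanking intron size ((1 kb / intron)^effect), exon class
(phase00, donor AGgt), and ESE density (1/(1 + coupling * density)).
Alternate alleles are uniform over the three alternatives and
consequences (silent/missense/nonsense) are derived from the actual
codon change. The implied splice-affecting fraction of a truth is
computed exactly as 1 - sum(baseline weights)/sum(weights), where the
baseline sets the domain mechanism to its core value; a helper solves
the flank multiplier that yields a requested fraction.

What passing the synthetic suite shows: coordinate arithmetic,
estimator algebra and test calibration are correct under known truth.
What it does not show: behaviour under real mutation-rate
heterogeneity, curated-database ascertainment, isoform complexity or
real ESE biology - none of which the generator models.

## Problem sizes and tolerances

Fixture sizes were chosen so each check's sampling error is well inside
its asserted tolerance: fraction-recovery runs use 200 genes and 8,000
planted SNPs (estimator SD ~0.02 against a +/-0.05 band, dominated by
the Poisson error of the core-region SNP count), Type-I calibration
uses 100 independent seeds of 400 uniform SNPs, and ordering/sign
recovery uses 2,000-3,000 SNPs. Worked-example reproductions are exact
to the printed precision except the domain chi-squared, which is
checked to 1% because the printed expected proportions are themselves
rounded (they sum to 100.01%).
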