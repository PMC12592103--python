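# Methods

This note records the models, conventions and design decisions behind
`salsel`, in the spirit of a statistical-methods appendix: what is
computed, under which assumptions, with which defaults, and what the
synthetic experiment does and does not emulate.

## The experimental design being modeled

A single source population of a euryhaline marine invertebrate is split
into one control tank (ambient salinity) and three replicate high-salinity
treatment tanks, 200 individuals each. Mortality is censused every 12 h
for 5 days. Survivors are sampled for whole-genome SNP genotyping
(sequencing cohorts of 19 control and 10/11/10 treatment individuals) and
RNA-seq. The scientific question is whether treatment mortality is
genotype-dependent — i.e., whether the survivors are a selected, not a
random, subset — and if so, where in the genome and with what functional
correlates.

## Survival stage

Interval mortality per census is `100 x deaths / alive-at-start`; a census
with nobody alive yields a missing value rather than an error. Control and
treatment interval-mortality distributions are compared with the
two-sided two-sample Kolmogorov–Smirnov test, using the exact
small-sample null distribution whenever `n*m <= 10,000` and the
asymptotic form otherwise. Because the design does not dictate whether
replicates are pooled for this test, both the pooled and the
per-replicate comparisons are reported.

## Variant QC

The filter chain is: (1) mask individual genotype calls with GQ ≤ 10 or
depth outside [10, 100]; (2) drop non-biallelic sites; (3) drop sites
whose post-masking missingness exceeds 30%; (4) drop sites with MAF
< 0.05 computed jointly across the analysis cohort. Genotype-level
masking precedes site-level filters because GQ and depth are per-call
quantities in the standard toolchain; a site can therefore be lost to
missingness purely through masking, and the drop tally records the first
rule that removed each site. Missingness is per-site; a per-sample
missingness report is emitted for inspection.

LD pruning follows indep-pairwise semantics: windows of 50 variants
advancing by 10, pairwise-complete dosage r² (pairs with fewer than five
complete observations are skipped), removal of the lower-MAF member of
any pair with r² > 0.2 (ties remove the later position), greedy in
position order. Unlike the single-pass tool behaviour, passes repeat with
windows rebuilt over the survivors until nothing changes; this makes the
operation idempotent (re-running on its own output is a no-op), which we
treat as a contract of the stage.

## Diversity statistics

* **Ho** per sample is the heterozygous fraction of its non-missing
  calls. **He** per sample is the mean of 2p(1−p) over the sample's
  non-missing loci with p estimated from the full cohort — a per-sample
  expected heterozygosity in the style of per-sample tool outputs (the
  quantity is not uniquely defined in the literature; this definition is
  recorded here as ours). Group contrasts use two-sided Wilcoxon rank-sum
  tests (exact when tie-free and small) with Benjamini–Hochberg
  adjustment across treatment-control pairs.
* **π** per site is `c_ref * c_alt / C(c_total, 2)` over called alleles;
  window π sums sites within non-overlapping 5-kb tiles and divides by
  the tile length. Tiles without variants are omitted: in a variants-only
  input they are indistinguishable from no-data regions. Group means
  weight windows equally.
* **Allelic richness** uses hypergeometric rarefaction to the smallest
  non-missing allele count across groups at each locus
  (`Ar = Σ_alleles [1 − C(N−N_i, g)/C(N, g)]`); loci with g < 2 are
  skipped.
* **PCA** mean-imputes missing dosages per variant, centers, and
  eigendecomposes the sample Gram matrix; no allele-frequency scaling
  (plain covariance), which is the more conservative choice for cohorts
  this small.
* **FST** is Weir & Cockerham's (1984) two-population θ from the a/b/c
  variance components with heterozygosity terms, combined across loci as
  a ratio of sums. Negative per-locus values are reported as computed.
  Significance comes from bootstrapping loci with replacement (default
  1000 resamples); p is the fraction of resampled θ ≤ 0, a one-sided test
  against "no differentiation". The bootstrap unit is the locus because
  the design provides no independent replication unit below that.

## Composite selection scan

For each treatment-vs-control comparison, windowed θ (ratio of sums per
5-kb tile) is Z-standardized across windows; the volcano pairs
ZF<sub>ST</sub> with log2(π_control / π_treatment). Windows lacking a
defined θ or lacking variants with defined π in either group are excluded
rather than pseudocounted, mirroring the upstream omission of empty
windows. Candidate intervals are windows with ZF<sub>ST</sub> at or above
the empirical 95th percentile (linear-interpolation quantile; ties at the
threshold included) *and* a strictly positive diversity ratio. Windows
with top ZF<sub>ST</sub> but a negative ratio (diversity reduced in the
control) are emitted for the volcano but never feed focal designation.
Intervals flagged in at least two of the three replicate comparisons are
"robust".

The neutral null is the empirical distribution of major-allele frequency
change at fourfold-degenerate (4DTV) sites lying outside every flagged
interval (flagged by any comparison, not only robust ones — the stricter
exclusion). The major allele is fixed in the control survivors (ties at
0.5 resolve to the reference allele) and Δf = f_treatment − f_control of
that allele, so the worked orientation check — a control-major allele at
63% dropping to 42% — reads −0.21. The band is the 5th–95th percentile of
this distribution, computed per comparison; a site exactly at a
percentile does not "exceed" it (strict inequalities).

A focal SNP, per comparison, passes all three rules: per-SNP θ at or
above the empirical 95th percentile (per comparison; a pooled-comparison
variant is available), Δf outside the open null band, position inside a
robust interval. The union over comparisons is reported with full
per-comparison provenance.

Two statistical properties of this construction are worth stating
plainly, because they surface in the acceptance suite:

1. Under pure drift, per-SNP θ rank and |Δf| are strongly positively
   dependent — both are monotone functions of the same sampling
   deviation — so the joint fraction of SNPs passing both marginal
   criteria (~4% at these cohort sizes) is an order of magnitude above
   the independence product 0.5%. The interval requirement is what
   restores stringency: the full three-rule focal fraction under the null
   is ~5 × 10⁻⁴.
2. Fixing the major allele in a finite control cohort (19 samples)
   induces a winner's-curse asymmetry in the null Δf distribution
   (median ≈ −0.007, skewness ≈ −0.23 at these sizes). The band is an
   empirical quantile of the same distribution, so the focal criteria
   remain internally calibrated, but the distribution itself is not
   symmetric.

## Annotation

Gene models are read from GFF3 (converted internally to 0-based
half-open). Region priority is exonic > 5'UTR > 3'UTR > intronic >
upstream > downstream > intergenic, with upstream/downstream within
5 kb of the gene span, strand-aware; among equal labels the nearest gene
wins, then the lexicographically lower id. Coding effects rebuild the
containing codon strand-aware with phase and translate with the standard
code; multi-transcript genes report the most severe effect. 4DTV sites
are third-codon positions where all four bases encode the same amino
acid, required to be fourfold in *every* containing codon when
transcripts overlap. Intergenic SNPs are assigned their nearest gene and
flagged as such. Enrichment is upper-tail hypergeometric over a universe
defined as the genes overlapping at least one analyzed SNP (the
candidate-gene framing; switchable), with BH control, and a
case-insensitive whole-word keyword screen for osmoregulation-related
terms that flags rather than removes.

## Expression

TPM is the length-rate normalization to one million per sample. The DE
rule is fold change > 2 on pseudocounted group mean TPM (pseudocount
1 TPM) together with BH-adjusted p < 0.05 from a two-sided rank-sum test
per gene. This distribution-free test stands in for a negative-binomial
shrinkage model deliberately: the design's inferential claim about the
DEG count rests on the label-permutation null, which is implemented
exactly — labels permuted preserving the unbalanced group sizes, the DEG
count recomputed per permutation under the identical rule, and
p = (1 + #{perm ≥ observed}) / (n_perm + 1). The add-one estimator never
returns zero; note that a count statistic with an atom at zero makes this
p valid but conservative (under a true null it concentrates at 1), not
uniform. Genotype–expression links report, per focal SNP and its gene,
group-wise allele and genotype frequencies, group-wise median TPM, a
group-level rank-sum p, and a rank-sum p between the extreme genotype
classes when both hold at least three samples.

## The synthetic experiment

The simulator emulates the study design at desk scale; one seed drives
everything through fixed-order named substreams, so outputs are
byte-identical across runs.

* **Genome and genes**: 14 chromosomes of 800 kb (matching the real
  genome's SNP density of ~1.8/kb at 20,000 variants), 200 three-exon
  genes with UTRs and phase-consistent CDS.
* **Variants**: 20,000 biallelic SNPs; 15% placed at fourfold-degenerate
  codon positions of the emitted models; 20 selected loci placed in first
  introns of 20 distinct genes (which become the expression-linked
  genes); ancestral frequencies from a U-shaped folded-spectrum Beta(0.6,
  0.6) scaled to [0.05, 0.95]; selected loci at U(0.48, 0.52) so their
  shift potential is maximal. Genotypes are Hardy–Weinberg; observed
  calls add 1% missingness plus GQ/depth artifacts for the QC stage to
  remove; the error-free genotypes drive selection and expression.
* **Mortality**: treatment death probability per census is
  `1 − (1−shock_t) · exp(−λ_t · exp(Σ β g))`, a complementary-log-log
  hazard. λ_t is a narrow bell (Gaussian in census index, peak 5.5, width
  0.7 — maximal mortality at 48–72 h) whose amplitude is calibrated by
  root-finding so expected treatment survival is 4.7%; shock_t =
  (5%, 7%) at the first two censuses is a genotype-independent
  transfer/handling mortality, and the control tank dies at a constant
  genotype-independent 0.6% per census. The shock makes treatment
  mortality distributionally separated from control at every census
  (without it, half the treatment censuses are exactly zero and tie with
  control zeros, collapsing the K-S statistic); being
  genotype-independent it cancels exactly from all allele-frequency
  expectations. The narrow bell keeps early hazard negligible even for
  the highest-risk genotypes, so the realized curve stays bell-shaped
  under strong selection; per-locus effects are β = 1.5 on the log
  hazard, additive across loci, no epistasis.
* **The viability oracle**: whole-experiment survival given burden
  x = Σβg is exp(−Λe^x) with Λ the summed bell. The expected survivor
  allele frequency at each locus integrates over the exact
  background-burden distribution of the other loci (a dynamic-programming
  convolution, exact for a shared β); for a single locus this reduces to
  the per-census genotype-frequency recursion. Under the defaults every
  selected locus has an expected survivor shift of ≥ 0.154. This is
  close to an information bound: at ~5% survival the total selection
  intensity i·σ_x is shared across 20 loci, capping the per-locus shift
  near i·β·2pq/σ_x ≈ 0.16 regardless of how large β is made. A
  consequence worth knowing before interpreting recovery numbers: with
  sequencing cohorts of 19/10/11/10, the sampling standard error of a
  cohort allele-frequency difference (0.11–0.14) is of the same order as
  the true shift, and every threshold in the scan is an empirical
  quantile of that same noise, so single-locus recovery power at this
  design size is intrinsically low. The pipeline reports recall and
  precision against the planted truth rather than asserting them.
* **Expression**: negative-binomial counts (dispersion 0.2), lognormal
  base means (median 100), library sizes uniform in [0.5, 2] (≤ 4-fold),
  a mild gene-by-sample latent factor (log2 sd 0.15) for realistic
  correlated noise, and a log2 shift of 2 per alternate allele for the
  20 linked genes. Because the between-group expression signal comes
  only through the survivor allele-frequency difference, group-level
  fold changes for linked genes are ≈ 2^(2·Δdosage) ≈ 1.5–2.5 at the
  default shifts — around the DE rule's threshold — so genome-wide DEG
  counts at default scale are small; strong DE appears for loci whose
  realized shifts are large.
* **Term map**: ~25 GO-style terms (10 osmoregulation-flavoured, 15
  generic); linked genes are preferentially assigned to
  osmoregulation-flavoured terms so enrichment has a planted signal when
  focal recovery succeeds.

What the simulator does **not** emulate: linkage disequilibrium and
recombination (loci are independent, so LD pruning removes only sampling
correlation), sequencing read-level error, population structure in the
source, direct (genotype-independent) treatment effects on expression,
and reproduction during the experiment. Passing tests therefore
demonstrate correctness of the statistical machinery and calibration
under drift-plus-viability-selection, not robustness to LD or batch
structure in real data.

## Numerical conventions

Empirical quantiles use linear interpolation; ties at outlier thresholds
are included; null-band boundaries are strict. Z-standardization uses the
sample standard deviation and maps a zero-variance vector to all zeros.
Bootstrap and permutation draws take an explicit generator or seed.
Missing dosage is coded −1 and excluded pairwise from every statistic.
Division-by-zero cases (no called alleles, empty windows, zero-count
samples) yield missing values with warnings, not errors, except where an
input contract is violated (negative counts, zero-length genes,
mismatched census grids), which raise.

## Known limitations

The scan's per-SNP criteria are strongly mutually dependent under drift
(see above), so marginal-criterion counts should not be multiplied as if
independent. The permutation p for the DEG count is conservative, not
uniform, under the null. Recovery of individually selected loci at the
study's cohort sizes is noise-limited; the design's strength is the
window/replicate-sharing construction, which controls the null focal rate
(~5 × 10⁻⁴) rather than guaranteeing recall. Effect sizes are additive on
the log hazard with a single shared β; heterogeneous or epistatic
architectures are not modeled.
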