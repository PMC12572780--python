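# Methods

## The inference chain

The package detects and genotypes a non-recombining supergene from a
biallelic SNP genotype matrix plus per-sample phenotype/colony metadata.
Genotype calls are kept as {hom-ref, het, hom-alt, missing}; coordinates
are 1-based inclusive throughout (VCF/GFF3 convention), and missing calls
are never imputed at the I/O layer.

1. **Variant filtering** mirrors vcftools semantics: per-call depth
   masking first (`minDP`, default 3), then site-quality (`minQ`, default
   20, sites with quality < threshold dropped), then the missingness filter
   (`max-missing` 0.6 keeps sites with ≥ 60% called genotypes). Depth
   masking feeds the missingness count, so a well-genotyped site can still
   fall to the missingness filter after losing low-depth calls. The filter
   is idempotent and never reorders samples or sites.
2. **Windowed F<sub>ST</sub>** uses the Weir & Cockerham (1984) variance
   components (*a*, *b*, *c*) computed per site from per-population
   genotype counts; windows tile each chromosome (default 10 kb) and report
   both the ratio-of-sums ("weighted") estimate Σa/Σ(a+b+c) — the scan
   statistic — and the mean of per-site ratios. Negative estimates are
   reported, not clamped; sites monomorphic overall, or with an empty
   population, carry not-a-value and drop out of the sums. The groups
   scanned are the queen morphs classified from head width (macrogynes
   > 1.08 mm vs microgynes < 1.04 mm; the 1.04–1.08 mm interval is closed
   and called intermediate), the most contrasted pair.
3. **Detection** thresholds the weighted window values and takes the
   longest gap-tolerant run (≤ 2 below-threshold or empty windows inside,
   configurable), requiring a minimum span of 10× the window size.
   Two refinements operationalise the run rule:
   * *Threshold percentile.* The conventional rule highlights windows above
     the genome-wide 95th percentile, which presumes the differentiated
     region occupies a small minority of windows (a few percent of a real
     genome). The desk-scale simulated genome is 2 × 10 Mb with a 2.7 Mb
     region — ~14% of windows — so a 95th-percentile threshold would fall
     inside the region's own F<sub>ST</sub> distribution and fragment the
     run. The pipeline default is therefore the 75th percentile, which on
     this geometry lands in the upper background tail; on genome-scale data
     use 95 (the `fst_percentile_threshold` default). An absolute threshold
     can be supplied instead.
   * *Edge refinement.* A permissive threshold lets isolated background
     windows chain onto the run via gap tolerance and drag the bounds
     outward. Terminal supporting windows with F<sub>ST</sub> below half
     the candidate's median supporting value are peeled off
     (`edge_trim_frac = 0.5`; 0 disables, recovering the plain run rule).
     Genuine region windows sit far above this cut, background strays far
     below, so the refinement is insensitive to the exact fraction.
4. **Rolling-window PCA** (default 50 kb windows) builds the per-window
   dosage matrix, imputes missing cells with the site mean, centers at 2p
   and scales by √(2p(1−p)) (plink-style variance standardisation,
   configurable), and takes PC1 from a singular decomposition. PC signs are
   arbitrary, so each window is oriented to correlate positively with the
   previous informative window; the first window gives the
   lexicographically smallest sample a non-negative score. Windows with
   < 2 polymorphic sites, or no dosage variance, are emitted empty.
5. **Genotype assignment** averages each sample's PC1 over the region's
   informative windows and clusters the scores by one-dimensional k-means
   with deterministic initialisation at the minimum, median and maximum
   score (k = 3). The middle cluster is AB; the outer clusters are oriented
   by majority call at the AB-heterozygous site set (mostly hom-ref → AA;
   an exact tie labels the low-PC1 cluster AA, with a warning). Validation
   requires AB to have the strictly highest mean region heterozygosity,
   otherwise assignment raises. If the scores support only two clusters
   (an empty middle cluster, or a center gap below 10% of the score range,
   or fewer than three distinct scores), two clusters are reported with a
   warning rather than forcing a third; a lone cluster is labelled AB only
   when its heterozygosity is both 1.5× the other cluster's and above 0.35
   in absolute terms, i.e. clearly heterozygote-like.
6. **Diagnostic SNPs**: sites heterozygous in *every* AB sample (strict —
   a missing AB call excludes the site), then opposing fixation between AA
   and BB among non-missing calls (equivalent to per-site θ = 1; each group
   needs ≥ 1 call), then intersection with the CDS of each gene's longest
   isoform (largest summed CDS length; ties to the lexicographically
   smallest transcript id). "Within-exon" is interpreted as within-CDS.
   Genes are ranked by diagnostic-SNP count, ties broken by genomic
   position then gene id.
7. **Associations**: Kruskal–Wallis (tie-corrected) on head width across
   genotype classes with Dunn rank-sum post hoc z tests (Holm adjustment by
   default, Benjamini–Hochberg selectable — the choice is not critical and
   both are exposed); Fisher exact tests (two-sided, point-probability rule
   with the conventional 1 + 1e−7 tolerance) on colony type × genotype
   class (a colony is AA if any resident queen is AA; colonies are the
   unit, which reproduces both published P values from the published
   counts) and genotype class × matriline count (1 vs > 1).
8. **Matrilines** are estimated by parsimony: the minimum number of blocks
   partitioning a colony's workers such that each block is
   family-consistent under haplodiploid inheritance. Monandry requires a
   shared paternal allele and ≤ 2 maternal alleles per locus; polyandry
   only a shared diploid mother. Exhaustive branch-and-bound partition
   search for ≤ 9 workers, otherwise a greedy cover (seeded at the worker
   with fewest compatible peers) whose block count upper-bounds the exact
   minimum. Missing locus data is uninformative and never falsifies a
   family. This replaces likelihood-based sibship reconstruction with a
   deterministic, auditable criterion; it has no per-call genotyping-error
   model, so error-prone data will inflate matriline counts.

## The synthetic-data generator

The generator emulates the downstream data of a queen-size-dimorphic ant
survey at desk scale. Defaults (all in `SimConfig`):

* Genome: 2 chromosomes × 10 Mb, SNP density 1/500 bp (~20 000 sites per
  chromosome); the supergene occupies 2.0–4.7 Mb of chr1 (2.7 Mb, a scaled
  version of a ~9 Mb region on a ~480 Mb genome).
* Haplotypes are mosaics of 8 founders with copy-switches at 10⁻⁶ per bp,
  producing LD that decays with distance in background. Inside the region
  there are two founder pools (A, B) with no exchange between pools; a
  fraction *d* = 0.5 of interval SNPs is fixed ref-vs-alt between pools
  (pool A carries the reference allele) and the rest are shared
  polymorphisms whose per-site base frequency is Beta(0.8, 0.8), drawn by
  both pools from the same base. The within-interval, within-pool switch
  rate defaults to 0: suppressed recombination is the defining property of
  such a region, and a nonzero rate would leak distance-dependent LD decay
  into it (it is exposed as `supergene_switch_rate`). With these values the
  expected AB region heterozygosity is d + (1−d)·E[2p(1−p)] ≈ 0.65 and the
  homozygote expectation (1−d)·(7/8)·E[2p(1−p)] ≈ 0.14 — the designed
  analog of the 60–63% vs 13–16% contrast such regions show.
* Cohort: 60 queens, AA/AB/BB assigned by largest-remainder quota from the
  class frequencies (default ⅓ each, i.e. exactly 20/20/20) and shuffled.
  Head width ~ Normal(class mean, 0.03 mm), truncated at zero and reported
  to 0.01 mm; class means 1.20/1.05/0.98 mm (AA/AB/BB), matching the
  reported per-class medians so the morph cut-offs (1.04, 1.08 mm) separate
  classes imperfectly, as in real data.
* Colonies: 20 monogyne (one AA queen each; with probability 0.15 a
  replaced earlier AA mother also contributed workers — serial polygyny,
  a second matriline) and 10 polygyne (2 + Poisson(1.2) AB/BB queens,
  truncated so the cohort's non-AA queens suffice, largest colonies shrunk
  first). 10 workers per colony; every mother singly mated; haploid fathers
  carry the B supergene haplotype with probability 0.5.
* Microsatellites: 5 loci × 8 equifrequent alleles; each worker inherits
  one maternal allele plus the paternal allele. Allelic dropout (het →
  apparent hom) and false-allele substitution rates default to 0.
* Annotation: genes tiled every 50 kb, 1–3 isoforms of 2–5 CDS segments.

All randomness flows from one seed through named substreams; outputs are
bit-identical for identical (config, seed). The generator records complete
truth (interval, per-sample class, per-site category, per-worker matriline
and parents, per-gene diagnostic tallies) as the oracle for every stage.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: sequencing/genotyping error and missingness in
the SNP matrix (calls are clean); coalescent population structure,
mutation-rate variation and recombination hotspots (the founder-mosaic
background is a caricature with roughly exponential LD decay); inversion
breakpoints and structural variation; environmental variance in head width
beyond a single Gaussian per class; microsatellite mutation. Degraded or
error-rich inputs will behave worse than the clean simulation suggests,
particularly the strict all-AB-heterozygous filter (sensitive to missing
calls) and the matriline parsimony criterion (sensitive to genotyping
error).

## Numerical choices

* Percentiles use linear interpolation between order statistics ("95th
  percentile" is otherwise ambiguous).
* The 1-D k-means is Lloyd's algorithm with fixed initialisation; it is
  deterministic and needs no randomness.
* LD r² is the squared Pearson correlation of dosages over
  pairwise-complete samples (composite LD, appropriate for unphased
  genotypes); pairs need ≥ 2 jointly called samples and non-degenerate
  variance, else not-a-value. Decay curves use a minor-allele-frequency
  filter of 0.05, 300 kb maximum distance and 10 kb bins; regions are
  thinned to at most 6000 evenly spaced sites (deterministic) to bound the
  pair count — at the default simulation size this thins only the 20 000
  background sites, and slope estimates use ordinary least squares on
  populated bin means.
* K80 distances exclude sites that are not A/C/G/T in both sequences; a
  non-positive log argument is reported as saturation (not-a-value with a
  flag) rather than an error.
* Fisher exact p values follow the point-probability two-sided rule with a
  1 + 1e−7 relative tolerance, the convention of the common statistical
  environments; the test suite verifies equality with exhaustive
  integer-arithmetic enumeration for all small-margin tables.
* Kruskal–Wallis with all observations identical returns H = 0, p = 1
  (no evidence) instead of the undefined tie-correction ratio.

## Problem sizes

The default simulation (60 samples × 40 000 sites, 30 colonies, 300
workers) runs the full pipeline in seconds; the acceptance script adds 200
colony-structure replicates and 100 microsatellite replicates and completes
in well under a minute. These sizes give the Monte-Carlo checks tight
operating bands while keeping every truth-comparison exact.

## Known limitations

Single supergene per genome and per scan; unphased analysis only (no D/D′,
no haplotype phasing); no hierarchical or multi-population F<sub>ST</sub>;
morph-based scan groups require both macrogynes and microgynes to be
present; the matriline estimator reports a parsimony minimum, which is a
lower bound on the true matriline count when allele sharing between
families causes collisions, and both mating modes are reported because the
data often cannot distinguish one multiply-mated mother from two sisters'
families.
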