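# supergene-scan

Discovery and genotyping of social supergenes from SNP genotype matrices.

Several ant lineages carry large non-recombining chromosomal regions —
*supergenes* — whose alternative haplotypes control queen phenotype and
colony social organisation (single- vs multiple-queen colonies). Because the
two haplotypes stop recombining, a supergene leaves a characteristic
multi-signal footprint in population sequencing data:

* a contiguous run of windows with extreme Weir–Cockerham
  F<sub>ST</sub> between phenotype groups,
* three clusters on local PC1 of the genotype-dosage matrix (the two
  opposite homozygotes, AA and BB, flanking the heterozygotes, AB),
* heterozygote excess in AB individuals across the region (most diagnostic
  SNPs are 0/1 in every AB sample),
* linkage disequilibrium that stays flat with distance inside the region
  while decaying outside it.

`supergene-scan` implements this entire inference chain as a tested,
reusable library for queen-size-dimorphic ants and similar systems:
vcftools-style variant filtering, windowed F<sub>ST</sub> scans
(Weir & Cockerham 1984 variance components, ratio-of-sums per window),
rolling-window PCA genotype assignment, extraction of fixed
haplotype-diagnostic coding SNPs with candidate-gene ranking, queen-morph
classification and genotype–phenotype statistics (Kruskal–Wallis, Dunn post
hoc, Fisher exact tests), and a parsimony matriline estimator for worker
microsatellite genotypes under haplodiploid inheritance. A seeded
synthetic-data generator plants all of this structure in a desk-scale
genome and records the ground truth, so every stage is testable end to end.

## The statistics at the core

Per site with populations *i* = 1..*r* (sample sizes *n<sub>i</sub>*, alt
allele frequencies *p<sub>i</sub>*, heterozygote frequencies
*h<sub>i</sub>*), the Weir–Cockerham variance components *a* (among
populations), *b* (among individuals within populations) and *c* (within
individuals) give θ = *a* / (*a* + *b* + *c*); a window's scan statistic is
Σ*a* / Σ(*a* + *b* + *c*) over its sites. The supergene call is the longest
run of above-threshold windows (gap-tolerant, edge-refined). Within the
called region, samples are clustered on mean PC1 by deterministic 1-D
k-means; the middle cluster is AB, and outer clusters are oriented AA/BB by
their majority call at sites heterozygous in all AB samples. Diagnostic
SNPs are the AB-heterozygous sites with opposing fixation between AA and BB
(per-site θ = 1), counted inside the longest isoform's CDS per gene. LD is
the squared Pearson correlation of genotype dosages (composite, phase-free).
K80 distances for mitochondrial identity checks use
d = −½·ln(1−2P−Q) − ¼·ln(1−2Q).

## Worked example

```python
from supergene_scan.pipeline import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(preset="paper-like", seed=1, outdir="out"))
stages = report["stages"]
print(stages["scan"]["call"])
print(stages["assign"]["class_counts"], stages["assign"]["mean_het_by_class"])
print(stages["associations"]["colony_fisher"])
```

prints (abridged):

```
{'chrom': 'chr1', 'start': 2000001, 'end': 4700000, 'n_windows': 270, 'threshold': 0.0195...}
{'AA': 20, 'AB': 20, 'BB': 20} {'AA': 0.144, 'AB': 0.650, 'BB': 0.116}
{'table': [[20, 0], [0, 10]], 'p': 3.33e-08}
```

The scan recovers the planted 2.7 Mb non-recombining region on chr1 exactly
(270 supporting 10 kb windows), assigns all 60 queens to the correct
AA/AB/BB class, and the AB class shows the expected heterozygote excess
(~65% vs ~12–14% in homozygotes). All 20 single-queen colonies carry AA
queens and all 10 multiple-queen colonies carry only AB/BB queens, giving a
Fisher exact p of 3.3 × 10⁻⁸ for the genotype–social-organisation link.
Inside the region the LD-decay slope is ~0 (−5.6 × 10⁻⁹ per bp) versus
−2.1 × 10⁻⁷ per bp in background — flat, as expected where recombination is
suppressed.

The same stages are exposed on the command line:

```bash
supergene-scan simulate --seed 1 --out simdata/
supergene-scan scan --vcf simdata/cohort.vcf --samples simdata/samples.tsv \
    --out windows.tsv --percentile 75
supergene-scan all --preset paper-like --seed 1 --out out/
```

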