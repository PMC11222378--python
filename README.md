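# allelescope

Read count-based analysis of allele-specific gene expression, chromatin
accessibility, and DNA methylation in reciprocal-cross hybrids.

## The problem

When two genetically divergent lines (here: Duroc and Lulai pigs) are
crossed reciprocally (A♀×B♂ and B♀×A♂), every F1 individual carries one
allele from each breed, and every sequenced read that covers an
*informative variant* — a site where the two parents are homozygous for
different alleles — reveals which parental genome it came from. Comparing
the two alleles inside the same nucleus removes all shared *trans* and
environmental variation, so allelic imbalance is a direct readout of
*cis*-regulatory divergence; the reciprocal design additionally separates

* **POE** (parent-of-origin effect): bias that follows the maternal or
  paternal origin of the allele — genomic imprinting at its extreme;
* **AGE** (allele-genotype effect): bias that follows the breed (sequence)
  of the allele, the signature of a *cis*-regulatory variant.

Rather than testing allele counts SNP by SNP (which over-disperses and
over-estimates bias), allelescope assigns whole sequenced *fragments* to
their parental genome of origin and feeds ordinary read counts into
count-based models:

1. **Individualized genomes** — each parent's homozygous SNPs and indels
   are substituted into the reference; a bidirectional coordinate map
   handles the indel-induced shifts (annotation liftover, and conversion
   of results back to the reference frame).
2. **Fragment assignment** — reads aligned against both parental genomes
   are scored at the informative sites they cover; a read is assigned to
   the genome matching strictly more of its alleles, an RNA read must also
   have ≥80% of its bases in constitutive exons, and the two mates of a
   fragment must not disagree (disagreements are discarded). Sample-level
   QC rejects samples whose paternal read fraction leaves [0.45, 0.55].
3. **Allelic model** — per feature, the two allelic counts of each sample
   are modeled as `count ~ POE + AGE + MG + Sex` (negative-binomial GLM
   with log total-allelic-library offsets; MG = maternal-breed covariate).
   CpG methylation uses the binomial analogue on (methylated,
   unmethylated) read-count pairs. Likelihood-ratio tests with BH FDR
   control, fold-change gates (>4× for RNA, ≥2× for ATAC), the 95%/5%
   imprinting rule and the 75%/25% strong-POE rule give the final calls.
4. **Regions & context analyses** — poeMR/ageMR calling (≥3 consecutive
   significant CpGs within 1.5 kb), priority interval annotation
   (promoter → 5'UTR → 3'UTR → exon → intron → intergenic), peak-to-gene
   aggregation, 16-fold tissue/stage specificity, the 27-class
   developmental-trend classifier, permutation enrichment and the 1-Mb
   pairwise clustering statistic.
5. **Synthetic data** — a full generator (`allelescope.sim`) emits
   reference + parental VCF + GTF + pre-aligned RNA/ATAC/bisulfite SAM
   reads with planted effects and truth tables, so the entire pipeline is
   testable end to end without external data or aligners.

## Worked example

`examples/03_allelic_model.py` simulates a balanced 6+6 reciprocal design
with 40 null genes, one planted POE gene (paternal allele 8× the maternal
in both cross directions) and one planted AGE gene (Duroc allele 8× the
Lulai allele whichever parent carried it), then fits and classifies:

```
feature_id effect   log2fc          fdr
  poe_gene    POE 2.977687 1.417452e-43
   null_32    AGE 0.616251 3.922827e-02
  age_gene    AGE 2.904879 6.324172e-37

classified:
feature_id               class      min_fdr
  poe_gene POE_paternal_biased 1.417452e-43
  age_gene    AGE_duroc_biased 6.324172e-37
```

The planted log2 fold changes of 3 are recovered (2.98 and 2.90), each on
the correct axis of the design — the POE gene shows no AGE signal and vice
versa. `null_32` is a borderline false positive by FDR alone but is *not*
classified: classification additionally requires a >4-fold allelic ratio,
which a null gene essentially never reaches.

Other examples: `01_individualized_genomes.py` (coordinate maps),
`02_read_assignment.py` (fragment assignment vs. truth labels),
`04_methylation_regions.py` (poeMR calling), `05_full_pipeline.py`
(complete simulate→analyze run with recovery metrics).

A thin CLI mirrors the library for shell use:
`allelescope build-genomes | assign | ase-test | meth-extract |
meth-filter | mr-call | specificity | enrich | simulate | run-all`.

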