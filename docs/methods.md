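# Methods

This note documents the models and procedures implemented in allelescope,
the assumptions behind them, the defaults that matter, and what the
synthetic data generator does and does not emulate.

## Individualized genomes and coordinate translation

An individualized parental genome is the reference with that parent's
homozygous non-reference variants substituted in. Applicable variants are
homozygous-alt calls (the sample's own allele at multi-allelic records);
heterozygous sites are never substituted, so the individualized genome is a
haploid consensus of the parent's transmitted sequence at informative
sites. Overlapping records are resolved first-by-position (indels win ties
at the same start), which also removes any SNP inside the reference span
of a retained indel.

Each chromosome's edit list yields a piecewise-linear `CoordinateMap`:
co-linear blocks `(ref_start, ind_start, length)` broken only at indels,
plus the inserted intervals (individualized-only sequence) and deleted
intervals (reference-only sequence). Forward and backward lifts are
binary searches over the block starts; positions inside deletions /
insertions return sentinel values. Annotation liftover shifts feature
bounds through the map; a boundary falling inside a deleted interval is
clamped to the nearest surviving base (logged) so no feature identity is
lost. Invariants enforced by construction and verified by tests: length
change equals the summed indel deltas exactly, and forward-then-back is
the identity on every non-deleted base.

Coordinates are 0-based half-open in memory everywhere; the VCF/GTF
1-based conventions exist only in `allelescope.io`.

## Fragment assignment

Reads aligned to each parental genome are scored at informative
substitution sites (both alleles single bases). The site positions are
lifted into the aligned genome's frame once per sample; each read base at
a site (quality ≥ 20 by default) votes for the allele it matches; bases
matching neither allele vote for neither. A read is assigned to the genome
with strictly more matching alleles. For RNA, an assignable read must have
at least 80% of its aligned bases inside constitutive exons — the bases
exonic in *every* annotated transcript of the gene — which protects
gene-level counts from intronic and pre-mRNA signal. Mates of a fragment
must agree; a fragment whose mates resolve to different genomes is a
conflict and is excluded from every count. A fragment mapped in only one
genome is scored there (assignment still requires at least one informative
match). Informative indel alleles are used in genome construction but not
in per-base read scoring, which would require gapped-alignment comparison;
the generator and the QC metrics therefore treat substitution sites as the
assignment currency.

Counting is interval overlap in the reference frame (alignments are lifted
back through the coordinate map); a fragment overlapping several features
counts for each, with the per-gene constitutive-exon rule re-checked per
gene in RNA mode. Sample-level QC excludes samples whose paternal read
fraction falls outside [0.45, 0.55] (bounds inclusive), the signature of
maternal contamination in placenta; samples with zero assigned reads are
excluded with a distinct reason code.

## Bisulfite-specific handling

Bisulfite conversion turns unmethylated C into T (and makes bottom-strand
reads report G→A in forward coordinates). Two consequences are built in:

* Read assignment excludes informative sites whose allele pair is {C,T}
  for top-strand (CT) reads and {G,A} for bottom-strand (GA) reads — the
  conversion destroys exactly that contrast. The conversion strand comes
  from the aligner's `XG` tag, defaulting to top-strand.
* Methylation calls are per cytosine: top-strand reads report the
  plus-strand C of a CpG (C = methylated, T = unmethylated), bottom-strand
  reads the minus-strand cytosine opposite the CpG's G. CHG/CHH cytosines
  are discarded. The two strands of a CpG are reported as separate records
  (no dinucleotide pooling), matching common extractor output.

Per-parental-genome cytosine positions are converted back to the reference
frame; cytosines inside inserted sequence have no reference counterpart
and are dropped; maternal and paternal records of the same reference
cytosine are merged (the merge never changes the summed m+u). Cytosines at
parental variant positions are removed, since an allele-distinguishing SNP
under a cytosine corrupts the methylation call. Coverage filters follow
the two-stage scheme: a bulk filter (coverage > 10 in ≥ 10 of 12 samples
by default; the "≥ 8 samples" variant is a parameter) and an allelic
filter within each cross direction (at most 2 of 6 samples below coverage
5, per allele; group sizes other than 6 scale the allowance
proportionally, with a warning). An unmethylated spike-in contig provides
the non-conversion estimate (fraction of spike-in cytosines still read as
C). Methylation level of an allele without coverage is missing, never 0.

## The allelic model

Each sample contributes two observations per feature — its maternal and
paternal allelic counts. Within one cross direction, parent-of-origin and
breed are perfectly confounded; across both directions the design

    intercept + PO (paternal = 1) + AG (Duroc = 1)
              + MG (Duroc dam = 1) + Sex (male = 1)

is full rank, and `build_design` raises on single-direction sheets. MG and
Sex are covariates without formal inference. The offset is the log of the
sample's total assigned allelic reads, shared by both alleles of a sample,
so normalization cannot alter within-sample allelic ratios. The two
allelic observations of a sample are treated as independent given the
design (no within-sample pair effect) — a deliberate simplification that
matches count-framework practice; it leaves a conservative amount of
shared-sample variance in the dispersion.

RNA and ATAC counts use a negative-binomial GLM (log link), CpGs a
binomial GLM (logit link) on (m, u) pairs. Because every feature shares
one small design matrix, the fits run as batched IRLS across all features
simultaneously; coefficients agree with statsmodels' GLM to ~1e-8 (tested)
and the batch solver fits thousands of features per second, which is what
makes per-CpG testing practical. Inference is by likelihood-ratio test of
the PO (or AG) column; BH FDR is applied within each tissue×stage context
and modality. Complete separation in the binomial model (|coefficient| >
15) is flagged and yields a missing p-value, never 0.

### Dispersion

NB dispersion is estimated per feature by the residual-df-corrected
Pearson estimating equation `Σ (y−μ)² / (μ(1+αμ)) = n − p` and shrunk on
the log scale (default weight 0.9) toward a trend: the *common* dispersion
of each expression-strength bin maximizing the Cox–Reid adjusted profile
likelihood on a log-spaced grid with parabolic refinement. Both the df
correction and the Cox–Reid adjustment are needed at the small per-feature
sample sizes of this design (24 observations, 5 coefficients); without
them dispersion is underestimated by ~30% and the nominal 5% test rejects
~9.5% of null features. The CR-adjusted common estimate itself retains a
small O(1/n) downward bias at these sizes, compensated by an n/(n−1)
inflation of the trend; the combination was verified by simulation to give
a realized false positive rate of ≈0.048 at p<0.05 and uniform null
p-values. A uniform Bartlett-type rescaling of the LRT statistic was
evaluated instead and rejected: it corrected the tail at the cost of bulk
uniformity.

### Classification

A feature is classified in a context when FDR < 0.05 and its allelic fold
change — computed from library-normalized allelic means, origin fold for
POE, breed fold for AGE — clears the modality gate: strictly greater than
4× for RNA, at least 2× for ATAC. A cross-context rescue also classifies
features significant in one context with |log2FC| ≥ 1 in at least two
contexts ("1-fold change" is read as ≥2-fold, i.e. |log2FC| ≥ 1). When a
feature carries both effects, the class with the smaller minimum FDR is
reported. Imprinting: mean paternal expression fraction ≥ 0.95 or ≤ 0.05
in a tissue at ≥ 1 stage (bounds inclusive); strong POE: > 0.75 or < 0.25.
Direction switches are flagged when significant biases of opposite sign
occur across stages within a tissue.

## Regions and context analyses

* **poeMR/ageMR**: maximal runs of *tested* CpGs, every member significant
  (adjusted p < 0.05) for the effect, run length ≥ 3, consecutive members
  ≤ 1.5 kb apart. "Sliding window of 1.5 kb" is implemented as this
  max-gap constraint (window anchoring is otherwise ill-defined), and
  "consecutive" means consecutive among filter-passing CpGs — a tested,
  non-significant CpG breaks a run. The caller is tested identical to a
  brute-force enumerator on randomized instances.
* **Priority annotation**: promoter (strand-aware 3 kb upstream of the
  TSS), 5'UTR, 3'UTR, exon, intron, in that order, 1 bp of overlap
  sufficing; otherwise intergenic. Peak-to-gene aggregation sums counts
  over a gene's non-intergenic peaks.
* **Specificity**: a gene is tissue-specific at a stage when it is ≥
  16-fold above *every* other tissue with FDR < 0.05 per contrast
  (pairwise NB GLMs with a sex covariate); stage specificity is the same
  with stages as levels. ATAC tissue specificity defaults to the fold ≥ 2
  gate.
* **Trends**: the three transitions of the four ordered stages (F40 → F70
  → D1 → D168) are each classified up/down/flat (significant at FDR < 0.05
  and |log2FC| ≥ 1, else flat), giving 3³ = 27 pattern classes.
* **Enrichment**: observed overlap divided by the mean overlap of seeded
  random draws of equal size; p = (1 + #{draws ≥ observed}) / (n_perm+1).
* **Clustering**: proportion of same-chromosome gene-midpoint pairs closer
  than 1 Mb, relative to equally sized random gene sets; cross-chromosome
  pairs are excluded.

## The synthetic data generator

`allelescope.sim` emulates the study design: two breeds, monomorphic
within breed, divergent between; reciprocal crosses with 3 replicates per
sex per direction; tissue×stage sample sheets up to the full 168-sample
design. It writes real file formats (FASTA, VCF, GTF, SAM, BED, TSV) and
reads come pre-aligned — the generator knows each read's source position
in its parental genome, so SAM records are exact and no aligner runs in
the tests. All randomness flows from one seed; outputs are bit-identical
under a fixed seed.

Defaults define the demo conditions: two 600 kb chromosomes; 300 compact
genes (2–4 exons of 150–350 bp) with 10% large intergenic gaps to host
intergenic ATAC peaks; between-breed SNP rate 0.002/bp and indel rate
2e-4/bp (≤ 6 bp), plus guaranteed informative SNPs every ~120 bp inside
constitutive exons so most RNA fragments are assignable — mirroring the
informative-variant density that makes genes assessable in real crosses.
Expression: mean 100 fragments per gene per sample (log-normal across
genes), NB dispersion 0.1 — typical biological-replicate variability.
Planted effects: 6% POE, 6% AGE genes at |log2FC| ∈ {1, 2.5, 3.5}, 3%
imprinted at paternal fraction 0.95/0.05. The planted magnitudes
deliberately avoid exactly 4-fold (log2FC = 2): the >4× classification
gate makes a feature whose true fold sits on the gate a coin flip by
construction, so demo effects are placed clearly on either side of it.
ATAC: ~1000-peak catalog (promoter-proximal, genic, intergenic), mean 30
fragments per peak, nucleosomal insert-size mixture (~80/200/400 bp).
Methylation: 250 CpG clusters of 6–14 consecutive CpGs; cluster classes
none/poe/age with methylation 0.85 vs 0.10 on the contrasting allele;
single-end bisulfite reads targeted to cluster neighborhoods at ~20× per
allele; conversion applied with non-conversion rate 0.005; every cluster
gets conversion-safe informative SNPs of both orientations (an A/G pair
for top-strand reads, a C/T pair for bottom-strand reads) so reads of
either strand are assignable; an unmethylated spike-in contig calibrates
the non-conversion estimate.

What the generator does **not** emulate: alignment and mapping-bias
errors (reads are emitted at their true positions; the real pipeline's
mapping step can introduce reference bias the tests cannot see), splicing
isoform structure beyond exon skipping, PCR duplicates, CNVs or
mappability artifacts, M-bias along bisulfite reads, and cell-type
composition differences between tissues. Passing tests therefore certify
the statistical machinery and the coordinate/assignment logic, not
robustness to alignment artifacts.

## Numerical choices and degenerate inputs

IRLS runs to a 1e-9 coefficient-change tolerance with a 200-iteration cap
(strongly misspecified reduced models need ~70 iterations); linear
predictors are clipped at ±30 and singular systems stabilized with a 1e-10
ridge, with |β| > 15 flagged as separation. Zero-trial binomial rows carry
zero weight. LRT statistics are clipped at 0. Empty feature sets, unknown
samples, unsorted inputs, and single-direction designs raise errors;
constant vectors in correlations return NaN with a flag; features with no
covered CpGs are missing, not zero. BH adjustment delegates to
statsmodels and excludes NaN p-values.

## Known limitations

* No within-sample pairing of the two allelic observations (see above).
* Fold-change gates make effects near the gate intrinsically borderline;
  the rescue rule recovers some of them only when multiple contexts exist.
* Read scoring ignores informative indels.
* The per-cytosine (unpooled) CpG representation halves per-record
  coverage relative to dinucleotide pooling; the allelic coverage filter
  is correspondingly the binding constraint at moderate depth.
* Single-end bisulfite simulation; paired-end WGBS fragment overlap is not
  modeled.
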