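# Methods

## Data model and quality control

Genotypes are held as an n_samples × n_variants matrix of alternate-allele
dosages {0, 1, 2} with −1 for missing; phase is discarded at VCF parse time
and half-missing genotypes are treated as missing. Missing genotypes are
never imputed at I/O — each analysis chooses its own policy (PCA imputes to
the locus mean, allele counting excludes, HD profiling zero-weights).
Internal coordinates are 1-based inclusive (the VCF convention); BED input
is converted at the boundary and converted back on write, so the round trip
is the identity.

QC removes, in order: all records sharing a chrom:pos with any other record
(removing *all* colliding records is deterministic and order-independent,
which matters because no tie-break rule could be audited otherwise),
multi-allelic records, indels, and variants with zero minor allele frequency
inside the analysis group. Each variant is charged to the first rule that
removes it, so the filter report's per-rule counts always sum to the number
removed. Only autosomal-style biallelic SNVs survive; sex chromosomes are
out of scope.

## Variant categories

Within an analysis group (the whole-continental group over five continents,
or one continent over its populations), each polymorphic variant is
classified from its subgroup MAFs: SNP if every polymorphic subgroup has
MAF > 0.01, RV if every polymorphic subgroup has MAF ≤ 0.01, SNP/RV when the
two mix. The pooled "SNV" family contains all three. The 0.01 threshold is
the conventional common/rare boundary; it is a parameter of
`categorize_variants`.

## Sample-space PCA

With m ≫ n, the locus-space covariance is never formed. Individual-level
allele frequencies x = dosage/2 are locus-mean-centered, and the n × n Gram
matrix X_c X_cᵀ is accumulated over locus blocks (default 8,192 loci per
block), keeping memory at O(n² + n·block). A symmetric eigendecomposition
gives eigenvalues equal to the nonzero locus-space eigenvalues —
the equivalence is the test oracle — and coordinates eigenvector·√eigenvalue.
Signs are fixed by making each component's largest-magnitude sample loading
positive. Covariance (not correlation) is the default; per-locus
standardization is available as a switch because whether to standardize
loci before a genotype PCA is a genuinely open choice. Missing-genotype
handling (locus-mean imputation) is the simplest deterministic choice and
shrinks the contribution of a missing entry to zero after centering.

## UPGMA clustering

Average-linkage agglomeration over Euclidean distances between
individual-level allele-frequency vectors, with ties broken by the smallest
(i, j) pair in row-major order so dendrograms are reproducible. The O(n³)
implementation is deliberate: it keeps the tie-break explicit and is cross-
checked against an independent average-linkage implementation on tie-free
data. The CLI clusters population mean-frequency vectors (26-leaf scale);
clustering individuals is supported through the library.

## Homozygosity disequilibrium

Homozygosity intensity at an anchor SNV is a locally weighted estimate of
the homozygous-genotype proportion: a degree-1 local polynomial of the
indicator (1 homozygous, 0 heterozygous) against position, evaluated at the
anchor, with weights K(u)·w. K is the tricube kernel (1 − |u|³)³ on
u = (pos − pos_anchor)/h, h the largest in-window distance; w is the locus
weight min(MAF, 0.05)/0.05, discounting rare variants whose genotypes are
almost always homozygous regardless of autozygosity. Missing indicators get
weight zero; windows with fewer than 10 usable loci are undefined (NaN, not
zero). Intensities are clipped to [0, 1]. Gene-level intensity is the
degree-0 (locus-weighted mean) fit over the SNVs inside the gene region.

The exact kernel/degree/window parameterization of double-weight local
polynomial smoothing is not fixed by any single convention; the choices
here (tricube kernel, degree-1 genome profile, degree-0 gene fit,
MAF-threshold locus weight at 0.05) have the stated structure and are all
exposed as parameters.

Window defaults: anchors every 10 SNVs, 51-SNV windows (half-window 25).
The window width sets the smallest resolvable run of homozygosity: a window
much wider than a segment dilutes its intensity below the HD threshold, so
the default was chosen to resolve segments from roughly 50 SNVs up, the
scale the region caller is expected to detect; at this width the anchor
false-positive rate on Hardy–Weinberg genotypes with common alleles is
≈0.05% (bounded at 2% in tests). Wider smoothing remains available through
`WindowConfig`.

Regions under HD are maximal runs of consecutive anchors with intensity
above 0.9 (the conventional HD threshold); region bounds are the first and
last anchor positions — conservative and deterministic — and NaN anchors
break runs. Per individual, #(HD) counts regions and L(HD) collects their
lengths. Between-group differences in intensity are tested per region or
gene with the tie-corrected Kruskal–Wallis statistic ("difference in
medians" is implemented as Kruskal–Wallis, the same test used for AIGs,
rather than Mood's median test), BH-adjusted across regions.

## Exact tests at genome scale

The one-sided 2×2 Fisher tail is the hypergeometric upper tail summed in
log space from log-gamma binomial terms; `log10_p` is reported alongside
`p` because genome-scale tables produce values below double-precision
underflow. The odds ratio is a·d/(b·c) with no continuity correction
(a Haldane–Anscombe +0.5 variant exists for zero cells).

The two-sided subgroups × 2 test uses the probability-mass criterion — the
total null probability of tables no more probable than the observed one
(relative float tolerance 10⁻⁷ for ties) — because doubling one tail gives
different values and the probability-mass convention is the classic Fisher
definition. The fixed-margin support is enumerated exactly when it holds at
most `max_enumeration` tables; larger supports fall back to seeded
Monte-Carlo sampling via `multivariate_hypergeometric` with the add-one
estimate (1 + hits)/(reps + 1), reproducible under the seed. The AIM scan
lowers `max_enumeration` to 5,000 so exactness is kept where Monte-Carlo
resolution would be poorest (sparse tables) without paying Python
enumeration costs on dense ones. Kruskal–Wallis and BH adjustment delegate
to scipy/statsmodels behind validated wrappers (degenerate all-identical
input returns H = 0, p = 1 so genome scans stay total).

## Catalogs

BH families follow the analysis design: one family per (group × category)
for AIMs — six groups × four categories — and one per group for AIGs.
The enrichment universe is the group's polymorphic (MAF > 0) variants, with
PGx membership by exact variant-id match. Δ is computed on the alternate
allele's frequencies as given and is invariant under allele relabeling.

## Synthetic data generator

A two-level Balding–Nichols hierarchy: ancestral frequency p per locus from
a mixture of Uniform(0.05, 0.95) (weight w_common, default 0.5) and
Uniform(0.0005, 0.01); continental frequency Beta(p(1−F_c)/F_c,
(1−p)(1−F_c)/F_c); population frequency drawn the same way around the
continent (or around a q-weighted mixture of continental frequencies for
admixed populations); genotypes Binomial(2, p_pop), i.e. Hardy–Weinberg.
Closed-form moments (E = p, Var = F·p(1−p)) make recovery testable: Hudson's
FST between two populations drawn at F converges to F.

Default study conditions: five continents × two populations × 60
individuals, F_c = 0.10 (a 1000-Genomes-like continental FST), F_p = 0.01,
20,000 loci on a 50-Mb chromosome. The American-ancestry populations are
admixed (weights 0.45 EUR / 0.25 AFR / 0.30 AMR), mirroring the admixed
Americas. ROH injection is Poisson-count, exponential-length, genotype-level
(dosage set to 2 with the population allele frequency, else 0), with
continent-specific rates ordered as observed in global cohorts: East Asians
most and longest (λ = 8, mean 1.5 Mb), Africans fewest and shortest (λ = 2,
0.5 Mb), Americans intermediate with a large spread. PGx labeling marks a
seeded random fraction of loci (default 5%) and can multiply their F by a
factor β — β > 1 creates genuine AIM-in-PGx enrichment, β = 1 is the
calibration null. Drug categories and functional annotations are sampled
from weight tables echoing public PGx resources (pharmacodynamics-heavy
categories, intron-heavy annotations).

What the generator does *not* emulate: linkage disequilibrium and haplotype
structure (genotypes are independent across loci given frequencies),
realistic site-frequency spectra from demography, mutation processes, and
sex chromosomes. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, not robustness to LD
confounding in real data.

## Ancestry panel

Flexible discriminant analysis in the optimal-scoring formulation: class
indicators are ridge-regressed (jitter 10⁻⁸ on the cross-product) on the
features, the between-class structure of the fits is eigen-decomposed into
at most (classes − 1) discriminant directions, and samples are assigned to
the nearest class centroid under the pooled within-class metric with
log-prior correction. With the linear basis this decision rule coincides
with classical LDA — verified against an independent LDA implementation —
while the architecture leaves room for spline bases. Forward selection
refits the full model per candidate (no shortcut updates); the tie-break
"within/between sum of squares" is one-way ANOVA on the candidate's raw
genotypic values. Stratified folds are per-class round-robin after a seeded
shuffle, so per-class fold sizes differ by at most one. Candidate pools for
the CLI and benchmarks rank AIMs by Δ: Monte-Carlo p-values tie at their
resolution floor for strongly differentiated markers, so the frequency
spread is the informative ordering. No feature scaling is applied (the
linear-basis rule is affine-invariant per feature).

## Benchmark problem sizes

The acceptance benchmarks use desk-scale problem sizes chosen for stable
estimates: FST recovery with two populations of 200 at 5,000 common loci;
ROH recovery with 12 individuals and 6,000 loci on 60 Mb (λ = 3, mean 4 Mb,
segments ≥ 50 SNVs scored at ≥ 50% length overlap); AIM power at F = 0.15
with five groups of 100 over 500 common loci (5 replicates); null
calibration at F = 0 (10 replicates) and enrichment calibration with
β ∈ {1, 4} (20 and 10 replicates); the panel on the full default dataset
(600 individuals, 10,000 loci, 200 candidates) where held-out folds of 60
keep the accuracy estimate's binomial noise near ±3%.

## Known limitations

* Exact r×2 enumeration is pure Python; dense supports are delegated to
  Monte-Carlo, whose p-value resolution is 1/(reps + 1).
* The published absolute catalog sizes (tens of millions of AIMs, the
  31-marker panel) require the full 77M-variant cohort and are out of desk
  scale by design; synthetic recovery benchmarks stand in for them.
* HD regions are genotype-based; haplotype-aware ROH semantics (PLINK
  `--homozyg`) are a non-goal.
* The CLI accepts `--threads` for interface stability but runs
  single-threaded; results are trivially independent of parallelism.
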