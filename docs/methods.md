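# Methods

This note records the statistical models, the defaults that matter, the
design decisions made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Synthetic populations (`simdata`)

Genotypes are haplotype mosaics, not coalescent samples.  Per
chromosome, a founder pool (default 30 haplotypes) is built from a small
set of base haplotypes drawn site-wise from a Beta(0.5, 0.5)
allele-frequency distribution (U-shaped, so the folded MAF spectrum is
rare-heavy) plus gene-conversion-style mosaics of earlier pool members;
each individual draws two pool haplotypes recombined with
Poisson(recombination rate) crossovers (default 1 per chromosome per
meiosis).  Shared pool segments create block-wise LD; the scheme is a
deliberate stand-in for imputed sequence data and makes no claim of
population-genetic realism (no pedigree, no breed structure, no
mutation model).  Positions are 1-based bp; intervals elsewhere are
closed on both ends.

Functional classes (GWAS, eeQTL, aseQTL, ieQTL, seQTL, asbQTL,
ChIPseqQTL, ATACQTL, coding) are assigned by a categorical draw per
variant from the configured proportions (default total 0.38, largest
for open-chromatin classes), with a 15% chance of one extra label so
variants can carry signals in multiple categories.  Causal variants for
each primary trait are drawn without replacement with weights equal to
the product of per-class enrichment odds (defaults 2–8, GWAS highest);
the paper trail for real traits provides no generative truth here, so
these are free parameters of the simulator, not estimates.

Traits: two percent traits (h² = 0.50) and a volume trait (h² = 0.30),
typical dairy values.  Effects are Normal, rescaled so the realized
genetic variance equals h² on a unit-variance scale; fixed effects add
contemporary-group/breed factor effects (SD 0.5) and
heterosis/inbreeding covariate effects.  Yield traits are formed as
percent × volume × lognormal noise with CV 0.05, so they compound the
errors of both parents — their accuracy deficit downstream is a
structural property, not an assertion.  True genetic values are stored
per individual; for yields the truth is the product form
(μ_p + g_p)(μ_v + g_v) − μ_pμ_v.

Molecular counts: each feature links a transcribed marker (whose
heterozygotes are the informative individuals) to a regulatory variant
nearby.  Allelic counts are Binomial(Poisson depth 100, p) with
p = 0.7 for regulatory heterozygotes and 0.5 otherwise; parental phase
is known and taken as aligned (the maternal haplotype carries the
alternate allele), so no phasing algorithm is modelled.  Splice counts
are Binomial with proportion sigmoid(base logit 1.0 + 0.5 × dosage),
depth 200.

All generators are deterministic given the config seed; one
`SeedSequence` is spawned per generator in fixed order.

## Phenotype adjustment (`adjust`)

Estimation is ordinary least squares per trait — the literal reading of
the adjustment model; no mixed-model machinery is used.  Factors are
treatment-coded with the first (sorted) level dropped; interactions
multiply the expanded bases; Legendre polynomials of days-in-milk are
available as caller-supplied covariate columns (standard basis on days
rescaled to [−1, 1]).  Rank deficiency is handled by the minimum-norm
LAPACK solution with aliased columns identified by pivoted QR and
reported.  Traits are adjusted one at a time.

## GWAS tagging (`gwas`)

The scan is covariate-adjusted least squares on yield deviations:
phenotype and test dosages are projected off the conditioning set
(intercept + previously selected tags + optional caller covariates) and
each variant is tested by a two-sided t-test.  The discovery engine of
large production systems (mixed-model LOCO association) is intentionally
not reproduced — the reusable procedural content is the
iterate-and-condition loop.  Per iteration, at most one variant per
chromosome is taken: the most significant below the fixed genome-wide
threshold 1.9 × 10⁻¹⁰ (no FDR machinery), ties broken by smaller p,
then lower position, then lexicographic id, which makes the tag set
invariant to input order.  Selection is strictly between iterations
(a chromosome's top hit is never conditioned on within the iteration
that found it); tags are never removed.

## Molecular QTL (`molqtl`)

Splicing efficiency is logit((spliced + c)/(total + 2c)); intron
(pre-mRNA) expression is standardized log1p(unspliced) — a monotone
variance-reducing transform chosen over a count-model
variance-stabilizing transform to keep the phenotype construction
dependency-free; features with fewer than 20 individuals are dropped.
The cis scan regresses each feature on every variant within a closed
symmetric 1 Mb window around the feature midpoint with MAF > 0.1
(thresholds 10⁻⁶ for eQTL/ieQTL/seQTL-type scans, 10⁻⁸ for exon
expression), tags the most significant variant of each significant
feature, and deduplicates tags across features keeping the most
significant source.

The allele-specific test is two-stage.  Stage 1 pools maternal and
paternal counts over informative individuals heterozygous at the
candidate and refers Z = (M − P)/√(M + P) to a standard normal (gate
p < 10⁻³); whether the original statistic pooled across individuals or
tested per-individual ratios is not documented anywhere, so the pooled
binomial-normal form was chosen and is recorded here.  Stage 2 regresses
log((M + ½)/(P + ½)) (Haldane–Anscombe pseudocount) on candidate dosage;
final thresholds 10⁻⁸ (expression) and 10⁻⁶ (binding).  Features with
fewer than 10 informative individuals are skipped.

## Panel construction (`panel`)

Benchmark QC applies, in order: MAF ≥ 0.02; call rate ≥ 0.9; greedy LD
pruning within a 1 Mb window keeping the earlier-position member of any
pair with r² > 0.9; exact Hardy–Weinberg test removing p < 0.15.  The
HWE test is the exact conditional (Levene/Haldane) test with the mid-p
convention — under H0 the mid-p is close to uniform, so the p < 0.15
rule removes ≈15% of well-behaved markers, which is what the published
filter implies; the plain exact test is conservative and would remove
far fewer.

LD blocks for functional candidates use single-linkage clustering over
pairs with r² ≥ 0.98 within 1 Mb (the blocking algorithm is not
published; single-linkage is cheap and order-independent, and a
no-window mode exists for brute-force verification).  Representatives
are chosen by priority tier — expression QTL > coding > GWAS > other
classes — with ties broken by more class labels, then lower position.
MAF bins are half-open [k·0.05, (k+1)·0.05) with MAF = 0.5 in the top
bin; within-bin subsampling weights each candidate by its number of
distinct class labels ("categories and numbers of associated QTL"; the
uniform alternative is a one-line change).  Bins short of candidates
keep everything and log the deficit.  The final filter keeps biallelic
variants with MAF ≥ 0.1.  Random baselines are uniform without
replacement, canonically sorted, deterministic given their seed.

## BayesCπ (`bayescpi`)

The standard formulation: common effect variance, Bernoulli inclusion
with the effect integrated out of the indicator update, scaled
inverse-χ² variance updates, π ~ Beta(m − k + 1, k + 1) under a uniform
prior (π is the exclusion probability).  The residual vector is
maintained incrementally; markers are visited in fixed genomic order
for reproducibility (panels are canonicalized to genotype-matrix order
before fitting, so a panel's id ordering never changes the chain).
Initialization: all indicators 0, μ = mean(y), σ²_e = var(y), π = 0.5.

Priors: ν = 4.2 for both variances; scales set so the prior modes match
an assumed h² (default 0.3) partitioned over the markers expected in
the model a priori, and (1 − h²)·var(y) for the residual.  These
hyperparameters are free parameters; the posterior is insensitive to
them at the sample sizes used here.  Fixed-variance and fixed-π modes
exist and reduce the sampler to ridge regression when π = 0, which the
test suite verifies against the closed-form solve (relative RMS ≈ 1%).

The default schedule is 10,000 iterations, 2,000 burn-in, thinning 10 —
adequate mixing for panels of a few thousand markers at desk scale; the
production-scale schedule (300,000 / 50,000 / 200) is available as the
`"paper"` preset.  The kernel is numba-compiled; its RNG is seeded per
chain, so chains are bit-reproducible.

## Evaluation (`evalcv`)

Folds are a random permutation split into k near-equal parts (first
n mod k folds get the extra individual).  Accuracy is the Pearson
correlation of GEBV with the adjusted phenotype — deliberately not
rescaled by √h², matching the definition used for the published
comparison.  One fold plan is drawn per experiment and reused for every
panel (paired design: strictly better for the comparison being made,
though the original's fold-reuse policy is unstated); one baseline draw
per functional panel by default, with a flag for multi-draw averaging.

## Experiment designs (`experiments`) and problem sizes

Three bundled designs back the validation suite and the acceptance
script; sizes were chosen so everything runs in minutes on one CPU.

* **Ridge limit**: n = 200, m = 50, π = 0, σ²_α = 0.05, σ²_e = 1 fixed,
  6,000 iterations; posterior mean effects vs the direct solve.
* **Architecture recovery**: n = 2,000 (1,600 train / 400 validation),
  m = 1,000 across 10 chromosomes, 50 causals, h² = 0.5, in a low-LD
  population (pool 100, 3 crossovers/meiosis) so the 50 causals are
  ~50 independent signals.  Expected outcomes: posterior π near
  1 − k̄/m ≈ 0.95, GEBV–truth correlation ≈ 0.95, GEBV–phenotype
  correlation below the √h² ceiling, strong causal enrichment among
  top inclusion probabilities.  At much larger marker counts with the
  causal count held fixed, the posterior π approaches 1 − k̄/m with
  k̄ < 50 (weak Normal-drawn effects are undetectable), so π converges
  to just above the true exclusion fraction; the m = 1,000 design keeps
  the quantity informative.
* **Panel comparison**: 10 replicate populations (n = 500, m = 900,
  25 causals planted exclusively in functional classes), functional
  panel = annotated variants with MAF ≥ 0.1, benchmark panel =
  QC-filtered unannotated variants (generic chips historically avoided
  functional sites), paired 5-fold cross-validation on a percent trait
  and its yield trait, chains of 1,200 iterations.

## What passing tests do and do not show

The generator produces block LD, rare-heavy MAF spectra, multi-label
functional annotation, compound-noise yield traits and phase-known
allelic counts — enough structure for every pipeline stage to be
exercised against a known truth.  It does not produce pedigree/breed
structure, imputation error, genotype–environment correlation, selection
footprints, or realistic recombination maps; results on synthetic data
validate the machinery and its internal consistency, not field
performance on real cattle.  Published improvement percentages from
proprietary-data studies are not reproducible at desk scale and are not
targets of the test suite.

## Numerical choices and degenerate inputs

Monomorphic variants: p = 1, β = 0, flagged in scans; excluded from
causal sampling; zero-variance columns skipped inside the Gibbs kernel.
p-values are clipped below at the smallest positive double.  Constant
molecular features standardize to 0 (sd tolerance 10⁻¹²).  Zero-total
splice rows are dropped when the pseudocount is 0.  Zero-variance
phenotypes and n ≤ p designs raise errors rather than produce output.
Ties everywhere break deterministically (p, then position, then id).
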