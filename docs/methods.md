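# Methods

This note documents the models implemented in `twinqtl`, the synthetic
data they are exercised on, the numerical choices made where the design
was genuinely open, and what the test suite does and does not establish
about behaviour on real herdbook data.

## The trait and its coding

Multiple birth in cattle is recorded per calving event and coded 1
(single calf) or 2 (twins or triplets).  The pipeline follows the common
national-evaluation practice of fitting *linear* mixed models directly to
this 1/2 coding.  That choice is pragmatic, not ideal — the response is
binary, its variance depends on the mean, and predictions are not
probabilities — but it makes variance components, EBVs and de-regression
tractable at population scale.  A generalized linear or threshold model
is explicitly out of scope.

## Direct–maternal animal model

The phenotype preparation (module `records`) removes embryo-transfer
records, then herds with fewer than 260 records, then — for the
variance-component dataset — herd-year classes with fewer than 5 records.
Each rule's count is evaluated on the survivors of the previous rule,
making the herd-year rule a refinement of the herd rule; the order is the
package's own choice since only the thresholds, not the order, are
conventionally reported.

The model (module `animal_model`) is

    y = X b + W h + Z_d a + Z_m m + e

with fixed effects for parity (levels 1..5+, parities above five capped),
season of calving (spring = Mar–May, summer = Jun–Aug, fall = Sep–Nov,
winter = Dec–Feb; month-to-season boundaries are a package convention),
sexed-semen use (missing treated as "no") and a linear age-of-dam
covariate (months, centred); a random herd-year effect h ~ N(0, I
sigma2_h); correlated direct (calf) and maternal (dam) additive values
(a, m) ~ N(0, G0 ⊗ A), G0 the 2×2 genetic covariance matrix with
direct–maternal covariance sigma_am; and residual e ~ N(0, I sigma2_e).
A is the pedigree numerator relationship matrix; its sparse inverse is
assembled by Henderson's rules with Meuwissen–Luo inbreeding
coefficients, exactly for inbred pedigrees.

### Heritability convention

h² = sigma²_component / sigma²_p with

    sigma2_p = sigma2_h + sigma2_a + sigma2_m + sigma_am + sigma2_e,

the covariance counted once.  This is the only convention under which
the reference component set used in the tests reproduces both published
heritabilities (direct 0.0015, maternal 0.0348) to within a unit in the
fourth decimal.  The "correlation animal/dam" row of the reference table
is interpreted as the covariance sigma_am: its magnitude (−1.58e-4) is
two orders below any admissible correlation given the printed variances,
so it can only be a covariance.

### REML

Variance components are estimated by restricted maximum likelihood on
the sparse mixed-model equations (MME).  The log-likelihood uses the
identity log|V| + log|X'V⁻¹X| = log|R| + log|G| + log|C| with C the full
MME coefficient matrix; log|C| comes from a sparse LU factorization
(SuperLU, minimum-degree ordering in symmetric mode) and log|A| from the
Meuwissen–Luo within-family variances.  First derivatives use the
standard MME trace identities; the traces tr(C^hh) and tr(A⁻¹C^{uu})
are exact (block solves against the identity) for systems up to 6,000
unknowns and Hutchinson Rademacher-probe estimates (32 probes, one fixed
internal seed, probes reused across iterations so the iteration map is
deterministic) above that.  Starting values come from unbiased
within-group pair covariances of the fixed-part OLS residuals (herd-year
groups for sigma2_h, dam groups for sigma2_m, a small positive sigma2_a,
zero covariance).  Updates are damped average-information
(Levenberg–Marquardt schedule on the AI matrix, which is near-singular
when components sit on very different scales), with candidates projected
into a numerically safe region (variances floored at
max(1e-12, 1e-8·var(y)) and capped at 10·var(y), the residual
additionally bounded below by var(y)/1000, direct–maternal correlation
capped at |rho| ≤ 0.99) and limited to a ×10 multiplicative change per
component per iteration — a single wild step that crashes a variance to
the floor would strand the iteration there, since the floor is an
absorbing state of the EM map.  Expectation-maximisation steps take over
when no damped AI step improves the likelihood, and Aitken-style
extrapolation fires when successive steps shrink geometrically — the
signature of a ridge or boundary crawl, where plain EM can need
thousands of iterations.  The sparse factorizations run SuperLU in
symmetric mode with a small diagonal-pivot threshold: the coefficient
matrix is positive definite, and partial pivoting on badly scaled
candidates would destroy the fill-reducing ordering.  Convergence
requires the relative likelihood change to fall below 1e-8 *on an EM
step*: EM stalls only at stationary points, whereas a heavily damped AI
step can stall anywhere, and an apparent AI convergence is therefore
verified by EM before being accepted.

Both likelihood values and all five analytic score components are
checked against dense-matrix oracles in the test suite, and the REML
optimum on a toy matches a dense Nelder–Mead polish of the V-based
restricted likelihood.

### Identifiability of sigma_am

With founder dams only — every response from a calf whose dam has no own
record — the likelihood carries exactly three genetic functionals
(sigma2_a from sire half-sib covariances, sigma2_m + sigma_am from
within-dam covariances, and their sum from the phenotypic variance), so
sigma_am and sigma2_m are confounded and REML wanders a flat ridge; any
reported maternal heritability from such a design is arbitrary within a
wide range.  Dam–daughter record pairs (animals with own calf records
that later appear as dams) break the confounding.  The parameter-recovery
experiment therefore simulates two overlapping generations of recorded
dams; this is a statistical requirement, not a convenience.

### BLUP, reliabilities, standardization, trend

At converged (or supplied) components the MME are solved once;
prediction-error variances come from the genetic diagonal of C⁻¹,
obtained exactly by chunked unit-vector solves, and reliability is
r² = 1 − PEV/sigma2_g clamped to [0, 1] (exact PEV replaces the usual
large-scale approximations, which is feasible at the scales this package
targets).  Standardized EBVs map the base group — by default male,
main-breed fraction ≥ 7/8, born 8–10 years before the evaluation year
(the maximum pedigree birth year unless given) — to mean 100 and sample
SD 12; the same affine transform applies to all animals.  The genetic
trend is the per-birth-year mean of standardized EBVs.

## De-regression

EBVs are de-regressed through the classical parent-average/individual
two-equation system: the parent average carries reliability
(r²_sire + r²_dam)/4; the individual's own information content d_i is
solved from consistency of its stated reliability with the 2×2 system's
prediction-error variance; the de-regressed value is the own right-hand
side divided by d_i, which removes both shrinkage and the parent
average.  Animals with both parents unknown reduce to EBV/r².  Records
with d_i ≤ 0 (reliability no better than the parent average) are flagged
and excluded rather than given infinite-variance pseudo-records.  The
weight

    w = (1 − h²) / ((c + (1 − r²_dereg)/r²_dereg) h²)

uses c = 0.5 by default — the fraction of genetic variance not captured
by markers is unknowable a priori; 0.5 is the conventional middle ground
and the value is configurable.  h² is the trait-appropriate heritability
from the animal model.  The association stages use records with source
reliability ≥ 0.35 (inclusive).

## Mixed-model association scan

The genomic relationship matrix is VanRaden method 1 on 0/1/2 alt-allele
dosages: columns centred at 2p, cross-product scaled by 2·Σp(1−p);
monomorphic and sub-MAF (default 1%) markers are excluded and counted.
Animals enter the scan when their pedigree-based main-breed fraction is
strictly above 0.6.  The polygenic null model y = mu + g + e,
g ~ N(0, G sigma2_a), is fitted by profiled REML in the eigenbasis of G
(golden-section over log(sigma2_e/sigma2_a), then closed-form variance
recovery).  Each marker is then tested by generalized least squares with
the rotation and variance components fixed at the null fit — the
single-rotation strategy standard in large-scale mixed-model GWAS; exact
per-marker REML would change p-values negligibly at the scales tested
while multiplying cost.  Wald p-values are two-sided normal.  The
explained-variance column is 2p(1−p)·beta², reported per marker but
never used as a test statistic.  Bonferroni significance keeps
p ≤ alpha/n_tests with n_tests supplied by the caller (the marker count
of the full panel, not of the analysed subset, when reproducing
genome-wide thresholds).

## BayesB window partitioning

All markers enter a Gibbs sampler simultaneously.  Locus j carries a
mixture state: zero with prior probability pi = 0.989, otherwise an
effect with locus-specific variance under a scaled inverse chi-square
prior (df 4.2; scale derived so the prior genetic variance matches an
assumed fraction — default one half — of the response variance spread
over the expected (1 − pi) fraction of loci).  The variance state is
sampled by Metropolis–Hastings with the effect integrated out
analytically along the locus direction and the prior as proposal (10
proposals per locus per iteration), the effect by its normal full
conditional, and the residual variance by its conjugate update.  Chains
default to 21,000 iterations with 1,000 burn-in; the recovery tests use
shorter chains (3,000–4,000) after checking that window conclusions are
stable.  Each post-burn-in iteration the genome is partitioned into
1-Mb windows (a 25-SNP chunked mode is also provided); a window's
variance is the variance over animals of its genomic value, its share is
that variance divided by the *sum of window variances* (so shares sum to
one by construction), p>0 is the fraction of iterations with any nonzero
effect in the window, and p>Average the fraction with share above
1/n_windows.  Significance maps p>Average ≥ 0.95 to the 5% level and
≥ 0.99 to 1%; this mapping is a package construction, as window-posterior
significance has no canonical definition.  Under a null response the
posterior inclusion frequency sits *below* the prior 1 − pi (the
integrated likelihood penalises inclusion), a property the tests assert.

## Haplotype scan

Within a caller-specified segment every window of L consecutive markers,
L odd from 9 to 301, shifted one marker at a time, is enumerated.  For
each window the distinct phased allele strings across all 2n gametes are
tallied; every string with frequency ≥ 0.05 (configurable — GLS on
singleton haplotypes is degenerate) becomes a 0/1/2 dosage regressor
tested with the same fixed-rotation GLS core as the single-SNP scan, so
a one-marker window reproduces the single-SNP statistics exactly.
Dosage vectors recur massively across overlapping windows; fits are
cached by dosage pattern, which both speeds the scan and guarantees that
windows with identical focal-haplotype dosages report identical
effect/SE/p — the mechanism that produces long runs of equal rows among
the top hits.  Results are ranked by p, ties broken longer-window-first
then by position, so the top-K export is stable.  The top haplotype's
diplotype dosage (copies per animal) is exported for fine-mapping and
can be tested against other traits' de-regressed EBVs with a
single-regressor mixed-model fit (refused below 30 overlapping animals).

## Fine-mapping

The sequence panel passes QC in a fixed order — variant missingness
> 0.1, MAF < 0.01, sample missingness > 0.1, then Mendelian-error rates
> 2% for samples and then variants, each count evaluated on the
survivors of the previous rule.  Duo errors are opposing homozygotes;
trio errors are child genotypes impossible given both parents; rates
divide by non-missing tested transmissions, and absent family links make
the Mendelian rules a recorded no-op.  LD is genotypic r²: the squared
Pearson correlation between the haplotype diplotype dosage and each
variant's dosage over pairwise-complete samples (missingness handling is
the package's choice), which is invariant to allele relabeling on either
side.  Variants with r² ≥ 0.7 are reported sorted by r²; per-breed
alt-allele frequencies are reported for breeds with at least 50
genotyped samples.  Coordinates are 1-based inclusive throughout.

## Synthetic herds

The generator (module `simherd`) produces, deterministically given a
seed (independent numbered stream per stage):

- **Pedigree** — founders alternating sex (configurable ratio), dams
  assigned to herds; generations laid out in consecutive blocks of
  calving years with one calving per dam per year of her block; matings
  drawn from a limited AI-sire pool per generation (default 150 — both
  realistic for dairy breeding and essential to keep the A⁻¹ graph
  sparse enough for fast factorization); daughters stay in their dam's
  herd; static breed fractions averaging down the pedigree.
- **Genotypes** — founder haplotypes drawn from a pool of mosaics over
  per-block ancestral variants (block LD, default 500-kb blocks, 6
  variants per block, 40 pool haplotypes); gene dropping with Poisson
  crossovers at 1 cM/Mb.  A planted focal haplotype occupies a QTL
  window in a target fraction of pool haplotypes (realised population
  frequency then varies by drift within binomial error); carrier status
  is defined as an exact allele-string match over the window markers.
- **Phenotypes** — breeding-value pairs sampled recursively down the
  pedigree from G0 with inbreeding-corrected Mendelian-sampling
  variances; herd-year effects i.i.d.; fixed-effect values default to
  the published solution magnitudes (parity 0.305..0.379, sexed semen
  0.354/0.346, season 0.346..0.364, a small negative age slope); the
  planted haplotype adds its effect per carrier copy to the dam's
  maternal value.  Gaussian mode emits the latent value as the 1/2-coded
  response (a correctly specified model, needed for exact REML
  recovery); binary mode thresholds it, calibrating the threshold to the
  empirical quantile matching the target prevalence (default 3.56%).
- **Sequence panel** — dense variants around the QTL whose alleles copy
  the per-gamete carrier indicator with per-variant flip rates (a
  controllable r² ladder; one designated causal proxy gets the lowest
  rate), a configurable fraction drawn independently, missingness
  injected at random, breed labels per sample, and duo/trio links taken
  from the pedigree.

What the generator does **not** emulate: coalescent-scale LD decay,
selection and allele-frequency change over generations, genotyping or
phasing errors (synthetic phase is perfect by construction), age-parity
confounding beyond the layout implied by the year blocks, multi-breed
admixture dynamics, or real pedigree depth.  Tests passing on these
herds therefore establish the *correctness of the estimators and the
internal consistency of the pipeline* under the assumed model — not
robustness to the model violations real data would add.

## Problem sizes in the shipped experiments

The parameter-recovery experiment runs 10 replicates of ~20,000 records
(50 herds, 5 calving years, two generations, ~5,250 founders), matching
the conditions the recovery claim is stated for.  The BayesB recovery
uses n = 1,500 animals, 1,000 markers in twenty 1-Mb windows, 4,000-
iteration chains; the haplotype-scan recovery a 2,000-animal herd with a
260-marker chromosome and window lengths 9–31; the LD ladder 60 panel
variants over ~580 animals.  These sizes are chosen so the full suite
exercises every stage end-to-end in minutes on a single core while
keeping every statistical claim at the scale it is stated for.

## Known limitations

- The linear treatment of a binary trait inherits all caveats above;
  heritabilities are on the observed (1/2) scale.
- REML standard errors are not reported (the information matrix at the
  optimum is available internally but not exposed).
- The BayesB pi is fixed, not estimated.
- Exact PEV computation is quadratic in pedigree size per chunk and
  intended for up to a few tens of thousands of animals.
- The haplotype scan tests each focal haplotype marginally; rare
  haplotypes below the frequency floor are never pooled.
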