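# Methods

This note documents the models, the synthetic data they are exercised
on, the numerical choices, and what a passing test does and does not
establish.

## Models

### Phenotype adjustment

Traits are pre-adjusted in a first stage: ordinary-least-squares
residuals of the trait on categorical fixed effects (herd, year, sex,
…; interactions as combined factors), by pseudoinverse so rank-deficient
full-dummy designs are fine. Every mixed model downstream sees only
these residuals plus an intercept. The two-stage approach slightly
underestimates standard errors relative to a joint fit, which is
acceptable at the scale of the questions asked here (accuracy
comparisons, not fixed-effect inference).

### GBLUP and REML

The base model is y = 1μ + Σᵢ gᵢ + e with var(gᵢ) = Gᵢσ²ₐᵢ and
var(e) = Iσ²ₑ. GRMs are VanRaden method 1, G = Z_c diag(w) Z_cᵀ / Σ 2pⱼqⱼwⱼ,
with 2p-centered genotypes, observed (in-sample) allele frequencies, and
optional positive per-SNP weights; monomorphic SNPs are dropped. A ridge
of 10⁻⁶ is added to any GRM before factorization; because the ridge is
on the identity it is mathematically an addition of 10⁻⁶σ²ₐ to the
residual variance, so the SNP-BLUP dual remains exact (this identity is
asserted in the equivalence test).

Single-GRM REML is solved exactly: one eigendecomposition of G turns the
restricted likelihood into a 1-D function of θ = σ²ₐ/(σ²ₐ+σ²ₑ), profiled
over the total scale and maximized by bounded search (xatol 10⁻¹²).
Multi-GRM REML uses average-information (AI) iterations with two
safeguards: an active-set step (components a step would push below the
variance floor, 10⁻⁸·var(y), are pinned there and the step re-solved on
the rest) and step-halving toward the current point whenever a proposed
step lowers the restricted likelihood. Convergence is |Δlogℓ| < 10⁻⁸;
unconstrained AI alone oscillates when a component sits on the zero
boundary, which is the common case in two-GRM fits with a weak second
panel. Standard errors come from the inverse AI matrix at the optimum.

Prediction uses the BLUP identity ĝᵢ = σ²ₐᵢ Gᵢ[:, ref] V_rr⁻¹(y_ref − μ̂),
with μ̂ the GLS intercept on the training rows. Validation individuals
enter only through relationship rows; a test asserts their phenotypes
can be garbage without changing any prediction.

### Mixed-model GWAS

Per-SNP tests hold the variance components at their null-model estimates
(the P3D/EMMAX approximation): one eigendecomposition of G whitens the
model, after which every SNP is a two-column GLS problem and the scan is
two matrix products. Wald p-values use the normal approximation.
Refitting variance components per SNP would change p-values negligibly
at the simulated scales and cost an eigendecomposition per SNP.
The per-SNP genetic-variance share is 2p(1−p)α̂²/σ²ₐ × 100.

LD pruning walks windows (default 5000 SNPs, shifted by 100) in genomic
order within chromosome: in each window the most significant retained
SNP is found and every other retained SNP with squared genotype
correlation ≥ 0.95 against it is removed. Ties in significance break
toward the smaller coordinate. Pruning is per chromosome; cross-
chromosome r² is never computed. Pruning each chromosome's ranked stream
independently (rather than one genome-wide stream) is a choice; the
windows never span chromosomes either way.

### Weighted GBLUP

Iteration 1 is plain GBLUP. Effects are back-solved from training
breeding values, α̂ = diag(d) Z_cᵀ G_rr⁻¹ ĝ_ref / s (s the GRM scale), so
Z_c α̂ reproduces ĝ at full column rank; weights are
dᵢ = 1.25^(|α̂ᵢ|/sd(α̂) − 2), monotone in |α̂| and scale-free. Weights are
not renormalized — the GRM denominator Σ2pq·d absorbs the level. sd(α̂)
is recomputed each iteration. The accuracy denominator for *all*
iterations is the iteration-1 (unweighted) REML h²: the weighted-GRM h²
is not a trait heritability (the weights deliberately distort the
relationship scale), and using it per iteration makes the trajectory
incomparable — in testing the apparent accuracy dropped by ~0.1 between
iterations while the raw validation correlation rose.

### BayesR

SNP effects on the standardized-genotype scale follow a four-class
normal mixture with variances (0, 10⁻⁴, 10⁻³, 10⁻²)·σ²g and Dirichlet
(1,1,1,1) mixture prior. The Gibbs sampler is residual-updating: per
sweep each SNP's class is drawn from the marginal conditional (effect
integrated out) and its effect from the conditional normal; then π
(Dirichlet), σ²ₑ (scaled inverse chi-square, prior df 4, scale var(y)/2),
and σ²g.

σ²g is sampled from its scaled-inverse-chi-square conditional over the
current effects, but its prior is **anchored**: prior scale var(y) with
prior df of the order of the SNP count. This is a stability requirement
discovered during implementation, not a tuning choice: with a diffuse
prior the σ²g update is a near-martingale multiplicative random walk
that drifts toward zero whenever the per-SNP signal is weak, the 10⁻⁴
class becomes indistinguishable from the null class, and the mixture
proportions can never concentrate (verified empirically on null data:
the scale halved every few thousand sweeps and π₀ stalled near 0.7).
Anchoring pins the class grid near phenotypic variance — the same effect
as pre-estimating the genetic variance, a known alternative formulation
— while strong data can still shift it.

Two genetic-variance summaries are reported: `sigma2_g_mean`, the
posterior mean of the *realized* genetic variance var(Wβ) per sweep
(comparable to a REML additive variance; σ²g + σ²ₑ ≈ var(y) on
well-specified data), and the sampled mixture scale, kept in
diagnostics. Chains are deterministic given the seed; the default
desk-scale schedule is 10,000 sweeps / 4,000 burn-in / thin 10 (the
published-scale 50,000/20,000 is a config value), and the effective
sample size of the genetic-variance chain is reported so adequacy can be
checked.

Statistical limits worth knowing: with m SNPs and discriminability
a = γ₁σ²g·n/σ²ₑ between the null and the 10⁻⁴ class, the posterior width
of π₁ scales as 1/(a√m). Null-class concentration above 0.95 therefore
needs n in the thousands at m = 2000 — the calibration tests use n =
8000 (null) and n = 1000 (30-QTL recovery), and no setting of the
sampler can beat that information bound.

### Expression-based selection

GSA regresses per-gene expression on the adjusted phenotype with diet
and sire as fixed effects; repeated ages are collapsed to the per-animal
mean first, so each animal is one observation. eQTL scans regress
expression on allele count per (SNP, gene) at each age via the
residualize-then-correlate identity (equivalent to per-pair OLS t-tests,
vectorized). Both use the fixed nominal threshold p < 0.0032 with no
multiplicity correction — appropriate for pre-selection, where a false
positive only pads the SNP panel. Expression enters as log(count+1) by
default (variance stabilization); raw-scale regression is a flag.
Harvested intervals are strand-aware: [TSS−300, end] on +, [start,
end+300] on −. Cis/trans is annotated but both enter selections.

### Cross-validation design

The discovery set is the best of 100 random subsets under Σ x'Gx/2
(ties break by draw order). k-means folds: k-means (best of 50 starts)
on the top 20 GRM principal components, 100 clusters at full scale
(scaled to the simulated n in the drivers), clusters packed greedily —
largest first into the smallest fold — so no cluster splits. The
packing rule and the PC truncation are choices the original description
leaves open; both are parameters.

### Evaluation

Accuracy = r(adjusted phenotype, GBV)/√h² per fold; empirical SE =
sd(fold accuracies)/√(n_folds); bias = OLS slope of phenotype on GBV,
averaged per fold (pooled-regression mode available upstream by
concatenating folds). The h² in the denominator is the training REML
estimate of the same strategy (for wGBLUP: of iteration 1, see above).

## The synthetic world

Haplotypes are latent Gaussian AR(1) processes along each chromosome,
thresholded at per-SNP allele-frequency quantiles — so adjacent-SNP
correlation decays geometrically with `ld_decay` (default 0.7) and
pruning/windowing behave as on real block-structured data. Families are
half-sib: a family shares a sire whose two haplotypes are recombined
into each offspring's paternal gamete (switch probability 0.02/SNP);
the maternal gamete is drawn fresh. `n_families <= 1` means an unrelated
base population. Default sizes in the analysis drivers (1,500 animals,
75 families, 3,000 SNPs, 20 QTL, h² = 0.25) are desk-scale stand-ins
for the original design (~13,700 animals, ~59,000 array SNPs, h²
0.24–0.27); every second simulated SNP acts as the "array" and the full
panel as imputed sequence so pre-selection can add off-array variants.

What the generator does **not** emulate: coalescent-realistic allele
frequency spectra and long-range LD, genotyping/imputation error,
selection, assortative mating, maternal pedigree structure, and
RNA-seq count overdispersion (expression is log-normal around a gene
baseline). A green directional test therefore establishes that the
methods rank as expected *under the stated genetic architecture and
family structure*, not that effect sizes match any real cattle
population — the original study's headline accuracies are properties of
a private 13,717-animal dataset and are not reproducible from it.

## Numerical choices and degenerate inputs

- Missing genotypes are mean-imputed (2p) only at GRM/regression entry;
  the stored integer matrix is never modified.
- Monomorphic SNPs: excluded from GRMs (warning), skipped in eQTL
  subsamples (counted), rejected by BayesR standardization (dropped
  before sampling).
- sd(α̂) = 0 in the weight update returns all-ones weights with a
  warning (weighted GRM = unweighted GRM).
- Empty top-SNP selections are valid and degrade two-GRM strategies to
  the base strategy (asserted to 10⁻⁸).
- GWAS effects for SNPs with degenerate design (zero variance after
  whitening) get α = 0, p = 1.
- Hardy-Weinberg QC uses the exact conditional test on genotype counts
  (default threshold 10⁻⁶, default on).

## Known limitations

- AI-REML is dense (O(n³) per iteration); the exact eigen path covers
  the single-GRM case but two-GRM fits beyond ~3,000 individuals get
  slow.
- The BayesR sampler runs one chain; the ESS diagnostic flags, but does
  not fix, poor mixing.
- The GWAS scan does not remove the tested SNP's own contribution to
  the GRM (proximal contamination); at the simulated panel sizes the
  deflation is negligible, and the null-calibration test bounds it.
- `run_strategy` reports weighted GBLUP at iteration 2 as its headline
  (the first weighted round); the full trajectory is available from
  `wgblup.run_wgblup` and the per-iteration bias growth is tested.
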