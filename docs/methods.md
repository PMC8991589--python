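# Methods

This note documents the statistical models behind `prsforge`, the choices
made where the design was genuinely open, and what the synthetic cohorts do
and do not establish about real data.

## The two-cohort design

The pipeline mirrors the standard development/validation split for
small-panel polygenic risk scores: weights are estimated on a GWAS-like
training cohort (individual-level dosages, array-scale QC) and all
performance metrics are computed on an independent case-control validation
cohort (genotyping-panel QC). Nothing estimated on the validation cohort
ever feeds back into a score; the only coupling is the frozen weight file
and its effect-allele labels, which validation dosages must match (a
mismatch raises rather than silently flipping).

## Synthetic cohorts

`synthdata.simulate_cohort` draws genotypes per haplotype in Hardy–Weinberg
equilibrium. Within an LD block each haplotype carries a latent Bernoulli
allele `Z ~ Bern(p0)` (`p0` = block mean MAF); each member SNP copies `Z`
with probability `c` and otherwise redraws an allele whose frequency is
adjusted so the SNP's marginal MAF is preserved exactly. The dosage
(composite) correlation between two block members with equal MAFs is `c²`,
so `c = target_r2^{1/4}`; with unequal MAFs `c` is solved from the same
closed form at the block-mean frequency and the realized r² can deviate a
few percent from the target. The verification metric is composite r²
(squared Pearson correlation of dosages) because phase is never observed
downstream.

Disease status follows a logistic liability

    logit P(case) = α + Σ_k β_k x_k + Σ_j γ_j (c_j − c̄_j) + Σ δ · x_i x_j

with per-SNP log odds ratios β, centered covariate effects γ and optional
pairwise interaction coefficients δ on the dosage product. The intercept α
is calibrated by bisection (tolerance 1e-4 on the prevalence scale) against
a simulated reference pool so the expected case probability equals the
requested case fraction; samples are then drawn in batches and retained
until both strata are exactly full. Estrogen-receptor subtype labels are
assigned by thinning cases at `er_pos_fraction`, or — when per-SNP subtype
overrides are given — by two separate subtype liabilities whose intercepts
are calibrated to the marginal subtype prevalences (the overlap correction
is second-order and absorbed by the exact-count rejection sampling).

Covariate distributions (age uniform 35–70, BMI ≈ N(23.5, 3), menarche
≈ N(14, 1.5), parity Poisson(1.2), 2% family history, menopause linked to
age, log-normal external 5-year risk around 0.54%) are conventions chosen to
be demographically plausible for a middle-aged female study population; they
are drawn independently of genotype unless the `genotype_covariate_corr`
robustness switch is set. Consequences: passing tests show the *methods*
behave correctly under the assumed generating model; they say nothing about
allele-frequency misspecification, cryptic population structure beyond the
two-subpopulation MAF-shift helper, genotyping batch effects, or covariate–
genotype confounding, none of which the generator emulates by default.

Related samples are planted on unphased dosages: duplicates copy rows;
parent–offspring transmits one allele per locus with probability `x/2`, the
other drawn at the population frequency; second-degree relatives transmit
through a coin-flipped ancestral path (expected kinship 1/8). These
constructions reproduce the expected KING-robust φ of 0.5 / 0.25 / 0.125
without simulating pedigrees.

## Quality control

The exact Hardy–Weinberg test conditions on the observed allele counts and
sums, over heterozygote counts of matching parity, the probabilities of all
configurations no more probable than the observed one — the standard exact
construction, enumerable by an independent big-integer oracle, which the
test suite sweeps exhaustively for all tables up to total 50. KING-robust
kinship is `φ = (N_{Aa,Aa} − 2·N_{AA,aa}) / (N_{Aa}(i) + N_{Aa}(j))` over
jointly observed loci; a pair with no heterozygous loci is reported
not-evaluable and kept. Kinship is only meaningful with thousands of loci —
at 24 SNPs the estimator's noise dwarfs the 0.0884 threshold, so the demo
pipeline disables the relatedness filter for its panel-sized data and the
relatedness tests run on 2,000–5,000-SNP simulations.

Filters run in a fixed order (SNP call rate → sample call rate → MAF → HWE
in controls then cases → duplicate concordance → monomorphic → kinship →
per-sample failed-SNP count → mean imputation), and per-SNP statistics are
recomputed after every sample removal. Conventions worth knowing:

* the per-sample "failed SNP" count is the number of no-calls among
  surviving SNPs (the reading under which the rule can differentiate
  samples);
* kinship exclusion removes one member per flagged pair — the lower
  call-rate member, ties keeping the earlier sample in input order;
* MAF, HWE and kinship are computed on hard 0/1/2 calls only; mean
  imputation (cases and controls pooled) is strictly the last step and may
  produce fractional dosages, which no earlier statistic ever sees. This
  makes `apply_qc` idempotent, which the suite asserts.

## Weighting models

**RLR** fits one univariate, unadjusted logistic regression per SNP;
separation or non-convergence falls back to a lightly penalized fit and is
flagged on the weight object. Because the regressions are unadjusted,
confounding shifts RLR weights where it would not shift LRR's.

**LRR** maximizes the penalized log-likelihood `ℓ(β, γ, α) − (λ/2)‖β‖²`
with the penalty on SNP coefficients only (age, PC1, PC2 and the intercept
are free), via L-BFGS with analytic gradients. λ is the argmin of mean
10-fold cross-validated log-loss over a grid ordered strongest-penalty
first, so ties resolve to the simpler (more-shrunken) model. At λ → 0 the
fit reproduces the joint MLE to <1e-3; the SNP-beta L2 norm is
non-increasing in λ (per-coordinate monotonicity can fail under
correlation, so the norm is the asserted invariant).

**ANN.** Dosages (z-scored with training statistics) pass through
`n_hidden_layers` dense layers of width `round(√m) + 2` (7 for a 24-SNP
panel) with leaky-ReLU (slope 0.01) and inverted dropout, then a *linear
bottleneck* of width 6; the bottleneck concatenated with (age, PC1, PC2)
feeds a single sigmoid output trained with Adam (lr 0.01) on cross-entropy.
Tuned defaults: 60 epochs, 3 hidden layers, dropout 0.4. Open design points
and how they were resolved:

* *Bottleneck width vs. hidden-width rule.* The width-6 bottleneck and the
  `√m + 2 ≈ 7` rule are both kept: the bottleneck is a distinct narrower
  layer by default, with `bottleneck_is_last_hidden=True` collapsing the two
  readings.
* *Batch size.* Sixty **full-batch** Adam steps provably cannot train this
  network (the loss stays at ln 2 and held-out AUC at chance), so "60
  iterations" is read as 60 epochs of mini-batch SGD with the TF-1.x-era
  default batch size 32 (`batch_size=0` restores full-batch for
  comparison). All randomness (init, shuffling, dropout masks) derives from
  one seed; training is bit-reproducible.
* *The score.* The network is a classifier; the continuous PRS extracted
  from it is the genotype pathway's additive contribution to the pre-sigmoid
  logit — bottleneck activations times their output weights plus the output
  bias. Since the full logit is exactly this quantity plus the covariate
  terms, "full logit minus covariate contributions" is the same number, and
  a single implementation serves both readings. Covariates can therefore
  never leak into the score, which the suite asserts by scoring identical
  genotype rows under different covariates.

Subtype-specific training uses exactly the subtype's cases plus *all*
controls; the training mask is exposed (`training_mask`) and asserted.

Cross-validation is stratified by case status (guards against degenerate
folds at small n), partitions every sample into exactly one validation
fold, and scores grid points by mean validation log-loss.

## Evaluation

* **IQ-OR**: logistic slope of status on score divided by the control-stratum
  IQR; Wald 95% CI. Invariant to affine score rescaling.
* **Q4 vs Q1 OR**: cross-product OR of the extreme control-defined
  quartiles; Woolf log-scale CI; Haldane–Anscombe +0.5 when a cell is empty
  (flagged).
* **AUC**: Mann–Whitney with ties counting ½; Hanley–McNeil closed-form SE
  with `Q1 = A/(2−A)`, `Q2 = 2A²/(1+A)`; normal CI truncated to [0, 1].
  Exhaustive pair counting is the test oracle.
* **Calibration**: control-score decile bins; the reference is the pooled
  middle pair of bins so expected log-ORs straddle zero (a bottom-bin
  reference is available, under which all expected log-ORs are positive).
  Expected log-OR of a bin is its mean score minus the reference mean (the
  score is already on the log-OR scale); observed log-OR comes from the
  bin-vs-reference 2×2 table. The O/E OR is the through-origin least-squares
  slope of observed on expected (an intercept-free regression, matching the
  single-coefficient reading of the summary), with a t-based CI from the
  regression SE. On correctly specified scores the slope approaches 1, and
  doubling all scores halves it.
* **Residual adjustment** regresses the score on non-genetic risk factors
  (or the external absolute-risk column alone) by OLS and hands the
  residuals to every metric unchanged. The external 5-year risk is consumed
  as an opaque column; no absolute-risk model is implemented.
* **Interaction scan**: per unordered pair, logistic regression of status on
  both dosages and their product; Wald P on the product term
  (likelihood-ratio fallback under separation, flagged); Bonferroni
  threshold α / C(m, 2) — 0.05/276 ≈ 1.8e-4 for 24 SNPs. An interaction
  term can be appended to the ridge design as a product pseudo-SNP.

## The interaction demonstration

The claim that a nonlinear score captures SNP×SNP interactions is tested in
isolation. For an interacting pair at MAF 0.3, about two thirds of the
variance of δ·x_i·x_j is linear in the marginal dosages, so a per-SNP
weighting recovers most of a planted interaction and the nonlinear residual
(~0.007 AUC at δ = 0.7) is smaller than the tuned network's own excess
risk; a mixed additive-plus-interaction benchmark therefore measures
optimizer noise, not interaction capture. The benchmark instead plants a
*purely epistatic* pair: main effects β = −δ·E[x] cancel each marginal
association exactly, leaving RLR at chance (AUC ≈ 0.50) while the network
learns the interaction (held-out AUC ≈ 0.52, mean paired advantage ≈ +0.02
over 20 seeds at n_train = 4,000). This isolates the property; it does not
claim the network wins on predominantly additive architectures, where it
tracks the ridge score to within ~0.01 AUC.

## Problem sizes and numerics

The test suite and acceptance script use training cohorts of 2,000–20,000
samples, validation cohorts of 800–8,000, panels of 24 SNPs (5,000 for
relatedness experiments), 100 replicates for calibration coverage and 20
seeds for the paired interaction comparison — sizes at which every targeted
effect is identifiable while a full run stays in the minutes range on one
CPU core. Tolerances: HWE vs enumeration 1e-12; ridge-vs-MLE 1e-3 at
λ → 0; intercept calibration 1e-4; PC sign fixed by orienting each
component's largest-magnitude loading positive; logistic separation
anywhere falls back to penalized estimation with a flag rather than an
error.

## Known limitations

* Panels are tens-to-thousands of SNPs; no genome-scale methods (clumping +
  thresholding at scale, LDpred) and no recombination maps.
* Composite (dosage-correlation) r² throughout; haplotype-based reference
  LD values differ by design.
* The generator's covariates are independent of genotype by default, so
  adjusted and unadjusted metrics nearly coincide in simulations — real
  cohorts need not behave this way.
* Binary PLINK (.bed) and VCF input are out of scope; text dialects
  (.ped/.map, .raw, TSV) only.
* The ANN score's absolute scale is only approximately a log-OR; its
  calibration slope on simulated data is noticeably farther from 1 than the
  linear scores', consistent with dropout-regularized underconfidence.
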