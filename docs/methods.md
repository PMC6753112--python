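# Methods

`famh2` implements a family-based heritability analysis of left- and
right-ventricular phenotypes measured by ECG and cardiac magnetic
resonance (CMR), together with a synthetic family-cohort generator that
reproduces the statistical structure such a study assumes. This note
records the models, the generator's design, the numerical choices, and
the known limitations.

## Variance-components model

For a covariate-adjusted phenotype vector *y* on *n* individuals the
model is

    y ~ N(mu 1, sigma_g^2 K + sigma_e^2 I)

with narrow-sense heritability h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2).
The kernel *K* is one of:

* **Pedigree kernel** — the expected additive relationship 2*Phi*, with
  the kinship matrix Phi computed by the standard recursion
  Phi(i,i) = (1 + Phi(f_i, m_i))/2,
  Phi(i,j) = (Phi(f_i, j) + Phi(m_i, j))/2 over a topological ordering;
  unknown parents contribute zero. Cross-family entries are exactly
  zero and 2*Phi* is positive semidefinite.
* **SNP kernel** — the genetic relationship matrix (GRM) from dosage
  data, standardized by sample allele frequencies, with per-entry SNP
  counts under missingness. Off-diagonal entries below a relatedness
  cutoff (default 0.05) are zeroed, so the heritability signal is
  carried by close-relative sharing; in family panels this approximates
  identity-by-descent estimates and avoids the bias of mixing close and
  distant relatives in one kernel.

### Fitting

Both fitters work in the eigenbasis of *K*: one O(n^3)
eigendecomposition per kernel, after which every likelihood evaluation,
score and average-information term is O(n). A `KernelEigen` object can
be shared across fits on the same kernel, which is what makes
200-replicate simulation studies cheap.

* `fit_vc_ml` (pedigree path) — maximum likelihood. The mean and the
  total variance are concentrated out analytically, leaving a
  one-dimensional profile likelihood in h^2 on [0, 1], maximized by a
  101-point grid plus bounded refinement (xatol 1e-8). The polygenic
  model is compared to the individual-specific-only null
  (sigma_g^2 = 0) by a likelihood-ratio test.
* `fit_greml` (SNP path) — REML via average-information (AI) updates
  with EM fallback steps whenever an AI step leaves the feasible region
  or decreases the restricted likelihood; convergence when the
  restricted log-likelihood changes by < 1e-8 (relative), maximum 200
  iterations, non-convergence is an error. Constrained fits clamp
  components at ~0 (1e-8 of the phenotypic variance); unconstrained
  fits allow negative components provided V stays positive definite and
  the component sum is positive. The SE of h^2 comes from the inverse
  AI matrix by the delta method.

The ML/REML split mirrors the two tool families the analysis emulates;
on the same data and kernel the two h^2 estimates agree to ~0.02 at
n >= 400, which is tested.

### Inference conventions

* **LRT P-values** default to the 50:50 chi2_0/chi2_1 boundary mixture
  (P = 0.5 P(chi2_1 >= LRT), P = 1 at LRT = 0); the plain chi2_1 tail is
  available for strict concordance with tools that report it.
* **Wald-approximation SE** for the pedigree path: SE = h^2 / sqrt(LRT),
  reported missing when LRT = 0. This is deliberately the crude
  approximation used in the emulated pipeline; its empirical coverage at
  1.96 SE is ~90–98% across h^2 in 0.2–0.8 (tested), but it degrades
  near the boundary.

## Covariate adjustment

Order fixed: blood-pressure treatment pre-adjustment (+15 mmHg SBP,
+10 mmHg DBP for treated individuals, applied exactly once) -> Box-Cox
-> stepwise selection -> residual extraction. Residuals, not
mixed-model BLUEs, feed the heritability fits.

* **Box-Cox**: profile maximum likelihood over lambda in [-3, 3]
  (601-point grid + bounded refinement to ~1e-5); strictly positive
  input required, no automatic shifting; the profile log-likelihood
  matches the standard normal-plus-Jacobian form (cross-checked against
  an independent reference implementation in the tests).
* **Stepwise selection**: classic forward-backward OLS at entry/stay
  threshold P < 0.01 using partial t-tests (1-df partial F); ties break
  by column order, so selection is deterministic; perfectly collinear
  candidates are skipped with a warning. Candidates default to age,
  sex (0/1), height, weight, BSA, BMI and treatment-adjusted SBP/DBP,
  plus chest lateral diameter for the chest-adjusted ECG-LVM recipe.
* Casewise deletion per trait, so each trait is analysed on its own
  complete-case subset (the modality-specific missingness the generator
  produces mimics ECG/CMR exclusions).

## Phenotype derivation

ECG: Sokolow-Lyon = SV1 + RV5; Cornell = RaVL + SV3 (+0.6 mV in women);
duration products multiply by QRS duration (mV.ms); the 12-lead sum adds
peak-to-nadir QRS amplitudes over all leads. ECG LV mass uses the
sex-specific linear equations in (RaVL + SV3) and weight. The equations'
voltage coefficients (0.026/0.020 g per unit) are negligible against
millivolt-scale sums, so the voltage unit they expect is evidently finer
than the mV in which modern amplitudes are tabulated; `voltage_scale`
(default 1.0) makes the unit explicit, and the synthetic cohort records
scale 100 (0.01-mV units) in its truth manifest, at which the voltage
term carries a physiologically sensible share of the mass.

LVH classification uses >= threshold (35 mV Sokolow-Lyon; 28/20 mV
Cornell male/female; 2840 and 2440 mV.ms products); the boundary
convention is configurable because the source only states that values
below the cut-offs are non-hypertrophic.

CMR: mass = tissue volume x 1.05 g/cm^3; all masses and volumes indexed
to body surface area (Du Bois 0.007184 h^0.725 w^0.425 by default,
Mosteller selectable); ejection fraction = (EDV - ESV)/EDV; chest volume
= pi (lateral diameter / 2)^2 x chest height.

## Genotype QC

Cascade mind (0.05) -> geno (0.05) -> MAF (0.01) -> Hardy-Weinberg exact
test (founders only, P < 1e-8) -> heterozygosity outliers (|F - mean F|
> 3 SD of the method-of-moments inbreeding coefficient). The cascade is
iterated to a fixed point so QC is idempotent. Founders-only HWE avoids
relatedness-driven rejections in family data; the exact test uses the
stable heterozygote-count recurrence and matches a direct enumeration
oracle to 1e-12.

## The synthetic cohort

The generator emulates a panel of ~116 white-British families with ~427
phenotyped members, ascertained for a cardiovascular phenotyping study.
Because the mean number of phenotyped members per family (~3.7) is
smaller than any two-parent family template, each template includes
unphenotyped connector members (typically one parent and married-in
spouses): nuclear families contribute 3–4 phenotyped members, the
three-generation and sibship-with-avuncular templates 5, giving sibling,
parent-child, grandparent and avuncular pairs among phenotyped members.
Default mix: 50% nuclear-2-child, 20% nuclear-3-child, 20%
three-generation, 10% sibship-with-avuncular; multiplicities are
adjusted to bring the phenotyped total within 5% of the target.

* **Genotypes**: gene dropping. Founder alleles are Bernoulli draws at
  per-SNP frequencies (uniform in the MAF range, default 0.05–0.5);
  each non-founder allele is drawn uniformly from the corresponding
  parent's two alleles. Defaults: 2,000 SNPs, 20 causal — GRM-based
  recovery does not need genome scale.
* **Polygenic values**: founder/segregation decomposition — founders
  N(0, sigma_g^2), each non-founder the parental mean plus a
  segregation deviate of variance sigma_g^2/2 (non-inbred pedigrees),
  giving covariance 2 Phi sigma_g^2. A genotype-causal mode sums
  standardized causal dosages with N(0, sigma_g^2/n_causal) effects.
* **Traits and covariates**: age ~ N(59.7, 13^2) truncated to [18, 95];
  sex from the pedigree (~52.5% female); height heritable (h^2 0.75, SD
  6.5 cm net of a 13 cm sex difference); weight = BMI x height^2 with
  BMI ~ N(28.1, 4.8^2); blood pressure ~ N(140.5/81.5) with
  antihypertensive treatment prevalence 0.30 whose measured values are
  lowered by 15/10 mmHg (so the pipeline's pre-adjustment recovers the
  underlying values); CMR LV mass (h^2 0.20) and RV mass (h^2 0.44)
  with weight and SBP loadings; ECG voltages built from a heritable
  myocardial latent (h^2 0.60) plus a chest-lateral-diameter loading.
* **The confounding structure**: chest lateral diameter is modelled as
  a heritable trait (h^2 0.60, SD 2.5 cm) essentially independent of
  height, weight and sex, and loads on the RaVL+SV3 voltage with 4.8 mV
  per cm. These two choices are forced jointly by the calibration
  targets: with the loading at zero, derived ECG LV mass and chest
  diameter must be uncorrelated (which rules out material
  height/weight/sex pathways into chest, since the mass equation
  carries weight directly), while at the default loading the pooled
  Spearman correlation between chest diameter and derived ECG LV mass
  is ~0.67 at large n. A consequence the generator accepts: the
  RaVL+SV3 SD (~12 mV at these settings) is wider than the ~5 mV a real
  cohort shows — the generator prioritizes the dependence structure
  that drives the confounding-attenuation analysis over marginal
  voltage dispersion. Anatomically, the loading direction (larger chest
  -> larger recorded voltage contribution to ECG mass) simply encodes
  the observed positive correlation; it is not a claim about
  torso-impedance physics.
* **Missingness**: 5% of individuals lose their ECG block and 5% their
  CMR block, mimicking modality-specific exclusions.
* All draws flow from one seed through named substreams (one per
  component), so adding a trait does not perturb the others, and
  identical (spec, seed) reproduces output files byte-for-byte.

### What the generator does not emulate

Linkage disequilibrium, X chromosome, genotyping error, assortative
mating, shared-household environment, age structure within pedigrees
(ages are drawn marginally), and the real study's family-size
distribution (see below). Passing tests therefore demonstrate that the
estimators are calibrated under the assumed model, not that real-data
estimates would be unbiased in the presence of, e.g., shared
environment — which the pedigree model attributes to genetics by
construction.

## Design precision and a known limitation

The package's power simulation (200+ replicates of a h^2 = 0.35 trait on
the default panel, each refitted by ML) reports the empirical sampling
SD of the heritability estimate, alongside the asymptotic
Fisher-information SE for the same design (`scripts/acceptance.py`
computes both). For the default template panel both land near 10
percentage points. A design of ~427 phenotyped members organized as
true large extended families — which is what the emulated study used,
including families with solitary phenotyped members at one end of the
size distribution — concentrates more squared-relationship weight per
individual and can reach the ~7.5-point precision such studies
anticipate. The four fixed templates at mean ~3.8 phenotyped members
per family cannot, and within each template the phenotyped-member
patterns were chosen to maximize relative-pair information, so this is
a property of the template approximation itself, not of the fitters.
The phenotyped patterns and this precision gap are recorded here
deliberately: analyses of the package's own output should expect
~10-point sampling SEs at this design scale.

## Problem sizes used in the test and acceptance suites

Simulation studies are sized to keep the full suite in tens of seconds
on one core while leaving Monte-Carlo error well inside the asserted
tolerances: 200 replicates for power and recovery studies (the kernel
eigendecomposition is shared across replicates), 2,000 SNPs / n = 500
for the GRM path, 50 cohort seeds for the confounding-attenuation
majority check, ~5,000 individuals for correlation-target checks, and
100 random pedigrees of up to 40 members for the kinship oracle.

## Numerical choices

* Kernel PSD tolerance: smallest eigenvalue >= -1e-6 (scaled); the
  thresholded GRM is allowed indefinite entries since REML only needs
  V positive definite.
* Profile-likelihood boundary: if the interior optimum's likelihood
  falls below the null's, the estimate is set to the h^2 = 0 boundary.
* GRM monomorphic SNPs are excluded with a warning; missing dosages are
  skipped pairwise with per-entry SNP counts.
* Stepwise ties and all orderings are deterministic; every stochastic
  routine takes an explicit seed.
* Relative-pair correlations double-enter symmetric pair classes
  (sibling, avuncular) so the coefficient is invariant to within-pair
  ordering; the distinct-pair count is reported. Parent-child pairs use
  parent-as-x.
* The heterogeneity z-test between two heritability estimates treats
  them as independent; on overlapping individuals this understates the
  covariance and so overstates |z| — output metadata carries this
  caveat.
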