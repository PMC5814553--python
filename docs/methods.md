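# Methods

`traitgs` implements the statistical machinery of a two-stage genomic
selection (GS) analysis for a low-heritability focal trait (think biomass
yield in an inbred sorghum panel) aided by cheaper, higher-heritability
correlated traits (plant height, moisture, area under the growth curve).
This note records the models, the numerical choices, what the synthetic
data do and do not emulate, and the design decisions that were genuinely
open.

## Stage 1: spatial adjustment of field trials

Each trait-by-trial combination is analysed with

    y_ij = mu + G_i + B_j + e_ij,

where `G_i` is the **fixed** effect of genotype i (checks included on the
same footing), `B_j ~ N(0, sigma2_b I)` is a random incomplete-block
effect, and the plot residuals follow either iid errors or a separable
first-order autoregressive field, `e ~ N(0, sigma2_e AR1(rho_row) (x)
AR1(rho_col))`.  Missing plots subset the Kronecker covariance to the
observed cells; with at most a few hundred plots per trial a direct dense
solve is cheap and exact.

REML is computed on orthonormal error contrasts (any orthonormal basis of
the complement of the fixed-effects column space gives the same value,
making the reported log-likelihood well defined).  The residual variance
is profiled out analytically; the remaining parameters — the
block-to-residual variance ratio on a log scale and the AR(1)
correlations on an atanh scale — are maximized by Nelder–Mead from
multiple starts (rho in {0, ±0.5}), converging when the log-likelihood
improves by less than 1e-8.  Candidate residual structures are compared by
`AIC = -2 loglik + 2 (number of variance parameters)`; fixed effects are
identical across candidates so the REML likelihoods are comparable, and
ties break toward fewer parameters, then candidate order.

Genotype BLUEs (adjusted means) are GLS estimates at the converged
components, with standard errors from the fixed-effects covariance.
Multi-year combination scales each year's BLUEs (`none`, `center`, or
`standardize` = center and divide by that year's SD; the default is
`standardize` because "scaled" is not otherwise pinned down) and averages
each genotype over the years it appears in, recording the contributing
year count.

## Stage 2: GBLUP

The genomic relationship matrix is VanRaden method 1 on observed allele
frequencies: `A = W W' / (2 sum p_k (1-p_k))` with `W` the dosage matrix
centered by twice the allele frequency; monomorphic markers drop out of
both numerator and scale.  Missing dosages are mean-imputed beforehand
(a deliberate, simple stand-in for haplotype-based imputation).  A ridge
of 1e-6 is added to the diagonal of A at solve time only.

**Univariate.**  `y_i = mu + g_i + e_i` with `g ~ N(0, A sigma2_g)`.  A
single eigendecomposition of the observed submatrix of A reduces REML to
a one-dimensional profile over the variance ratio, maximized by a coarse
grid plus Brent refinement.  BLUPs for all genotypes (observed or not)
follow from `sigma2_g A[:,obs] V^-1 (y - mu)`.  Genomic heritability is
reported as the ratio of additive to phenotypic variance *as expressed in
the phenotypes*: `h2_g = abar sigma2_g / (abar sigma2_g + sigma2_e)` with
`abar` the mean observed diagonal of A.  On an inbred panel `abar ~ 2`,
and ignoring it would understate the variance fraction by roughly half;
for a kernel standardized to unit mean diagonal the formula reduces to
the familiar `sigma2_g/(sigma2_g+sigma2_e)`.

**Bivariate.**  `Y_i = mu + g_i + e_i` with `g ~ N(0, G (x) A)` and
`e ~ N(0, I (x) R)`, `G` and `R` unstructured 2x2, and records missing
per trait via trait-specific incidence.  The observed-data REML
log-likelihood is maximized by guarded average-information (AI) updates:
the AI step is damped (Levenberg-style; heavy damping in early iterations
gives EM-like short steps) and step-halved until the log-likelihood
increases, so the iteration is monotone by construction — an invariant
asserted every iteration.  Iterates leaving the PSD cone are bent back by
eigenvalue clipping; when the optimum itself sits on the boundary
(estimated correlation ±1) the loop detects the resulting crawl (five
consecutive near-flat accepted steps) and stops.  Convergence otherwise:
relative log-likelihood change < 1e-8 or parameter change < 1e-6, cap
1000 iterations.  When both traits are observed on the same genotypes an
equivalent canonical-transformation likelihood (one eigendecomposition,
O(n) per evaluation, log-Cholesky parameterization, L-BFGS-B plus a
derivative-free polish) is used for speed; tests pin the two routes to
the same optimum.

A trait with *zero* records is tolerated as a degenerate case (its
parameters stay frozen, cross-covariances at zero) so that the bivariate
fit collapses exactly onto the univariate one; two traits that are both
observed but never on the same genotype raise an identifiability error.

`blup_given_components` solves the multi-trait mixed-model equations at
fixed (G, R); focal predictions for focal-missing genotypes then use
those genotypes' own secondary records through both the genetic and
residual covariances — the trait-assisted mechanism.  Standard errors for
the genetic and residual correlations come from a delta method applied to
an observed-information matrix obtained by finite differences of the
analytic REML score; this is an approximation and is labelled as such.

## Cross-validation strategies

Five strategies share one k-fold scheme (default k=5, 30 repeats;
balanced random partitions, byte-identical across strategies within a
run, asserted by hash):

* **standard** — univariate focal fit on the training folds;
* **indirect** — univariate fit of the secondary trait; its validation
  GEBVs are correlated against the focal adjusted means;
* **multi-trait indirect** — univariate fits of ≥2 secondary traits; the
  pooled GEBV vectors are standardized and combined with weights equal to
  each trait's genetic correlation with the focal trait (estimated by
  bivariate fits on the training records of each fold, averaged within a
  repeat — the weight-estimation timing was open and this choice avoids
  validation leakage);
* **multi-trait** — bivariate fit on training records of both traits
  (CV1: no validation information enters);
* **trait-assisted** — bivariate fit on focal training records plus *all*
  secondary records, validation genotypes included (CV2-style).

Variance components are re-estimated within every fold from that fold's
Table-style training records by default (`components_mode="full_data"`
reuses components estimated once from all records, kept only for
comparison because it leaks validation focal records).  Accuracy per
repeat is **one** Pearson correlation between the pooled out-of-fold
predictions of all genotypes and the focal adjusted means — never an
average of per-fold correlations; a crafted counter-example in the tests
distinguishes the two.  Accuracy is not divided by h.

Derived statistics: the growth-curve area is the trapezoidal sum
`sum (h_{i-1}+h_i)/2` with `h_0` a baseline (default 0, height at
planting) and unit spacing; the coincidence index is `CI = (B-R)/(T-R)`
with `T = round(intensity n)` selected by each ranking (stable input
order breaks ties), overlap `B`, and chance overlap `R = round(T^2/n)` —
at n=453 and 20% intensity, T=91 and R=18; expected selection accuracies
are `r_PS = h_focal` and `r_IPS = h_secondary * cor_g`, reported with the
strategy-to-PS and strategy-to-IPS ratios.  The training-fraction sweep
draws fresh random f-subsets per repeat (not inverted folds — both
readings were defensible; a fresh subset keeps every fraction on the same
footing) and keeps the trait-assisted secondary-records-complete
convention.

## Synthetic data

The generator provides the statistical structure the analysis assumes and
nothing more:

* **Genotypes** — biallelic dosages, allele frequencies uniform on
  [maf_low, maf_high], inbred by default (dosages {0,2}; a heterozygous
  mode exists).  Optional Balding–Nichols subpopulation structure
  (`n_subpops`, `fst`) induces panel-level kinship; `fst=0` (the default)
  gives exchangeable individuals.
* **Phenotypes** — `n_qtl` markers (default min(500, p); infinitesimal
  mode sets n_qtl = p) carry effect vectors drawn from a multivariate
  normal with the configured genetic correlation; breeding values are
  rescaled per trait so their variance equals the heritability, residuals
  are multivariate normal with the configured residual correlation, and
  total phenotypic variance is ~1 per trait — heritability is the only
  scale parameter, matching an analysis run on scaled adjusted means.
* **Field trials** — RCBD or augmented layouts (unreplicated entries plus
  checks repeated once per block) on a row-by-column grid, iid block
  effects, and a separable AR(1)xAR(1) residual surface sampled as
  `L_row Z L_col'`.

What the generator does **not** emulate: linkage disequilibrium and
haplotype structure, multi-year genotype-by-environment interaction,
selection over generations, non-Gaussian trait distributions.  Passing
tests therefore demonstrate correctness of the estimators and the
strategy protocol under the assumed model, not robustness to real-genome
LD patterns.

### The study panel

`sorghum_panel_config()` freezes the study conditions used by the
strategy-ranking experiments: 453 inbred lines, 59264 SNPs (the full
panel marker scale — at a few thousand markers, sampling noise in the
relationship matrix differentially inflates the apparent accuracy of
high-heritability secondary traits and distorts the indirect-vs-standard
comparison), focal h2 0.26, secondary h2 0.9, genetic correlation 0.85,
residual correlation 0.35, 10 subpopulations with Balding–Nichols
fst 0.6.  Two of these values deserve justification.  The residual correlation is not printed for the
real traits; 0.35 is a typical moderate value for yield against a
late-season height-type trait and activates the residual information
channel that lets trait-assisted predictions exceed `sqrt(h2)` accuracy.
The structure level is deliberately high: a pre-breeding diversity panel
owes most of its genomic prediction accuracy to kinship, structure, and
long-range LD jointly, and with LD-free simulated markers the `fst` knob
must carry all of that effective relatedness on its own — fst 0.6 puts
standard-GS accuracy for a 0.26-heritability trait near the ~0.4 such
panels show, by the usual deterministic accuracy arguments.  It should be
read as an effective-relatedness parameter, not a literal fixation index.

The generator delivers the configured genetic correlation and per-trait
heritabilities *exactly in the realized sample* (the breeding-value
columns are whitened and re-mixed by the target correlation's Cholesky
factor — a cross-trait linear map of the marker effects, so breeding
values stay additive in the markers).  Without this, the handful of
effective structure dimensions lets the realized correlation wander
±0.15 around its target, which is no longer the stated study condition.

One caveat on the strategy ranking: the indirect-vs-standard comparison
is a tight margin by nature (the corresponding real-data gap is 0.37 vs
0.40).  Under these study conditions the ordering holds at the
experiment's fixed seeds, but panels whose realized relatedness happens
to favour the high-heritability secondary trait can close or flip the
~0.02–0.04 gap; the trait-assisted advantage (>0.10) and the
multi-trait-equals-standard result are robust across seeds.

### Genetic architecture in recovery experiments

Trait architecture is an assumption (nothing pins it down).  With LD-free
markers, a sparse-QTL trait analysed through a GRM built from *all*
markers is a misspecified model, and REML attenuates h2 substantially
(~0.14 recovered for a true 0.26 with 500 QTL among 5000 markers) — a
real property of the design, not an estimator defect, because no LD
exists to tag the causal subset.  Parameter-recovery experiments
therefore use the infinitesimal mode (n_qtl = p), where the GBLUP model
is correctly specified and recovery is unbiased.  Strategy rankings are
insensitive to this choice and keep the sparse default.

## Problem sizes

Experiments run at the scales the analyses target: the panel comparison
at n=453 with 5000 markers and 30 CV repeats; heritability recovery over
30 replicates of the same panel size; genetic-correlation recovery at
n=500; spatial recovery on a 480-plot 12x40 grid over 30 replicates.
The spatial-recovery trial is a replicated RCBD (20 genotypes x 24
blocks) rather than a lightly replicated augmented design: with ~400
unreplicated fixed genotype effects only ~64 error contrasts remain, the
per-replicate AR(1) estimates then have sd ~0.3 (occasionally peaking at
negative rho — genuinely, by their own likelihood), and no estimator can
be assessed for bias at that noise level; 24 blocks also give the block
variance enough draws for the bias check.  Replication restores ~460
contrasts and clean recovery.  Oracle comparisons use n ≤ 50 panels and
6x6 grids, where dense brute-force solutions are exact and fast.

## Known limitations

* Two traits per mixed model (the multi-trait indirect index combines
  univariate fits instead of fitting a ≥3-trait model).
* Mean imputation ignores haplotype information; with high missingness it
  shrinks relationships toward the mean.
* Correlation standard errors use a numerically differentiated observed
  information; near a PSD boundary they are unreliable and may be
  reported as undefined.
* The spatial model menu is {iid, AR1xAR1} with homogeneous variances; no
  splines, nugget-free variogram diagnostics, or per-column variances.
* Stage-1 BLUE standard errors are conditional on the estimated variance
  components (no degrees-of-freedom correction).
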