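# Methods

## The problem

A biallelic SNP that interacts with an unobserved partner — an environment,
another locus, anything latent — leaves no trace in the usual additive GWAS
scan, but it does leave a second-moment footprint: conditional on genotype
X, the residual variance of an affected trait and the residual covariance
between affected traits become functions of X.  For a trait
Y_k = beta_k X + phi_k M + gamma_k M X + eps_k with a standardized latent
environment M:

    Var(Y_k | X)       = (phi_k^2 + sigma_k^2) + 2 phi_k gamma_k X + gamma_k^2 X^2
    Cov(Y_k, Y_k' | X) = phi_k phi_k' + (phi_k gamma_k' + phi_k' gamma_k) X
                         + gamma_k gamma_k' X^2

Testing whether these individual-specific variances (ITV) and covariances
(ITC) depend on genotype detects the interaction without ever specifying M.
With r correlated traits the covariance terms add r(r-1)/2 extra channels,
which is where the power gain over single-trait variance tests comes from.

## The testing pipeline

1. **Residualization.** Traits are standardized (optionally within groups
   such as sex, with an optional outlier cut at 4 sd above the group mean)
   and residualized by OLS on an intercept, measured covariates, structure
   axes, and the tested SNP (additive coding; a 2-df genotypic coding is
   available for the dominance retest).  The genotype is residualized on
   the structure axes.  Per SNP, the SNP effect is removed from the
   H-residualized traits through the Frisch–Waugh–Lovell identity (a
   rank-1 update), which is exactly the joint fit at O(n·r) per SNP.
   Residuals are internally studentized, e/sqrt(1-h), so their squares are
   unbiased for the conditional variance; h is the leverage of the joint
   design.  (External studentization would require a per-observation
   refit; at GWAS sample sizes the two are indistinguishable, and internal
   is one pass.)

2. **SQ/CP features.** Z = [e_k^2 | e_k e_k'] is the n x (r + r(r-1)/2)
   matrix of squared residuals and pairwise cross products, columns
   mean-centered.  Columns are centered but not variance-scaled: the
   weighted statistic is meant to weight directions by their variance, and
   scaling would silently change that weighting (we verified empirically
   that scaling moves only the weighted variant, not the projection
   variant or the marginal tests).

3. **Kernel independence test.** With linear kernels K = xx' and L = ZZ',
   the HSIC statistic is T = tr(KL)/n.  Everything is computed from the
   d x d Gram matrix of Z — eigenvalues of L are those of Z'Z, and the
   cross-rotation R = V_K'V_L needs only x'Z — so cost is O(n d^2) and
   memory O(n d); no n x n matrix ever exists.  Under the null,
   n·T is asymptotically sum_{ij} (lam_K,i lam_L,j / n) chi2_1.
   * wLIT weights eigenvectors by eigenvalues (the statistic above);
   * uLIT weights them equally, T = tr(RR')/n, equivalent to projection
     kernels; its null is exactly chi-square with d1·d2 degrees of freedom
     (we keep this closed form rather than running the generic machinery);
   * aLIT is the Cauchy combination of the two p-values, hedging the
     unknown position of the interaction signal in the eigenspectrum.
   Feature centering makes the usual double-centering of HSIC kernels a
   no-op (H Z Z' H = Z Z' when Z is column-centered); a test asserts the
   identity instead of assuming it.

### Weighted chi-square tails

The wLIT null requires P(sum w_i chi2_1 > q) to genome-wide accuracy.  We
invert the characteristic function (Imhof's integral) with a truncation
point chosen from an alternating-series bound and composite Gauss–Legendre
panels matched to the oscillation wavelength, vectorized over nodes.
Against high-precision quadrature the absolute error is ~1e-11 in the
regions that matter (p < 0.3 and all tails down to ~1e-9); only for two to
three near-degenerate tiny weights at p ~ 0.5 does it degrade to ~1e-7,
which no decision here depends on.  Below p ~ 1e-9 the oscillatory
integral loses absolute accuracy and the Lugannani–Rice saddlepoint
approximation takes over (relative accuracy at the percent level, ample at
genome-wide thresholds).  Equal weights short-circuit to the exact
chi-square form.  P-values are floored at 1e-300.

### Cauchy combination

T' = mean of tan((0.5-p) pi), referred to the standard Cauchy.  For
p < 1e-10 the tangent is evaluated by its asymptote 1/(p pi) and a large
T' maps back through p ~ 1/(pi T'), so deep-tail aggregates (p ~ 1e-46)
stay exact; inputs are clipped only at the floating-point edges.

### Region test

Multiple SNPs are tested jointly by building the genotype kernel from all
m0 adjusted SNP columns (their joint additive effects removed first); d2
is the numerical rank, and collinear SNPs reduce the rank with a warning.
m0 = 1 reduces exactly to the single-SNP test.

### Numerical rank

Singular values below 1e-10 of the largest are dropped throughout.  This
makes duplicated or collinear SQ/CP columns harmless to the projection
kernel and keeps the chi-square degrees of freedom honest.

## Marginal baselines

Marginal (SQ) regresses each squared residual on the adjusted SNP;
Marginal (SQ/CP) adds the cross products.  Each takes the minimum p-value
over its own column set and applies Bonferroni at alpha / K, with K the
number of principal components of that column set explaining 95% of its
variance.  PCA is on the correlation scale so K is unit-invariant, and K
is computed once per dataset — removing one SNP's additive effect moves
Z's covariance negligibly.  Per-column tests are normal-approximation
score tests (n in the 10^4–10^5 range); an exact-t option exists for
small n.

## Robustness adjustments

* **Genomic control.** lambda = median chi2 / 0.4549 per LIT variant,
  computed on an LD-thinned, significance-pruned p-value set; p-values are
  deflated on the chi-square scale *before* the Cauchy combination.
  lambda < 1 is never used to inflate significance.
* **LD retest.** Neighbors within the window with |r| > 0.1 to the lead
  SNP are screened by a cross-trait *additive* kernel test (the same
  statistic applied to the trait matrix itself rather than SQ/CP — the
  GAMuT-style multivariate additive test); significant ones are regressed
  out of the traits and the lead is retested.  This removes the classic
  vQTL artifact where imperfect additive correction of an LD partner
  manufactures heteroskedasticity.  Note the artifact requires
  *asymmetric* LD: with symmetric haplotype frequencies the conditional
  variance of the neighbor given the lead is constant and no artifact
  arises (our test constructs the asymmetric case).
* **Dominance/scale retest.** A 2-df genotypic fit per trait absorbs any
  genotype-level mean function before retesting.  This fully rescues
  mean-nonlinearity artifacts (e.g. a convex genotype effect analyzed
  additively).  It cannot — and no mean adjustment can — remove
  genotype-dependent residual *variance* induced by analyzing a trait on
  the wrong scale (e.g. an exponentiated trait); such signals remain
  detections, and distinguishing them from real interactions is outside
  what second-moment tests can do.
* **IAF standardization.** For modest n, per-individual allele frequencies
  from a binomial GLM on the structure axes standardize the genotype,
  correcting structure-driven variance effects.  This is deliberately the
  plain-GLM version; latent-factor allele-frequency estimators are out of
  scope, and at biobank scale the mean-adjustment-plus-genomic-control
  route is used instead.

## The simulator

The generator reproduces a polygenic two-environment GxE design: m SNPs
(the first with MAF fixed at 0.25, the rest U(0.1, 0.4), genotypes
Binomial(2, maf)); r traits built from standardized components scaled by
the square root of their variance budget:

| component                | PVE |
|--------------------------|-----|
| risk SNP (additive)      | 0.2% |
| interacting environment M| U(0.5%, 2.0%) per trait |
| GxE (M·X, formed before standardization) | U(0.1%, 0.15%) per interacting trait |
| shared environment W     | 15% |
| background polygenic score | baseline correlation − 15% |
| noise                    | remainder |

The shared environment and the background score use a single realization
(one effect vector over SNPs 2..m) common to all traits.  This is what
makes the baseline correlation exactly 15% + background PVE (0.25, 0.50,
0.75): with per-trait effect vectors of common sign the cross-trait
correlation of the background would be ~2/pi of its PVE and the stated
correspondence could not hold.  The raw Normal(0, 0.01) effect draws
survive only inside the background score (relative SNP weights); the
component standardization overrides every other magnitude, leaving the
drawn effects to control signs.

Sparsity: the first round(tau·r) traits carry the interaction
(exchangeable by construction).  Pleiotropy modes set gamma signs:
`positive` (all +, aligned with the environment effect), `mixed` (fair
coin per trait), `positive_opposed` (all −, opposing the environment),
and `mixed_opposed` (coin per trait, with that trait's environment-effect
sign set opposite its gamma — the only reading of "interaction opposite
the environment" compatible with per-trait random signs).  Uniform PVE
draws are per trait, per dataset, creating the effect-size heterogeneity
a Normal effect model implies; this is configurable.

Null designs (tau = 0) keep every non-interaction component and support
chi-square(5) and t(3) error distributions, centered and scaled to unit
variance, for type-I-error studies under skewed and heavy-tailed traits.
The trait intercepts are Normal(0, 5^2) scalars — irrelevant to every
test, retained for fidelity of the marginal trait distribution.

What the generator does *not* emulate: linkage disequilibrium between
simulated SNPs, population structure / admixture, missing genotypes or
phenotypes, and non-Gaussian environments.  Passing power and calibration
tests on these data therefore says nothing about LD artifacts or
structure confounding in real data — those are exactly the failure modes
the adjustments layer exists for, and they are exercised by dedicated
constructions in the test suite instead.

## Problem sizes used in the checks

Power cells are evaluated at the full n = 300,000 with 200 simulated
datasets per cell in the reproduction script (the method is tested only
at the interacting SNP, so one dataset contributes one replicate;
binomial noise at 200 replicates is up to 3.5 percentage points of
standard error) and 60 per cell in the test suite, with tolerances
widened accordingly.  Type-I error uses six null datasets of 5,000 SNPs
at n = 20,000 — two per error distribution (normal, chi-square(5), t(3))
— checked against the exact binomial interval at alpha = 1e-3 over the
pooled 30,000 tests.  Coefficient-recovery checks use a single
10^6-sample draw.  These sizes make each check reproducible in minutes on
one core while keeping every structural parameter of the design at its
stated value.

## Known limitations

* The asymptotic null (weighted chi-square / chi-square) is trusted down
  to genome-wide levels for n in the 10^4+ range; for small n a
  permutation option exists on the single-SNP test.
* aLIT combines exactly the (wLIT, uLIT) pair; additional kernels would
  slot into the same Cauchy combination but are not defaults.
* Discoveries are evidence of *some* non-additive relationship involving
  the SNP — GxE, GxG, parent-of-origin, or scale misspecification are not
  distinguishable from the second moments alone.
* The scan assumes unrelated individuals; no mixed-model relatedness
  adjustment is provided.
* Inverse-Normal transformation of traits is deliberately not offered: it
  does not remove a genotype-dependent mean–variance relationship and can
  invalidate variance-based inference.
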