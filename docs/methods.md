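# Methods

This note documents the models, estimators and numerical choices behind
`gardenqg`, and what the synthetic-data tests do and do not demonstrate.

## The mixed model and REML

All quantitative-genetic statistics derive from the clonal nested model

    Y_ijk = mu + B_i + P_j + G_k(P_j) + eps_ijk

with block effects B_i fixed, population effects P_j ~ N(0, sigma2_P),
genotype-within-population effects G_k(P_j) ~ N(0, sigma2_G), and
residuals eps ~ N(0, sigma2_E), all mutually independent. Because
populations are independent and genotypes nested, the marginal covariance
of the data is block-diagonal by population, and within a population it
is sigma2_E I + sigma2_G (blockdiag of J per genotype) + sigma2_P J. Two
nested Sherman–Morrison identities reduce the restricted log-likelihood —
including log-determinants and all quadratic forms — to sums over
per-genotype and per-population sufficient statistics, so one evaluation
is O(n) with small constants.

The fit profiles out sigma2_E and the fixed effects and minimizes the
profiled −2·log-restricted-likelihood over (log γ_P, log γ_G), the
variance ratios γ = sigma²/sigma2_E:

* a damped Newton iteration driven by the **analytic gradient** of the
  profiled criterion (the Hessian is finite-differenced from gradients,
  eigenvalue-floored, and the step is length-capped so the log-scale
  directions that flatten as γ → 0 cannot produce runaway steps);
  convergence at log-space gradient norm < 1e-8;
* a Nelder–Mead fallback for interior stalls;
* explicit one-dimensional Brent profiles on the boundaries γ_P = 0 and
  γ_G = 0 (and the double boundary), entered whenever the interior search
  heads below γ ≈ 1e-4; the best candidate wins and near-zero ratios are
  pinned to exactly 0.

On balanced designs with interior optima this reproduces the closed-form
expected-mean-squares (ANOVA) estimators to ~1e-7, which the test suite
checks against an independently coded oracle. Estimates are invariant to
relabeling, and missing phenotypes are handled by case deletion (the
likelihood handles the resulting imbalance natively; missingness is
assumed completely at random, which is also what the generator produces).

A refit costs a few milliseconds at typical design sizes, which is what
makes data-level parametric bootstraps with 10^5 refits practical: the
bootstrap swaps the response vector on a prebuilt design layout and
warm-starts each refit at the parent fit's variance ratios (with a
slightly relaxed gradient tolerance of 3e-6, far below the sampling noise
of any bootstrap statistic).

## BLUPs and correlations

Genotype BLUPs are conditional means of the random effects at the REML
optimum. The default "clonal BLUP" is the **total genetic value**
(population effect + genotype effect), because across-collection trait
correlations should include among-population signal; `blup_scope="within"`
gives the within-population effect alone.

Genetic correlations r are Pearson correlations of genotype BLUPs;
phenotypic correlations R are Pearson correlations of genotype means; the
environmental correlation follows Searle:

    r' = (R − r·sqrt(H2_G1·H2_G2)) / sqrt((1 − H2_G1)(1 − H2_G2)),

using the across-collection H2_G. Values outside [−1, 1] (possible under
estimation noise) are reported raw with a warning, never truncated.

**Known caveat.** This estimator mixes scales: R is computed on genotype
means, where the residual enters with variance sigma2_E / (number of
ramets), while H2 is an individual-level variance fraction; residual
averaging also leaks into BLUPs. Consequently r' detects residual
correlation reliably (planted-zero residual correlation gives r' centered
on 0; planted positive correlation gives clearly positive r') but its
magnitude is attenuated relative to the generating residual correlation.
The tests assert exactly those two properties and no more.

## Q_ST, heritabilities, bootstrap intervals

    Q_ST    = sigma2_P / (sigma2_P + 2 sigma2_G(P))
    H2_G(P) = sigma2_G / (sigma2_G + sigma2_E)
    H2_G    = (sigma2_P + sigma2_G) / (sigma2_P + sigma2_G + sigma2_E)

With clonal replication sigma2_G is broad-sense (non-additive variance and
C-effects are confounded with it), which deflates Q_ST slightly; estimates
are therefore conservative lower bounds for additive-based Q_ST. No
additive/dominance partition is attempted — a clonal design cannot
identify it.

Confidence intervals are a **data-level parametric bootstrap**: simulate
complete datasets from the fitted Gaussian model on the observed design
(same rows, hence the same missingness pattern), refit by REML, recompute
the statistics, and take percentile intervals (2.5/97.5 for 95%).
Percentile rather than BCa intervals are used; the refit failure count is
tracked and a record with > 20% failures is flagged unreliable. With the
default 1000 iterations and a 10-populations × 6-genotypes design the
95% Q_ST interval achieves ~95–96% empirical coverage in the suite's
200-replicate check (band asserted: 90–98%).

When a variance component is pinned at 0, bootstrap replicates can land on
Q_ST = 0 or 1; these are genuine boundary optima (verified against grid
scans) and are retained, which is why intervals for poorly resolved traits
can legitimately reach [0, 1].

## F_ST and the divergence test

Per-SNP F_ST uses the Weir–Cockerham variance components (a, b, c) for
diploid samples with unequal sizes and observed heterozygote counts (no
Hardy–Weinberg assumption), theta = a/(a+b+c), computed across all
populations at once; a "mean pairwise" mode averages theta over population
pairs. Per-SNP complete-case sample sizes handle missing genotypes;
monomorphic SNPs are excluded with a reason; negative estimates (standard
for theta near zero differentiation) are retained in the distribution.
The 99th percentile uses numpy's linear-interpolation quantile. A
scalar, independently coded implementation of the published component
formulas serves as the test oracle; the two agree to 1e-12 on the
exhaustive grid of two-population genotype-count tables with class counts
up to 10.

A trait is flagged as a candidate for divergent selection when its Q_ST
point estimate exceeds the 99th percentile. **Known limitation:** with 20
populations the sampling distribution of Q_ST under weak differentiation
is heavy-tailed (σ̂²_P has 19 degrees of freedom), so the point-estimate
rule has high sensitivity but limited specificity — a trait whose true
Q_ST equals the neutral F is flagged in roughly a fifth of simulated
gardens. This is a property of the statistic (the independent ANOVA
estimator shows the identical tail), widely discussed in the Q_ST–F_ST
literature; conclusions for traits near the threshold should lean on the
bootstrap intervals rather than the binary flag.

## Multivariate regression trees

Responses are genotype-level multivariate phenotypes (by default the two
leading principal components of the eight growth/branch traits plus bud
set, bud flush, cold injury and δ¹³C). Because the response columns are
incommensurate (scores, days, percent, ‰), each column is **z-scored by
default** before any SS computation — this choice changes the splits and
is therefore surfaced prominently (`standardize=False` gives raw-scale
fitting). PCA similarly centers and scales (correlation-matrix PCA),
since the growth block mixes cm, mm², counts and ratios.

Fitting is greedy and best-first: at each step the leaf whose best split
removes the most summed within-child SS is split, considering every
predictor and every midpoint between consecutive distinct values, subject
to `min_node_size` (default 5), `max_leaves` (default 5, the tree size
used throughout) and optional `max_depth`. Best-first growth makes
explained variance, 1 − Σ leaf SS / total SS, non-decreasing in
`max_leaves` by construction. Ties in SS reduction break
deterministically by predictor column order then lower threshold, and all
equally good (variable, threshold) pairs at each internal node are
reported by `surrogate_equivalent_splits` — the "this split could equally
have been made on latitude" readout. Greedy partitioning is myopic by
design: it is verified split-for-split against exhaustive per-node
enumeration, and bounded below by a dynamic-programming depth-2 optimum,
but it does not (and cannot, in general) guarantee globally optimal trees.

Tree-size selection by K-fold cross-validation is available
(`select_max_leaves_cv`): held-out rows are predicted by their leaf mean,
and the smallest size within 10% of the minimal CV error is chosen (a
one-standard-error-style parsimony rule).

## Synthetic data

The generator mirrors the fitted model exactly — Gaussian population,
genotype and residual effects on a randomized complete block design
(default 4 blocks, 20 populations, 124 genotypes, one ramet per genotype
per block) — so recovery tests are unbiased by construction. Optional
correlation matrices couple the traits at the population, genotype and
residual levels (each validated as symmetric PSD with unit diagonal);
missingness is completely at random; all draws descend from one seed via
spawned child streams, one per trait and data product, so adding a trait
does not perturb the others.

What the generator deliberately does **not** simulate: non-additive
genetic variance and maternal/C-effects (the generator matches the fitted
model, so tests certify the estimation machinery, not robustness to
confounding a clonal design cannot separate), linkage disequilibrium or
selection at SNPs (panels are independent Balding–Nichols draws:
population frequencies Beta(p(1−F)/F, (1−p)(1−F)/F) around a uniform
ancestral p), spatial autocorrelation within blocks, and informative
missingness. Passing tests therefore demonstrate correctness of the
estimators under the model's own assumptions, not robustness to their
violation in real gardens.

The planted regression-tree scenario (`planted_mrt_scenario`) arranges 20
populations in five groups of four, with an evapotranspiration-like step
separating groups {1,2} from {3,4,5} and a frost-free-period-like variable
separating the rest; every trait's dominant contrast follows the primary
step (as in real multi-trait clines), with among-population variance ~0.2
against sigma2_G = 0.1 and sigma2_E = 0.7 — the signal-to-noise ratio of
the recovery benchmarks. Three unstructured climate columns act as
distractors.

## Problem sizes in the test suite

The statistical checks run at: 100 balanced instances for REML–ANOVA
agreement; 200 replicate gardens at the full design for parameter/Q_ST
recovery; 200 outer × 500 inner replicates at 10 populations × 6
genotypes for bootstrap coverage; the exhaustive ~1.77M-table grid plus a
5000-SNP panel for the F_ST estimator; 100 replicates for the divergence
rates; and 200 instances/seeds for the tree checks. The acceptance script
reports the same quantities at somewhat smaller replication so a full
from-scratch run completes in a few minutes.
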