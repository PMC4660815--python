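# Methods

## Model

`bhit` infers which columns of a mixed genotype/phenotype matrix are
mutually dependent.  Columns (additively coded SNPs, categorical phenotype
columns, quantitative traits) are partitioned into groups by an indicator
vector `I` with `H` groups; columns in different groups are modeled as
independent, columns within a group as jointly dependent.  The likelihood of
a partition factorizes over groups, and each group's marginal likelihood is
available in closed form by conjugacy:

* **Discrete groups.**  The joint combination counts `n_j` over the
  `c_h = prod(cardinalities)` possible value combinations follow a
  multinomial whose probability vector carries a Dirichlet prior
  (`alpha_1..alpha_{c_h}`).  Integrating the probabilities gives the
  Dirichlet-multinomial marginal
  `prod_j Gamma(n_j+alpha_j)/Gamma(alpha_j) * Gamma(sum alpha)/Gamma(n + sum alpha)`,
  computed entirely in log-gamma space.  Combination spaces larger than
  `3^12` cells are handled sparsely over the observed combinations
  (unobserved cells contribute factors of 1).
* **Quantitative trait in a group with discrete columns.**  The group's
  joint discrete combinations cluster the samples; within cluster `m` the
  trait is Gaussian with unknown `(mu_m, sigma_m^2)` under a
  Normal-Inverse-chi-squared prior `mu|sigma^2 ~ N(mu0, sigma^2/kappa0)`,
  `sigma^2 ~ Inv-chi^2(nu0, sigma0^2)`.  The conjugate update is
  `kappa_n = kappa0+n`, `nu_n = nu0+n`, `mu_n = (kappa0 mu0 + n ybar)/kappa_n`,
  `nu_n sigma_n^2 = nu0 sigma0^2 + (n-1)s^2 + kappa0 n (ybar-mu0)^2 / kappa_n`
  (the `(n-1)s^2` term is 0 for `n <= 1`), and the cluster's marginal is the
  Student-t-family expression
  `(2 pi)^(-n/2) sqrt(kappa0/kappa_n) * Gamma(nu_n/2)/Gamma(nu0/2)
   * (nu0 sigma0^2/2)^(nu0/2) / (nu_n sigma_n^2/2)^(nu_n/2)`.
  The `(2 pi)^(-n/2)` normalizer is the one that passes the `n = 1`
  closed-form check (the marginal of a single point under the unit prior is
  the `t_1(mu0, scale^2 = 2 sigma0^2)` density) and the numerical-integration
  oracle in the test suite.  Multiple continuous members of a mixed group
  are conditionally independent given the cluster.  Empty clusters
  contribute nothing.
* **Groups of two or more continuous columns with no discrete member.**
  No clustering variable exists, so the group is scored with the
  multivariate Normal-Inverse-Wishart marginal, hyperparameters matched to
  the 1-D priors (`Lambda0 = diag(nu0 sigma0_j^2)`, `nu0_NIW = nu0 + d - 1`),
  which reduces exactly to the Normal-Inv-chi^2 marginal at `d = 1`.  This
  case is a package design choice: the clustering construction does not
  define it, and the dependency simulations (multivariate-normal blocks)
  need a likelihood that rewards correlated continuous pairs.

### Priors and defaults

* Dirichlet pseudo-counts: symmetric `alpha_j = 1` per combination cell
  (flat).  An optional `maf_informed` scheme sets
  `alpha_j = alpha0 * P_HWE(combination j | MAF)` with the user's minor
  allele frequency, for workflows where genotype frequencies are known a
  priori; its pseudo-counts sum to `alpha0` (default 1), i.e. one prior
  observation spread over the combination space.
* Continuous priors are empirical Bayes per column: `mu0` = column mean,
  `sigma0_sq` = column variance, `kappa0 = nu0 = 1` (one pseudo-observation
  of shrinkage).  These are deliberately weak; see "Known limitations".

## Sampling

The posterior `P(I, H | data)` is sampled by Metropolis-Hastings over
canonical partitions (group labels renumbered 1..H by first appearance, so
each grouping has exactly one representative).  The partition prior is
uniform over canonical partitions, hence the acceptance ratio is the
marginal-likelihood ratio times the Hastings correction.

* **Iterations are sweeps.**  One iteration performs `R` single-column
  update attempts (`R` = number of columns), so each column receives on
  average one reassignment opportunity per iteration regardless of problem
  width.  This keeps the stated iteration budgets meaningful from 5-column
  toys to 100-locus panels.
* **Proposal.**  An update picks a column uniformly; with probability 0.75
  it proposes moving it to a fresh group (a split), otherwise it joins the
  group of a second uniformly chosen column (a merge whose proposal rate
  scales with the target group's size).  The exact Hastings correction is
  applied.  Both asymmetries are deliberate: size-biased merges let large
  dependent groups assemble quickly, and the extra split mass lets a wrongly
  fused group dissolve before its members reinforce each other.  The
  sampler's exactness under this proposal is validated against the
  enumerated posterior on 3- and 4-column datasets (chi-square test).
* **Incremental evaluation.**  Group marginals depend only on the member
  set and are cached by frozenset; a move re-evaluates at most two groups.
  A stored likelihood trace is reproducible from the stored partitions to
  1e-8 (tested).
* **Summaries.**  Post-burn-in samples give the pairwise co-occurrence
  matrix (fraction of samples grouping columns i and j together).  Reported
  groups are the transitive closure of pairs with co-occurrence strictly
  above 0.5; a pair exactly at the threshold is not linked.  The
  maximum-likelihood visited partition is also retained
  (`ChainResult.map_partition`).  Multi-run mode derives run seeds as
  `seed + run_index` and may share the marginal cache across runs.
* **Checkpointing.**  `checkpoint_every`/`checkpoint_path` write a versioned
  JSON state (iteration, partition, RNG state, trace); resuming reproduces
  the uninterrupted chain bit-for-bit (tested).

## Synthetic data

The generators implement the three simulation families used for power and
type-I-error measurement; all are deterministic under their seed and emit a
ground-truth manifest.

* **Epistasis models 1-4.**  100 loci by default (desk-scale tests use 30),
  i.i.d. Hardy-Weinberg genotypes at the configured MAF.  The 2 (models
  1-3) or 3 (model 4) causal loci determine the trait mean via carrier
  indicators `z_i = 1[genotype >= 1]`: additive (`e*(z1+z2)`), conjunctive
  (`e*z1*z2`), threshold (`e*max(z1,z2)`), three-way conjunctive
  (`e*z1*z2*z3`); the trait is `N(mu, 1)`.  Observed markers equal the
  causal genotypes with probability `r` (the LD parameter), otherwise one of
  the other two codes uniformly.  The default effect size `e = 1.5` SD is
  calibrated so single-run recovery power is ~1.0 at the favorable setting
  (MAF 0.5, LD 1, study sample sizes); the original study's per-combination
  odds tables are not public, so `e` is a single-knob surrogate.
* **Dependency models 5-8.**  Fixed layouts (9+9, 1+4, 10+10, 8+8
  discrete+continuous columns) with the published generating partitions.
  Dependent discrete groups put 80% of the mass on one designated joint
  value and spread 20% uniformly over the rest; dependent continuous groups
  are multivariate normal with off-diagonal correlation 0.8; mixed groups
  draw each continuous member from a cluster-specific normal per joint
  discrete value, with cluster means on a 3-SD-spaced grid permuted
  independently per member (so members are dependent through the clustering
  without being collinear copies).  Independent discrete columns are uniform
  over three codes.  The correlation, mean separation and within-20%
  uniformity are package choices where the study text is silent.
* **Null models 1-2.**  100 genotype columns: one 2-locus and one 3-locus
  dependent group (80/20 rule) plus 95 independent Hardy-Weinberg loci
  (MAF 0.3, a typical common variant), and 2 (model 1) or 1 (model 2)
  standard-normal phenotypes independent of everything.

What the generators do *not* emulate: linkage structure along a chromosome
(background loci are exchangeable), missing genotypes, population
stratification, non-Gaussian trait noise, and real allele-frequency spectra.
Power numbers under these generators therefore validate the inference
machinery under its own assumptions, not field performance on real panels.

## Power evaluation

Statistical power is the fraction of replicate simulated datasets whose
reported structure matches the generating truth; Wilson 95% intervals are
attached.  Scoring is strict:

* epistasis: the extracted group containing the trait must equal exactly
  {causal loci + trait}; supersets and subsets are misses.  Spurious
  locus-locus groups elsewhere do not affect the score.
* dependency: the thresholded co-occurrence grouping must equal the
  generating partition exactly, singletons included.
* null: a dataset is a false association if any extracted group contains
  both a phenotype and a genotype column; genotype-genotype and
  phenotype-phenotype groups are permitted.

With `k` runs per dataset a hit requires any single run to match, so
multi-run power is non-decreasing in `k` by construction.

### Study conditions and problem sizes used

Dependency models run at their study sizes (5000/1000/5000/10000 samples)
with the stated budgets (T=2000, burn-in 1000 sweeps; model 6: T=1000/500),
100 replicate datasets per cell.  Null models run at 100 replicates with
T=500/burn-in 250 sweeps — each of the 102 columns still receives 500
update opportunities, and the measured false-association rate is insensitive
to longer windows.  The epistasis property checks run at 30 loci with
T=2000/1000 sweeps (T=3000/1500 for the 3-locus model): at this width
single-run group assembly is reliable, which is what the >= 0.9 single-run
property needs; at the full 100-locus width single-chain assembly within
fixed budgets becomes proposal-rate-limited and multiple runs are the
practical remedy, consistent with the original tool's heavy use of
multi-run aggregation.

## Preprocessing pipeline

PLINK text `.ped/.map` pairs are parsed with hard validation (allele
character set, allele-pair/record count agreement); missing alleles (`0`)
are an error — imputation belongs upstream.  Additive recoding counts minor
alleles per SNP (exact 50/50 allele ties treat the alphabetically first
allele as major; monomorphic SNPs recode to all zeros).  The MAF filter
removes SNPs with `(2 n2 + n1) / 2G` strictly below the threshold (default
0.05; a SNP exactly at the threshold is kept).  Quantitative traits can be
screened with a one-sample Kolmogorov-Smirnov test against
`N(mean, sd)`; since the parameters are estimated from the same data the
p-value is anti-conservative (Lilliefors caveat, warned), and failure is
advisory, not fatal.  The assembled dataset round-trips through a versioned
tab-separated file (`#bhit-v1` header, `label|kind|role|cardinality`
descriptors).

Genome-scale strategies: **A** prefilters SNPs by an L1-penalized regression
of the phenotype on additive codes (LassoCV; the hook is pluggable),
**B** runs one chain per chromosome with phenotypes in every block (with a
single chromosome this is bit-identical to a plain run), **C** restricts to
SNPs inside user regions (0-based half-open intervals; `.map` positions are
1-based, converted internally).  All strategies end in pooled co-occurrence
plus thresholded extraction and merge block reports.

## Numerical choices

* All marginals in log space; finite for `G <= 1e5` and `c_h <= 3^10`
  (tested at the boundary).
* Cluster variance terms clamp `(n-1)s^2` at 0 against floating-point
  cancellation.
* Welch t-test reporting utility returns `(t, p) = (0, 1)` for two
  identical constant classes.
* Chi-square exactness tests thin chains (every 25th sweep) because the
  test assumes independent draws.

## Known limitations

* The empirical-Bayes continuous priors (`kappa0 = nu0 = 1`) are weak; on
  null data at moderate sample size (n = 1000) the posterior genuinely
  favors merging a phenotype with one locus in roughly 5-10% of datasets,
  which is the dominant contribution to the measured type-I rate.  Stronger
  `nu0` would trade type-I for power; the default keeps the model close to
  uninformative.
* Single-column moves cannot cross deep valleys: two dependent groups that
  fuse early can be practically inescapable within a fixed budget.  The
  split-heavy proposal reduces trap entry but does not eliminate it
  (~5% of model-5/7 replicates).  Split-merge moves would remove this
  failure mode but are deliberately out of scope.
* Continuous-only dependence is modeled as a single multivariate Gaussian
  (NIW); non-linear or mixture-shaped dependence between quantitative
  columns is invisible to it unless a discrete column joins the group.
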