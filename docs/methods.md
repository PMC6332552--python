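# Methods

`ldsim` simulates genotypes that preserve the allele-frequency spectrum and
pairwise linkage disequilibrium (LD) of an input phased VCF, gene-drops
haplotypes through pedigrees with explicit crossover modeling and exact
identity-by-descent (IBD) tracking, and provides phenotype generators plus a
correlated-frailty survival association test. This note records the models,
the numerical choices, and what the synthetic-data tests do and do not show.

## Haplotype model

A haplotype over M biallelic sites is a thresholded multivariate Gaussian:
site j carries the alternate allele iff `Z_j < q_j`, where
`q_j = Phi^{-1}(p_j)` and `Z ~ N(0, R)`. Marginals are matched exactly by
construction. Each off-diagonal `R_jk` is the tetrachoric correlation solving

    P(Z_j < q_j, Z_k < q_k; rho) = p_jk,

with `p_jk` the observed haplotypic joint frequency of the 1/1 cell. The
orthant probability is computed from Owen's T function
(`scipy.special.owens_t`), which is vectorized and accurate to ~1e-14; the
equation is solved by 60 bisection steps on `rho in [-0.999, 0.999]`
(monotonicity of the orthant probability in `rho` guarantees the bracket),
far below the 1e-8 tolerance target. Joint frequencies are clipped to the
Frechet bounds before solving; targets unattainable at the clip bound
saturate at +-0.999.

Zero co-occurrence cells — common for rare-variant pairs in finite samples —
force `rho = -0.999`. The assembled matrix is therefore usually indefinite
and is repaired by eigenvalue clipping at `1e-6`, rescaling to unit diagonal,
iterated to a fixed point (the rescale alone can push the smallest eigenvalue
back below the floor). The maximum entrywise change introduced by the repair
is reported on the fitted model (`pd_deviation`). Only pairwise LD is
modeled; three-way and higher haplotype moments are not matched.

Generation draws `Z = L u` with `L` the Cholesky factor of the repaired `R`,
in batches of 1000 haplotypes (configurable); a pool is refilled lazily each
time it is exhausted. Fitting costs O(M^2) time and memory.

## Genetic map and meiosis

Physical positions map to genetic positions by piecewise-linear interpolation
of a (bp, cumulative cM) table, extrapolating with the terminal segment's
rate; without a map a uniform 1 cM/Mb fallback (the human genome-wide
average) is used. Crossovers live in genetic distance; physical coordinates
never enter the meiosis code.

Two crossover models, both calibrated to 1 crossover per gamete per Morgan:

* no interference — Poisson process, intensity 1 per Morgan;
* chi-squared (two-pathway) interference — interfering-pathway chiasmata are
  every (m+1)-th event of a Poisson stream of rate `2(m+1)(1-p_escape)` per
  Morgan on the four-strand bundle, stationarized by a uniformly random
  initial counter phase (this reproduces the equilibrium forward-recurrence
  distribution of the Erlang renewal process exactly), and each chiasma is
  passed to the gamete independently with probability 1/2; the escape
  pathway adds Poisson crossovers at rate `p_escape` per Morgan directly on
  the gamete.

Defaults `m = 4`, `p_escape = 0.05` are human-scale interference values;
`m = 0` (or `p_escape = 1`) reduces the model to Poisson exactly, which the
tests verify distributionally. No obligate chiasma is imposed; short regions
can have zero crossovers.

Each gamete carries an origin track — segment boundaries in cM plus the
founder-haplotype id of each segment. Gametes are formed by copying the
parental gamete chosen by a random start phase up to the first crossover and
alternating thereafter; tracks are spliced at the same positions, so the
allele at every site equals the founder allele named by the track (asserted
by a brute-force per-site oracle in the tests).

## IBD

For a pair of individuals the four origin tracks are overlaid; within each
refined segment the IBD state is the best 2x2 pairing of founder ids (0, 1
or 2 shared), and proportions are genetic-length (cM) weighted — weighting
in bp would misrepresent sharing because recombination operates in genetic
distance. The mean IBD is reported as the standard pi-hat = IBD2 + IBD1/2,
which is 0.5 for parent-offspring and sibs and 0.25 for avuncular and
grandparent-grandchild pairs; parent-offspring pairs are IBD1 = 1
identically. (Some sources print the mean-IBD formula with the roles of IBD1
and IBD2 interchanged; that form contradicts the parent-offspring identity
and is read here as a typesetting slip, not implemented.)

## Phenotypes

Binary traits: `logit P(y=1) = b0 + b1 s + sum_j G_j c_j` with dosages
`G in {0,1,2}` and an optional stratum indicator `s` for population-
stratification designs. The rare-variant effect-size rule
`beta = (ln5/4)|log10 MAF|` is provided as a helper.

Survival traits: Weibull proportional hazards with baseline
`lambda0(t) = (rho/lam)(t/lam)^(rho-1)` and a family-correlated log-normal
frailty, `b ~ MVN(0, sigma2 * B)` per family with `B` the family's mean-IBD
matrix over the simulated region (unit diagonal; a 1e-8 ridge is added
before factorization). Event times come from Weibull inversion
`T = lam(-log U / exp(b + X'beta))^(1/rho)`. Right-censoring uses each
individual's current age, drawn per generation from normal distributions
with means 95/75/55 (generations 1/2/3) and variance 2.5, truncated at zero;
status is `1{T <= age}` and the observed time is `min(T, age)`.

Study defaults are `rho = 3`, `lam = 143` (median survival ~126.6 years,
so events are rare below the censoring ages), `beta_sex = 0.5`, and
generation-side `sigma2 = 0`: under the no-association null the frailty tied
to the tested region must be absent, and under the alternative the familial
correlation is induced by the genotype covariates themselves. With these
settings and population-sampled three-generation families the generator
censors ~81% of individuals. A reported figure of ~60% censoring for this
parameter set is reachable only when families are ascertained through
affected probands, which concentrates events within sampled families;
proband-based ascertainment (and the matching conditional-likelihood
correction) is deliberately out of scope here — families are population
samples — so all downstream operating characteristics are those of the
unascertained design (see Limitations).

## Correlated-frailty fit and LRT

The marginal likelihood integrates each family's `MVN(0, sigma2 B)` random
effects out of the Weibull PH likelihood. With `sigma2 = 0` the closed form
is used. Otherwise the integral is approximated by Laplace expansion around
the mode of the joint log-density, plus the closed-form next-order term: the
conditional log-likelihood has diagonal third and fourth derivatives in `b`
(both `-mu_i`, with `mu_i` the conditional cumulative hazard), so with
`V = (Sigma^{-1} + diag(mu))^{-1}` the correction factor is

    1 + (1/8) sum_i (-mu_i) V_ii^2 + (1/8) u'Vu + (1/12) sum_ij mu_i mu_j V_ij^3,

`u_i = -mu_i V_ii`. Against adaptive quadrature on families of up to three
members the corrected approximation is accurate to ~3e-4 relative at
`sigma2 = 1` (plain Laplace: ~2e-3); the plain version was not accurate
enough for the package's own oracle contracts.

Numerics that matter:

* The inner mode-finding is damped Newton with Armijo backtracking,
  converged on the Newton decrement (< 1e-11) per family, always started
  from `b = 0`. Together with maintaining `w = B^{-1} b` incrementally
  (never through an inverse — `B` is singular whenever a family contains an
  IBD2 = 1 pair, which happens regularly on short regions), this makes the
  log-likelihood a smooth deterministic function of the parameters. That
  smoothness is essential because the outer optimizer (L-BFGS-B on
  `log rho, log lam, beta`, and box-constrained `sigma2 >= 0`) uses
  finite-difference gradients.
* Newton steps use `delta = Sigma (I + diag(mu) Sigma)^{-1} g` and the
  Laplace determinant `logdet(I + Sigma diag(mu))`, so `sigma2 -> 0` is
  stable without inverting `Sigma`.
* Families are padded to a common size with inert members (t = 0, d = 0,
  X = 0, identity B block) whose likelihood, mode and correction
  contributions are exactly zero; each Newton iteration is then a single
  batched solve across all families.
* The alternative fit is run from two `sigma2` starts (0.2 and 1.0) and the
  better likelihood wins; the profile in `sigma2` can be flat near the
  boundary and a single quasi-Newton run occasionally stalls.

The association test is the likelihood ratio for `sigma2 = 0`. Because the
null value lies on the boundary, the statistic's null distribution is the
equal mixture of a point mass at zero and chi-square(1): p = 1 when the
statistic is 0, else `0.5 P(chi2_1 >= LRT)`.

## Simulation study

One study cell simulates N three-generation families (two parents, 1-2
children, 1-2 grandchildren per child; 4-8 blood members). Married-in
spouses are simulated as founders so that grandchildren have two parents,
but only blood members enter the phenotype sample and the fit. Genotypes
come from a fitted fixture region of 30 variants with MAF in [0.02, 0.1]
(600 diploid input samples, AR-1 latent correlation 0.8, ~1 Mb / ~1 cM);
three causal variants are drawn per study. Per replicate: gene-drop,
per-family mean-IBD matrix `B`, survival generation with the genotype
dosages as covariates (effect `beta_g` each, `beta_sex = 0.5`), null and
alternative fits with sex as the only estimation covariate (the genotypes
must stay out of the estimation design — the variance component is the
association signal), and the mixture p-value at alpha = 0.05.

Desk-scale problem sizes: the packaged acceptance run uses 400 replicates
for the N=100 type-I-error cell and >= 10,000 individuals for the censoring
fraction; the test suite runs 120 null replicates, 25 power replicates at
N=100 and 6 at N=500. A replicate costs ~0.7 s (null) to ~8 s (strong
signal, N=100) on one core.

## Synthetic data: what it does and does not emulate

Fixtures are drawn from the same latent-Gaussian mechanism the engine fits,
with known marginals and AR-1 or block latent correlation, so fitted models
can be checked against exact ground truth, and MAF/LD preservation can be
tested without external data. Real phased panels differ in ways the
fixtures do not capture: empirical LD is not exactly a thresholded-Gaussian
pairwise structure (higher-order haplotype structure, recombination
hotspots, mutation-age-dependent allele-frequency/LD coupling), genotyping
and phasing errors exist, and allele-frequency spectra are skewed far more
heavily toward rare variants. Passing fixture tests therefore demonstrates
self-consistency of the model-fit-simulate loop and correctness of the
mechanics (filters, meiosis, IBD, likelihoods), not that simulated cohorts
are indistinguishable from any particular real population.

## Limitations

* Pairwise-LD-only haplotype model; rare-variant pairs with zero observed
  co-occurrence are pushed to the clip bound and then smoothed by the PD
  repair, which perturbs the realized LD of those (weakly informative)
  pairs.
* No proband ascertainment. The study's operating characteristics under
  population sampling are materially different from an ascertained design
  with the same parameters: ~81% censoring (vs ~60% when ascertained), a
  conservative type-I error (~3% at alpha = 5%, N = 100), and lower power
  (~72% at beta_g = 1, N = 100). With richer event information (younger
  censoring ages) the same test is near-nominal, so the conservatism is a
  property of the heavily censored unascertained design, not of the
  likelihood machinery.
* Sex-averaged map; autosomes only; no gene conversion; no sex-specific
  recombination.
* The Laplace-based likelihood degrades slowly with `sigma2` (~1e-3 relative
  at `sigma2 ~ 2-3`); for the study's range (`sigma2 <= ~1.5`) the error is
  well below the Monte Carlo noise of any reported quantity.
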