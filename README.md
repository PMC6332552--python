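# ldsim

Simulation of realistic genetic-variant data for methods development in
statistical genetics: unrelated cohorts whose genotypes preserve the
minor-allele-frequency (MAF) spectrum and linkage-disequilibrium (LD)
structure of an input phased VCF, and pedigrees of arbitrary size built by
gene-dropping with explicit recombination and exact identity-by-descent
(IBD) tracking. On top of the genotype engine, the package provides the
phenotype models used in family-based association studies — a logistic
case–control model and a Weibull correlated-frailty survival model — and the
boundary likelihood-ratio test for the frailty variance component.

Intended users: developers of rare-variant and family-based association
methods who need replicated datasets with known truth (allele frequencies,
LD, IBD, effect sizes) rather than downloads of real cohorts.

## Models in brief

**Haplotypes.** A haplotype over M biallelic sites is a thresholded latent
Gaussian: site j carries the alternate allele iff `Z_j < Φ⁻¹(p_j)` with
`Z ~ N(0, R)`. `p` comes from observed haplotype column means; each `R_jk`
is the tetrachoric correlation reproducing the observed haplotypic joint
frequency, and `R` is repaired to positive definiteness by iterated
eigenvalue clipping. New haplotypes are drawn through the Cholesky factor in
pools of 1000.

**Meiosis.** Crossovers are placed in genetic distance (a bp→cM map, or a
uniform 1 cM/Mb fallback), under either a Poisson model or a two-pathway
chi-squared interference model (every (m+1)-th event of a Poisson chiasma
stream, thinned 1/2 to the gamete, plus a non-interfering escape pathway);
both are calibrated to 1 crossover/Morgan. Every gamete carries a founder
origin track, so pairwise IBD0/1/2 proportions are computed exactly (cM
weighted), with mean IBD π̂ = IBD2 + IBD1/2.

**Phenotypes and test.** Binary traits follow
`logit P(y=1) = b0 + b1·s + Σ G_j c_j`; survival traits follow a Weibull
proportional-hazards model `λ(t|b) = (ρ/λ)(t/λ)^{ρ-1} exp(b + X'β)` with
family frailties `b ~ MVN(0, σ²B)`, `B` the family mean-IBD matrix, and
right-censoring at generation-specific current ages (means 95/75/55,
variance 2.5). Association between a variant region and survival is tested
by the likelihood-ratio statistic for `σ² = 0`, with the boundary-mixture
null `0.5·χ²₀ + 0.5·χ²₁`; the marginal likelihood uses a corrected Laplace
approximation validated against adaptive quadrature.

See `docs/methods.md` for assumptions, numerics and limitations.

## Worked example

```sh
# 1. a synthetic phased VCF (50 variants, 200 samples, AR-1 LD) + map + truth manifest
ldsim fixture --n-variants 50 --n-samples 200 --maf-min 0.05 --seed 1 --out-dir .

# 2. 100 unrelated individuals preserving the fixture's MAF and LD
ldsim simulate-unrelated --vcf fixture.vcf --n 100 --seed 7 --out sim.vcf

# 3. gene-drop a trio and report exact pairwise IBD
printf 'fam1\tdad\t0\t0\t1\nfam1\tmom\t0\t0\t2\nfam1\tkid\tdad\tmom\t1\n' > trio.ped
ldsim ibd --vcf fixture.vcf --pedigree trio.ped --map fixture.map --seed 3 --out ibd.tsv
```

The run logs (standard error) report what was read and how much the
positive-definiteness repair changed the fitted correlation matrix:

```
INFO ldsim: read 50 variants x 200 samples
INFO ldsim: PD repair max deviation: 0.432
INFO ldsim: wrote 100 individuals to sim.vcf (seed=7)
```

(the 0.432 deviation is concentrated on rare-variant pairs with zero
observed co-occurrence, whose tetrachoric estimate saturates at −0.999; see
the methods note). `ibd.tsv` contains the exact sharing proportions:

```
id1	id2	ibd0	ibd1	ibd2	mean_ibd
dad	mom	1.0	0.0	0.0	0.0
dad	kid	0.0	1.0	0.0	0.5
mom	kid	0.0	1.0	0.0	0.5
```

Parent–offspring pairs are IBD1 = 1 identically — one allele is always
shared by descent, and π̂ = 0.5. The same pipeline is available from Python
(`ldsim.read_phased_vcf`, `ldsim.fit_model`, `ldsim.HaplotypePool`,
`ldsim.mate`, `ldsim.compute_pair_ibd12`, `ldsim.run_study`, …).

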