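# Methods

`imprintscan` implements a quantitative-genetic treatment of genomic
imprinting (more precisely: parent-of-origin effects detectable at the DNA
level) in three layers: a closed-form one-locus model, single-marker linear
mixed models with nested likelihood-ratio tests, and a genome-scan workflow
that turns per-marker tests into marked-variance and heritability reports.
A synthetic-data layer generates phased cohorts with known truth for
validation and power studies.

## The one-locus model

A biallelic locus with alleles A1 (frequency `p`) and A2 (`q = 1 - p`) has
four ordered genotypes once parental origin is known (maternal allele
written first): A1A1, A2A1, A1A2, A2A2. Genotypic values are

    G(A1A1) = a,   G(A2A1) = d + i,   G(A1A2) = d - i,   G(A2A2) = -a

where `a` is the additive value, `d` the conventional dominance effect and
`i` the imprinting effect (`d1 = d - i`, `d2 = d + i` is the equivalent
two-heterozygote parameterization). The genotype coding matrix

    I_a in {-1, 0, +1},  I_d in {0, 1},  I_i in {-1, 0, +1}

assigns rows (1,0,0), (0,1,1), (0,1,-1), (-1,0,0) to the four classes;
`G = (I_a, I_d, I_i) . (a, d, i)` is the single source of truth so codes
and values cannot disagree. The sign convention (`I_i = +1` for A2A1) is
arbitrary; flipping it negates estimated imprinting effects and swaps the
maternal/paternal direction calls, and nothing else.

Under Hardy-Weinberg equilibrium the parental substitution effects are
`alpha_pat = a + i + (q-p)d` and `alpha_mat = a - i + (q-p)d`; their mean is
the ordinary substitution effect `alpha` and their half-difference is `i`.
The genetic variance decomposes into

    sigma2_Men = 2pq (a + (q-p)d)^2     (Mendelian additive)
    sigma2_Imp = 2pq i^2                (imprinting, transmissible)
    sigma2_Dom = (2pq d)^2              (dominance)

with `sigma2_A = sigma2_Men + sigma2_Imp = pq (alpha_pat^2 + alpha_mat^2)`
(1:1 sex ratio). Because the imprinting term enters the breeding values it
is heritable: `h2e = (sigma2_Men + sigma2_Imp) / (sigma2_G + sigma2_e)`
always dominates the imprinting-blind `h2 = sigma2_Men / (sigma2_G +
sigma2_e)`, with equality iff `i = 0`. The imprinting fraction
`sigma2_Imp / sigma2_G` reduces to `i^2 / (a^2 + i^2)` when `d = 0` and is
then frequency-independent.

One printed-formula caveat: with `p = Pr(A1)` and `G(A1A1) = +a` the
population mean is `mu_G = a(p - q) + 2pq d`. A commonly reproduced variant
with `a(q - p)` is inconsistent with the genotype frequencies that produce
the variance formulas above; we carry the internally consistent form
(verified against the brute-force four-genotype expectation in the tests).

The fraction surfaces are *not* monotone in `d` everywhere: raising `d`
inflates both the Mendelian term (for `p < 1/2`) and the dominance variance,
so the imprinting share can fall with dominance except near fixation of A1.
The tests assert monotonicity in `i` and `p` everywhere and in `d` only for
`p >= 0.8`.

## Mixed models and tests

Per marker the observation model is

    y = 1 mu + X b + I_a b1 + I_d b2 + I_i b3 + Z u + Q c + e

with covariates `b` (sex, cage density, ...), polygenic `u ~ N(0, A
sigma2_u)` (A = pedigree numerator relationship matrix by the tabular
method), cage `c ~ N(0, I sigma2_c)` and residual `e`. Variance components
are estimated by REML, profiled over the ratios `gamma = sigma2 / sigma2_e`:

- no random terms: closed-form OLS, exact ML/REML log-likelihoods;
- one random kernel: the kernel is eigendecomposed once per dataset and a
  bounded scalar search runs over `log gamma` (boundary `gamma = 0` always
  checked);
- polygenic + cage: Nelder-Mead over `(log gamma_u, log gamma_c)` with the
  likelihood evaluated through a Woodbury identity on the low-rank cage
  factor in the polygenic eigenbasis (equal to the dense Cholesky reference
  to < 1e-8); boundary solutions are evaluated explicitly. Genome scans
  warm-start every per-marker search at the null model's ratios.

Convergence: log-likelihood change below 1e-8 (optimizer `fatol` 1e-9),
components constrained non-negative with the boundary allowed. Asymptotic
SDs of the components come from the finite-difference observed information
of the REML log-likelihood at the optimum; a component estimated at the
zero boundary gets `NaN` (its sampling distribution is not Gaussian there).
Fixed-effect SEs are GLS standard errors at the REML optimum.

Nested marker terms are tested by likelihood-ratio tests: additive vs null,
dominance vs additive, imprinting vs additive+dominance (or vs additive
alone when the no-dominance variant is requested; the dominance and
imprinting codes are orthogonal under HWE so the two imprinting estimates
agree, which the tests verify as a regression slope of 1). REML criteria
are not comparable across fixed-effect structures, so LRTs use ML
log-likelihoods by default; `paper_mode=True` differences the REML criteria
instead, mimicking the widespread REML-package practice, and both
log-likelihoods are retained on every fit. Marker codes that are constant
or collinear in the sample (no heterozygotes; a single heterozygote class)
are flagged *inestimable* rather than silently dropped; such markers keep
their remaining tests but never enter a significance box.

## Genome-scan workflow

1. **MAF filter** — markers with minor allele frequency strictly below the
   threshold (default 0.05) are removed; a marker exactly at the threshold
   stays.
2. **Multiple testing** — the effective number of independent tests is the
   eigenvalue-based (Li-Ji-style) count on the haplotypic Pearson
   correlation matrix, per chromosome, summed; a Bonferroni fallback
   (`M_eff = m`) is available. The per-test threshold is Šidák:
   `1 - (1 - alpha)^(1/M_eff)`, shared across the three test families.
3. **Boxes** — box 1 = imprinting-significant markers; box 2 =
   additive-significant markers not in box 1; dominance-only markers are
   reported but enter no box.
4. **LD pruning** — within each box, significant markers are clustered by
   connected components under pairwise haplotypic `r^2 >` threshold
   (default 0.99, transitive chaining allowed); the representative is the
   smallest relevant p-value (imprinting p in box 1, additive p in box 2),
   ties broken by position.
5. **Marked variance** — assuming linkage equilibrium between retained
   markers, `sigma2_SNP(without) = sum_box2 2 p q alpha^2` and
   `sigma2_SNP(with) = sigma2_SNP(without) + sum_box1 2 p q (alpha^2 +
   i^2)`, with `p` the sample-frequency MLE.
6. **Direction** — for a box-1 marker, equal signs of `alpha` and `i`
   suggest maternal imprinting (the maternal substitution effect
   `alpha - i` is the attenuated one), opposite signs paternal; a zero
   estimate yields `n/a`.
7. **Heritability** — combined bottom-up + top-down estimate
   `(sigma2_SNP + sigma2_u) / (sigma2_SNP + sigma2_u + sigma2_c +
   sigma2_e)`, computed per model variant with variance components averaged
   over the per-marker fits.

A deliberate "wrong model" re-estimation utility refits one box's retained
markers under the other model, quantifying how much marked variance an
additive-only analysis loses at imprinted loci.

## Synthetic data

**Validation cohort** (`make_validation_dataset` / `make_validation_pair`).
Defaults are the reference design: 5,000 unrelated individuals, 500
biallelic loci in linkage equilibrium, allele frequencies cycling
deterministically over {0.05, 0.10, ..., 0.95} so every frequency class is
represented; 100 loci receive standard-normal additive effects, and 50 / 10
of those (drawn independently, so the subsets may overlap) receive
standard-normal dominance / imprinting effects. Maternal and paternal
alleles are independent Bernoulli(p) draws (HWE). Environmental noise is
normal with variance equal to the *realized* variance of the total
genotypic values, recomputed per replicate, so realized broad-sense
heritability is ~0.5 by construction (sampling spread about ±0.01-0.02 at
n = 5,000). The "Dom" companion reuses the same genotypes, effects and
standard-normal noise deviates but rebuilds genotypic values without the
imprinting effects (only the noise *scale* differs, tracking that
configuration's Var(G)); it is the false-discovery control.

**Mouse-like family cohort** (`make_mouse_like`). Emulates an F2
heterogeneous-stock design at desk scale: 40 full-sib families of 10 by
default (the real study had 168 families, 1,940 mice), unrelated non-inbred
founder pairs, offspring genotypes by Mendelian transmission of unlinked
loci, 1,000 markers spread over 19 chromosome labels. Offspring are
assigned randomly to cages (default 80, ~5 mice each); fixed effects are
sex (Bernoulli(0.5), effect 0.25 pre-scaling) and standardized cage
occupancy ("cage density", effect 0.1). Raw variance components default to
sigma2_u = 0.3, sigma2_c = 0.2, sigma2_e = 0.5 — ratios chosen to echo the
reported mouse BMI decomposition, where the cage and polygenic components
are comparable and the residual dominates. A small causal-marker set
(10 additive / 5 dominance / 2 imprinting, effect SD 0.15) keeps the marked
variance at a few percent of the total, as in the real trait. The phenotype
is affinely rescaled to a BMI-like mean (-0.4568) and variance (0.0357);
all truth components (including the true variance components) are stored on
the rescaled scale, and the truth tables reproduce the phenotype exactly.

What the generators do **not** emulate: linkage disequilibrium and
recombination maps (loci are independent, so LD pruning on this data is
exercised only through duplicated-marker fixtures), genotyping error and
missingness, phasing uncertainty (parental origin is exact by
construction), sex-linked loci, and non-normal phenotypes. A green scan on
synthetic data therefore establishes correctness of the statistical
machinery under the model's own assumptions, not robustness to real-data
artifacts such as phase-inference error — which materially affects real
imprinting scans and must be assessed separately.

## Numerical choices and degenerate inputs

- Allele-frequency MLE: allele count / 2n over non-missing individuals.
- Estimability is decided by the norm of the marker column's residual
  against the columns already in the design (tolerance 1e-8 relative).
- LRT statistics are clipped at zero; a zero-df comparison returns p = 1.
- `effective_tests` validates unit diagonals, |r| <= 1 and PSD-ness
  (eigenvalue floor -1e-6) and errors otherwise.
- Individuals with missing phenotype or covariates are dropped with a
  logged count; kernels are masked accordingly.
- Monomorphic markers get zero correlation with everything in LD matrices
  (they are normally removed by the MAF filter first).
- Pedigrees are topologically sorted internally; cycles, duplicate ids and
  references to absent parents raise errors.
- Seeds: every generator consumes a single `numpy` Generator seeded from
  the spec; reruns are bit-identical.

## Known limitations

- The two-kernel REML search is derivative-free; pathological likelihood
  surfaces could in principle defeat Nelder-Mead, though boundary checks
  and warm starts make this unlikely at the scales used here.
- Asymptotic SDs are unreliable for components near zero (reported as NaN
  at the boundary) and, at very small family counts, 2-SD intervals
  undercover slightly — parameter-recovery checks run at >= 40 families.
- Marked variance adds per-marker contributions under a linkage-equilibrium
  assumption; with real LD between retained markers it overstates the
  jointly explained variance.
- Heritability reporting assumes the phenotypic variance is exhausted by
  the fitted components (no GxE, no epistasis).
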