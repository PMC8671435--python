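# Methods

This note documents the statistical models the package implements, the
parameters that matter, the synthetic-data model used to validate them,
and the numerical and design choices made where the methodology left
genuine freedom.

## Genotype model

Genotypes are alternate-allele counts in {0, 1, 2, 9(=missing)} on an
individuals × SNPs matrix. Pseudo-haploid data — one randomly sampled read
standing in for a diploid genotype — is kept on the same {0, 2} scale with
a dataset-level ploidy flag, so one code path serves both ploidies. The
flag only changes *slot counting* in frequency estimation: a called
pseudo-haploid genotype contributes one allele draw, a diploid genotype
two. All finite-sample corrections (admixture-f3, Hudson FST) are written
in terms of slots, which makes them correct for either ploidy.

Genetic positions in `.snp` files are read as **Morgans**. No unit
auto-detection is attempted; a centimorgan-dialect file must be converted
by the caller. The X chromosome is label "23"; Y/mtDNA SNPs are dropped
with a warning, since uniparental analyses consume haplogroup tables, not
SNP matrices.

## Block jackknife

All allele-frequency statistics get standard errors from a weighted
delete-one jackknife over contiguous genetic-map blocks (default 0.05
Morgans, never spanning chromosomes; one block per chromosome when a small
simulated map yields fewer than four blocks). Blocks are weighted by
usable SNP count, with the hole-size (Busing-style) variance formula; with
equal weights this reduces exactly to the classical delete-one jackknife,
which the tests verify against brute-force enumeration. Statistics are
ratios of sums across blocks, not means of per-block ratios. Calibration
is tested directly: the jackknife SE of f4 matches the empirical SD over
100 independent replicates within a factor of 1.5.

The 0.05 M default block size is a convention of the ancient-DNA
toolchain this package parallels, chosen to exceed both typical background
LD and the admixture-tract scale (1/g ≈ 0.045 M at g ≈ 22); it is
exposed everywhere as a parameter.

## f-statistics

Per SNP, `f4(A,B;C,D)` is `(p_A − p_B)(p_C − p_D)` averaged over
complete-case SNPs (any involved population with zero called slots drops
the SNP for that statistic). The admixture f3 subtracts the target's
sampling-variance term `h_T/n_T` with `h_T = p(1−p)·n/(n−1)` computed on
slots — the unbiased ("inbreed"-style) estimator appropriate when each
pseudo-haploid call is a single allele draw; it therefore requires at
least two target individuals. Hudson's FST uses the ratio-of-averages
form with per-population finite-sample corrections, again on slots.

Sign conventions, asserted by tests: f4 is antisymmetric in each pair and
invariant to a global ref/alt flip; negative admixture f3 is evidence of
admixture; in the leave-one-out outlier scan the statistic is oriented
`f4(WE-proxy, Nilotic-proxy; individual, pool−individual)` so that
**positive Z means the individual carries excess West-Eurasian-related
ancestry** relative to the remaining pool. Default outlier threshold
|Z| > 5; cladality scans report a Bonferroni-adjusted threshold over the
test populations.

## Two-source admixture model

With references O₁..O_m and sources S₁..S_k, each population's constraint
vector is `v_j = f4(pop, O₁; O_j, O₁)`, j = 2..m. Under admixture the
target vector is the weight-combination of the source vectors; weights
minimize `r(w)ᵀ C_r(w)⁻¹ r(w)` subject to `Σw = 1`, where `C_r(w)` is the
residual covariance assembled from the full jackknife covariance of all
(k+1)(m−1) statistics. Keeping the weight dependence of `C_r` *inside*
the objective matters: a fixed-design GLS (iterated to a fixed point) is
attenuated toward equal weights when the source statistics are noisy,
because it ignores that part of the residual variance scales with the
weights. The minimization is Nelder-Mead over the k−1 free weights from a
GLS starting point; simulations show the estimator is unbiased with
jackknife SEs matching the empirical spread (20-replicate check: mean
bias ~0.001 on a 0.55 proportion, SD ratio ~1.05).

Model fit: residual χ² with `dof = (m−1) − (k−1)`; p-value from the
upper tail. Weight SEs: delete-one-block refits (full re-minimization per
block) through the hole-size jackknife. A singular residual covariance is
ridge-regularized with a logged magnitude. Model competition refits each
candidate pair with one candidate appended to the references; a model
"survives" at p > 0.05. The cladality (rank-0) test uses the difference
vector `f4(G_A, G_B; O_j, O₁)` with χ² on `m − 1` dof; two identical
groups short-circuit to p = 1.

Basis bookkeeping differs from the original software in detail (base
reference pairing, covariance estimation); equivalence is claimed at the
level of estimates and SEs on simulations, not numerical identity.

## Sex-biased admixture

Females carry 2/3 of X chromosomes but 1/2 of autosomes, so with female-
and male-derived amounts F and M of one ancestry component,
`X = (2F + M)/3` and `A = (F + M)/2`. Inverting: `F = 3X − 2A`,
`M = 4A − 3X`, female share `P = F/(F+M) = (3X − 2A)/(2A)`. The CI for P
is first-order error propagation from the two compartment SEs
(`∂P/∂X = 3/2A`, `∂P/∂A = −3X/2A²`). The Z-score is
`(X − A)/√(σ_A² + σ_X²)`, **positive for more focal ancestry on the X**,
i.e. female-biased gene flow. (The source literature states the same Z
with the opposite algebraic sign in one place and this orientation in its
results table; this package fixes the table's orientation and documents
it here.) A poor X-compartment model fit sets a flag on the result rather
than raising, since the decomposition may still be descriptively useful.

## Kinship and the cross-cemetery test

For pseudo-haploid pairs the mismatch rate over jointly-called SNPs has
expectation `b(1 − k)` with b the unrelated baseline and k the kinship
coefficient (1/2 identical, 1/4 first degree, halving per degree). The
baseline is the cohort median p0 — valid when most pairs are unrelated,
which is why fewer than 20 usable pairs raises an error instructing an
explicit baseline. Degree bands sit at the halving midpoints of the
normalized coefficient: < 0.625 identical, [0.625, 0.8125) first,
[0.8125, 0.90625) second, [0.90625, 0.953125) third degree, else
unrelated; the third-degree band extends the standard two-band scheme at
the next halving midpoint. Pairs under `min_overlap` (default 15,000
SNPs, exposed as config because the underlying study reports the rule but
not the number) are "unknown".

Cross-cemetery machinery: for a degree set, n_R and n_S count *distinct*
individuals involved in pairs of that set (an individual in several pairs
counts once per degree-set row — the deduplication that reproduces the
published individual counts); the chance a random unordered pair is
cross-cemetery is `p = n_R n_S / C(n_R+n_S, 2)`; observing c of T pairs
cross gives the one-sided binomial `P(X ≤ c)`. The exact tail is verified
against enumeration of all 2^T outcomes for small T.

ROH analysis is deliberately reduced to binning user-supplied segment
lengths (> 4, 4–8, 8–20, > 20 cM sums); ROH *inference* is out of scope.

## Admixture dating

Per SNP, weight `w_s = p_ref1 − p_ref2` and signal
`x_s = g_s/2 − (p_ref1 + p_ref2)/2`. The binned statistic
`C(d) = Σ x_i x_j w_i w_j / Σ w_i² w_j²` (same-chromosome pairs, bin width
`binsize`, up to `maxdis`; defaults 0.001 and 1.0 Morgans) has expectation
`θ(1−θ)·a·e^{−g d} + c` under a Markov ancestry mosaic: the decay rate
per Morgan equals the generations since admixture regardless of the
attenuation factor `a` (pseudo-haploid sampling halves the amplitude;
reference-frequency noise inflates the denominator; missing genotypes
contribute zero — none of these depend on map distance, so ĝ is
unaffected, which is why missingness and ploidy need no correction here).
The affine offset `c` absorbs baseline covariance from per-individual
ancestry variation and is always fitted. The fit is weighted least
squares of `A·e^{−λd} + c` over `[start_distance, maxdis]`, with
`start_distance` default 0.0045 M to skip unmodeled short-range LD (both
exposed). SEs come from a leave-one-chromosome-out jackknife on the
retained per-chromosome bin sums.

Estimates with `g/SE < 2.8` are flagged invalid rather than dropped.
Conversions: years = 28·g; the calendar interval subtracts the ±1.96 SE
band in years from the sampling midpoint; reporting rounds years to the
nearest 10 and calendar years to integers while raw values stay on the
object (the 22.2 ± 1.4 generation example therefore prints a 112 CE lower
bound where full-precision arithmetic gives 111.6 — a one-year rounding
difference from the published value, accepted and documented). Pairwise
comparisons use `Z_ij = (g_i − g_j)/√(SE_i² + SE_j²)` against the
two-sided normal quantile at `0.05/n_tests` (3.65 at 190 tests); any
exceedance yields the "multiple waves" verdict.

## Uniparental statistics

The maternal-ancestry inversion scans proportions on a 1 % grid and keeps
those whose exact central binomial acceptance region contains the
observed count: k is accepted at level L iff both `P(X ≤ k)` and
`P(X ≥ k)` are at least `(1−L)/2` (exact tail sums; a tail exactly at the
boundary is accepted). This convention reproduces the published 43–68 %
for 35 of 63 and is exposed in the function signature because the
convention is not otherwise pinned down. The Yates χ² subtracts 0.5 from
each |O − E| (clamped at zero), squares, divides by E, and sums; p from
χ²(1). Haplogroup origin classes are an input annotation — the biology of
"predominantly West-Eurasian distribution" is user-declared, keeping the
module purely statistical.

## Projection PCA

Axes come from reference individuals only: SNPs centered by reference
mean, scaled by `√(p(1−p))`, monomorphic sites dropped with a logged
count, SVD of the standardized matrix. Sparse individuals are
least-squares-projected using only their called SNPs. No shrinkage
correction is applied to projected coordinates, so projected and fit
coordinates should be compared qualitatively only. Projections from fewer
than `min_snps` called SNPs (default 30,000, mirroring the coverage
cutoff used for graying out individuals in the source study's plots) are
flagged unreliable.

## Synthetic cohorts

The generator emulates the structure the analyses assume, not sequence-
level reality. Sources and outgroups drift from a uniform(0.05, 0.95)
ancestral frequency under the Balding–Nichols model on a small tree: each
source branch accumulates ≈ the nominal divergence so realized pairwise
Hudson FST between sources matches `fst_source_divergence` (within 20 %
at 50k SNPs, tested); outgroups hang off both sides of the tree at varied
depths so they are *differentially* related to the sources — the property
that makes the f4 system identifiable.

Per target individual, the West-Eurasian-like proportion θ_i is truncated
normal; each haplotype is a Markov mosaic with re-draw events at rate g
per Morgan and stationary θ_i (covariance `θ(1−θ)e^{−gd}`, mean focal
tract length `1/(g(1−θ))`, both tested against the truth sidecar).
Sex bias acts at the ancestor-contribution level: `F_i = 2θ_iP`,
`M_i = 2θ_i(1−P)` (clipped into [0,1], which constrains θP ≤ 1/2 — at the
defaults F ≈ 0.78), and the X chromosome is simulated at `(2F_i+M_i)/3`
— the exact identity the estimator inverts, closing the recovery loop.
Males get one X haplotype, females two; pseudo-haploid sampling collapses
both to one call. Relatives are gene-dropped: degree d is a chain of d
meioses (Poisson crossovers at 1/Morgan) from the founder, each
generation mated to a fresh individual with the founder's parameters so
ancestry does not confound kinship. Cemetery labels follow the relative
plan and split counts, independent of genotype.

Defaults mirror the study conditions: 66 target individuals split 27/39
across cemeteries, mean focal ancestry 0.57 with SD 0.045 (≈ the reported
individual range), female fraction 0.68, admixture 22.2 generations
before a sampling midpoint of 810 CE, 30 % missing calls, source
divergence 0.08 (a Nilotic-vs-Levantine-scale value), five outgroups, 15
reference individuals per panel. Everything is driven by one mandatory
seed; identical seeds give bitwise-identical outputs.

What the generator does **not** model — and hence what passing tests do
not show about real data: sequencing error and post-mortem damage,
contamination, reference bias, realistic per-individual coverage
variation (missingness is one Bernoulli rate), background LD within
sources (sites are independent given local ancestry), mutation, and deep
population-tree misspecification. Recovery results on these cohorts
demonstrate estimator correctness under the assumed model, not robustness
to those artifacts.

## Validation problem sizes

The closed-loop checks run at deliberately modest scales chosen to make
each test well-posed: weight recovery on 28k-SNP cohorts of 30
individuals; cladality calibration on 200 random 30/30 splits of a 60-
individual, 18-chromosome cohort with per-individual ancestry SD 0.005
(a genuinely homogeneous cohort — with the default SD the splits differ
in real ancestry and the test correctly rejects more often); the outlier
scan on 44k SNPs over 22 chromosomes with 40-individual reference panels
(power for a 15-point shift is limited jointly by genome length, which
sets the individual's realized-ancestry noise, and reference-panel size,
which inflates the f4 weights); dating recovery at 100k SNPs over 20
chromosomes for pulses of 10, 20 and 45 generations; sex-bias coverage
over 51 replicates at female fractions 0.5/0.68/0.9 with mean ancestry
0.45 (keeping F = 2θP below 1 at the highest fraction); kinship
classification at 100k SNPs with ten planted pairs.

## Known limitations

* The admixture model is two-source-oriented; k > 2 works mechanically
  but rotation schemes and 'allsnps: YES'-style union-of-SNP handling are
  not implemented.
* The dating estimator assumes a single pulse; multi-wave histories yield
  an intermediate average (the pairwise-Z machinery detects, but does not
  deconvolve, multiple waves).
* FST between groups containing close relatives is biased, as in any
  Hudson-type estimator; the kinship module exists partly to identify and
  exclude such pairs first.
* The O(S²) per-chromosome pair accumulation in dating is exact, not
  FFT-accelerated; it is comfortable up to ~10k SNPs per chromosome.
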