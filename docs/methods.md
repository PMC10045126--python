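# Methods

This note documents the models behind `chukarpop`, the defaults and
why they were chosen, the numerical choices that affect results, and
what the synthetic-data experiments do and do not demonstrate.

## Sequence statistics

Diversity indices follow the conventional definitions: haplotype
diversity h = n(1 − Σp²)/(n − 1) on full-sequence haplotype classes;
k counts haplotypes after deleting alignment columns containing a gap,
K on the full alignment; π and the mean pairwise difference d use
*pairwise deletion* — a site is dropped from a pair's comparison when
either sequence carries `N` or `-`. Pairwise deletion is the common
convention of population-genetics packages for mtDNA panels and is
applied identically in distances, mismatch histograms and segregating
sites, so all downstream statistics see the same data.

Tajima's D uses the 1989 constants and is **undefined (NaN), not 0**
when s = 0 or when the variance term vanishes (as it does identically
at n = 2): printing 0 would fabricate a neutrality signal. Fu's Fs
uses S′ = P(K ≥ k_obs | θ̂, n) from the Ewens sampling distribution
with θ̂ = d (the mean pairwise difference), the usual convention when
the test is reported alongside mismatch analyses. Unsigned Stirling
numbers of the first kind are computed in log space by the recurrence
|S(n,k)| = |S(n−1,k−1)| + (n−1)|S(n−1,k)|, so the test remains finite
for samples of hundreds of sequences.

Population differentiation for sequences is the AMOVA Φ_ST on squared
K2P distances (a haplotype-frequency F_ST is also exposed, since
"pairwise F_ST" on mtDNA can mean either; Φ_ST is the default).
Negative estimates are reported as computed. Note a finite-sample
property that the tests codify: two samples with *identical*
haplotype composition give SS(among) = 0 while σ²_within > 0, so the
estimator is slightly **negative** (−1/(n−1)-like), approaching 0
with sample size. Microsatellite differentiation is Weir–Cockerham θ
as a multi-locus ratio of summed variance components; expected
heterozygosity uses the unbiased (2n/(2n−1)) factor and
F_IS = 1 − Ho/He (undefined at He = 0).

## Mismatch demography and the expansion clock

The expected mismatch under a sudden expansion is

F_i(τ) = F̂_i(θ₁) + e^{−τ(θ₁+1)/θ₁} Σ_{j≤i} τ^{i−j}/(i−j)! [F̂_j(θ₀) − F̂_j(θ₁)],

with F̂_i(θ) = θ^i/(1+θ)^{i+1}. The vector is truncated at the
largest observed difference class + 5 and renormalized. Fitting
minimises Σ(obs − exp)² with bounded multi-start least squares
(≥5 starts; τ ∈ [0, 2·dmax], θ ∈ [0, max(10·d̄, 5)]): the τ/θ₁ ridge
makes single-start optimisation unreliable. Raggedness is
Σ_{i=1}^{d+1}(x_i − x_{i−1})² with one zero class appended after the
last observed class and no implicit class before the first.
Goodness-of-fit p-values are parametric bootstraps: re-simulate at the
fitted (τ, θ₀, θ₁) with the observed n and L, refit, and report the
fraction of simulated statistics ≥ the observed one.

Calendar dating uses τ = 2µt. The default clock is calibrated so that
2·µ_site·L = 4.3008×10⁻⁴ per generation — µ_site = 2.1×10⁻⁷
/site/generation with L = 1024 bp — and 3.9 years per generation.
This constant is the unique value consistent with all of the
published per-population (τ, t) pairs this package set out to
reproduce; the nominal "0.21%" figure usually quoted with such tables
is ambiguous about its per-site/per-sequence scaling, and the
back-solved constant resolves it. All three clock fields are
user-configurable.

The τ-recovery experiment run by the acceptance script simulates
n = 30 sequences of 1000 bp at τ = 2 under a *pronounced* expansion
(θ₀ = 0.1, θ₁ = 100) — the regime in which mismatch dating is
scientifically meaningful (star-like genealogies; the mismatch wave
position identifies τ). Under weak expansions the τ/θ₀ trade-off
inflates the spread of τ̂ considerably; users dating real populations
should trust τ̂ only where the expansion signal (negative Fs,
unimodal mismatch) is strong.

## Coalescent simulator

The simulator is a continuous-time structured Kingman coalescent:
k lineages in a population of s haploid gene copies coalesce at rate
k(k−1)/2/s per generation (s = 2N for diploid autosomal loci). This
continuous-time approximation, rather than generation-by-generation
simulation, is exact in the Kingman limit and orders of magnitude
faster. Demographic events (backwards in time) are splits, one
instantaneous admixture (each lineage joins donor A with probability
*ra*, else B), and size changes; there is no migration outside the
admixture event. The three built-in scenarios share the t₁ admixture
creating Central Anatolia from West (*ra*) and East (1−*ra*) and
differ in split order: (1) East+West merge at t₂, Thrace joins at t₃;
(2) all merge at t₃; (3) Thrace merges into West at t₂, East+West at
t₃. The post-root population takes its own ancestral size N_A.

Microsatellite mutation is Poisson on branches with per-locus rate µ;
steps are ±1 (strict SMM) or ±(1 + Geometric(P)) (GSM, default
P = 0.1), reflected mutation by mutation into a bounded allele range
(40 contiguous states by default, the customary range-constraint
behaviour for simulated microsatellites). mtDNA sequences use
infinite-sites placement of Poisson mutations on L positions with a
10:1 transition:transversion ratio (Cyt-b-like); when more mutations
than positions arise, positions are resampled with replacement. The
inner loops (coalescence, mutation, summary statistics) are numba
kernels; all randomness in a kernel call derives from one 32-bit
seed, so every simulated object is bit-reproducible.

Correctness anchors in the test suite: E[T₂] = 2N for a pair; the
variance of the SMM allele difference equals 2µT; the constant-size
mean pairwise sequence difference equals θ; and the distribution of
cross-population coalescence times under a clean two-population split
matches msprime (KS test), an independent coalescent implementation
used only as an oracle.

## ABC protocol

Parameters (11: four cluster sizes, an ancestral size, t₁ < t₂ < t₃,
*ra*, mean µ, GSM P) have uniform priors with ordering enforced by
rejection. The published analysis this design follows used 13
parameters and 42 summary statistics whose exact identities are not
public; the parameter set above and the 30-statistic default below
are documented stand-ins, and both are pluggable.

Summary statistics (30 for four groups): per group the mean number of
alleles, mean unbiased expected heterozygosity and mean allele-size
variance across loci; per pair of groups Weir–Cockerham θ, an
allele-frequency sharing distance 1 − mean_l Σ_a min(p₁, p₂) (a cheap
surrogate for individual-assignment likelihood), and Goldstein's
(δµ)². Statistics are standardized by median/MAD over the reference
table (robust to heavy-tailed F_ST draws; zero-MAD statistics are
dropped from distances). Rejection keeps the ⌈tolerance·rows⌉ closest
rows by Euclidean distance (default tolerance 1%).

Model choice: the *direct* estimate is the scenario frequency among
the closest k = 1000 rows with binomial CIs; the *logistic* estimate
fits a weighted multinomial logit of the scenario indicator on the
statistics, covariates centered at the observation and Epanechnikov
kernel weights on distance, so the intercept softmax is the posterior
at the observed point. The logit is fitted by L-BFGS with an
analytic-Hessian Newton polish and a small L2 ridge (1e−6) that also
regularises complete separation; CIs come from the delta method on
the intercept block of the inverse Hessian. Parameter estimation is
the standard regression adjustment: each parameter is logit-mapped to
its prior bounds (guaranteeing adjusted draws respect the prior
support), regressed on the standardized statistics with the same
kernel weights, and the intercept-plus-residual draws are mapped
back; degenerate designs fall back to the unadjusted rejection sample
(flagged). POD validation re-simulates datasets with known truth and
reports assignment error rates and the relative median absolute error
of the estimates; a PCA projection of standardized statistics
provides the goodness-of-fit picture.

Two prior sets ship with the package. `DEFAULT_PRIORS` span the
published posterior point estimates (t₃ ≈ 12,600 and t₁ ≈ 2,140
generations, *ra* ≈ 0.5) with broad, overlapping time ranges.
`SEPARATED_PRIORS` give the three event times disjoint ranges
(t₁ ∈ [100, 3000], t₂ ∈ [4000, 12000], t₃ ∈ [15000, 50000]); the
validation experiments use them because with overlapping time priors
the three topologies become nearly unidentifiable at desk-scale
reference tables (3×10⁴ rows/scenario versus the 10⁶ of a full-scale
analysis) — a genuine property of the inference problem, not of this
implementation. Group sample sizes default to the observed design
(Thrace 17, West 72, East 140, Central Anatolia 100 diploids).

What the validation experiment shows: PODs simulated under the
simultaneous-divergence hypothesis are recovered by logistic model
choice in ≈ 88% of cases at that scale, and the posterior median of
*ra* for a *ra* = 0.5 POD lands near 0.5 (±0.15). What it does not
show: that the field data favour any hypothesis — real-data
posteriors require the original genotypes, which are not distributed
with this package.

## Barrier detection

Coordinates are projected planar (equirectangular about the
centroid — adequate at single-country extent and it makes edge sets
reproducible), Delaunay-triangulated (collinear inputs are jittered
by 1e−6°, escalating tenfold on retry), and each edge is annotated
with the corresponding genetic distance. Monmonier tracing: cross the
globally maximal edge, then repeatedly cross the maximal remaining
edge of the triangle just entered, stopping at the convex hull or
when a triangle would be revisited (self-intersection). Ties break
deterministically toward the lexicographically lowest population-id
pair. Additional barriers exclude previously crossed edges, making
paths edge-disjoint. Bootstrap support for each point-estimate edge
is the percentage of replicate matrices whose own barrier crosses it;
the replicate matrices can come from any generator (the package's
coalescent is the natural one).

## Synthetic data

The generator emulates the study design, not its field data: 16
populations on a Türkiye-like grid; 277 mtDNA sequences of 1014 bp
with per-population sample sizes 9–22 (stand-in sizes 3–5 for the two
populations the study judged too small), simulated as per-population
sudden expansions (default τ = 2, θ₀ = 0.5, θ₁ = 20) around one
shared ancestral haplotype — giving the star-like within-population
structure and modest between-population divergence of a post-glacial
radiation; 347 diploid individuals at 13 loci simulated under a truth
scenario (default: simultaneous divergence at t₃ = 12,600 generations
with admixture at t₁ = 2,140 and *ra* = 0.5, the published point
estimates) with ~22% missingness applied uniformly at random; and a
contaminant haplogroup placed 30 substitutions from the native root
replacing 23/277 sequences by default. Real data differ in ways the
generator does not emulate: per-locus missingness structure, allele
frequency spectra of the actual loci, isolation-by-distance within
clusters, and selection/Numt artefacts. Passing pipeline tests on
bundles therefore demonstrates computational correctness and
estimator calibration under the model, not field-data conclusions.

## Numerical notes

- The stationary mismatch law is evaluated in floating point from the
  start (an integer θ would overflow silently in `θ^i`); the
  transient term uses a log-space Poisson weight vector and a single
  `np.convolve`.
- Least-squares fits use tight tolerances (1e−14) so the
  self-consistency recovery of an exact model curve reaches SSD at
  machine precision.
- Seeds: every public simulation entry point takes one integer seed;
  internal per-replicate seeds are drawn from `numpy` Generators so
  nested experiments are reproducible; numba kernels are seeded per
  call and all seeds stay below 2³¹.
- Known limitations: no migration outside the admixture event, no
  recombination or selection, single shared µ across loci per draw
  (per-locus rate *arrays* are supported at the API level), and the
  logistic CI is asymptotic (delta method), so it narrows faster than
  the direct binomial CI.
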