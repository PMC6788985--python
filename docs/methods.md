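# Methods

This note documents the statistical models implemented in `escapetrace`,
the assumptions behind them, what the synthetic-data generator does and
does not emulate, and the numerical and design choices made where the
design was genuinely open.

## Data model

Genotypes are diploid, co-dominant microsatellite calls stored as indices
into each locus's sorted allele-label list, canonicalized so that the
unordered pair (a, b) ≡ (b, a); a missing call is (−1, −1).  GENEPOP text
(title line, locus names, case-insensitive `POP` blocks, 2- or 3-digit
allele codes, 0 = missing) is the exchange format.  Individuals missing at
every locus are rejected at load because every downstream estimator
assumes at least one genotype.  A dataset carries an *active locus* list
so that the full panel and the post-QC panel coexist; estimators operate
on the active panel.

## Diversity statistics

Per (population, locus): observed heterozygosity Ho is the fraction of
heterozygous non-missing genotypes; unbiased expected heterozygosity is
He = 2n/(2n−1)·(1 − Σp²); effective allele number Ae = 1/Σp²; PIC = 1 −
Σp² − Σ_{i<j} 2p_i²p_j².  Allelic richness is the hypergeometric
rarefaction expectation Ar = Σ_i [1 − C(N−N_i, g)/C(N, g)] at a
standardized gene count g, defaulting to the smallest per-locus gene count
across populations (the FSTAT convention; computed with log-gamma for
stability).  F<sub>IS</sub> is Weir & Cockerham's within-population *f*
from the per-allele variance components b and c, multilocus values being
ratios of summed components; significance comes from shuffling allele
copies among individuals within the population (1000 permutations by
default, seedable), with deficit- and excess-side p-values both reported.

## Exact equilibrium tests

Both exact tests run a Markov chain over explicit arrangements: for HWE,
random transpositions of allele copies between individuals (allele counts
fixed); for LD, random transpositions of the pairing between the two
loci's genotypes (margins fixed).  Transpositions are symmetric and always
accepted, so the stationary law is uniform over arrangements, which
induces exactly the conditional null distribution of the table.  The
p-value is the probability-ordering tail (fraction of visited states whose
conditional probability is ≤ the observed table's, via an incrementally
maintained log-probability), with a Monte Carlo SE from batch means.  The
default chain (10 000 dememorization, 100 batches × 5000 iterations) is
the convention for this analysis family; tests use shorter chains.  A
complete-enumeration biallelic HWE oracle (Levene–Haldane distribution) is
provided and used to validate the chain.  Multiple testing uses Holm's
sequential Bonferroni applied per statistic family.

## Null alleles and ENA-corrected FST

The null-allele model assumes HWE with one unobservable allele at
frequency r: apparent homozygotes i/i mix true i/i (p_i²) and i/null
(2p_i r); null homozygotes appear as missing and are excluded from the
likelihood (the estimation conditions on visibility — the alternative
convention of treating missing calls as null homozygotes is not used).
The EM iterates the expected-count partition and the frequency update; the
observed-data log-likelihood is non-decreasing and tracked.  Loci whose
mean estimated r across populations reaches 0.1 are flagged for removal, a
threshold chosen between the conventional retain (<0.08) and drop (~0.3)
regimes; it is configurable.

Weir–Cockerham θ is computed from the per-allele variance components a, b,
c with unequal sample sizes, summed over alleles and loci:
θ = Σa/Σ(a+b+c).  Pairwise and global significance use permutation of
individuals among populations.  The ENA correction replaces each cell's
raw allele frequencies with the EM-adjusted visible-allele frequencies
*left on the full-allele-set scale* (summing to 1 − r̂): the null allele's
mass is excluded from the per-allele components rather than renormalized
away.  This matters because when the null frequency drifts between
populations, renormalizing over visible alleles inflates the
among-population variance — the documented upward FST bias — while the
unrenormalized frequencies remove it (verified by the bias-reduction
benchmark).  Observed heterozygote frequencies are kept, since
visible-visible heterozygotes are scored correctly even with nulls.  With
all r̂ = 0 the ENA estimate equals plain θ exactly.  The bootstrap 95% CI
resamples loci (50 000 replicates by default).

AMOVA uses allele-identity sums of squares at three levels with the
standard unequal-size coefficients; variance components are computed per
locus and summed, percentages floor negative components at zero, and each
level has its own permutation scheme (populations among groups;
individuals among populations within groups; individuals among all
populations).  PCoA is classical scaling (double-centred −D²/2,
eigendecomposition); negative eigenvalues are reported, not dropped, and
infinite Nei distances are refused rather than silently imputed.

## Admixture model

The likelihood is the standard admixture model: every allele copy chooses
an ancestry cluster from the individual's membership vector q and then an
allele from that cluster's frequencies P.  Point estimation by EM block
updates replaces the Bayesian sampler; the maximized log-likelihood per
replicate stands in for lnP(D) in Evanno's ΔK.  Implementation notes:

* Copies are flattened into gather arrays so one EM iteration is a few
  vectorized operations; convergence tolerance is 10⁻⁴ log-likelihood
  units (500 iterations cap) by default.
* **Choosing K.**  ΔK is reported, but it is undefined at the range edges
  (it cannot select K = 1) and is noisy for point-estimated likelihoods.
  The programmatic criterion (`select_k`, used by the hierarchical
  recursion) is held-out cross-validation: ~15% of allele copies are
  masked (each individual keeps at least one typed locus), the model is
  refitted on the rest with a Dirichlet pseudocount of 0.5 on the
  frequency update (without smoothing, alleles absent from a cluster's
  training copies get floor probability and wreck the held-out score), and
  K maximizes the mean held-out log-probability.  This selects K = 1 on
  panmictic data and recovers the true K on well-separated clusters; on
  very subtle structure it is deliberately conservative.
* **Membership coefficients for ancestry banding.**  A maximum-likelihood
  q is noisy for pure individuals (the MLE sits near a simplex corner),
  and a MAP estimate under a sparse Dirichlet prior is ill-posed (the
  prior density diverges at the corners and collapses genuinely admixed
  individuals).  The hybrid pipeline therefore uses the **posterior mean**
  of q under a Beta(α, α) prior with the cluster frequencies fixed at
  their fitted values, computed by quadrature for K = 2
  (`posterior_mean_q2`).  α defaults to 0.2, in the range the
  sampler-based model typically infers on strongly structured data; it
  concentrates pure individuals near 0/1 while leaving F1-like
  individuals at their ancestry fraction.
* Supervised mode fixes designated populations' q to pure membership;
  label alignment across replicates maximizes summed q-column correlation
  via optimal assignment.
* The hierarchical recursion assigns individuals to their modal cluster at
  q ≥ 0.5 (no threshold is conventional for this step), re-analyses each
  subset over K = 1..(number of source localities), and stops at K = 1,
  single-locality subsets, or subsets under 10 individuals.

## Hybrid classes, classification and calibration

The six genotype classes are parameterized by allele-origin pair
proportions (both-from-wild, one-each, both-from-farmed): Pure1 (1,0,0),
Pure2 (0,0,1), F1 (0,1,0), F2 (¼,½,¼), BC1 (½,½,0), BC2 (0,½,½).
Simulation draws, per locus, an origin pattern from the class proportions
and alleles from the reference panels' empirical frequencies (loci
independent; linked-locus simulation and F3+ classes are out of scope).
Classification evaluates each class's likelihood with the pool
frequencies fixed (the Anderson–Thompson genotype-frequency class model
with maximum-likelihood plug-in instead of MCMC) and assigns by posterior
under a uniform prior at the conventional 0.5 threshold.

Calibration builds simulated sets at 15/33/66% hybrids (200 individuals
per set by default), runs the K = 2 admixture route (posterior-mean q) and
the six-class route, and reports efficiency (recall), accuracy (precision)
and performance (their product) per threshold on the 0.60–0.95 grid in
0.05 steps, both at group level (hybrid/pure) and per genotype class.
The selected threshold maximizes mean performance over the six classes.
Escapee/hybrid calling then bands the farmed-ancestry coefficient:
farmed-origin above the threshold, pure wild below 1 − threshold, hybrid
between.

## Parentage and effective size

The parent–offspring LOD sums per-locus log-ratios of the transmission
likelihood to the unrelated (HW) likelihood.  The genotyping-error model
replaces the true genotype by a random HW genotype with probability e per
locus, applied symmetrically to parent and offspring, so an exclusion
contributes a large negative but finite term at e > 0.  Critical values
are simulated: offspring are generated with their true parent present in
the candidate set with probability equal to the assumed sampled
proportion; the critical LOD is the smallest cut-off at which the
fraction of accepted best assignments that are true parents reaches the
stated confidence, additionally guarded by the same-confidence quantile
of the best-unrelated LOD distribution (so a candidate set containing no
true parent is accepted with probability at most 1 − confidence).  The
raw-LOD precision criterion is used (the Delta-statistic variant is not);
accepted pairs must also clear the hard floor of 2.

LD-Ne uses the Burrows composite disequilibrium for every allele pair
across locus pairs (alleles at frequency ≤ 0.02 excluded, the
conventional rare-allele cutoff), r² = Δ̂²/(p(1−p)q(1−q)) with the
n/(n−1) factor, the random-mating Waples correction E[r²|n] = 1/n +
3.19/n² (sample sizes over 30 required; smaller samples are refused), and
Nₑ = (1/3 + √(1/9 − 2.76 r²'))/(2 r²') with r²' ≤ 0 mapped to infinity.
Confidence limits are a jackknife over locus pairs; group summaries use
the harmonic mean with infinite estimates dropping their term.

## Power simulation

Populations diverge by pure drift from shared base frequencies (binomial
resampling of 2Nₑ copies per generation, so expected FST = 1 −
(1 − 1/(2Nₑ))ᵗ), samples are drawn multinomially at the study sizes, and
each locus is tested by a Monte Carlo conditional exact test (gene copies
shuffled over populations, χ² statistic, 99 permutations).  The returned
per-locus p-value is the randomized version (extreme + U)/(B+1), which is
exactly uniform under the null despite Monte Carlo discreteness, so
Fisher's −2Σln p combination across loci stays calibrated — the type-I
rate at t = 0 sits at the nominal α.  An asymptotic χ² per-locus variant
(rare columns pooled) is available and agrees in the high-power regime.

## Larval transport

Transport is 2-D passive surface advection: bilinear space and linear
time interpolation of u/v, RK4 with dt = 600 s by default (dt must divide
one hour), positions in geographic coordinates converted on a local
tangent plane with a fixed metres-per-degree scale at the domain's
reference latitude (adequate for sub-degree coastal domains; the uniform-
current benchmark is accurate to under a metre over 30 days).  Releases
are daily at a set clock time, 1000 particles uniform in a 2-km stain by
default; the 30–60 m release depth band is metadata only.  Beaching is
cell-based: a particle whose position falls in a land cell is removed,
unless inside an axis-aligned "area of success" rectangle around a
nursery, where it is counted as a successful arrival and frozen
(no re-suspension).  Particles crossing the open boundary are removed and
counted separately; the count identity released = beached + left + active
+ successes is asserted every run.  Optional horizontal diffusivity adds
a random walk (default off: passive transport).  Fields are read/written
as classic NetCDF via xarray's scipy engine; three analytic regimes
(uniform, solid-body rotation, coastal jet with optional cross-shore
pulsing and steady onshore drift) support testing and synthetic
experiments.

## Synthetic-data generator

Population allele frequencies follow the Balding–Nichols model:
Dirichlet(p·(1−F)/F) around ancestral frequencies p, so divergence is
controlled by the one parameter every downstream estimator consumes.
Ancestral panels use geometric-decay allele frequencies scaled to a target
He (default 19 loci, 7–14 alleles, He ≈ 0.8).  Scenarios draw cluster
pools at stated F, then population samples with extra within-cluster
drift; escapees are whole individuals drawn from a farmed pool, F1s take
one gamete from each pool, trios are Mendelian offspring of two sampled
parents placed in a different (nursery) sample.  Null alleles are a
hidden extra allele appended to the ancestral vector *before* divergence,
so their frequency drifts between populations — the regime in which nulls
genuinely bias differentiation; masking converts null/visible to an
apparent homozygote and null/null to a missing call, exactly the EM
model's data-generating assumptions.  Random missingness (default 0.3%)
is applied last.

The frozen survey scenario has 27 samples totalling 1586 individuals with
the group structure of a coastal survey (8 wild, 5 YoY, 7 farm-associated,
7 farmed samples from four hatchery strains), cluster divergences chosen
so the realized global θ lands near 0.02 and the within-farmed θ near
0.04, two loci with 5% null alleles, planted escapees/F1s concentrated in
the farm-impacted samples, and six pedigree trios linking farm-associated
adults to nursery juveniles.  A separate benchmark scenario
(`escapee_mixture_scenario`) plants 10% escapees and 15% F1s in one
impacted sample against a strongly diverged farm strain (pool divergence
~0.27): ancestry-band calling on a 19-locus panel is quantitatively
accurate in that regime, which is what the recovery benchmark measures.
At study-scale wild–farmed divergence (~0.06) the same banding inflates
hybrid fractions through membership noise — a genuine limitation of
19-locus panels, visible in the pipeline outputs on the survey scenario.

What the generator does **not** emulate: genotyping artefacts other than
nulls (stutter, large-allele dropout), linkage, selection, overlapping
generations, spatial kinship structure, and temporal drift within the
survey.  Passing recovery tests therefore demonstrate estimator
correctness under the stated models, not robustness to every property of
real survey data.

## Pipeline

`run_pipeline` executes QC (missing data, null-allele EM, locus QC) →
diversity → differentiation (global/pairwise/ENA) → clustering (replicate
fits, ΔK table, cross-validated K) → hybrid calibration and calling →
parentage and Ne, writing per-stage outputs and JSON manifests keyed by a
config hash; an unchanged stage is skipped on re-run and a failed stage
marks its dependants skipped.  If unsupervised clustering selects K = 1,
the hybrid stage falls back to a supervised wild/farmed K = 2 fit
anchored on the group labels.  Stage defaults follow the conventional
settings of this analysis family (HWE chain 10000/100/5000, 1000 FST
permutations, 50 000 ENA bootstrap replicates, 20 000 AMOVA permutations,
10 clustering replicates per K, threshold grid 0.60–0.95, 1% genotyping
error, 0.02 Ne allele cutoff, α = 0.05).  Test and example runs use
smaller replicate counts; the methods are identical.

## Problem sizes used in the shipped benchmarks

The shipped tests and the acceptance script size their simulations for a
single-CPU desk run: θ recovery uses 100 replicates of 8 samples × 40
individuals; ENA bias reduction 60–100 replicates of 16 samples × 50 with
nulls at r = 0.2 on 10 of 19 loci; null-EM recovery n = 200; LD-Ne 50
Wright–Fisher replicates at true Nₑ = 100 sampled at n = 60 after 20
generations of random mating; power 100 replicates (500 for the null
calibration) at the survey's 27 sample sizes; hybrid calibration 8–20
replicate simulation-set triplets of 200 individuals; connectivity 500
particles over a 10-day release window at dt = 1800 s.
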