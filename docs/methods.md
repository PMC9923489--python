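# Methods

This note documents the models and procedures implemented in `holopop`,
the numerical choices behind them, what the synthetic-data generator does
and does not emulate, and the design decisions taken where the method left
room for interpretation.

## Host pipeline

### Genotype likelihoods and filtering

At ~5x coverage, genotype calls are unreliable, so every host analysis
works on genotype likelihoods. For a biallelic site with base counts
(n_major, n_minor, n_other) and per-base error rate `e` (default 0.01),
the likelihood of g ∈ {0, 1, 2} copies of the minor allele is a product
over reads: a homozygote emits its allele with probability 1 − e and each
other base with e/3; a heterozygote emits either allele with probability
1/2. Likelihoods are stored in log10 with the per-entry maximum at 0;
zero-read entries are flat and flagged in an explicit missingness mask
(never imputed at this stage).

Two filter stages are provided. *Discovery*: sites with ≥ 3 reads in
≥ 40% of individuals (boundary inclusive, evaluated over the full
individual set), then only the top floor(0.65·n) individuals ranked by
number of positions covered at ≥ 3 reads (ties broken by sample id).
*Analysis*: sites with ≥ 3 reads in ≥ 85% of individuals. The individual
cut is recorded on the matrix so re-applying a stage is a no-op
(idempotence); a filter report counts removals per criterion.

Per-site minor-allele frequencies are ML estimates from the likelihoods
(EM over individuals under Hardy–Weinberg). Sites are retained as SNPs iff
the polymorphism likelihood-ratio test against the best monomorphic model
has p < 1e-6 and MAF ≥ 0.05.

### Clone detection

Pairwise genetic distance is 1 − IBS from one sampled read per covered
site (mode `sample`; a called-genotype mode is available — the sampled-read
mode is the default for low coverage, and we make no claim about which a
given study used). The clone threshold is the upper 95% confidence limit
of the mean distance among technical-replicate pairs,
mean + t(0.975, n−1)·sd/√n (a normal-approximation variant mean + 1.96·sd
is available, since "upper 95% confidence interval" is ambiguous with few
pairs). Clone groups are connected components of the graph joining pairs
below the threshold (transitive closure); each group keeps its
highest-coverage member; technical replicates are removed first. Clone
detection runs on the full library set, before the individual cut, so the
replicate pairs anchoring the threshold are always present.

### Population structure

The PCA follows the iterative individual-allele-frequency approach for
genotype likelihoods: posterior genotype dosages under the current
frequencies are reduced by truncated SVD (rank = `n_latent`, typically
clusters − 1), the reconstruction updates the frequencies, and the
covariance is computed from standardized posterior dosages. The same
posterior dosages divided by two give the individual allele-frequency
matrix in [0, 1] (0 major homozygote, 0.5 heterozygote, 1 minor
homozygote) used as the ordination response downstream.

Admixture uses the standard GL-aware likelihood
P(data_ij) = Σ_g GL_ij(g)·Binom(g; 2, π_ij) with π = F Qᵀ, maximized by EM
(renormalizing Q rows each step) from `n_starts` random starts; default
convergence is relative log-likelihood change < 1e-6 or 2000 iterations.
Individuals are assigned to their majority cluster iff max q ≥ 0.85
(boundary inclusive), else labelled admixed. The choice of K is reported
(log-likelihoods for K = 2..6 plus the PCA eigenvalue spectrum), not
automated.

### Site-frequency spectra and diversity

The SFS estimator is the standard EM for genotype likelihoods: per site,
P(data | k minor alleles among 2n) comes from a polynomial product over
individuals with hypergeometric allele-sampling weights; the spectrum
maximizing the composite likelihood over sites is found by EM (tolerance
1e-10 relative, 500 iterations — the stopping rule is our default and is
documented because reference implementations leave it unstated). Spectra
are estimated unfolded with respect to the per-site minor-allele coding
and folded afterwards; folding merges counts k and 2n − k, halves the
hinge class, and preserves totals. The joint 2D spectrum is the same EM
with per-site outer products of the two populations' count likelihoods.
Unequal samples are balanced by hypergeometric projection to the smaller
size.

Diversity: π = Σ_k k(2n−k) η_k / (C(2n,2) L) and Watterson's
θ_W = S/(a_n L) with a_n = Σ_{i<2n} 1/i; both weights are symmetric under
folding.

### FST

The Hudson estimator with the Bhatia finite-sample correction, fixed to
the ratio-of-averages form: per site,
num = (p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1),
den = p1(1−p2) + p2(1−p1); the genome-wide value is Σnum/Σden, and the
same aggregation is reported in 50-kb windows stepping every 10 kb
(0-based half-open; a window is emitted only with ≥ 10 variable sites).
At identical allele frequencies the corrected numerator can be slightly
negative; this is expected and documented. Reynolds-type estimators are
not implemented.

### Demographic models

Four two-population histories: strict isolation (`div`), isolation with
symmetric or asymmetric continuous migration (`im_sym`, `im_asym`), and
secondary contact (`sc`: isolation, then migration over the final T_sc
units; internally T_sc = f_sc·T with f_sc ∈ [0,1] so the constraint is
built in). Parameters follow the diffusion convention: sizes ν relative
to N_ref, time in units of 2·N_ref generations, migration M = 2·N_ref·m,
scale θ = 4·N_ref·μ·L.

Expected spectra come from a forward diffusion solver written for this
package. The density φ(x, y) evolves under per-coordinate drift
(½ ∂²[x(1−x)φ/ν]) and mean-field migration advection (∂[M(y−x)φ]),
discretized in flux form on a non-uniform grid concentrated at the
boundaries, with implicit (backward Euler) steps in alternating
coordinates and continuous injection of new mutations at the lowest
interior frequency of each axis. Three numerical points matter:

1. **Face fluxes by exponential fitting.** In u = Vφ the stationary
   per-face problem u′ = (2M/V)u − 2F has an exact two-point flux with
   coefficient s = 2Mν·Δlogit(x) integrated analytically across the face.
   This resolves the steep boundary layers (density ~ y^(2Mν−1)) that
   migration builds against the drift-degenerate boundaries; a central
   flux cannot represent them at any practical grid size.
2. **Accumulating boundaries.** No absorbing terms: mass fixed or lost in
   one population piles up on the boundary nodes and keeps evolving in the
   other coordinate; migration advection can carry it back inside. This
   keeps the marginal spectrum of each population exactly stationary under
   neutrality (verified to machine precision) and represents private and
   fixed variants correctly. Corner mass is masked at sampling.
3. **Boundary-refined grid.** The first and last grid cells are
   subdivided geometrically down to 1e-8 so the layer profile between
   there and the regular grid is resolved; the sampled low-count spectrum
   cells are sensitive to exactly this region.

Against mean branch-length spectra from large coalescent simulation
ensembles, the solver's folded spectra agree to total-variation distance
< 0.005 (no migration) and ~0.015–0.02 under strong asymmetric migration,
with a residual nearly-uniform positive offset that θ-profiling absorbs.
The implicit scheme is unconditionally stable; the per-integration step
count is capped at 250 (coarser late-time steps near quasi-equilibrium
cost little accuracy).

Fitting maximizes a Poisson composite likelihood over unmasked folded
cells, with θ profiled analytically at every evaluation. Optimization is
multi-round with perturbed restarts around the incumbent (log10-uniform
within configurable fold ranges), the default schedule being four rounds
of 10/10/20/30 replicates with shrinking perturbations; the analysis
scripts and validation experiments use a two-round schedule with a coarse
engine for exploration and the default engine for the final polish, and
seed the migration models from the strict-isolation fit (nested-ladder
starts). The fitted likelihood surface has a known soft ridge trading T,
ν and m against each other; medians across replicate datasets are the
robust summary and are what the validation experiments report.

Conversions: μ_gen = μ_year·generation_years (defaults 1.86e-8/bp/year
and 5 years); N_ref = θ/(4·μ_gen·L); N_e,i = ν_i·N_ref; divergence years
= T·2·N_ref·generation_years; migrants/generation into population i
= M_ji·ν_i/2. Confidence intervals come from a block bootstrap: contiguous
50-kb blocks of sites resampled with replacement (per-site resampling is
available), spectra rebuilt, models refit from the empirical estimate with
a light perturbation schedule, and 2.5%/97.5% quantiles reported over the
successful refits (count disclosed).

### Spatial analyses

Geographic distances are Vincenty inverse geodesics on WGS84 (iterated to
1e-12; the rare non-convergent near-antipodal pairs fall back to a
mean-radius great circle). Isolation by distance is a Mantel test: Pearson
correlation of off-diagonal distances with a one-sided permutation p-value
over joint relabelings (default 1000 permutations).

The partial RDA residualizes the response and the constraining predictors
on the conditioning covariates (plus intercept), fits the residualized
response by least squares, and eigen-decomposes the fitted values for the
constrained axes. Continuous constraints are standardized; categorical
constraints are dummy-coded against an explicit reference level (inshore
for shelf position). Inference uses the residuals-of-reduced-model
permutation scheme: the whole model permutes conditioning-model residuals,
each marginal (type-III-like) term permutes the residuals of the model
with that term removed, and each axis is tested against its eigenvalue.
After permuting, rows are re-residualized on the conditioning space —
omitting this inflates the type-I error badly (verified: shelf-term null
rejection 0.4 instead of 0.05), because permuted residuals are no longer
orthogonal to the conditioning covariates. Terms fully absorbed by the
conditioning covariates contribute zero constrained variance rather than
erroring; genuinely collinear constraint terms raise an error naming the
aliased term.

## Symbiont pipeline

Colonies are treated as pooled samples of their symbiont community. The
ITS2 screen calls a reference present iff it attracted ≥ 3 mapped reads
(MAPQ-filtered upstream) and reports the genus set per colony. The plastid
panel counts alleles (SNP bases or exact indel strings) per colony-locus;
within a colony-locus, alleles need ≥ 2 reads and ≥ 1% of local depth
(pool-seq noise floor), and colonies are kept only with ≥ 20 post-filter
reads at every locus, so the analysis tensor is complete. These filter
defaults are declared substitutes for unavailable upstream detail, not
reconstructions, and are configurable and logged.

Alpha diversity (N_A, alleles per colony-locus) is modelled with a
Gaussian linear mixed model — scaled read counts + scaled latitude + shelf
(inshore reference) + host cluster as fixed effects, crossed random
intercepts for locus and colony (variance components) — fit by REML
(cross-checked against an independent REML implementation to 1e-4). The
response distribution family is not dictated by the data source, so a
Poisson mixed-model option exists; Gaussian is the default. Multi-level
factors get joint Wald tests converted to F with the residual df as
denominator — an approximation, labelled as such. Composition (beta
diversity) uses the partial RDA above with the colony × allele count
matrix as response (a Hellinger-transform option exists but is off by
default, keeping raw counts) conditioned on per-locus read counts.

## Synthetic data generator

The generator produces data with the statistical structure the analyses
assume, at the study's conditions: 2–3 host clusters split ~0.5–1.5 My-
analogue times (T ~ 0.5–1.5 in 2·N_ref units) with low-to-moderate
migration, ~5x Poisson read depth with 1% base error, planted clonal
ramets and technical replicates, and pooled plastid counts at 19 loci with
2–17 alleles per locus whose diversity and composition follow latitude and
shelf position but never the host cluster.

Hosts: standard coalescent ancestry with binary mutations; multi-allelic
sites are discarded so every retained site is a biallelic SNP. The genome
can be simulated as independent chunks (`n_chunks`), trading intra-chunk
linkage realism for speed; the spectra and all frequency-based summaries
are unaffected in expectation. The recombination landscape within chunks
is a single uniform rate with no claim of fidelity to any real map.

Reads: clonal ramets copy a genotype column but draw independent reads
(distinct physical samples). Technical replicates are an independent
re-sequencing of a sample with a tripled error rate (library re-preps
accumulate batch artifacts). The margin this buys is small but
quantifiable: with binary major/minor haploid calls only errors hitting
the minor base (e/3) flip a call, so the replicate-vs-clone expected
distance gap is 2·hom_frac·(f−1)·e/3 ≈ 0.006 at f = 3 — several standard
deviations of per-pair scatter once the SNP panel is in the tens of
thousands of unlinked loci. The alternative of copying a read set and
re-noising it makes replicates *more* similar than clones — the two draws
share binomial sampling noise at heterozygous sites — which inverts the
replicate-derived threshold, so it is deliberately not used.

Symbionts: per locus, an allele pool of uniform size 2–17. A colony's
allele richness at a locus is K = clip(round(x), 1, pool) with x Gaussian
around base 3.0 + 0.3·latitude(SD) + shelf offsets (0/0.2/0.8) + locus and
colony intercepts (sd 0.5 each) and noise sd 1.0. Which alleles are
present, and their Dirichlet proportions, are tilted by shelf- and
latitude-linked loadings (composition effects 2.0 and 0.5); a 35% uniform
mixture floor keeps every present allele at a detectable expected share at
the simulated depth (~90 reads), so observed richness tracks planted
richness rather than sequencing effort. Rounding and clipping attenuate
the planted latitude coefficient; the exact marginal slope on the
allele-count scale has a closed form (a Gaussian-density sum over the pool
distribution) and is what the recovery experiments use as the estimand.

What the generator does **not** emulate: linked selection, batch and
reference-bias artifacts, bait-capture composition bias, spatially
autocorrelated sampling, paralogy in the symbiont reference, or
overdispersion beyond Dirichlet-multinomial. Passing tests demonstrate
correctness of the estimators under the generator's assumptions, not
robustness to these real-data complications.

## Validation experiment sizes

The validation experiments (test suite and `scripts/acceptance.py`) use:
SFS fidelity at n = 10 diploids, 5·10⁴ sites, 20x; demographic recovery at
16 + 16 haploids and ~10⁵ SNPs over 10 replicate datasets (two-round
optimizer, nested starts); clone detection over 20 replicates of 30
colonies at 5x with 3 clone groups and 4 replicate pairs; Mantel/RDA null
calibration over 200 runs and power over 100 runs at the generator
defaults; alpha-diversity coverage over 100 runs of 80 colonies. These
sizes are the package's own choices balancing Monte-Carlo error against
runtime on a single core.

## Known limitations

- The diffusion engine's residual error under strong migration (~2% per
  cell after θ-profiling) interacts with the flat T–ν–m likelihood ridge;
  individual fits can wander along the ridge, which is why medians across
  replicates are the reported summary.
- The folded joint spectrum at modest sample sizes cannot separate
  isolation-with-migration from secondary-contact histories with brief
  isolation; `compare_models` flags near-ties instead of pretending to
  resolve them.
- Mixed-model denominator degrees of freedom are a residual-based
  approximation, not Satterthwaite/Kenward-Roger.
- The per-axis RDA permutation test is marginal (each axis against the
  residual), not the sequential scheme some references use.
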