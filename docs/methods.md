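# Methods

This note documents the statistical machinery, the defaults and why they
were chosen, the numerical decisions, and what the synthetic-data tests do
and do not demonstrate about real survey data.

## Dual-threshold abundance classification

Local relative abundance is a taxon's fraction within one sample; its
regional abundance is the mean of local abundances over **all** samples,
zeros included. Defaults: locally abundant ≥ 1%, locally rare < 0.01%,
regional thresholds derived by dividing by 10 (≥ 0.1% and < 0.001%).

The abundant label requires both clauses (a locally abundant occurrence
*and* a regionally abundant mean). The rare label requires a regionally
rare mean and at least one locally rare occurrence (absences count as
below threshold). The "at least one" reading of the rare local clause is
deliberate: taxa that are locally rare in *every* sample are a strictly
smaller set, tracked separately by `local_status_profiles`, and a
regionally rare mean arithmetically forces sub-threshold local abundance
in most samples anyway (with 22 samples and a regional mean < 10⁻⁵, a
taxon can reach 10⁻⁴ locally in at most 3 samples). Report percentages
are rounded half-up to two decimals.

## Alpha diversity

Shannon H uses natural logarithms (nats). Simpson is reported as the
Gini–Simpson diversity 1 − Σp² (the inverse form is selectable). Pielou
J = H/ln S, defined as 0 for single-species samples. Chao1 defaults to
the bias-corrected form S + F₁(F₁−1)/(2(F₂+1)) with the classical
F₁²/(2F₂) selectable and the standard variance formula for its SE; ACE
uses the conventional rare/abundant cutoff of 10 individuals. The
rarefaction curve is the analytic hypergeometric expectation
E[S_d] = Σᵢ [1 − C(N−nᵢ,d)/C(N,d)], evaluated with log-gamma; at d = N it
returns observed richness exactly, and it matches exhaustive subsample
enumeration on small fixtures (tested).

Rarefaction of count tables draws each sample from the multivariate
hypergeometric distribution (without replacement), so column totals equal
the target depth exactly and a fixed seed reproduces the draw
bit-for-bit. OTU rows left empty are kept unless `prune_empty` is set;
the full pipeline prunes them.

The Mann–Whitney comparison reports min-U and a two-sided p: exact
enumeration of all group assignments (tie-safe) when n₁+n₂ ≤ 10, the
normal approximation with tie correction above.

## Dissimilarity, ordination and matrix tests

Bray–Curtis is computed on square-root transformed relative abundances by
default (on a closed composition this coincides with the Hellinger
transform). NMDS minimises Kruskal stress-1 by SMACOF majorization
alternating with isotonic regression on the dissimilarity ranks; ties are
handled by the secondary (equality) approach, so fully tied
dissimilarities cannot be trivially embedded. Defaults: k = 2, 20 random
starts, 300 iterations, tolerance 10⁻⁷ — common ecological practice.

ANOSIM R = (mean between-group rank − mean within-group rank)/(M/2) with
M = n(n−1)/2 and average ranks on ties; labels are permuted freely
(one-way design). Mantel tests correlate upper-triangle vectors (Pearson,
or Spearman by ranking the triangle once) and permute one matrix's rows
and columns simultaneously; the partial form correlates residuals of
matrix regressions on the third matrix and re-residualises the permuted
matrix. All permutation p-values use (count + 1)/(n_perm + 1), one-sided
toward positive association by default (the distance-decay direction);
999 permutations unless stated.

## Spatial predictors

Geographic distance is great-circle (haversine, R = 6371.0088 km) —
sites span several degrees of latitude, so raw-degree Euclidean distance
would distort longitudes. Environmental distance log(x+1)-transforms
every variable except pH, z-scores each variable, and takes Euclidean
distance; z-scoring makes mixed units commensurable and the distance
affine-invariant per variable.

PCNM axes: truncation t defaults to the longest minimum-spanning-tree
edge of the geographic distances; distances above t are replaced by 4t
(the original prescription); −½D*² is Gower double-centred and
eigendecomposed; axes with eigenvalue > 10⁻⁸ are kept, scaled by
√eigenvalue, numbered in descending eigenvalue order and sign-fixed so
each axis' largest-magnitude loading is positive (reproducible across
linear-algebra backends). On a regular transect the axes are sinusoids of
increasing frequency (tested against sin(πk(i+1)/(n+1))).

## Constrained ordination and variation partitioning

The DCA gradient-length gate extracts correspondence-analysis site scores
by reciprocal averaging, detrends axes 2–4 against earlier axes by
26-segment centring, and rescales each axis to species-turnover SD units:
the axis range is divided by the abundance-weighted mean within-species
dispersion of site scores and multiplied by the square root of the axis
eigenvalue, which undoes the shrinkage of the reciprocal-averaging step.
This reproduces the reference behaviour of decorana-style implementations
across short and long simulated gradients (axis-1 lengths 0.10/3.6/18.6
against 0.10/3.5/17.9 on tolerance-0.5/0.25/0.05 Gaussian gradients).
Longest axis < 3 SD recommends the linear engine (RDA), > 4 SD the
unimodal one (CCA).

RDA centres the community matrix (Hellinger-transformed by default, the
standard for species data; plain √ selectable) and projects it onto the
explanatory column space; the constrained fraction is SS(fitted)/SS(total)
and adjusted R² is Ezekiel's 1 − (1−R²)(n−1)/(n−m−1) with m the predictor
rank. CCA operates on the chi-square standardised residual matrix with
row-weighted predictors; its adjusted R² has no closed form and is
estimated by the permutation analogue 1 − (1−R²)·mean(1/(1−R²_perm)).

VIF filtering iteratively drops the highest-VIF column while any exceeds
20, treating perfect collinearity as infinite VIF and breaking ties
toward the later column. Forward selection adds, at each step, the
candidate with the largest partial pseudo-F if its permutation p
(reduced-model residual permutation) is below α = 0.05, stopping at the
first failure; the α-only stopping rule is the default, with Blanchet's
global adjusted-R² ceiling available. The step test's type-I error is
calibrated on single-candidate nulls (best-of-many selection inflates the
familywise rate by construction, as in any forward procedure).

Variation partitioning fits the E, S and E∪S models, adjusts each R², and
derives pure/shared/residual fractions by the standard identities; the
four fractions sum to 1 by construction (asserted to 10⁻⁹) and negative
adjusted fractions are reported as-is, never clamped. Pure fractions are
tested by partial permutation ANOVA (residuals-under-reduced-model
permutation). The VPA engine is linear (RDA) by default even when the DCA
gate suggests CCA for the response, keeping all fractions on the closed-
form adjusted-R² scale; a CCA engine is available behind the `method`
flag.

## Sloan neutral community model

Regional abundance p is the mean relative abundance over all samples
(zeros included); observed frequency is the fraction of samples with ≥ 1
read; N is the mean read depth. Under the Sloan formulation the latent
local abundance of a taxon is Beta(Nm·p, Nm·(1−p)).

Two detection kernels map that law to a predicted frequency. The classic
threshold kernel, 1 − BetaCDF(d; ·) with d = 1/N, treats a taxon as
detected when its latent abundance exceeds one read's worth. The default
*sampling* kernel models what sequencing actually does — detection is
drawing at least one read in a multinomial of size N — giving
1 − B(a, b+N)/B(a, b) in closed form. The distinction matters: on
neutrally assembled test data (Dirichlet–multinomial, the joint law whose
marginals are the Sloan Beta) the threshold kernel overestimates Nm by
roughly 25% at depth 10⁴, while the sampling kernel recovers the true
value within a few percent; the threshold kernel remains available via
`kernel="threshold"` for comparability with published workflows.

Nm is located on a 120-point log grid spanning 10⁻² to 10⁹ and polished
by bounded scalar minimisation (re-widened once if the bound is hit);
R² = 1 − SSres/SStot on the frequency scale; 95% bands are Wilson score
intervals around the predicted frequency at the sample count.

## Synthetic metacommunity generator

The generator emulates a coastal survey design: stations in 3 clusters
(bays) along a ~5° one-dimensional coastline arc (1D keeps the PCNM
sinusoid structure predictable; 2D placement is a straightforward
extension), 22 samples, 28,923 reads per sample, and a lognormal regional
pool (σ = 2.5) of 20,000 OTUs by default — matching the scale of the
surveys this pipeline targets. A five-variable physico-chemical panel
(temperature, salinity, DO, NH₄-N, NO₂-N) loads on a latent environmental
score that mixes the spatial coordinate with independent noise through a
confounding parameter, giving the shared VPA fraction a known dial.

Each OTU has a pool abundance, an environmental optimum and a geographic
source; expected composition multiplies the pool by Gaussian niche
filters (weight `w_env`, breadth in latent-score SD units) and
exponential dispersal kernels (weight `w_space`, range in km), and counts
are multinomial at the configured depth. With both weights zero every
sample is an iid multinomial from the pool.

Recovery and calibration experiments use scaled problem sizes chosen to
exercise the statistics at realistic signal-to-noise: NCM recovery on a
500-OTU pool, 50 samples × 10⁴ reads, Nm = 1000, 20 seeds; VPA process
recovery at 40 sites, 400 OTUs, depth 2000, 50 runs per direction;
permutation calibrations on 500 null simulations with 199 permutations
each.

What the generator does **not** emulate: temporal dynamics, phylogenetic
structure in the pool, taxon interactions, compositional sequencing
biases, or chimeras/contaminants — passing tests therefore demonstrate
the statistics' correctness and power under the stated generative model,
not robustness to every artefact of real amplicon data.

## Numerical choices and degenerate inputs

- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); the pipeline derives per-stage seeds by
  hashing stage names into one master seed.
- Rank-deficient explanatory matrices are handled by SVD-based
  orthonormal bases with a relative 10⁻¹⁰ singular-value cutoff.
- Distance matrices must be symmetric with zero diagonal (10⁻¹⁰
  tolerance); all-zero samples, empty tables, single-group ANOSIM,
  coincident PCNM sites, and degenerate (constant-frequency) NCM inputs
  raise `DataError` with the offending identifier.
- Partial Mantel returns r = 0 when the residual of the permuted matrix
  on the control is numerically null (controlling a matrix for itself).
- DCA falls back to length 0 for axes with vanishing weighted variance
  (duplicated samples).

## Known limitations

- CCA forward selection permutes residuals of the chi-square standardised
  response with fixed row weights — an approximation to re-deriving
  weights per permutation; adequate for the gate-driven use here.
- The DCA rescaling is a one-pass global approximation to iterative
  segment-wise rescaling; axis lengths agree with reference output to a
  few percent, which is ample for the < 3 / > 4 SD gate but not intended
  for publication-grade DCA scores.
- ANOSIM assumes a one-way design; stratified permutation is not
  implemented.
- The Wilson bands on the NCM fit describe binomial uncertainty at the
  fitted frequency, not uncertainty in Nm itself.
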