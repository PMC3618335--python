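# Methods

This note documents the statistical machinery in `coexnet`: the models and
their assumptions, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
choices that matter.

## Network inference

**Model.** Gene expressions are modelled as a multivariate normal vector
with covariance Σ; zeros of the precision matrix Ω = Σ⁻¹ encode conditional
independence, and the co-expression network is the support of Ω off the
diagonal.  Edge strength is the partial correlation
ρ_ij = −Ω_ij/√(Ω_ii Ω_jj).

**Shrinkage.** With n samples ≪ p genes the empirical covariance S is
singular, so the estimator uses C = (1−λ)S + λ·diag(S).  The default λ is
the analytic variance-minimising intensity for the diagonal target,
λ* = Σ_{i≠j} Var̂(s_ij) / Σ_{i≠j} s_ij², clipped to [0,1], with the usual
unbiased plug-in for Var(s_ij) from centred cross-products; a fixed
intensity can be supplied instead.  C is positive definite for any λ > 0,
so the inversion is always well posed.  Note a consequence relevant to
interpretation: when most gene pairs are truly uncorrelated λ approaches 1
and every partial correlation is strongly attenuated; the estimator
preserves ranking, not magnitude.

**Bootstrap.** The final estimate is the elementwise mean of the shrinkage
partial correlations over bootstrap resamples of the samples — 4,000
resamples of size 20 by default.  Replicates in which a gene is constant
are skipped and logged, not repaired.  One seed governs the whole run;
replicate r uses an independent stream spawned from (seed, r), so the
result does not depend on execution order, and the columns are
canonicalised by sample id before resampling, so it does not depend on
storage order either.

**Edge significance.** Off-diagonal estimates are modelled as a two-group
mixture η₀·f₀(r;κ) + (1−η₀)·U(−1,1), where
f₀(r) ∝ (1−r²)^((κ−3)/2) is the null density of a sample correlation with
κ effective degrees of freedom.  κ is estimated by maximum likelihood on
the central region (|r| within 2.5 robust null standard deviations, the
robust scale being MAD/0.6745), and η₀ follows by matching the observed
central mass to the null probability of that region.  The truncation
matters: a full-likelihood fit with a uniform alternative systematically
widens the null when true effects concentrate at moderate values,
swallowing the signal.  η₀ is capped at 1 − 1/N so that an extreme value
can always be called.  Each pair receives the local false-discovery score
η₀f₀(r)/f(r); pairs scoring ≤ 0.2 (the published default of the local-fdr
edge-calling approach) become edges.  With fewer than 10 pairs the mixture
is not identifiable and an absolute-value quantile threshold is used, with
a warning.

**Phenotype.** Gene–phenotype partial correlations append the trait as a
(p+1)-th variable and rerun the same bootstrap estimator; the returned
vector is the trait row restricted to genes.  Degenerate inputs (trait
duplicating a gene) produce capped, finite values — never silent NaNs.

## Network structure

Density is reported under two conventions: m/(p(p−1)) over ordered node
pairs (the convention matching the reference study's printed 6.4%) and the
graph-theoretic 2m/(p(p−1)).  Betweenness uses raw shortest-path counts,
each unordered pair counted once, because absolute cutoffs (e.g. "greater
than 350") are only meaningful unnormalised.  The hub rule is inclusive
(degree ≥ t) — the reference study's own hub list includes nodes exactly at
its quoted cutoff — while the high-betweenness rule is strict (> t).  When
no absolute thresholds are supplied the pipeline uses the 92.5th percentile
of degree and the 90th of betweenness, which reproduce the study's
selection fractions (≈21/272 and ≈25/272).

## Clustering

**Modularity.** Q is computed in the per-cluster form
Σ_c [e_c/m − (D_c/2m)²]; the pairwise form over same-cluster ordered pairs
(including i=j in the degree term) is kept as an independent cross-check
and the two agree to machine precision.

**Annealing.** Single-node label moves from a uniform random start;
proposal targets are uniform over current labels plus one fresh label;
acceptance probability min(1, exp(ΔQ·T)) with the inverse temperature T
rising geometrically from the annealing parameter to ten times it over the
sweeps.  The schedule endpoint and the grid of annealing parameters
(10 … 10⁵, exponential) follow the reference protocol; the geometric ramp
itself is this package's choice, as is the improving-moves-only polish
applied to the best state seen, which guarantees the result never scores
below its initialisation.  The cluster count is emergent: empty labels are
dropped and the rest renumbered.  Node order is canonicalised internally so
results depend only on the seed, not on storage order.

**Kernels.** Heat kernel exp(−βL) (β grid {0.1, 1, 10} by default, since no
single β is canonical) and commute-time kernel L⁺, both via symmetric
eigendecomposition; the commute-time kernel requires a connected graph and
says so.  Kernel k-means uses Lloyd iterations with the kernel-trick
distance and the best of several random restarts by feature-space inertia;
empty clusters are re-seeded from the farthest point.  The batch kernel SOM
keeps prototypes as convex combinations of kernel rows on a small 2-D grid
(2×2 … 4×4 by default), with a Gaussian grid neighbourhood whose radius
shrinks linearly to zero; with radius zero the update reduces exactly to
batch kernel k-means.  Across all methods and grids the selected partition
is the modularity maximiser, ties broken by fewer clusters then method
name.

## Phenotype spatial statistics

Moran's I of a node attribute x is
I = (n/S₀)·Σ_ij w_ij (x_i−x̄)(x_j−x̄) / Σ_i (x_i−x̄)², with weights from the
adjacency — row-standardised by default (standard in the spatial-statistics
methodology this stage follows), binary available and recorded.  Isolated
nodes enter only the mean and denominator.  Significance comes from
permuting x over nodes: p = (1+#{I_perm ≥ I_obs})/(B+1), one-sided
"greater" by default (the scientific question is positive autocorrelation),
B = 999 by default; the exhaustive-permutation expectation is −1/(n−1).
The Moran plot pairs each node's value with its spatial lag (mean over
neighbours); quadrants are H/L by position relative to the attribute mean
and the lag mean.  Influential genes are those whose Cook's distance on the
lag-on-attribute least-squares line exceeds 4/n (the common convention; the
influence literature gives no universal cutoff), with an absolute override.

The per-cluster test is a Welch t-test on |ρ| inside vs. outside the
cluster at level 1%.  It is one-sided ("greater") by default: the question
is whether a cluster is *more* strongly tied to the phenotype, and a
two-sided test mechanically flags other clusters as significantly weak
whenever one cluster is strong, because the strong cluster inflates the
comparison group.

## Synthetic data

The generator plants a sparse block precision matrix: a fraction
`within_density` of within-module pairs (and a fixed number of
between-module pairs) receive the value `within_strength`, and positive
definiteness is enforced by diagonal dominance — each diagonal entry is the
absolute row sum plus a margin of 0.1, which bounds the smallest eigenvalue
below by the margin.  The default shape mirrors the reference study: 272
genes in 7 modules of sizes 33, 44, 58, 28, 41, 28, 40, 56 samples, and a
pH-like phenotype equal to `effect_size` (default 1) times the mean
expression of module 4 plus N(0, 0.2²) noise.

Two structural choices deserve comment.  First, diagonal dominance caps
planted |partial correlations| at roughly 1/(within-degree), so density and
strength trade off; the defaults (`within_density=0.1`,
`within_strength=−0.6`) give a median planted |ρ| ≈ 0.2, the magnitude
regime the small-sample estimator can actually detect — denser, weaker
configurations produce networks that are real but invisible at n = 56.
Second, the default strength is *negative* in the precision matrix, i.e.
positive partial correlations: positively coupled modules compound into
strong marginal correlations, as real co-expression modules do, whereas
repulsive modules (positive precision entries) barely correlate marginally
and leave the shrinkage estimator with nothing to work on.

What the generator does **not** emulate: microarray noise models and
probe-level effects, heavy-tailed or skewed expression distributions,
global correlation induced by latent technical factors, eQTL genotype
structure, and the edge density of the real study's network — at n = 56
with the conservative local-fdr cutoff the synthetic network keeps only the
strongest few dozen conditional dependencies (at high precision), not
thousands of edges.  Passing tests therefore demonstrate correctness and
calibration of the machinery under a known sparse GGM, not that real
microarray data would yield networks of any particular richness.

## Problem sizes used in tests and the acceptance script

Oracle tests run exact comparisons at p ≤ 6 (partial correlations), n ≤ 7
(exhaustive Moran permutations) and ≤ 20 nodes (modularity forms).
Simulation suites use p = 30, n = 56 with 400 bootstrap resamples for
support recovery; 272-node planted-partition graphs with five seeds for
annealing; 1000 null simulations with 199 permutations for Moran
calibration; and 20–50 study-shaped simulations with 200 bootstrap
resamples for phenotype-module recovery.  These sizes keep the whole suite
within a few minutes while leaving each check statistically sharp
(Monte-Carlo standard errors an order of magnitude below the margins
asserted).

## Known limitations

* The bootstrap mean inherits the attenuation of per-replicate shrinkage;
  reported partial correlations are useful for ranking and testing, not as
  unbiased effect sizes.
* The empirical-null fit assumes the majority of pairs are null; designs
  where most pairs are truly dependent (e.g. a global latent factor) will
  inflate the fitted null and suppress discoveries.
* Simulated annealing is stochastic; a single run can merge adjacent
  modules.  The pipeline's grid-plus-selection protocol makes recovery
  reliable in practice but offers no optimality guarantee.
* The commute-time kernel requires a connected graph; disconnected
  networks must be analysed per component.
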