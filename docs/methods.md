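# Methods

This note records the statistical procedures exactly as implemented,
the defaults and why they were chosen, what the synthetic generator
does and does not emulate, and the known limitations.

## Containers and elementary transforms

All stages speak pandas-backed containers: a long survey table (one
row per site × year × session with integer counts), a site-by-species
matrix in abundance or incidence mode, per-grain environment tables,
coordinates, and the tree-cover gradient. Pooling takes the arithmetic
mean of a species' counts over all surveys of a station; a species is
scored present at a station if it was detected in at least one survey
(the pooling-and-mean description implies any detection counts; no
other conversion rule is defensible without a stated threshold).
Coefficients of variation are undefined where the mean is zero and are
stored as missing; predictor screening drops columns containing
missing values before forward selection.

The Hellinger transform, y′ᵢⱼ = √(yᵢⱼ/yᵢ₊), maps each non-empty row to
the unit sphere, making Euclidean-based ordination appropriate for
sparse count data; empty rows map to zero rows and are flagged.

## Correspondence analysis

CA is computed by SVD of the chi-square standardized correspondence
matrix S = D_r^{-1/2}(P − rcᵀ)D_c^{-1/2}; eigenvalues are squared
singular values and total inertia equals the table's chi-square
statistic over its grand total. Scaling is row-principal: site scores
are the weighted averages of column-standard species scores, matching
reciprocal-averaging semantics (tests verify agreement with the naive
fixed-point iteration to 1e−8). Empty rows/columns are dropped before
analysis and reported unscored. Sign convention: each axis is oriented
so its first nonzero species loading is positive; when an anchor
(species richness by default in the pipeline) is supplied, axes are
instead oriented to correlate positively with it, which gives the
latent tree-cover gradient a reproducible direction. Matrix ordering
sorts rows and columns by their scores with a stable sort, so tied
scores keep their input order (permutation invariance therefore holds
only up to ties).

## EMS indices and null model

Embedded absences are counted over species columns only (gaps inside
each species' range along the site ordering), following the
operationalization of the classic Matlab tool. Turnover fills ranges
first, then counts, for every unordered pair of species, the product
of the site counts where exactly one of the two occurs. Boundary
clumping takes each species' first and last occurrence on the filled
matrix as two boundaries, computes Morisita's index of dispersion of
the per-site boundary counts, and tests it with the large-sample
chi-square statistic I_d(F−1) + n − F on n−1 degrees of freedom,
two-tailed (the exact procedure inside the original tool is not
documented; this is the standard Morisita test and is reported as
such).

The null model fixes each site's richness at its observed value and
draws that many distinct species with probability proportional to
their observed occurrence frequency (sites differ in suitability;
common species are common everywhere). Each replicate is re-ordinated
by its own CA before recomputing the indices, mirroring the treatment
of the observed matrix. Coherence and turnover are tested with
two-tailed z-scores against the Monte-Carlo moments (the convention of
the classic tool); exact Monte-Carlo p-values are reported alongside.
Default iterations: 200.

Classification follows the extended decision tree: non-significant
coherence → random; significantly more embedded absences →
checkerboard; otherwise significantly negative turnover → nested,
significantly positive → Clementsian / Gleasonian / evenly spaced by
the clumping test, and non-significant turnover → the corresponding
`quasi_` structure, directed by the sign of the turnover deviate.
Quasi-structures are the same headline pattern with sub-threshold
turnover evidence and are treated as such in recovery experiments.

### Known statistical behaviour

Two properties of the re-ordinated proportional null matter in
practice and are measured by the test suite:

- The turnover null distribution has large variance, so noisy nested
  metacommunities frequently classify as `quasi_nested` rather than
  `nested`.
- The coherence z-statistic is over-dispersed on large matrices
  (standard deviation ≈ 1.15–1.3 at 100 sites × 30 species when the
  observed matrix is itself a draw from the null mechanism), because
  null replicates are conditioned on the observed matrix's empirical
  occurrence frequencies and so understate marginal variability. The
  realized false-structure rate on structureless matrices is
  therefore ≈ 8–12% at a nominal two-tailed 5%, and ≈ 3% (mildly
  conservative) on small matrices (15 × 8). Users should read
  marginal coherence significance on large matrices with this in
  mind.

## Variation partitioning

RDA is multivariate least squares of the centred Hellinger matrix on a
centred predictor block; R² is the ratio of fitted to total sum of
squares, adjusted by Ezekiel's formula with the block's rank as the
parameter count. Partial tests residualize response and predictors on
the conditioning block and permute reduced-model residuals
(pseudo-F; p = (hits+1)/(n_perm+1); at least 99 permutations
required). Forward selection adds, at each step, the candidate with
the largest joint raw R², accepts it if its conditional permutation
p ≤ α (0.05 default), and stops once the cumulative adjusted R²
crosses the full-model cap — the crossing variable is retained,
matching the behaviour of the classic forward-selection
implementations (rejecting it instead makes the cap bind spuriously at
step one whenever a single informative predictor sits among noise,
because the junk-padded full model's adjusted R² fluctuates around the
single-predictor value).

The three-block partition fits the seven RDAs (E, S, T, ES, ET, ST,
EST) and solves the inclusion–exclusion system; the eight fractions
sum to one algebraically, negative fractions are reported as computed
(truncation is an output option), and absent blocks degrade the scheme
to the two- or one-block versions. The observation unit is site ×
year × session, so the temporal block (centred year and session
dummies) has within-site contrasts to explain; a pooled-site analysis
is available by passing pooled tables directly.

Spatial predictors: the nine trend-surface monomials of mean-centred
coordinates (each column re-centred; rank reported when site geometry
is degenerate), or classic PCNM — distances truncated at the longest
minimum-spanning-tree edge (beyond-threshold entries set to four times
the threshold), Gower-centred, eigen-decomposed, eigenvectors with
positive eigenvalues retained and scaled by √λ. PCNM supplies
finer-scale basis functions than the cubic surface, and with
forward-selected blocks it captures at least the spatial fraction TSA
does on the same data (verified on synthetic fields).

## Deconstruction

Species classes: pairwise Euclidean distances on axis-1 species
scores, complete-linkage dendrogram (Ward available), cut at the
three-cluster level; classes are labelled open-land / intermediate /
woodland by ascending mean score, which is stable because the axis is
richness-anchored. Landscape classes: half-open bins [0, 0.35),
[0.35, 0.70), [0.70, 1] on the tree-cover fraction. Cells with fewer
than 10 sites or 3 species are skipped with a warning; failures inside
one cell are recorded and the run continues.

## Synthetic generator

The generator emulates the shape of a five-year, two-session,
260-station farmland survey: sites on a jittered 1 km grid; tree cover
as a Gaussian random field with exponential covariance (range 2 km by
default) squashed through the normal CDF (uniform-ish marginal,
spatially autocorrelated); per-grain environment tables whose crop
areas are drawn per year (so CVs are non-degenerate) and whose
coarse-grain fields are distance-weighted smoothings of the fine-grain
ones; Poisson counts with a log-linear temporal layer whose
year/session scores act through per-species loadings (so composition,
not just total abundance, varies in time when the temporal weight is
positive).

Occupancy templates per scenario: Clementsian — species groups share a
niche centre and width on the gradient, hence common range edges;
Gleasonian — independent interior niches (kept away from the gradient
ends so range edges do not pile up there); evenly spaced — equal
widths on an even grid of optima, interleaving the two edge
sequences; nested — per-species thresholds on the gradient
(linspace 0.03–0.97, so only a handful of sites are near-full and the
ordering jitter at the rich end stays small); random — a draw from the
null mechanism itself (weighted sampling without replacement at random
richness), which is the method's own no-structure hypothesis;
checkerboard — a community-wide diffuse-exclusion network built by
margin-preserving swaps that flatten pairwise co-occurrence at low
site richness. A literal set of mutually exclusive species pairs is
*not* used for the checkerboard: one ordination axis separates the two
halves of any perfect pair split, so reciprocal averaging compresses
such matrices and the coherence test reads them as coherent; the
diffuse network is the configuration that actually produces the
canonical significant negative coherence.

Observation noise: detection dropouts anywhere at rate `noise_flip`
(default 0.05), stray presences five times rarer and restricted to
spillover near a species' occupied sites along the gradient (a
far-flung stray would stretch the apparent range across the whole
ordination, which point-count noise does not do). The random template
receives no noise layer (it is already the no-structure law); the
checkerboard receives dropouts only. Empty rows/columns that noise
creates are repaired by restoring one of the species' template
presences.

Structure recovery at 100 sites × 30 species, 25 seeds, 200 null
iterations (computed by the test suite and the acceptance script):
Clementsian 25/25, nested 24/25, checkerboard 24/25, random 22/25 —
the random shortfall is the intrinsic false-structure rate of the
re-ordinated null discussed above, not a generator artefact.
Gleasonian and evenly spaced scenarios are generated and documented
but their labels are only weakly recoverable at this size: the CA
ordering itself induces boundary clumping, so Gleasonian communities
often read as Clementsian — a known bias of boundary tests on
ordinated matrices.

`community_with_shares` provides the calibrated-variance route for
partition validation: predictors are made exactly orthonormal
in-sample and each species column mixes them with √share weights plus
orthogonalized noise, so sample R² against each block equals the
declared share to machine precision and estimated pure fractions are
unbiased up to the Ezekiel adjustment.

What the generator does not emulate: observer heterogeneity and
detection covariates, within-season territory dynamics, GIS geometry
of land-use polygons (buffer tables are generated directly), and
spatially contagious disturbance. Passing recovery tests therefore
demonstrate correctness of the inference chain under the stated data
model, not robustness to every field artefact.

## Problem sizes and tolerances

The test suite runs the exhaustive index oracles on every incidence
matrix up to 12 cells; the null-model contract on 10,000 replicates;
calibration of the coherence test on 300 null-drawn 15 × 8 matrices
(binomial band around 5%); permutation-test size on 400 null
replicates at 199 permutations; partition recovery on 50 seeds per
share setting (±0.03 on means); and structure recovery on 25 seeds per
scenario. Fraction additivity is asserted to 1e−10 (it is algebraic).
These sizes were chosen to give binomially meaningful bands at
desk-scale runtimes; the acceptance script re-runs the headline chain
at the full 260 × 40 × 10-survey shape.

Numerical notes: CA requires at least two non-empty rows and columns
and raises a degenerate-ordination error on zero-inertia tables (the
EMS stage converts this to an `undefined` label); rank-deficient
predictor blocks are fit by least squares with the rank as the
parameter count and a warning; permutation seeds are spawned from the
caller's seed, so every pipeline output is bit-reproducible from
(inputs, config, seed).
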