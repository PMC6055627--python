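# Methods

This note documents the models, numerical choices and limitations of
`gmnet`.  It is written for someone who wants to understand *why* the code
does what it does, not just what the API returns.

## Network extraction

**Nodes.** The grey matter density volume is tiled into non-overlapping
3×3×3-voxel cubes starting at voxel (0,0,0); trailing partial slabs are
discarded.  A cube becomes a node if its mean density exceeds
`min_gm_fraction` (default 0, exclusive — any nonzero grey matter
qualifies; the bound is exposed because segmentations differ in how much
near-zero partial-volume tissue they contain).  Nodes are ordered
lexicographically by the (z, y, x) of the cube's low corner; this order is
the node identity used in every output.

**Similarity.** Entry (i, j) is the Pearson correlation of the 27
corresponding voxel intensities of cubes i and j.  Zero-variance cubes
(homogeneous intensity) have an undefined correlation; it is set to 0 with
a warning rather than propagating NaN.  An optional variant maximizes the
correlation over the 48 axis-aligned rotations/reflections of one cube
(the orientation-invariant formulation used by some implementations of
this similarity measure); it is off by default, matching the plain
corresponding-voxel description, and the group structure makes the
maximized matrix exactly symmetric.

**Threshold calibration.** The null model permutes voxel intensities
*within every cube* and recomputes all pairwise correlations, 1000 times
by default (minimum 100).  This preserves each cube's marginal intensity
distribution while destroying spatial correspondence — exactly the signal
the similarity measure responds to.  The cutoff is the smallest value c
such that

  E[null pairs above c]  ≤  spurious_rate × (real pairs above c),

with `spurious_rate` = 0.05: at most 5% of retained connections are
expected to be chance.  Numerical details that matter:

* Candidate cutoffs are placed infinitesimally below each observed
  similarity value (`nextafter`), so the strictly-greater edge rule keeps
  a pair at its own threshold.  Placing candidates *at* observed values
  silently drops the weakest genuine connection, because on the order of
  one null value per permutation set exceeds the largest chance
  correlation.
* The scan walks down from the strictest candidate and stops at the first
  violation (contiguous satisfying run).  Accepting isolated satisfying
  candidates deeper in the noise tail — which arise as upward sampling
  flukes of the realized noise count — systematically admits extra
  spurious connections.
* Ties resolve toward the stricter cutoff; `spurious_rate ≥ 1` degenerates
  to the null minimum (everything above the weakest null value connects);
  if no candidate satisfies the bound (e.g. a pure-noise volume) the null
  maximum is returned and the network is flagged empty-at-calibration.

Under the calibration study conditions (8 planted pairs per 64-cube
volume, latent loading 0.9, noise SD 0.1) the realized chance share of
retained connections averages just under 5% — the per-volume value is
coarse (one extra connection among ~8 retained is ~11 points), so means
over few volumes are noisy; `scripts/acceptance.py` averages 300 volumes.

## Graph parameters

Degree, connectivity density (percent of possible pairs connected),
clustering (fraction of a node's neighbor pairs that are connected; 0 for
degree < 2, the Brain Connectivity Toolbox convention), characteristic
path length (BFS shortest paths; nodal = mean over reachable partners,
global = mean over all reachable pairs) and exact Brandes betweenness.
Choices:

* **Disconnected pairs** are excluded from path-length averages and their
  count reported with a warning; a harmonic-mean variant
  (`path_length_harmonic`) that penalizes disconnection is provided but is
  not the default.
* **Betweenness** is reported raw — the sum over *ordered* pairs (s, t) of
  the fraction of shortest s–t paths through the node — because
  whole-brain magnitudes in the thousands imply unnormalized counts; the
  normalized proportion is emitted alongside since the convention behind
  published numbers is not always stated.
* **Normalization**: γ = C/⟨C_ref⟩ and λ = L/⟨L_ref⟩ over 20 reference
  networks produced by Maslov–Sneppen double-edge swaps (10 swaps per
  edge, seeded), which preserve the degree sequence exactly.  Graphs
  admitting no legal swap (e.g. a triangle) are returned unchanged with a
  warning.  γ is rejected with guidance when the reference clustering is
  0 (graph too sparse to form triangles).

All metrics are verified in the test suite against independent brute-force
oracles (Floyd–Warshall distances, explicit shortest-path counting) on
random graphs up to 12 nodes, to 1e-10.

## Regional averaging

A cube is assigned to the majority label among its 27 voxels (ties to the
lowest label; background majority → unassigned).  Majority voting is
deterministic and robust to the parcellation's resolution relative to the
cube grid.  Regional tables carry the unweighted mean of each nodal metric
plus the local grey matter volume (sum of densities × voxel volume, mL).
Unassigned nodes stay in the global averages but never enter regional
tests.  The atlas is assumed aligned to the volume grid — warping an
MNI-space atlas into native space is an input contract, not something this
package does.

## Cognitive preprocessing

Twelve tests in four domains (attention 4, executive 3, memory 3,
language 2) plus the MMSE.  z-scores are referenced to the *in-sample
baseline* distribution (ddof = 1), the natural reading of "the
corresponding baseline distribution"; TMT-A/B and the three Stroop cards
are sign-flipped *after* the transform (equivalent to negating raw
deviations, and stated explicitly to avoid double-inversion bugs).  The
MMSE is z-transformed like any other test before entering the global
composite.

Missing scores are imputed by chained equations with predictive mean
matching (statsmodels `MICEData`), with age, sex, education, time and all
other test scores as predictors; m = 15 completed datasets after 5
burn-in cycles.  `MICEData` draws from NumPy's global random state, so the
state is saved/seeded/restored around the run for reproducibility.
Composites are unweighted means of member z-scores; global cognition
averages all twelve tests plus the MMSE.

## Longitudinal models

Per measure × domain: REML mixed model with fixed effects time, measure,
measure×time, age, sex, education, total grey matter volume and scanner,
and a random subject intercept (random slopes are available but off —
they are not part of the reference analysis).  Predictors are standardized
across subjects before entry so coefficients are comparable across
measures (flagged in metadata, can be disabled).  The covariate ladder is
data-driven: any basic parameter (size, degree, density) whose pooled
baseline term is significant (p < 0.05) in a domain joins that domain's
higher-order models as a covariate, since basic measures can influence
higher-order parameters.

Rubin pooling: pooled β = mean; total variance = within + (1+1/m)·between;
degrees of freedom by Rubin's formula with the Barnard–Rubin small-sample
adjustment using the median complete-data residual df; p from the t
reference.  Identical estimates across imputations give infinite df
(normal reference).  Imputations that fail to converge are dropped with a
warning up to 20% of the ensemble, beyond which the fit is rejected.

FDR: step-up adjustment within a declared family — all measures × domains
for the global analysis (baseline and annual-change terms as separate
families), the retained regions for local analyses.  Benjamini–Yekutieli
is the default (valid under arbitrary dependence, matching the cited
procedure; the network measures are strongly correlated), with
Benjamini–Hochberg available.  Local models drop regions whose predictor
is missing in more than 10% of subjects and always adjust for local grey
matter volume.

## Synthetic data: what it emulates and what it does not

**Volumes.** Each designated cube group (pairs by default) shares one
27-dimensional standard-normal latent intensity pattern scaled by
`latent_loading`; every in-mask voxel adds independent N(0, noise_sd)
noise; values are mapped to densities around 0.55 with amplitude 0.18 and
clipped to [0, 1].  A scalar latent added to both cubes could not produce
across-voxel correlation within a single volume, so the latent must be a
pattern; this is the minimal mechanism producing exactly the inter-cube
similarity the extraction detects, with chance-level similarity everywhere
else.  `cubes_per_latent > 2` makes each latent a clique, giving the
network triangles (and hence a defined γ); the analysis drivers use this
to create between-subject topology variation.

**Cohorts.** Trajectories follow the generative mixed model
score = β_base·x + β_time·t + β_int·x·t + covariate effects + u_subject +
residual, with a shared random intercept across domains (a general
cognitive level), per-test noise, and raw scores mapped onto realistic
test means/SDs for a memory-clinic population of cognitively intact older
adults (e.g. TMT-A 39.8 ± 15.7 s, MMSE 28.4 ± 1.6).  Default SDs (random
intercept 0.70, residual 0.71, test noise 0.30) make the baseline SD of a
test ≈ 1.04, so planted betas survive the z-transform nearly unattenuated
(≈ 4% shrinkage).  Visits are approximately annual (jitter SD 0.1 y) over
a follow-up drawn from 2.8 ± 1.0 years; missingness is MCAR at per-test
rates of 1–10% (only marginal rates are emulated — no informative
dropout).  Ground truth is written to a JSON sidecar so tests never
reverse-engineer it from outputs.

**Not emulated:** real neuroanatomy and spatial covariance structure,
registration error, partial-volume effects, scanner-specific intensity
profiles, informative missingness, practice effects.  Passing tests show
the *machinery* is correct and calibrated under known truth; they do not
certify effect sizes on clinical data.  In particular the synthetic
networks are far sparser and more fragmented than real grey matter
networks (density ~1% vs ~17%; γ magnitudes correspondingly inflated), so
synthetic metric values are not comparable to published cohort means.

## Problem sizes used in validation

The validation studies run at sizes chosen to make Monte-Carlo error small
relative to the tolerances they check: threshold calibration on 50 volumes
(1000 permutations) in the test suite and 300 in the acceptance script;
interaction recovery over 50 replicates of 400-subject cohorts (tolerance
±0.02 on β = 0.10); null CI coverage over 100 replicates of 150 subjects;
local-analysis FDR control over 15 replicates of 30 regions × 150
subjects; random-graph null checks on 20 Erdős–Rényi graphs (n = 200,
16% density).  The analysis drivers use a 200-subject cohort with
15 imputations.

## Known limitations

* The permutation null stores all n_permutations × n_pairs values in
  memory (float32); fine for the cube counts used here, but whole-brain
  7000-node networks would need streaming quantile estimation.
* MixedLM occasionally reports non-convergence on small or near-collinear
  data; the pooling layer tolerates up to 20% failures.
* The calibrated threshold targets the *expected* spurious share; single
  subjects can exceed 5% when few connections are retained.
* BY correction under the default settings is conservative; with small
  families and modest n, true effects may not survive it (visible in the
  local-analysis driver).
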