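# Methods

## Scope and model overview

`exposcreen` is an ecological association engine: every quantity is
defined at the zip-code level, and every association is between an
area-level exposure summary and an area-level diagnosis rate. The
pipeline has two complementary screening arms — a multivariable
penalized regression that handles toxicant co-linearity but ignores
space, and a univariate spatial mixed model that absorbs regional
autocorrelation but fits one chemical at a time — followed by SD-based
flagging and Fisher-exact mechanism enrichment.

## Exposure kernel

For zip z and chemical c, with facilities i at great-circle distance
d_zi (haversine, sphere radius 3958.8 mi; ellipsoidal corrections are
irrelevant at 30-mile scale):

    E_zc = Σ_i A_ic · P_i · k(d_zi) / Σ_i P_i · k(d_zi),
    k(d) = exp(−d² / 2σ²),   d ≤ 30 mi (closed ball),

where A_ic is the annual release amount and P_i a population weight.
Parameters, with units and defaults:

- `radius_miles` (30): catchment radius. Membership is `d ≤ radius`;
  the boundary convention is documented because nothing upstream fixes
  it.
- `sigma_miles` (10.7785): kernel SD, derived from the half-normal
  mean relation E|X| = σ√(2/π) with an assumed 8.6-mile mean
  patient-to-provider trip. `half_normal_sigma` exposes the
  derivation.
- `mode` (`weighted_mean`): the normalized form above keeps exposure
  in the units of release and makes the kernel's constant factor
  cancel, which is why the unnormalized Gaussian is the implementation
  contract. A `weighted_sum` mode (kernel-discounted total divided by
  the zero-distance weight mass) is provided because a plain summed
  catchment is the other defensible reading of the construction.
- P_i: population of the facility's nearest zip unit. This is a design
  choice — the weighting population is not otherwise pinned down — and
  an explicit `population` column on the releases table overrides it,
  so the patient-zip reading is representable too.

A zip with no in-catchment facility for a chemical gets an explicit 0;
a water zip with no monitor gets *no row*, because assuming zero
concentration where nothing was measured would fabricate data.
Chemicals present in a supplied universe but never released are dropped
(logged) rather than carried as all-zero columns.

## Rates and exclusions

rate = count / total billed diagnoses, per zip × ICD × stratum. Counts
may include every diagnosis on a visit, so rates are not bounded by 1
by construction and the code deliberately asserts only non-negativity
and finiteness. "Age-standardized" is implemented as
stratum-specific rates with age-bin proportions as model covariates;
no direct standardization is performed because no reference population
is defined anywhere upstream. Exclusions run in a fixed order:
population floor first (default 10,000), then the 2%-of-zips
occurrence rule and the 10,000 national-count floor, both strict `<`,
both evaluated on the zips that survive the population filter. The 2%
rule is pooled across strata by default (a per-stratum variant is a
caller choice); pooling is the simpler reading and the order/pooling
choices are fixed and documented precisely because they change which
codes survive. Exclusion is idempotent: re-applying the filter to its
own output removes nothing.

Stratum collapsing (0–5, 6–17, 18–54, 55–74, 75+ → 0–17, 18+) pools
counts and denominators and recomputes rates from the pooled values — a
pooled ratio, never a mean of ratios.

## Non-spatial screen

Per (outcome, stratum, medium): Gaussian elastic net on the z-scored
predictor matrix, objective

    (1/2n)‖y − β₀ − Xβ‖² + λ(α‖β‖₁ + (1−α)‖β‖₂²/2),

α = 0.5, λ = argmin of 10-fold CV MSE over 100 log-spaced values from
λ_max (the smallest λ zeroing every coefficient) down to λ_max·1e−4.
Fold assignment is a pure function of the seed. Numerical choices:
predictors are z-scored once on the analysis set (not per fold);
population-SD (ddof 0) z-scoring; constant columns are dropped and
reported; the CV-MSE argmin rule is used, not the 1-SE rule. The
outcome stays on its natural rate scale; exp(β) is emitted alongside β
because downstream displays conventionally label it an odds ratio,
but it is simply the exponentiated per-SD coefficient of a linear
model — both are always written so no information is lost. The screen
deliberately produces no p-values or intervals; selection pressure from
the penalty would invalidate naive ones, which is exactly why the
SD-distance filter exists downstream.

## Spatial hierarchy and the NB mixed model

One complete-linkage dendrogram is built on the pairwise great-circle
distances of the zip centroids, and cut at four counts
K_l = max(1, round(N / s_l)) for the size schedule s = (81, 27, 9, 3)
(halves round up). Cutting a single tree guarantees the four
partitions nest — this is load-bearing: nesting is what makes the four
random intercepts a coarse-to-fine decomposition rather than four
overlapping groupings. Zips are sorted by id before clustering so the
result is independent of input order and labels are stable. When N is
too small for distinct cuts, duplicate partitions are collapsed with a
warning.

Counts are modelled per (disease, focal chemical, stratum):

    y_z ~ NB(μ_z, θ),  Var = μ + μ²/θ,
    log μ_z = log T_z + β₀ + β_tox x_z + γ·covariates + Σ_l u_{l,c(z)},
    u_l ~ N(0, σ_l²) independent within level,

with T_z the stratum's total visits (zips with T_z = 0 are excluded —
the log offset is undefined — and counted in the report). Estimation
is a Laplace approximation in the lme4 nAGQ=0 spirit: an inner
penalized IRLS solves jointly for (β, u) at fixed (σ², θ), with
step-halving so the penalized log-likelihood never decreases; the
marginal log-likelihood is

    ℓ_NB(y|û) − ½ ûᵀΣ⁻¹û − ½ log det Σ − ½ log det(ZᵀŴZ + Σ⁻¹),

and an outer bounded derivative-free search (Powell) moves
(log σ₁²…log σ₄², log θ) within log σ² ∈ [−23, 5], log θ ∈ [−5, 12].
A variance at the lower bound (σ² ≈ 1e−10) is reported as a boundary
fit; non-convergence is returned flagged, never silently. Standard
errors are Wald, from the fixed-effect block of the inverse joint
penalized information; no interval procedure beyond that is claimed.
With all variances fixed at zero the machinery reduces exactly to a NB
GLM, which is verified against an independent maximum-likelihood
implementation, and at θ → ∞ to Poisson regression.

The spatial screen is univariate (one focal chemical per fit) — the
cost of a multivariable mixed model over hundreds of exposures is
prohibitive and co-linearity handling is the other arm's job. Spatial
fits use the two collapsed strata; water exposures are not modelled
spatially (monitored zips are too sparse a graph to cluster
meaningfully).

## SD filter and tallies

Flagging uses the beta scale: pooled mean m and sample SD s (ddof 1)
over a pooling scope, flag when |β − m| > k·s (k = 2, display k = 5).
The default scope pools within medium × stratum × model type, because
spatial and non-spatial coefficients live on incomparable scales; a
`global` scope reproduces the most literal single-cohort pooling.
Mean/SD do not commute with exp(·), so filtering on β versus the
displayed ratio genuinely differs; β is the fixed choice. Covariate
coefficients stay in the pool and may pass (latitude does, in
practice); a toxicants-only restriction is available. Filtering adds
flags and never drops rows. Degenerate pools (s = 0) pass nothing,
with a warning. ICD letter tallies compare each letter's share of
total diagnosis counts against its share of distinct flagged codes.

## Enrichment

`fisher_exact_right` is the hypergeometric right tail P(X ≥ a) — the
enrichment direction, matching the one-sided question being asked; a
two-sided option exists but is not the default. Protein tests take the
background universe to be the toxins present in both the interaction
map and the exposure matrix: "chance expectation" should refer to
chemicals the screen could actually have flagged. Proteins touched by
no flagged toxin are skipped (their right tail is 1 by construction).
BH-FDR is applied per family — across tested proteins, and per gene-set
library — with the q < 0.05 decision rule. Pathway tests use the
library's own distinct genes as the universe, the convention of
unordered-list enrichment tools. Note the BH step-up transform is not
idempotent (re-adjusting adjusted values inflates them); tests assert
the true step-up properties instead.

## Synthetic data generator

The generator's role is to produce data whose statistical structure
matches what the pipeline assumes, so that parameter recovery is a
fair test rather than an accident:

- Geography: uniform centroids in a 4°×5° interior-US box, log-normal
  populations (median ≈ 33k), Dirichlet(8) age proportions over 21
  bins, uniform visit totals in [5000, 20000] per stratum. Defaults:
  300 zips, 20 chemicals, 600 facilities — roughly two facilities per
  zip, so a 30-mile catchment holds a realistic handful of sources.
  With sparser facilities a single source dominates each catchment and
  induces spurious cross-chemical correlation, breaking the
  co-linearity dial below.
- Releases: log-amounts share a one-factor Gaussian structure with
  loading log(1 + ρ(e−1)) so the *lognormal* amounts correlate at
  ≈ ρ (`colinearity_rho`, default 0.5), emulating the co-linear
  traffic-pollutant-style exposure blocks that motivate the elastic
  net.
- Diagnoses: the generative twin of the spatial model — NB(μ, θ = 5)
  with log μ = log T + log(0.01) + Σ β·x(z-scored) + nested random
  intercepts (σ² = 0.05 per level). Planted β values are therefore on
  the per-SD scale the screens estimate. The latent rate is capped at
  1: z-scored heavy-tailed exposures can otherwise push exp(signal)
  past the billing denominator, producing rates no registry could
  emit. A Poisson-lognormal switch (`misspecified`) exists for
  robustness checks against the fitted family.
- Annotation: planted-effect chemicals hit each of three target
  proteins with probability 0.8 versus 0.1 background, and the targets
  sit in one planted pathway of a 10-set GMT library over a
  200-gene universe.

What the generator does *not* emulate: real US geography or zip
shapes, census marginals beyond simple parametric forms, reporting
artifacts, secular trends, or individual-level confounding. Passing
tests therefore demonstrate that the estimators recover the structure
they assume — they say nothing about unmodelled structure in real
registry data.

## Problem sizes used in the test suite

Chosen to exercise each property at the smallest scale where it is
well-posed: 810 centroids for the cluster-size schedule; n = 500 with
51 predictors × 20 replicates for elastic-net recovery; 729 zips × 20
replicates (nested cluster counts 9/27/81/243) for mixed-model
recovery; 10 seeds for the end-to-end planted-pathway run; every 2×2
table with total ≤ 30 for the exact-test oracle sweep.

## Known limitations

- Laplace (nAGQ=0) estimates of variance components are mildly biased
  for small cluster counts; the coarsest level has only ~9 clusters at
  N = 729, and its variance is often estimated at the boundary.
- Wald SEs from the penalized joint information ignore uncertainty in
  (σ², θ); coverage is adequate in the recovery tests but no small-N
  guarantee is claimed.
- The exposure kernel ignores wind, terrain, stack height and decay;
  water exposures ignore hydrological transport entirely (by
  construction: only monitor-zip assignment is defensible from the
  measurement model).
- Everything is 2016-style cross-sectional: no latency, no cumulative
  dose, no migration.
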