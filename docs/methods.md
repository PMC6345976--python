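# Methods

`phylocot` implements the phylogenetic comparative toolkit needed to ask
whether the rate of leg-force production (proxied by inverse foot contact
time, 1/t_c) explains interspecific variation in the energy cost of
terrestrial locomotion, and whether net cost of transport (NCOT) tracks
eco-physiological traits. This note records the models, the numerical
choices, and what the synthetic data do and do not establish.

## Phylogenies and covariance conventions

Trees are handled as rooted `dendropy` trees; polytomies are retained (the
taxonomy fallback produces them, and REML handles the resulting covariance
directly). Branch lengths follow Grafen's arbitrary method: node height
`((n_tips_below − 1)/(n_total − 1))^rho` with `rho = 1` by default
(exposed as an argument), which yields an ultrametric tree of depth 1. The
phylogenetic covariance matrix C therefore has unit diagonal, so the
phylogenetic heritability h² from the mixed model lives on the same scale
as Pagel's λ and the two are directly comparable. If numerical error makes
a pruned C indefinite, the smallest diagonal jitter in {1e-12, 1e-10,
1e-8} that lets a Cholesky factorisation succeed is added and recorded on
the matrix object.

When no phylogeny is supplied, a fallback tree nests species inside shared
taxonomy ranks (class → subclass/infraclass → order → family) as
polytomies, children sorted lexicographically for determinism. This is a
topology of convenience: it encodes only rank-level relatedness, and any
quantity conditional on topology (variance components, correlations)
inherits that approximation.

## Preprocessing

Raw mass-specific oxygen consumption V̇O₂ (ml kg⁻¹ min⁻¹) includes a
large zero-speed component, so within each data set an OLS line
V̇O₂ = a + b·U is fitted and the intercept `a` subtracted, leaving the
speed-dependent increment. Grouping is per species × source by default
(falling back to pooled per-species when requested); groups with fewer
than two distinct speeds pass through unadjusted and are flagged. Net
values pushed to or below zero are dropped from the model frame with a
count, never silently. All responses and covariates are log₁₀:
log₁₀(net V̇O₂), log₁₀(1/t_c), log₁₀(M in kg), log₁₀(U in m s⁻¹). Mass is
used per record, not per species, since within-species mass varies in
compilations. Intercept subtraction is stateful and refuses to run twice.

## The phylogenetic mixed model

Observations (long format over one or two traits) follow
y ~ N(Xβ, V) with V = Σ_i θ_i G_i, a covariance linear in its parameters:

* phylogenetic effect: per-species, covariance σ²_P·A (univariate) or an
  unstructured Σ_P ⊗ A (bivariate), A the Grafen-normalised relatedness;
* species-identity effect (univariate only): σ²_S on an exchangeable
  species indicator — with two traits there is not enough replication to
  separate it from phylogeny, so it is excluded there by construction;
* residual: per-trait variances. The between-trait residual covariance is
  only identifiable when observational units carry both traits; since
  oxygen and kinematic measurements typically come from different
  experiments the default fixes c_R = 0 (trait-disjoint), and an explicit
  paired mode estimates c_R for rows sharing an observation id.

Estimation is REML (ML available) by L-BFGS-B on log-variances and
tanh-transformed correlations, with analytic gradients (cheap because V is
linear in θ) and five deterministic multistarts spreading the initial
variance mass across components; simulation loops use two starts.
Convergence: relative criterion change below 1e-12, projected-gradient
tolerance 1e-6, at most 500 iterations. Variances ending within ~1e-7 of
zero are reported as exact zeros and flagged as boundary estimates, whose
SEs are unreliable. The REML criterion includes the `log|XᵀX|` constant so
it equals the log-density of an orthonormal error contrast exactly; tests
exploit this for an independent oracle.

Derived quantities:

* h² = σ²_P / (σ²_P + σ²_S + σ²_R), the proportion of conditional variance
  attributable to phylogeny; its SE comes from the first-order delta
  method on the inverse expected REML information (expected information is
  exact here because V is linear in θ).
* phylogenetic correlation r = c_P / √(σ²_P1 σ²_P2), delta-method SE;
  undefined when either phylogenetic variance is at the boundary.
* (co)variance tests: likelihood-ratio statistics referred to a plain
  χ²₁ — no 50:50 boundary mixture — matching the convention of the
  comparative literature this package follows. If a full model ever ends
  below its constrained counterpart, it is refitted starting from the
  constrained optimum before the statistic is clamped at zero.
* fixed effects: Wald-type conditional F-tests with Kenward–Roger
  small-sample denominator df (first-order adjusted covariance; the
  second-derivative terms vanish for linear V) and a Satterthwaite
  fallback. On balanced one-way toys the KR df reproduce the exact
  classical values (g − 1 between groups, N − g − 1 within).
* BLUPs of the species-level phylogenetic effects,
  û = Cov(u, y) V⁻¹ (y − Xβ̂), with prediction SEs from the prediction
  error variance G − Cov(u, y) P Cov(u, y)ᵀ. They are shrinkage estimates
  used for visualisation, not data.

## PGLS

For one value per species, GLS with residual covariance σ²·C_λ, λ scaled
onto the off-diagonals. λ is profiled on a 0.01 grid over [0, 1] followed
by bounded golden-section refinement, because the profile is regularly
flat or multimodal at the battery's small n (down to ~15 species). ML is
the default criterion (REML available; the REML variant makes the
mixed-model h² and λ agree to numerical precision when there is one
observation per species). Coefficient SEs use the n − p residual-variance
estimate; t statistics and two-sided p-values follow. At λ = 0 the fit is
exactly OLS, at λ = 1 plain GLS.

The eco battery fits one model per covariate,
log₁₀(NCOT) ~ log₁₀(mass) + covariate, log₁₀-transforming covariates that
are sizes, rates or scopes and leaving ordinal codes (terrestriality, diet
breadth, trophic level, habitat breadth) untransformed. Missing data are
deleted listwise per model; models with fewer than 5 complete species are
skipped with a warning; a rank-deficient design fails only its own row. No
multiple-comparison correction is applied. Derived scopes are
AAS = MMR − BMR, FAS = MMR/BMR (missing if BMR = 0) and AMR = FMR − BMR,
computed rather than accepted as input.

## Synthetic data

`synthetic.SimConfig` defaults define the study conditions the package is
exercised under: 21 species, 288 + 126 trait-disjoint observations, trait
intercepts (1.421, 0.719), mass slopes (−0.173, −0.285), speed slopes
(1.035, 0.754), phylogenetic variances (0.0053, 0.0291), species variances
(0.0276, 0.0007), residual variances (0.0140, 0.0025), zero phylogenetic
and residual correlations. Species mass is log-uniform over 0.032–467 kg.
Species speed midpoints scale as M^0.2 with log₁₀ scatter 0.15 and a
within-species range of ×/÷2 — chosen because in treadmill compilations
test speeds rise with body size (mice near 0.1–0.3 m s⁻¹, horses 2–7
m s⁻¹), and this speed–size confounding is exactly what makes the
partial-correlation analysis interesting. Trees are Yule-shape topologies
with Grafen lengths, so simulation and analysis share one covariance
convention. A single seeded generator is spawned into per-stage
substreams (tree, design, species effects, residuals) so each stage is
reproducible in isolation.

The generator reproduces the statistical structure the model assumes —
multivariate-normal species effects, log-linear fixed effects, iid
residuals. Real compilations violate these in ways the generator does not
emulate: within-species V̇O₂–speed curvature, digitisation error,
heteroscedastic residuals across studies, non-random missingness. Passing
recovery tests therefore demonstrates correctness of the estimation
machinery under its own assumptions, not robustness to those violations.

`synthetic_study.reconstruct_dataset` is a stand-in for the archived
observation-level compilation, rebuilt from the published per-species
summaries: speeds evenly spaced in each species' range, V̇O₂
endpoint-linear in speed (implied intercepts agree closely with the
published ones), 1/t_c log-log linear in speed, masses log-spaced, and
multiplicative log-normal noise at the fitted residual scales (log₁₀ sd
0.118 and 0.05). Observation totals (288/126) are split evenly across
species in the published order. Analyses of this reconstruction reproduce
the study's qualitative findings — no mass × speed interaction; V̇O₂
dominated by non-phylogenetic species variance, 1/t_c by phylogenetic
variance; strong positive phylogenetic correlations conditioning on mass
or speed alone that collapse to non-significance with both — and land
near, but not exactly on, the published point estimates: endpoint-linear
interpolation forces the V̇O₂ speed slope to ~1.0 and flattens the 1/t_c
speed slope, and range-based reconstruction cannot recover within-species
curvature. Quantities conditional on the exact observations or the exact
topology should be read as scale-correct approximations.

## Problem sizes

Parameter-recovery and test-calibration experiments run at 100 species
with two observations per species per trait and 200 replicates: piloting
showed the covariance-zero LRT is close to nominal there, while with a
single observation per species per trait the phylogenetic and residual
variances are nearly confounded and the LRT's tail becomes anti-
conservative — a design caveat worth knowing when fitting sparse data.
The full study-scale analysis (414 observations, 11 model fits including
LRT counterparts) completes in well under a minute on one CPU.

## Known limitations

* Kenward–Roger is implemented for the linear covariance structures used
  here; it is the component most sensitive to near-boundary variance
  estimates, where the Satterthwaite fallback is more stable.
* Delta-method SEs for h² and r are first-order and degrade near
  boundaries (flagged).
* The χ²₁ reference for variance LRTs is conservative at the zero
  boundary; it is retained deliberately for comparability.
* The taxonomy fallback tree equates rank membership with relatedness;
  topology-conditional estimates shift under better topologies.
* No Ornstein–Uhlenbeck or rate-heterogeneous models: the phylogenetic
  effect assumes Brownian-structured covariance throughout.
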