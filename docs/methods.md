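# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices, and the limitations of `resfish`.

## The density model

Corrected survey density y (kg ha⁻¹) is modelled as Gamma with log link:

    log mu_i = beta0 + a_c(i) + f_c(i)(age_i) + g(year_i) + u_r(i)

* `a_c` — fixed class effects (treatment coding against the first class).
* `f_c` — one penalized smooth of reservoir age per class (a factor
  smooth). All class smooths share one smoothing parameter, the usual
  "fs"-type factor-smooth construction: separate shapes, common wiggliness.
* `g` — a penalized smooth of sampling year, shared across classes.
* `u_r` — per-reservoir intercepts as a ridge-penalized dummy block, the
  standard random-effect-as-smooth equivalence; sigma_u^2 = phi / lambda_re.

Smooths are degree-3 B-splines (basis dimension 10) on uniform, unclamped
knots with a second-order difference penalty (P-splines). On this knot grid
the penalty null space is exactly {constant, linear-in-x}; the constant is
removed by a sum-to-zero centering constraint per smooth so smooths are
identifiable next to the intercept and class effects. The penalized-smooth
contract, not any particular basis, is the correctness surface: tests pin
the Gamma-GLM limit (all lambda → ∞ reduces the fit to the linear
respecification, checked against an independent IRLS implementation) and a
simulation oracle for curve recovery.

### Fitting

For a log-link Gamma the IRLS working weights are identically 1, so each
penalized IRLS step solves (XᵀX + S(λ)) β = Xᵀz with working response
z = η + (y − μ)/μ. The inner loop converges when the relative change of the
penalized deviance is below 1e-6 (hard cap 100 iterations; non-convergence
at the final smoothing parameters raises an estimation error with
diagnostics).

Smoothing parameters are selected by minimizing the Gaussian working-model
REML criterion

    (n − M_p)(log 2πφ̂ + 1) + log|XᵀX + S| − log|S|_+ ,  φ̂ = D_p/(n − M_p)

over log λ (one λ per penalty block: shared age, year, random) with
Nelder-Mead from λ = 1 and an explicit wide initial simplex (steps of 2 on
the log scale; the default simplex at the origin is degenerate). Bounds
are log λ ∈ [−10, 20] via a soft quadratic barrier. If the search returns a
non-finite score, a coarse GCV coordinate grid is used instead. This is an
approximation to a full Laplace REML (as an mgcv-style implementation would
compute); exact replication of any particular package's λ estimates is a
non-goal, and the parameter-recovery tests are the accuracy statement.

### Standardization-year prediction

Surveys end years before the standardization year (default 1993), so
class predictions extrapolate. Bases span the observed data range and
evaluation beyond it continues **linearly** from the boundary value and
slope. This is the asymptotic behaviour of thin-plate and
difference-penalized splines, it is independent of how small the selected
λ happens to be (basis functions supported only where there are no data are
otherwise determined by the penalty alone), and it makes predictions
continuous in year across the extrapolation boundary. Sampled reservoirs
are predicted with their own random intercept and their age advanced to the
prediction year; population-level predictions (unsampled reservoirs) set
u = 0. Class means are arithmetic means of per-sampled-reservoir
predictions — a deliberate choice over evaluating the class curve at a
single mean age, because it matches how the imputation step consumes them.

## Classification

Covariates are ln(x+1)-transformed and z-scored within the clustering
stratum (globally for schemas 2–3, within ecoregion for schema 5; "scaled"
is read as z-scoring). K-means is Lloyd's algorithm with 25 seeded
restarts (scikit-learn backend). Cluster naming is rank-based: the lower
half of centroids on the volume axis is "small", the upper half "large",
likewise "low"/"high" on discharge; ties break by the other axis then
cluster index, so labelling is deterministic even for identical centroids.
Schemas 2 and 3 are defined here as the natural ecoregion-free ablations of
schema 5 (k = 2 on volume; global k = 4 on volume × discharge) and are
config-swappable — a documented divergence risk versus any particular
published implementation. Records missing a needed covariate are labelled
`unclassified` and later receive the global-mean density. An ecoregion
stratum with fewer than k eligible reservoirs is kept whole as one
`<ecoregion>|all` family rather than force-split.

## Inventory cleaning

Three rules, each counted in a reconciling report
(|out| + removals = |in|, cleaning idempotent):

1. natural lakes — a flag column or a configurable name exclusion list
   (seeded with the Great Lakes and similar); no heuristic guessing;
2. no basis for area — rows with neither surface area nor storage volume;
3. duplicate dams — rows sharing case-folded, punctuation-stripped
   name + state collapse to the maximum-storage-volume dam.

Missing areas are predicted from an OLS of ln(area) on ln(volume) over
complete records (≥ 10 pairs), back-transformed; with fewer pairs, a
median(area/volume) ratio is used. Observed areas are never modified. The
ecoregion join is point-in-polygon with covers-semantics; a boundary point
goes to the first polygon in layer order. The real national inventory's
exact dedup rules live in its originating analysis code, so the published
85,470-row count is treated as an external benchmark, not a unit test.

## Scale-up, ensemble, production

Standing stock is exactly density × area; totals are group sums with an
explicit `unassigned` bucket for missing state/ecoregion so every grouping
partitions the national total. The ensemble mean across the schema totals
uses the sample sd (n − 1) over √n. Production uses P/B = 1.30 y⁻¹ with
quartiles 0.583 and 1.823 y⁻¹ as config defaults; these are the values
consistent with the published regional production figures (the per-reservoir
interquartile figures imply slightly different quartiles ≈ 0.51/1.59 — the
defaults follow the regional totals, and the discrepancy is noted here).

## Validation model

ln(observed) on ln(predicted) with a random intercept per classification
schema, fitted by REML profiled in closed form over the single variance
ratio θ = σ²_random/σ²_resid (bounded scalar search on log θ with a
boundary check at θ = 0). The ln–ln scale is the default because observed
stocks span five orders of magnitude; raw scale is available by flag.
R²_marginal = σ²_f/(σ²_f+σ²_r+σ²_ε) and R²_conditional =
(σ²_f+σ²_r)/(σ²_f+σ²_r+σ²_ε) with σ²_f the population variance of the
fixed-effect fitted values. A single group degenerates to OLS with a
warning. The implementation is cross-checked against statsmodels MixedLM
in the test suite. The standardized-major-axis slope
sign(r)·sd(y)/sd(x) is reported as a robustness companion.

## The synthetic generator

The generator emulates the study's data structure, with defaults chosen
once as a realistic national-scale configuration:

* 10,000 reservoirs in 6 ecoregions (a vertical tiling of a lon/lat box);
  survey fraction 3.5% with 5 draws per sampled reservoir over 1948–1978
  yields ≈ 300 sampled reservoirs and ≈ 1,500 usable surveys — the same
  order as the legacy survey programme relative to the inventory.
* ln volume ~ N(11, 2.5²) m³ and ln discharge ~ N(1.5, 1.8²) m³ s⁻¹,
  correlation 0.7, per-ecoregion volume shifts (sd 0.3), and four latent
  size-flow classes offset by 0.75 sd per axis so the classification step
  has real structure to recover.
* area_ha = 0.01 · V^0.8 · exp(N(0, 0.3)) — a power-law area–volume
  relation with plausible hypsography.
* log density = class intercept (5.0–6.2, i.e. ≈ 150–500 kg ha⁻¹)
  + α·age·exp(−age/τ) (α = 0.1, τ = 10 y: a transient post-impoundment
  "trophic upsurge" that peaks near age 10 and dissipates — the generator's
  stand-in curve family, not a claim about fitted shapes)
  + a −0.005 y⁻¹ sampling-year trend + reservoir intercept N(0, 0.4²),
  all times Gamma(shape 2) noise (CV ≈ 0.7, rotenone-survey-like
  variability). Recorded raw densities divide truth by 1.773056, so the
  correction step round-trips exactly.
* Missingness is MCAR (10% areas, 5% discharges, 2% coordinates);
  1% duplicate-dam rows and 3 flagged natural-lake rows exercise the
  cleaner. Setting gamma_shape = inf switches the multiplicative noise off
  (expectation mode) for exact-identity tests.
* One root seed spawns independent child streams per table, so enlarging
  the inventory does not perturb the survey draws.

What the generator does **not** emulate: spatial autocorrelation of
densities beyond ecoregion membership, species composition, informative
(non-MCAR) missingness, survey-method drift over decades, and the real
inventory's column-naming quirks. Passing tests therefore demonstrate that
the pipeline recovers the structure it assumes, not that the assumptions
hold for the historical data.

## Problem sizes and numerical tolerances

The test suite fits the reference recovery design (≈ 1,000 surveys on
≈ 200 reservoirs, Gamma shape 20, four latent classes, fixed seed) and a
full five-schema study at 10,000 reservoirs; both sizes were chosen so the
whole suite runs in well under five minutes on one CPU. Zero-noise
identities are asserted at 1e-5 relative (the PIRLS tolerance), closed-form
oracles at 1e-6–1e-9, and the GLM-limit check at 1e-4. Penalized solves add
a relative jitter of 1e-9 · tr(XᵀX)/p to the normal-equations diagonal for
Cholesky stability.

## Known limitations

* At high noise (Gamma shape ≈ 2) the exponentiated per-reservoir
  predictions inherit a Jensen-type upward bias through the fitted random
  intercepts, and ensemble totals can deviate from truth by tens of
  percent; at the reference design's shape 20 the class means recover
  within 10%. The calibration slope remains near 1 because the bias is
  shared between observed and predicted axes on the log scale.
* The Gaussian working-model REML criterion is an approximation; its λ
  estimates (especially for the random-effect block at high dispersion)
  can differ from a full Laplace REML.
* Schema 2/3 definitions and the within-ecoregion standardization for
  schema 5 are documented choices where the published description names the
  schemas without fully specifying them.
* The pipeline treats survey densities as whole-reservoir kg ha⁻¹.
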