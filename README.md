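# resfish

National-scale estimation of reservoir fish standing stock and secondary
production from legacy rotenone surveys and a dam inventory.

## The problem

Whole-community fish biomass was measured in hundreds of USA reservoirs
between 1948 and 1978 by cove rotenone surveys — block-netted coves poisoned
so that (nearly) every fish could be weighed, yielding densities *B* in
kg ha⁻¹. Those surveys cover a few hundred reservoirs, while a national dam
inventory lists tens of thousands. `resfish` implements the statistical
pipeline that carries the surveyed densities to every inventoried reservoir:

1. **Correction** — raw rotenone densities undercount fish; they are
   multiplied by a recovery constant *c* = 1.773056 (the mean of published
   species recovery rates).
2. **Inventory cleaning** — reservoirs listed once per dam are collapsed to
   the maximum-storage dam, natural lakes with small regulating dams are
   removed, missing surface areas are approximated from a ln(area)–ln(volume)
   regression, and reservoirs are joined to level-II ecoregion polygons.
3. **Classification** — five schemas of increasing complexity place every
   reservoir in a family: a single class; k-means (k = 2) on ln(volume+1);
   global k-means (k = 4) on ln(volume+1) × ln(discharge+1); ecoregion;
   and, per ecoregion, k-means constrained to four clusters
   (small/large × low/high discharge) on the standardized covariates.
4. **Density model** — a Gamma generalized additive mixed model with log
   link,

   log μᵢ = β₀ + α_c + f_c(ageᵢ) + g(yearᵢ) + u_r,  yᵢ ~ Gamma(μᵢ, φ),

   with a penalized smooth of reservoir age per class (factor smooth), a
   penalized smooth of sampling year, and ridge-penalized per-reservoir
   intercepts u_r. Smoothness is selected by REML; classes with fewer than
   five surveys are dropped. Predictions are standardized to a common year
   (1993) so reservoirs sampled in different decades are comparable.
5. **Scale-up** — every reservoir gets a standardized density (its own
   model prediction if surveyed, else its class mean, else the global mean),
   standing stock *S* = *B* · area (kg), and totals are summed by state,
   ecoregion, southern region (the 22 survey states) and nation. The mean
   and SE across the five schema totals is the "across calculations"
   uncertainty; production is *P* = *B*<sub>total</sub> · (P/B) with a
   literature whole-community ratio P/B = 1.30 y⁻¹ (interquartile
   0.583–1.823 y⁻¹).
6. **Validation** — independent whole-reservoir survey stocks are regressed
   on predictions (ln–ln) with the schema as a random intercept; slope ≈ 1
   and conditional pseudo-R² ≈ 1 indicate a one-to-one relationship.

Because the original survey and inventory datasets are distributed
separately, the package ships a first-class synthetic generator that
emulates their statistical structure (jointly log-normal volume/discharge
with ecoregion structure, a power-law area–volume relation, class-specific
age responses with a transient post-impoundment spike, year trends,
reservoir random intercepts, Gamma noise, and the recovery bias) together
with exact ground truth for parameter-recovery testing. The full pipeline
runs end to end on synthetic inputs; user-supplied national datasets drop
into the same paths.

## Worked example

```python
from resfish.config import PipelineConfig, SimulationConfig
from resfish.pipeline import run_pipeline

sim = SimulationConfig(seed=42, n_reservoirs=2000, n_ecoregions=4,
                       survey_fraction=0.1, surveys_per_reservoir=4)
art = run_pipeline(PipelineConfig(seed=42, simulation=sim))
report = art["report"]
print(report["ensemble"]["USA"])
print(report["validation"]["slope"], report["validation"]["r2_conditional"])
print(report["synthetic_truth_total_kg"])
```

prints

```
{'mean_kg': 810711417.6462042, 'se_kg': 43084847.501898676, 'n_schemas': 5}
0.979 0.917
858958683.4
```

meaning: across the five classification schemas the estimated national
standing stock of this 2,000-reservoir synthetic study is 0.81 B kg
(± 0.04 B SE), the generator's exact ground-truth total is 0.86 B kg
(a −5.6 % estimation error under heavy survey noise), and the mixed
calibration of 42 independent synthetic surveys against predictions has
slope 0.98 with conditional pseudo-R² 0.92 — a near one-to-one
relationship. The per-schema density-model summary is available as
`art["fits"][5].summary()`.

The same pipeline is exposed as a CLI:

```bash
resfish write-config cfg.yml
resfish simulate --config cfg.yml --out data/
resfish all --config cfg.yml --seed 42 --out results/
```

which writes per-schema stock tables, an ensemble CSV, `report.json` and a
`manifest.json` (config hash, seed, per-stage row counts) sufficient to
re-run identically.

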