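# lusa — land-use scenario assessment

`lusa` quantifies how multi-decade land-use change scenarios trade off three
national objectives for Brazil-like study systems:

* **climate change mitigation** — spatially explicit terrestrial carbon
  stocks (soil + living biomass, tier-1 accounting);
* **biodiversity preservation** — mammal species richness from stacked
  logistic species-distribution models (SDMs);
* **agro-economic development** — agricultural revenue from pastures and
  annual / perennial / semi-perennial croplands.

It is aimed at spatial ecologists and land-system scientists who work with
gridded land-use projections (fraction rasters per category and timestep,
e.g. 10 × 10 km, 2015–2050 in 5-year steps) and need a tested, reproducible
pipeline from raw scenario grids to per-pixel trade-off maps and national
trade-off ratios.  A synthetic-data module generates every required input
with known ground truth, so the whole chain runs — and is tested — without
any external download.

## The models

**Carbon.**  Per cell, carbon density (t C/ha) is the fraction-weighted sum
over land-use categories *i* of a soil and a biomass pool:

```
C = Σ_i  f_i · [ SOCref(climate, soil) · F(i, biome)  +  B(i, biome, climate) ]
```

where `SOCref` is the top-30 cm reference soil organic carbon, `F` the
stock-change factor (1 for natural vegetation), and `B` the living biomass:
`AGBref + BGBref` for forest and grassland (instantaneous mature systems),
managed defaults for pasture/croplands/plantations, zero for "other".
Dead wood and litter are set to zero.  National stocks are reported in
Gt C; a stock change ΔC over `T` years converts to an annual CO₂ flux as
`ΔC · (44/12) / T`.

**Species richness.**  Per species: presence records are thinned to one per
cell; 1000 pseudo-absences are drawn outside the expert range map; ten
predictors (four land-use fractions, slope, elevation, and four climate
variables) are pruned at |r| ≥ 0.7; the best predictor subset of a
class-balanced logistic regression is chosen by exhaustive AIC search; the
presence threshold maximises the True Skill Statistic (TSS = sensitivity +
specificity − 1); retention requires mean AUC > 0.5 and mean max-TSS > 0
under 5-fold stratified cross-validation.  Retained models are projected at
each timestep (climate and topography held constant), clipped to the expert
range, and stacked into richness maps; the biodiversity indicator is the
mean relative change of species distribution areas vs the base year.

**Revenue.**  `R_t = R_pasture + R_annual + R_perennial + R_semiperennial`,
each `R_i = P_i,t · Y_i,t · A_i,t` with prices indexed to the base year
(`P_i,t = P_i,2015 · I_i,t`), crop yields `Y = PY · M · CI` and pasture
yield `Y = PG · GI / F`.  Dominant-commodity proxies: soybean, coffee,
sugarcane, bovine carcass.

**Trade-offs.**  National deltas between the base and end year are paired
into ratios (`|Δb| per unit |Δa|`) labelled synergy / tradeoff / loss-loss;
each pixel is classified into one of seven outcome categories (synergy,
two trade-off directions, loss–loss, price-only gain/loss, no change) from
the signs of its carbon, richness and revenue deltas plus a
land-use-change flag, with magnitude maps on top.

## Worked example

```python
from lusa import ssp1_like, assess_scenario
from lusa.tradeoffs import indicators_frame

cfg = ssp1_like(grid_shape=(20, 20), seed=3, n_species=4,
                n_pseudo_absences=300)
out = assess_scenario(cfg)
print(indicators_frame(out.indicators).to_string(index=False))
print({k: round(v["ratio"], 2) for k, v in out.report["ratios"].items()})
```

prints (seed 3):

```
 scenario  year  carbon_stock_gt  mean_range_change_pct  revenue_usd
SSP1-like  2015         0.439478               0.000000 1.097795e+09
SSP1-like  2020         0.445555              -0.510348 1.045214e+09
...
SSP1-like  2050         0.481770              -7.504983 7.115931e+08
{'revenue_per_carbon': 9.13, 'revenue_per_range': 0.05,
 'carbon_per_range': 0.01, 'carbon_per_revenue': 0.11,
 'range_per_revenue': 19.43}
```

Reading: on this 20 × 20 synthetic landscape the sustainability-style
scenario (forest +23%, pasture −36%, falling prices) raises the national
carbon stock from 0.439 to 0.482 Gt while agricultural revenue falls from
1.10 to 0.71 billion USD/yr — a carbon–revenue trade-off of 9.13 billion
USD/yr per Gt of carbon gained.  `mean_range_change_pct` tracks the mean
relative change of the synthetic species' distribution areas (its sign
depends on the drawn species' habitat preferences).

The same run is available from the shell:

```bash
lusa run-all --seed 3 --outdir lusa_out           # three scenario presets
lusa tradeoffs --scenario SSP1-like --seed 3 --outdir lusa_out
```

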