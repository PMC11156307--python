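# fishcast

Climate-scenario projection of shelf-sea fishery resources: from coarse
multi-model climate layers to species abundance surfaces to bioeconomic
outcomes and their spatial summaries, exercised end-to-end on synthetic data
that emulates a Bering/Chukchi-like study system.

The package is aimed at quantitative ecologists and fisheries economists who
want a tested, fully reproducible implementation of the projection chain
used in scenario-based fisheries impact studies:

1. **Climate downscaling** — the delta method: the cross-member mean anomaly
   (future − historical) of a pseudo-GCM ensemble is computed on the coarse
   1° grid, bilinearly resampled to the 0.25° observational grid, and added
   to present-day fields, with physical clamping (sea-ice concentration to
   [0, 100] %, primary production to ≥ 0). Seasonal aggregation (winter =
   Jan–Apr, summer = Jun–Aug) and cold-pool extent (summer bottom
   temperature ≤ 2 °C) are included.
2. **Abundance modelling** — per species, a random forest and boosted
   regression trees are tuned by exhaustive grid search on cross-validated
   RMSE inside an 80 % year-stratified training split, then combined as an
   inverse-RMSE-weighted ensemble evaluated on the 20 % holdout. Surfaces
   are predicted on any environmental stack; permutation importance ranks
   the covariates.
3. **Bioeconomics** — with B the surface-integrated biomass (mt):

       MSY    = g · B · (φ+1)^(1/φ)
       MCP    = B · U_MSY
       R      = p · MCP
       c      = p · f̄ · b̄ · MSY / (g · f̄)^β
       π_MSY  = R − c · g^β
       MRP    = Σᵢ Rᵢ        MPP = Σᵢ π_MSY,ᵢ

   where g = MSY/B_MSY is the population growth rate, φ the Pella–Tomlinson
   shape parameter (0.188 for groundfish, −0.093 for crab, fixing B_MSY/K at
   0.40 and 0.35), U_MSY the exploitation rate at MSY, p the ex-vessel price
   (constant 2012 USD/mt), f̄ = F/F_MSY and b̄ = B/B_MSY at the open-access
   equilibrium, and β = 1.3 the nonlinear cost exponent. Price/cost
   sensitivity scenarios ramp linearly to +20 % in 2100.
4. **Spatial summaries** — abundance-weighted centers of gravity and their
   shift rates (km/decade, haversine on a 6371-km sphere, window-midpoint
   time base), percent changes of the fleet aggregates, mean catch potential
   in 100-km rings around ports, and fishing-ground comparisons between
   jurisdictions on the ≥ 1000-hour effort mask.
5. **Synthetic data** — a seeded generator produces every input: smooth
   latitudinal environmental gradients with an Arctic cold refuge, a
   four-member pseudo-GCM ensemble for four SSP scenarios and four 20-year
   future windows, trawl surveys with known Gaussian niche structure and
   multiplicative lognormal noise, bioeconomic reference parameters, ports,
   a two-jurisdiction EEZ split, and a gridded effort field.

## Worked example

```python
>>> import fishcast as fc
>>> fc.pella_tomlinson_bmsy_ratio(0.188)    # groundfish: B_MSY/K
0.3999817805253492
>>> fc.pella_tomlinson_bmsy_ratio(-0.093)   # crab: B_MSY/K
0.35007764354618665
```

A small end-to-end run (4 species, 2 scenarios, late-century window):

```python
from fishcast.config import PipelineConfig, SyntheticConfig
from fishcast.pipeline import run_pipeline
import pandas as pd

cfg = PipelineConfig(
    out_dir="demo", seed=42,
    synthetic=SyntheticConfig(n_species=4, n_surveys_per_year=60, seed=42),
    scenario_names=("SSP126", "SSP585"), periods=("2081-2100",),
)
run_pipeline(cfg)
print(pd.read_csv("demo/percent_changes.csv").to_string(index=False))
```

prints

```
scenario    period sensitivity variable  percent_change
  SSP126 2081-2100        base      MCP       -2.332874
  SSP126 2081-2100        base      MRP        0.621934
  SSP126 2081-2100        base      MPP      -65.072459
  SSP585 2081-2100        base      MCP      -15.302644
  SSP585 2081-2100        base      MRP       -9.532498
  SSP585 2081-2100        base      MPP     -162.752931
```

i.e. under the mild scenario the fleet's catch potential is nearly
unchanged by 2081–2100, while under the severe scenario catch declines
moderately but profit collapses — the high-value, cold-optimum species lose
the most habitat. The accompanying `cog_tracks.csv` shows every species'
center of gravity shifting poleward, faster under the severe scenario
(8–16 km/decade under SSP126 vs 20–54 km/decade under SSP585 in this run):

```
species scenario  shift_rate_km_per_decade
   sp01   SSP126                     11.59
   sp02   SSP126                      8.31
   ...
   sp01   SSP585                     33.66
   sp04   SSP585                     54.48
```

The same chain is available from the shell: `fishcast run-all --seed 42
--out demo/` (see `fishcast --help`).

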