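# Methods

This note documents the models implemented in `fishcast`, the assumptions
behind them, the defaults of every consequential parameter, and the places
where the design was genuinely open and a choice had to be made.

## Study design

The package projects the consequences of scenario climate change for a
multi-species shelf fishery in four chained stages: scenario climate layers
are downscaled onto an observational grid; per-species abundance models
trained on trawl-survey CPUE predict abundance surfaces under each
scenario/period; surfaces are integrated to biomass and pushed through a
Pella–Tomlinson bioeconomic chain; and spatial diagnostics summarise where
the abundance and its economic value move. Time is discretised into a
20-year observational present (2000–2019, midpoint 2009.5), a historical
anchor window (2000–2014) and four future windows (2021–2040, 2041–2060,
2061–2080, 2081–2100; midpoints 2030.5 … 2090.5). Scenarios carry the four
CMIP6 SSP labels.

## Delta-method downscaling

For each variable, the anomaly is the difference of cross-member means,
future minus historical, on the coarse (1°) grid. The anomaly — not the
absolute field — is resampled to the fine (0.25°) grid and added to the
present-day observation. This removes each member's mean-state bias exactly
and preserves observed fine-scale structure.

Numerical choices:

- **Resampling kernel**: bilinear between coarse cell centers, with linear
  extension of the edge gradient beyond the outermost centers so that every
  fine cell receives a finite anomaly; nearest-neighbour is available for
  categorical fields. Masked coarse cells are pre-filled from their nearest
  finite neighbour before interpolation so coastal cells are not poisoned
  by NaNs.
- **Clamping**: applied after the anomaly is added — sea-ice concentration
  to [0, 100] %, primary production to ≥ 0 — because an additive anomaly
  can leave the physical range. An additive delta with clamping was chosen
  over a multiplicative delta for the bounded variables; the multiplicative
  alternative would preserve zeros but distort the anomaly where the
  present-day field is small.
- **Identity and linearity**: a zero anomaly reproduces the present field
  bit-for-bit, and anomalies compose linearly before clamping; both are
  enforced by tests.
- **Seasons**: winter = January–April, summer = June–August; seasonal means
  are arithmetic per-cell means with partial cells averaged over available
  months and flagged via an `n_months` coordinate.
- **Cold pool**: summer bottom temperature at or below 2.0 °C by default;
  the comparator (≤ vs <) is configurable because both conventions appear
  in the literature. Areas use R·Δφ × R·Δλ·cos(φ) cell areas on a 6371-km
  sphere so area-dependent outputs are bit-reproducible.

## Abundance models

Each species is modelled twice — random forest (RF) and boosted regression
trees (BRT) — on six covariates: winter SST, winter sea-ice concentration,
winter and summer bottom temperature, summer net primary production, and
depth. CPUE is modelled on its natural scale (an optional log1p switch
exists, off by default, since multiplicative survey noise can argue either
way).

- **Split**: 80/20 train/holdout with sizes ⌊0.8n⌋/remainder, stratified by
  survey year so every year contributes at least one training row.
- **Tuning**: exhaustive grid search minimising 5-fold cross-validated RMSE
  inside the training split only (never the holdout, to avoid leakage).
  Ties break towards fewer trees, then the simpler model (smaller
  interaction depth for BRT; fewer candidate features and larger node size
  for RF), then grid order, so the argmin is deterministic. The default
  grids are compact stand-ins for a full 2700-combination search, which the
  tuner accepts and is smoke-tested against at reduced data size.
- **Ensemble**: weights w_m = (1/RMSE_m)/Σ(1/RMSE_k) from holdout RMSEs.
  This is the simplest rule that gives the more accurate member the
  strictly larger weight; degenerate cases (both RMSEs zero) fall back to
  0.5/0.5. Ensemble predictions are convex combinations, hence always
  within the members' envelope, and are floored at zero because CPUE is a
  density.
- **Importance**: permutation importance on the holdout (increase in RMSE
  when one covariate is shuffled, mean of 5 repeats), weight-averaged over
  members, negatives truncated to zero, normalised to sum to one.

## Bioeconomic chain

Biomass B (mt) integrates predicted density (kg/km²) times cell area (km²)
over a region mask, divided by 1000. Then, per species:

- MSY = g·B·(φ+1)^(1/φ), with g the population growth rate (MSY/B_MSY,
  yr⁻¹) and φ the Pella–Tomlinson shape: 0.188 for groundfish and −0.093
  for crab stocks, which pin B_MSY/K at 0.40 and 0.35 respectively via
  (φ+1)^(−1/φ). Note the ratio is strictly *increasing* in φ, with the
  logistic value 0.5 at φ = 1 and limit 1/e as φ → 0.
- **Exponent-sign switch**: the yield expression above (the `printed`
  convention) uses the positive exponent. Read literally with B as
  carrying capacity it is internally inconsistent with g = MSY/B_MSY, which
  would require the negative exponent (the B_MSY/K ratio itself). Both
  conventions circulate in the literature and differ by a factor of
  ((φ+1)^(2/φ)); we implement both behind `msy_exponent_sign`
  (`printed` default, `bmsy_consistent` alternative) and record the switch
  value in every run manifest rather than guess which was intended.
- MCP = B·U_MSY with U_MSY ∈ (0, 1] the exploitation rate at MSY;
  R = p·MCP with p the ex-vessel price in constant 2012 USD/mt.
- The cost parameter c = p·f̄·b̄·MSY/(g·f̄)^β is the unique grouping of
  those factors under which revenue equals cost (zero profit) at the
  open-access equilibrium, where catch is f̄·b̄·MSY and fishing mortality
  is f̄·g. The identity is enforced to 1e-9 relative tolerance in tests.
  β = 1.3 throughout: cost per unit of fishing mortality grows faster than
  linearly.
- π_MSY = R − c·g^β; MRP and MPP are exact species sums. Profit can be
  negative — under the `printed` MSY convention the cost term is inflated
  by the same factor as MSY, so negative π_MSY values are common in
  synthetic runs and percent changes use |present| as denominator to keep
  their sign interpretable.
- **Sensitivity scenarios**: prices and/or costs scale by
  1 + 0.2·(y − 2019)/(2100 − 2019), evaluated at the window midpoint
  (2030.5, 2050.5, 2070.5, 2090.5), reaching +20 % in 2100.

## Spatial summaries

Centers of gravity weight cell positions by density × cell area (true
biomass weighting, not raw density — the difference matters on a grid whose
cell areas shrink poleward). Shift rates divide the haversine distance
between the present and future COGs by the elapsed window midpoints in
decades; the COG of a basin can fall on land, which is reported, not
rejected. Port profiles assign marine cells to half-open 100-km rings
((k−1)·100, k·100] by haversine distance to the cell center and average
catch potential per ring within a jurisdiction; empty rings are missing,
not zero. Fishing grounds are cells with aggregated effort ≥ 1000 hours;
the full bioeconomic chain runs per jurisdiction on that mask with one
shared parameter table, and a jurisdiction with no qualifying cells is
reported as missing rather than zero.

## The synthetic study system

The generator emulates the *statistics* of a subarctic-to-Arctic shelf, not
its geography:

- A 20° × 15° box at 0.25° with an eastern land strip. Summer bottom
  temperature falls from ~7 °C in the south to ~−3 °C in the north (steep
  enough that a cold refuge exists at the poleward end), winter ice ramps
  from 0 to 100 %, primary production peaks mid-basin, and depth increases
  offshore. Smooth Gaussian random fields add spatial texture.
- Scenario forcing ramps linearly in window midpoint to its end-of-century
  magnitude: basin-mean warming 1.0/2.0/3.0/4.0 °C and ice decline
  30/50/75/90 % for SSP126/245/370/585 (NPP decline 5–20 %) — magnitudes
  chosen once as plausible for a Bering-like shelf. Warming is
  polar-damped (spatial shape 1 − 0.7t in normalised latitude, rescaled to
  preserve the basin-mean amplitude) and ice loss is weighted by 1 − t², so
  the far north keeps winter ice and stays cold — the Arctic-refuge
  structure that makes poleward tracking of cold-optimum species possible
  at all. Without it, severe warming pushes thermal niches out of the
  domain and projected centroids degenerate.
- Four pseudo-GCM members share the trend; each carries a persistent smooth
  climatology bias (shared between its historical and future fields, so it
  cancels exactly in the delta) plus a small future texture proportional to
  the trend magnitude. A zero-forcing scenario therefore reproduces the
  historical stack exactly.
- Surveys: annually repeated stations at uniformly drawn marine cells;
  every species is recorded at every station. Expected CPUE is
  max-density × a product of Gaussian kernels in summer bottom
  temperature, depth and primary production; observation noise is
  multiplicative lognormal (σ = 0.3 by default), which keeps CPUE
  non-negative and mimics the right skew of trawl data. The error
  structure is a modelling choice, not an observed one.
- Reference parameters: g ~ U(0.10, 0.50) yr⁻¹, U_MSY = g·U(0.8, 1.2)
  (the two quantities both approximate MSY/B_MSY, so they are drawn
  coherently), p ~ U(400, 3000) USD/mt, f̄ ~ U(1.1, 2.2) and
  b̄ ~ U(0.2, 0.7) (open access: effort above, biomass below MSY levels),
  β = 1.3; one species is flagged as crab. Tables round-trip through CSV.
- Geography: one southern and one northern port on the coast, a
  longitude-split two-jurisdiction EEZ, and background effort plus an
  exactly configured count of ≥ 1000-hour cells clustered at the southern
  port.

What passing tests on this system do **not** show: skill on real surveys
(no gear selectivity, no zero-inflation beyond the niche tails, no spatial
autocorrelation in the noise, no species interactions), realistic
bathymetry or coastlines, or CMIP-class model spread (the pseudo-ensemble
has a shared trend by construction).

## Problem sizes and determinism

All randomness descends from a single integer seed through named
substreams, so any config reproduces byte-identical outputs (the pipeline
manifest records SHA-256 checksums and the config hash). The test suite
runs the statistical checks at deliberately compact sizes — e.g. niche
recovery with 2 species × 2000 stations at σ = 0.1, and the
severity-monotonicity check with 5 replicate seeds × 2 cold-optimum
species on the default grid — sizes chosen to make the properties sharp
while keeping the suite quick on one CPU.

## Known limitations

- The bioeconomic chain is static: no stock dynamics between windows, no
  discounting, no price formation, no harvest-control rules; biomass is
  assumed at carrying capacity in the present window and driven only by
  environmental suitability thereafter.
- Tree ensembles cannot extrapolate beyond the training covariate range;
  projections under strong forcing partially leave that range and inherit
  plateau behaviour. This is intrinsic to the method, and is the main
  reason projected surfaces, not raw model outputs, should be interpreted
  comparatively (future vs present) rather than absolutely.
- The exponent-sign ambiguity in the yield equation (above) changes MSY,
  c and π by a species-specific constant factor; comparative statements
  (percent changes, COG shifts) are unaffected, absolute monetary levels
  are not.
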