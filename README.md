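# forest-vuln

Quantifies the **vulnerability of forests to natural disturbances** —
fires, windthrows and insect outbreaks — as the *relative biomass loss a
forest would suffer if the disturbance occurred* (not a risk: occurrence
probability and exposure are deliberately out of scope). The package
re-implements, as a tested and reusable pipeline, an analysis chain that
in its original application combined continental disturbance records with
satellite and reanalysis products; here a seeded synthetic-data generator
with known ground truth stands in for those archives, so every stage can
be verified offline against what it is supposed to recover.

## What it does

1. **Annual biomass reconstruction** (`biomass_recon`). A single-date
   biomass map `B_2010` is time-resolved with tree-cover change layers:

   `B_t = B_2010 + α · ρ_loss · TC_loss(t) − ρ_gain · TC_gain,2010 · (2010 − t)/10`

   where the densities ρ (t/ha per % cover lost/gained) are estimated on
   the change pixels and spatialized as coarse-grid medians, and the gain
   cover ramps linearly over 2000–2012 (`TC_gain,2010 = 10/12 ·
   TC_gain,2012`).
2. **Response variable** (`disturbance_loss`). Per disturbance patch,
   `BL_rel = (max B[t−n..t] − min B[t..t+m]) / max B[t−n..t]` with lags
   (1, 1) for fires/windthrows and (2, 5) for insect outbreaks; records
   with `BL_rel ≤ 5%` are discarded. Predictors (forest structure,
   climate, landscape) are footprint means, dynamic ones at the pre-event
   year.
3. **Vulnerability models** (`model_training`). `BL_rel = v(Q)`: median
   imputation, PC-space binned resampling (20 equal bins per axis on the
   first three principal components, area-weighted bin means, bins with
   < 3 records dropped) with a per-year 60/40 train/test split, Spearman
   pruning at |ρ| > 0.8 followed by backward elimination maximizing test
   R², and a 500-tree random-forest fit with a seeded hyperparameter
   search. Validation reports R², RMSE, NRMSE, PBIAS and per-bin relative
   errors.
4. **Interpretation** (`interpretation`). Zero-centred partial dependence
   curves; Friedman's H for two-way interaction strength with
   category-level averages; interaction peak amplification ΔP; per-cell
   ICE slopes ("local sensitivity") and the category share
   `Z_marg = 100 · Σ|s_i∈cat| / Σ|s_j|`.
5. **Space-time application** (`spacetime`). Models run annually over
   1979–2018 with dynamic climate and frozen (2009–2018 mean) forest and
   landscape predictors, PFT-weighted per cell, masked below 0.1 forest
   cover; ensemble standard errors; area-weighted zonal means with
   100-sample bootstrap CIs; OLS trends with two-sided Mann–Kendall
   significance; factorial one-driver-dynamic simulations attribute each
   cell's trend to its dominant climate driver; a climate-envelope mask
   bounds extrapolation.
6. **Overall vulnerability index** (`ovi`). Independent-union combination
   `OVI = 1 − Π(1 − PBL_p)` (inclusion–exclusion), contribution shares,
   conversion to absolute biomass, and the space-time integrated index
   (product of min–max-normalized current OVI and OVI trend).

`synth` generates landscapes, AR(1) climate with configurable linear
trends, and disturbance records whose losses follow a known response
function; `config`/`pipeline`/`cli` tie the stages together.

## Worked example

```python
from forest_vuln import ovi

means = {"fire": 0.256, "windthrow": 0.302, "insect": 0.199}
combined = ovi.combine(list(means.values()))
shares = ovi.contributions(means)
print(f"combined vulnerability: {100 * combined:.1f}%")
for name, pct in shares.items():
    print(f"  {name:10s} {pct:4.1f}%")
```

prints

```
combined vulnerability: 58.4%
  fire       33.8%
  windthrow  39.9%
  insect     26.3%
```

i.e. forests exposed to all three disturbances stand to lose about 58%
of biomass under independence, with windthrows the largest contributor.

An end-to-end synthetic run (32×32 grid, 40 climate years, 1500 patches,
about four minutes on one CPU):

```bash
forest-vuln run --out runs/demo
```

writes the landscape/climate/truth inputs, the reconstructed and
disturbed biomass stacks, the loss-record table, fitted model bundles
with validation reports, interpretation tables (PDP curves, pairwise H,
category means), annual vulnerability and trend grids per disturbance,
and `ovi.nc` + `ovi_summary.json` with the combined index, contribution
shares and bootstrap CIs.

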