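# ipsexp

Assessment of invasive-plant expansion potential in terrestrial and
freshwater ecoregions under climate-change scenarios, as a tested,
self-contained pipeline:

1. **synthgen** — synthetic worlds with known ground truth: spatially
   autocorrelated bioclimatic fields (Bio1–Bio15 subset), additive warming
   scenarios (RCP4.5/RCP8.5, optional GCM tags), contiguous ecoregions with
   biome/realm metadata, and species whose occupancy is an analytic Gaussian
   niche, sampled into occurrence tables with injectable contamination.
2. **occ_qc** — occurrence cleaning (bad names, invalid coordinates,
   0°/0° records, lon == lat, per-species cell duplicates at grid
   resolution) and the minimum-record species filter (default: more than 100
   records).
3. **climate** — Pearson collinearity screening (|r| ≤ 0.85, greedy
   elimination), per-pixel multi-GCM ensemble means, and point extraction.
4. **sdm** — presence-background maximum-entropy models: hinge features with
   quantile knots, L1-penalised Gibbs-density fitting (β = 1.5 default),
   bias-aware background sampling (≤ 10,000 points), raw / cumulative /
   logistic outputs, 10-fold cross-validation with fold-averaged maps.
5. **evaluation** — rank-based AUC, six named presence thresholds
   (fixed cumulative 5/10, equal training sens/spec, max training and test
   sens+spec, entropy-equating), training omission rates, and the retention
   rule (mean AUC > 0.7 AND mean omission < 0.017).
6. **expansion** — per-pixel multi-species suitability sums, future-minus-
   current change maps, per-ecoregion zonal potentials with the strict > 0
   inclusion rule, biome/growth-form rollups, and the cross-RCP regression.
7. **climate_features** — jackknife (leave-one-variable-out) importance,
   top-variable selection, per-ecoregion variable-change means, per-biome
   OLS regressions of potential on climate change, and per-biome mean/SD
   change summaries.
8. **pipeline / CLI** — one-config orchestration with a deterministic
   manifest (seeds, per-stage counts, SHA-256 checksums).

Everything runs on plain text artifacts: rasters are ESRI ASCII grids
(`.asc`) with JSON sidecars, tables are CSV, models are JSON.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (exact brute-force
oracle equivalence, QC exactness, SDM niche recovery, evaluation sanity,
multi-seed directional and driver recovery, regression correctness).

## CLI

```sh
# full pipeline from a YAML config (see ipsexp.pipeline.RunConfig for keys)
ipsexp run --config run.yaml --out out/

# built-in fast demo world (6 species, 40x60 grid)
ipsexp run --demo --seed 0 --out out/

# occurrence QC only
ipsexp qc --in occ.csv --grid grid.yaml --min-records 100 \
    --out clean.csv --report qc.csv

# one species' cross-validated model
ipsexp sdm-fit --species sp001 --occ clean.csv --stack climate/current \
    --beta 1.5 --k 10 --background 10000 --seed 0 --out models/
```

`RunConfig` defaults follow the study settings (β = 1.5, k = 10 folds,
10,000 background points, AUC > 0.7, omission < 0.017, |r| ≤ 0.85); the
demo overrides sizes (and the omission bound, which is not attainable when
presences cover a sizeable share of a small demo grid).

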