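# File formats

All interchange formats are plain delimited text (CSV) or Newick.

## Trees

Strict Newick with branch lengths on every non-root edge; multiple trees
(an ensemble) are concatenated `;`-terminated strings in one file. Writing
is canonical: children are ordered by the smallest tip label in their
subtree, so a file round-trips byte-identically.

## Trait table (`traits.csv`)

One row per species, indexed by the species name used as the tree tip
label. Standard columns:

| column | meaning |
|---|---|
| `log_body` | natural log body size |
| `log_brain` | natural log brain volume |
| `breeding_latitude` | degrees, centroid of the breeding range |
| `migratory_status` | `resident` or `migrant` |
| `migratory_distance_km` | great-circle breeding-wintering distance |
| `log_migratory_distance` | log(km + 1) |

## Gridded series (`raster.csv`)

One record per (cell, year, period):

```
cell,lat,lon,year,period,evi,snow
0,-65.0,0.0,0,0,0.31,0
```

`period` runs 0..22 (23 sixteen-day composites per year); `snow` is 0/1.
The index must be complete — every (cell, year, period) combination
present — which is checked at ingest.

## Range masks (`masks.csv`)

One record per (species, season, cell): `species,season,cell` with
`season` in `resident` / `breeding` / `wintering`. Cells refer to the
raster's `cell` ids.

## Regime histories (`map_*.csv`)

A painted tree is stored as a flat segment table against a given tree:

```
node,state,t_start,t_end
0,resident_low,0.0,0.31
0,resident_medium,0.31,0.55
```

`node` uses the package's canonical node numbering (tips `0..n-1` in tip
label order, root last); times are branch-local, starting at the parent
node. Segments tile each branch and states are continuous across nodes;
`RegimeHistory.validate()` checks both.

## Environmental metrics (`env_metrics.csv`)

One row per species: `mean_evi`, `cv_within_year`, `cv_among_years`,
`snow_weeks`, `log_snow`, `breeding_latitude`, `breeding_longitude`,
`migratory_status`, `migratory_distance_km`, `log_migratory_distance`,
`evi_summer`, `evi_winter`.

## Run configuration (YAML)

```yaml
seed: 11                # mandatory
synthetic:              # either this block ...
  n_species: 200
  regime_rate: 0.4
# trees_path: trees.nwk # ... or input paths (with traits_path)
# traits_path: traits.csv
# raster_path: raster.csv
# masks_path: masks.csv
thresholds:
  lat_low: 23.5
  lat_high: 50.0
  distance_split_km: 2000.0
n_maps_per_tree: 10
n_ou_maps: 20
```
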