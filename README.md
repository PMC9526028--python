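# ecofilter

A tested, reusable pipeline for the three-criterion test of trait-based
environmental filtering in site-by-species community data, built for
communities sampled along urbanization gradients (e.g. trap-nested bee and
wasp assemblages across urban green spaces).

Environmental filtering is claimed only when **all three** criteria are met:

1. **Trait clustering** — per-site standardized effect sizes (ses.MFD) of
   the abundance-weighted mean pairwise functional distance, computed from a
   mixed-variable Gower trait distance matrix and a frequency-preserving
   null model (each species' abundances shuffled across sites).
2. **Clustering tracks the gradient** — OLS of ses.MFD on percent open
   green cover, percent impervious surface, and green-space type, with
   estimated-marginal-mean pairwise contrasts (Tukey-adjusted), a
   collinearity screen, and Moran's I residual diagnostics.
3. **Traits covary with the environment** — RLQ coupled ordination
   (correspondence analysis of the abundance table, weighted PCA of the
   environment table, Hill–Smith ordination of the mixed trait table) with
   the sequential permutation test: species-permutation (model 2) and
   site-permutation (model 4) components combined by their maximum p.

A synthetic-data module generates full studies (collinear land-cover
gradients, mixed traits, sparse Poisson communities) with a tunable
filtering strength, so every stage has known ground truth. A simplified
landscape module extracts land-cover proportions in circular buffers from a
plain-text class raster, excluding water from the denominator.

## CLI

```bash
# write a synthetic study (community.csv, traits.csv, sites.csv)
ecofilter simulate --n-sites 192 --n-species 46 --beta-f 20 --seed 1 --outdir study/

# criterion I: per-site ses.MFD
ecofilter criterion1 --community study/community.csv --traits study/traits.csv \
    --n-null 4999 --seed 1 --out ses.csv

# criterion II: regression + EMM contrasts + Moran diagnostics
ecofilter criterion2 --ses ses.csv --sites study/sites.csv --scale 250 --out c2.json

# criterion III: RLQ + sequential permutation test
ecofilter criterion3 --community study/community.csv --traits study/traits.csv \
    --sites study/sites.csv --n-perm 49999 --seed 1 --out c3.json

# everything end to end from a YAML config
ecofilter all --config run.yaml
```

A minimal `run.yaml`:

```yaml
simulate: {n_sites: 192, n_species: 46, seed: 1, filtering_strength: 0.0}
n_null: 4999
n_perm: 9999
seed: 1
outdir: out/
```

## Layout

```
src/ecofilter/
  data_model.py    # schemas, CSV I/O, year pooling, study filters
  gower.py         # mixed-variable Gower distances
  null_diversity.py# MFD, frequency null, ses.MFD, classification
  regression.py    # OLS, EMM contrasts, Moran's I, collinearity screen
  rlq.py           # CA, weighted PCA, Hill–Smith, RLQ, sequential tests
  landscape.py     # buffer land-cover extraction from class rasters
  synthetic.py     # ground-truth study simulator
  pipeline.py      # run_all / report rendering
  cli.py           # `ecofilter` command group
```
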