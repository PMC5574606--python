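# File schemas

All tables are UTF-8 delimited text with a header row, "." decimal
separator, comma delimiter by default (tab accepted via the dialect /
`delimiter` options).

## Consumer isotope table

Required columns (extra columns are ignored):

| column | type | meaning |
|---|---|---|
| `taxon` | str | taxon label |
| `site` | str | site label (e.g. NOW, LS) |
| `guild` | str | one of `FF/SDF, FF, P/S, SSDF, SDF, unknown`; unknown strings map to `unknown` with a warning |
| `layer` | str | `0-5 cm`, `5-10 cm` or `pooled` |
| `d13c` | float | δ¹³C vs VPDB, ‰ |
| `d15n` | float | δ¹⁵N vs air N₂, ‰ |
| `n_pooled` | int ≥ 1 | individuals homogenised into the sample |
| `preserved_formalin` | bool | whether the +1‰ δ¹³C correction applies |

## Sources / TEF table

Columns `name, d13c_mean, d13c_sd, d15n_mean, d15n_sd`; the reserved
name `TEF` carries the per-trophic-level enrichment instead of a source.

## Baseline table

Columns `site, d15n_sediment` (required) and `d15n_sd, d13c_sediment,
d13c_sd, n` (optional).

## Core table

One row per core × layer × taxon: `core_id, site, layer, taxon, guild,
count, c_biomass_mg, n_biomass_mg, area_m2, fragment_flag`. Fragment
rows (`fragment_flag` true) count toward biomass but not density.

## Analysis config (YAML)

Keys: `isotopes, baselines, out_dir, seed` (required); `sources, cores,
group_by, enrichment_per_level, d13c_offset, d15n_offset, chains,
iterations, burn_in, thin, delimiter, verbosity` (optional). Unknown
keys are rejected.
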