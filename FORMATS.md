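# File formats

All tables are CSV with unit-bearing column names; configuration files are
YAML (JSON also accepted for parameter files). Units follow the package
convention: concentrations molar (unless the column name says otherwise),
surface densities per µm², time seconds.

## Condition table

One row per experimental scenario.

| column | type | meaning |
|---|---|---|
| `condition_id` | str | unique identifier, links to the count table |
| `variant` | str | IgG subclass: `IgG1`, `IgG3` or `IgG4` |
| `mutant` | str | `WT` or `E430G` |
| `c_bulk_nM` | float | bulk IgG concentration in nM |
| `dnp_fraction` | float | DNP-lipid mole fraction (e.g. 0.05 for 5%) |
| `t_incubation_s` | float | incubation duration in seconds |
| `spa_conc_uM` | float | SpA B-domain concentration in µM (0 = absent) |

## Oligomer count table

One row per condition; integer particle counts per oligomer size.

| column | type | meaning |
|---|---|---|
| `condition_id` | str | matches the condition table |
| `size_1` … `size_6` | int | particles observed per oligomer size |
| `area_um2` | float | *(optional)* scanned membrane area; required by the `poisson` fit objective, written by `oligokin synth --noise poisson` |

## Distribution output (`simulate`)

| column | meaning |
|---|---|
| `condition_id` | scenario identifier |
| `frac_size_1` … `frac_size_6` | fractional abundances (sum to 1) |
| `per_um2_size_1` … `per_um2_size_6` | absolute abundances per µm² |
| `total_igg_per_um2` | Σ size × abundance |

With `--timecourse`, a long-format `timecourse.csv` holds the full state
vector (`y1`, `y1b`, `y2b` … `y11b`, `yIgG_surf` [M], `yepi` [µm⁻²]) versus
`t_s` per condition.

## Rupture-event table (`smfs-fit`)

One row per rupture event: `loading_rate_pN_s`, `force_pN`. Optional
encounter table for the on-rate fit: `t_s`, `bound` (0/1 per curve).

## Biosensor trace table (`gci-fit`)

Long format, one row per sample: `time_s`, `response`, `conc_M`, `phase`
(`association` or `dissociation`). Rows are grouped into traces by
`conc_M`; the association/dissociation boundary must be a sampled time.

## Parameter file (YAML/JSON)

Keys mirror `RateParameters`: scalars `k1b`, `k2`, `k_minus2`, `k3`, `k4`,
`kT`, `e430g_factor` and per-surface maps `alpha_prefactors`,
`kon_fab_by_surface`, `koff_fab_by_surface` keyed by DNP mole fraction,
plus `spa: {kC, k_minusC}`. Unknown keys are rejected. See
`examples/params_igg1.yaml`.

## Fit specification (YAML)

`free` (name → initial value; dotted names address per-surface entries,
e.g. `kon_fab.0.025`), optional `bounds` (name → [lo, hi]), `kind`
(`ls` | `multinomial` | `poisson`), `n_starts`, `seed`, and `profile`
(list of parameter names to profile after the fit). See
`examples/fitspec_example.yaml`.

## C1 configuration (YAML)

`kon_c1` / `koff_c1`: maps from activating oligomer size (4, 5, 6) to 1:1
binding rate constants; `c1_conc`: molar C1 concentration. See
`examples/c1_example.yaml` (synthetic placeholder values).
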