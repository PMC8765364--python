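# mangrove-nbudget

Nitrogen budgets for peri-urban mangrove estuaries: per-core nitrogen
storage and accumulation with bootstrap uncertainty, estuary-wide stochastic
spatial upscaling, substance-flow accounting of human food nitrogen,
porewater nutrient stoichiometry, and stable-isotope depth-profile models —
driven either by your own dated sediment-core tables or by a built-in
synthetic estuary generator with known ground truth.

## Who this is for

Coastal biogeochemists and wetland managers who have radiometrically dated
mangrove soil cores (depth-sliced %N, %C, dry bulk density, accretion
rates) and want defensible, reproducible estimates of how much nitrogen the
soils hold, how fast it accumulates, whether sites or time periods differ,
and how those natural fluxes compare with the human food-nitrogen flows of
the surrounding watershed.

## The core quantities

For a dated slice of thickness *h* (cm), dry bulk density *ρ* (g cm⁻³),
and N mass fraction *f*:

- **N stock** (Mg ha⁻¹): `ρ · h · f · 100`, summed over the slices
  deposited within a time window (recent 1970–2016, historic 1930–1970 by
  default).
- **N accumulation rate** (g m⁻² y⁻¹): `SAR · ρ · f · 1000`, with SAR the
  sediment accretion rate in mm y⁻¹ (100 g m⁻² y⁻¹ = 1 Mg ha⁻¹ y⁻¹).
- **Uncertainty**: percentile bootstrap — 1,000 with-replacement resamples
  per core and period; derived quantities pair a random SAR, ρ, and f draw
  per replicate (not tied to a common depth); site bounds pool both cores'
  replicates (2,000 values); two estimates differ when their 2.5th–97.5th
  percentile intervals do not overlap.
- **Estuary totals**: site values are drawn from right-skewed (two-piece
  normal) distributions with the cores' means and standard deviations,
  interpolated onto a mangrove-mask grid by inverse distance weighting
  (`w ∝ d⁻²`), summed, and repeated 100 times; reported as mean ± SE of the
  iteration sums, plus areal means (total / mangrove area).
- **Food N flow**: population × per-capita food demand × 2.45% N, split
  into municipal solid waste (38%, mostly landfilled), ocean-bound treated
  wastewater (44%), and septic systems (18%), with areal rates over a 500 m
  site buffer or the watershed area.

## Worked example

The watershed-scale food-nitrogen budget (769,000 people, 41,572 ha):

```python
from mangrove_nbudget import flow_model as fm

fb = fm.flow_budget("watershed", 769_000, fm.WATERSHED_AREA_HA)
print(f"food N input : {fb.food_n:8.1f} Mg/y")
print(f"  landfill   : {fb.landfill:8.1f} Mg/y")
print(f"  compost    : {fb.compost:8.1f} Mg/y")
print(f"  ocean      : {fb.ocean:8.1f} Mg/y")
print(f"  septic     : {fb.septic:8.1f} Mg/y")
print(f"areal food rate        : {fb.areal_food_rate:.3f} Mg/ha/y")
print(f"wastewater export rate : {fb.wastewater_export_rate:.3f} Mg/ha/y")
```

```
food N input :   5390.3 Mg/y
  landfill   :   1926.2 Mg/y
  compost    :    122.1 Mg/y
  ocean      :   2371.7 Mg/y
  septic     :    970.2 Mg/y
areal food rate        : 0.130 Mg/ha/y
wastewater export rate : 0.080 Mg/ha/y
```

About 5,390 Mg of nitrogen enters the watershed in food every year; 0.08
Mg ha⁻¹ y⁻¹ of it leaves as wastewater — roughly half the recent soil N
accumulation rate of the estuary's mangroves, which is the comparison the
budget is built to make.

The full pipeline runs from the shell. Simulate a five-site estuary and
analyse it end to end:

```sh
mangrove-nbudget simulate --seed 17 --outdir demo/
mangrove-nbudget run demo/ --outdir demo/out --seed 17
```

`demo/out/` then holds per-core budgets (`budget.csv`), bootstrap
estimates and overlap-based significance calls (`estimates.csv`,
`comparisons.csv`), estuary-wide totals (`upscale.json`), food-N flows
(`flows.csv`), porewater summaries, isotope profile fits, and a manifest
that reproduces the run.

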