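# yieldgap

County-level grain **yield-gap** analysis: how far actual farm yields fall
short of what climate and soil would allow, how that gap has evolved over
decades, where it clusters in space, which factors drive its change, and
which counties offer the most headroom for yield improvement.

The package is aimed at agro-geographers and land-use analysts working with
county panels (yields, socioeconomic statistics) plus gridded climate and
land-use data. It ships a synthetic study-region generator with known ground
truth, so the entire pipeline can be exercised, tested and demonstrated
without any proprietary provincial data.

## The model

**Potential yield** is estimated per cultivated grid cell by a step-wise
revision chain in the agro-ecological-zone tradition, each step a
multiplicative correction of the previous:

    YQ = (10^5 / C) · F · Q · E        photosynthetic potential  [kg ha⁻¹]
    YT = (T / 30) · YQ                 light-temperature potential
    YW = f(w) · YT                     climatic potential
    YS = f(s) · YW                     soil potential

with `Q` the growing-season total solar radiation (kcal cm⁻²), `C` = 4.25
kcal g⁻¹ the calorific value of dry matter, `F` = 0.03 the light-energy
utilization rate, `E` = 0.4 the crop economic coefficient, `T` the
growing-season mean temperature (°C, ratio clamped to [0, 1]), and
`f(w)`, `f(s)` ∈ [0, 1] water and soil correction coefficients (`f(w)` = 1
in humid regions). The chain is monotone: `YQ ≥ YT ≥ YW ≥ YS` cell-wise.

**Gap statistics** at county level (t ha⁻¹):

    YGAP  = Y̅S − Y̅FARM           RYGAP = 100 · YGAP / Y̅S
    YGC   = YGAP(t+1) − YGAP(t)   (negative = gap closing)

**Spatial structure**: Getis–Ord Gi\* hot/cold spots of YGAP and YGC over
queen-contiguity weights, and bivariate global/local Moran's I between the
YGCs of successive periods with conditional-permutation inference.

**Determinants**: a random-forest regression of YGC on 27 climatic,
socioeconomic, land-use and investment factors; out-of-bag permutation
importances normalized to [0, 1], top-ten key factors, and per-category
contribution percentages.

**Screening**: counties with RYGAP > 30 % in the final epoch (municipal
districts excluded) are flagged, and the extra tonnage from a +5 % uplift of
their actual yields is computed.

## Worked example

```python
from yieldgap import SimulationConfig, run_pipeline

results = run_pipeline("out", SimulationConfig(seed=1), n_perm=199, n_trees=200)
summary = results["summary"]
for epoch, gap in summary["mean_ygap_by_epoch"].items():
    print(f"{epoch}: mean YGAP = {gap:.2f} t/ha")
for pair, res in results["bimoran"].items():
    print(f"bivariate Moran's I ({pair}): {res.global_i:.3f} (pseudo-p {res.pseudo_p:.3f})")
print(f"selected counties: {summary['n_selected']}")
print(f"+5% uplift adds {summary['incremental_production_tons']:,.0f} t")
```

prints

```
E1990: mean YGAP = 7.93 t/ha
E2000: mean YGAP = 5.23 t/ha
E2010: mean YGAP = 5.14 t/ha
E2018: mean YGAP = 6.13 t/ha
bivariate Moran's I (E1990-E2000|E2000-E2010): -0.145 (pseudo-p 0.015)
bivariate Moran's I (E2000-E2010|E2010-E2018): -0.028 (pseudo-p 0.490)
selected counties: 92
+5% uplift adds 672,444 t
```

The synthetic province's mean gap narrows sharply in the first decade and
partially re-widens at the end (the exploitation schedule plants exactly
this pattern); successive-period gap changes are weakly negatively
autocorrelated in space — counties that closed their gap strongly in one
period tend to sit next to counties that widened in the next; 92 of the 96
non-district counties clear the 30 % relative-gap bar, and lifting their
actual yields by 5 % would add about 0.67 Mt of grain.

The same stages are available from a shell:

```
yieldgap run --simulate --seed 1 --outdir out
yieldgap simulate|potential|gap|cluster|determinants|identify --help
```

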