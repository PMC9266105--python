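# tvdizone

Zoned drought analysis with the Temperature–Vegetation Dryness Index (TVDI)
for raster time series, built for plateau-scale studies where one global
NDVI–LST feature space is too heterogeneous to trust: the domain is first
partitioned into geomorphic zones, the dry and wet edges are fitted per
zone, and the per-zone TVDI grids are mosaicked back into a whole-domain
product.  Downstream stages classify drought grades, test pixel-wise
temporal trends, attribute variability to climate drivers, cluster zones by
their drought regime, and rank environmental factors with a random forest.
The audience is remote-sensing / ecohydrology analysts who want each of
those stages as a tested, reusable library call rather than a GIS plug-in.

## The model

Within a zone, the scatter of land-surface temperature (LST, °C) against
NDVI is triangular.  Binning NDVI at width 0.01 and fitting lines through
the per-bin LST extrema gives the envelope

```
wet edge:  LSTmin = a1 + b1·NDVI        (b1 > 0)
dry edge:  LSTmax = a2 + b2·NDVI        (b2 < 0)
```

and each pixel's dryness is its position between them:

```
TVDI = (LST − LSTmin(NDVI)) / (LSTmax(NDVI) − LSTmin(NDVI)) ∈ [0, 1]
```

Higher is drier; 10 cm soil moisture is negatively coupled to TVDI, which is
the validation handle.  Pixels with NDVI < 0.2 are excluded from edge
fitting by default (NDVI is unreliable over sparse cover).  Around this
core:

* **Grades** — extremely wet [0, 0.2], wet (0.2, 0.4], normal (0.4, 0.6],
  dry (0.6, 0.8], extremely dry (0.8, 1.0]; drought types no-drought /
  drought / severe drought at 0.6 and 0.8.
* **Trends** — closed-form least-squares slope of annual TVDI on the year
  index, slope t-test (df = n−2), six classes from sign × significance
  (p cutpoints 0.05, 0.01).
* **Climate drivers** — per pixel, partial correlations of TVDI with annual
  precipitation (temperature fixed) and temperature (precipitation fixed),
  multiple correlation with both; t-tests (df = n−3) and an F-test
  (df = 2, n−3) zone pixels into precipitation-driven / temperature-driven /
  jointly driven / other.
* **Zone clustering** — nine indicators per zone (max/min/mean/SD of annual
  TVDI, mean slope, four trend-class area fractions), agglomerative
  clustering with 1 − Pearson distance, average linkage.
* **Random forest** — mean-annual TVDI regressed on eight factors
  (precipitation, temperature, elevation, slope, aspect, distances to
  built-up land and water, land use) at a 4× analysis cell, seeded 70/30
  split, impurity-based importance, partial-dependence curves.

Because the satellite products such a study consumes are not
redistributable, the package ships a synthetic scene generator
(`tvdizone.synthetic`) that emulates the study's statistical structure with
known ground truth — true edges, latent wetness (so true TVDI =
1 − wetness), planted climate couplings and trends — giving every stage a
parameter-recovery test.  The one real dataset included is the published
9-indicator matrix for the eight geomorphological divisions of the
Qinghai–Tibet Plateau (AQM, QHB, KWKM, CEKM, QP, STR, HMLY, HDM), used by
the clustering stage.

## Worked example

```python
from tvdizone.clustering import cluster_zones, load_reference_indicators

part = cluster_zones(load_reference_indicators(), k=3)
for g, members in sorted(part.groups.items()):
    print(g, sorted(members))
```

prints

```
1 ['HDM', 'HMLY']
2 ['AQM', 'QP', 'STR']
3 ['CEKM', 'KWKM', 'QHB']
```

— the humid southern divisions, the central divisions, and the arid
north-central divisions separate cleanly at correlation distance.  An
end-to-end synthetic run:

```bash
tvdizone run-all --out results/demo --seed 1
```

or, stage by stage, the numbered scripts under `analysis/`
(`01_simulate_scene.py` … `08_validation.py`).  On the default scene
(120×120 cells, 8 zones, 2000–2019) `analysis/08_validation.py` prints

```
           n   slope  intercept      r2  p_value
zoned    893 -0.4166     0.4585  0.9700      0.0
global   893 -0.4871     0.5002  0.9309      0.0
```

the pooled regression of point soil moisture on collocated summer TVDI: the
slope is negative (drier surface ⇒ less soil moisture, ≈ −0.42 volumetric
units per TVDI unit) and the per-zone-edges product explains more variance
(R² 0.97) than a single global edge fit (0.93) on a domain whose zones have
genuinely different edges.

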