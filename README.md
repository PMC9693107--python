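# casanpp

Monthly vegetation net primary productivity (NPP) on raster grids with the
CASA light-use-efficiency model, plus a vulnerability–resilience assessment
of earthquake impact on vegetation, stratified by seismic intensity and
geohazard type. The package targets the kind of analysis done after the 2017
Ms 7.0 Jiuzhaigou earthquake: estimate NPP before, during and after the
event, and quantify how hard each intensity zone was hit and how much it
recovered on its own.

## The model

NPP (gC/m² per month) is the product of absorbed photosynthetically active
radiation and a realized light-use efficiency:

    NPP(x,t) = APAR(x,t) · E(x,t)
    APAR     = 0.5 · SOL · FPAR
    E        = TE1 · TE2 · WE · Emax

with, per pixel `x` and month `t`,

    SR   = (1 + NDVI) / (1 − NDVI)
    FPAR = min((SR − SRmin) / (SRmax − SRmin), 0.95), floored at 0
    TE1  = 0.8 + 0.02·Topt − 0.0005·Topt²
    TE2  = 1.1841 / (1 + e^{0.2(Topt−10−T)}) / (1 + e^{0.3(−Topt−10+T)})
    WE   = 0.5 + 0.5·ET/ETp        (in [0.5, 1])

`Topt` is the mean temperature of the month in which the pixel's NDVI peaks.
`SRmax` and `Emax` (gC/MJ) are per-land-cover constants for high-cold-altitude
southwest China, shipped as the default parameter table; `SRmin = 1.08`.

The earthquake assessment takes the NPP change across the quake month
(`dur-quake`: quake month minus the month before; `post-quake`: month after
minus quake month), min–max normalizes it over the whole region, bins the
normalized values into five equal classes, and forms the expected value of
the class mid-values A = (0.1, 0.3, 0.5, 0.7, 0.9) under the per-zone area
proportions B:

    S = Σ Aᵢ·Bᵢ   (vulnerability, dur-quake declines)
    R = Σ Aᵢ·Bᵢ   (resilience, post-quake gains)
    I = S·(1 − R) (impact coefficient: damage not undone by self-recovery)

## Worked example

Generate a synthetic alpine scene (a 120×120 grid of 250 m cells, months
June–September 2017, earthquake in August) with intensity-graded NDVI shocks
inside geohazard patches, run the CASA chain, and assess the impact:

```python
from casanpp import SceneRecipe, generate
from casanpp.pipeline import assess_scene
from casanpp.impact import assess_frame

scene = generate(SceneRecipe(seed=42))
report = assess_frame(assess_scene(scene))
print(report[["name", "S", "R", "I"]].round(3).to_string(index=False))
```

```
    name     S     R     I
  region 0.142 0.143 0.122
VII-VIII 0.119 0.100 0.107
 VIII-IX 0.192 0.122 0.169
     IX+ 0.255 0.265 0.187
```

The injected shocks depress NDVI by 15% / 30% / 45% in the VII–VIII, VIII–IX
and IX+ rings, and the computed vulnerability S recovers that ordering
(0.119 < 0.192 < 0.255). Resilience R is highest where the injected recovery
acts on the largest damage (IX+).

The same workflow is available from the shell:

```sh
casanpp simulate --out-dir scene/
casanpp run --scene-dir scene/ --year 2017 --month 8 --out npp-08.tif
casanpp assess --npp-before npp-07.tif --npp-quake npp-08.tif \
               --npp-after npp-09.tif --zones scene/zones.tif --out report.csv
casanpp pipeline --out-dir run/     # all of the above end to end
```

`casanpp index` computes S, R and I directly from a printed 5-bin
area-proportion table with no rasters at all.

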