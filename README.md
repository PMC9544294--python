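# oceanexposure

Exposure of marine biodiversity to extreme rates of oceanic warming.

Marine species richness is concentrated in tropical regions whose sea-surface
temperatures (SST) were comparatively stable through the last deglaciation.
This package quantifies how exposed those species-rich areas are to
*rates* of 21st-century ocean warming, by comparing future warming rates
against the most extreme centennial warming the same region experienced over
the last ~21,000 years. It is aimed at climate-change macroecologists who
want a tested, reusable implementation of the full analysis chain — from raw
gridded annual SST series to realm-level exposure summaries and
thermal-analogue redistribution distances — exercised end-to-end on a
seeded synthetic world generator that stands in for global paleoclimate,
scenario and species-distribution datasets.

## The method

1. **Extreme centuries.** Sliding 100-year windows (10-year step) over the
   area-weighted global-mean SST series get an OLS warming rate
   (°C/century). Windows at or above a threshold — the 95th percentile of a
   pre-industrial control run's natural variability (0.18 °C/century for the
   real-world control ensemble), or a value you supply — are *extreme*.
2. **Pattern-scaled SNR.** Within each extreme window, every grid cell gets
   an OLS trend *b* (°C/yr) and a variability σ (SD of residuals from the
   trend, n−2 dof). Averaging over an era's extreme windows and dividing the
   trend by the era-mean global rate Ḡ (pattern scaling, so eras with
   different forcing are comparable) gives the exposure metric

       SNR = | b / (Ḡ/100) | / σ ,

   and δSNR = SNR_future − SNR_past: positive values mark post-industrial
   warming rates beyond anything in the deglacial record.
3. **Richness hotspots.** Species occurrence probabilities (0.5°-style fine
   grid) are thresholded at τ = 0.4, summed to richness, block-averaged to
   the climate grid; cells at or above the 95th percentile are hotspots.
   Sensitivity to τ is measured with Warren's I = 1 − ½Σ(√p−√q)².
4. **Realm comparisons.** Within each biogeographic realm (≥3 cells), past
   and future SNR samples are compared with a two-sample Kolmogorov–Smirnov
   test (Benjamini–Yekutieli adjusted across realms) and with the
   proportional overlap ∫min(f̂_past, f̂_future) of Gaussian kernel densities
   (low overlap = high exposure). Hotspot *exceedance* is the percentage of
   a realm's hotspot cells whose future SNR strictly exceeds the realm's
   95th percentile of past SNR, reported per realm, globally, and as a
   realm-area-weighted mean, with a 90th–100th-percentile sensitivity sweep.
5. **Thermal analogues.** The deglacial series is delta-bias-corrected onto
   the scenario series (per-cell mean difference over 1851–1950). A cell j
   is a thermal analogue of hotspot cell i if j's maximum annual SST in
   2080–2100 stays at or below i's maximum during the Holocene thermal
   maximum (~9000–5000 yr BP). The nearest analogue minimises *nautical
   distance* — Dijkstra shortest paths through an 8-connected graph of ocean
   cells with haversine edge lengths (land blocks movement; no
   corner-cutting between diagonal land pairs; longitude wraps at the
   dateline) — optionally restricted to near-shore EEZ cells. Distance over
   the 2020–2090 horizon (70 yr) gives the required redistribution rate in
   km/yr (e.g. 1625 km → ≈23 km/yr, 2190 km → ≈31 km/yr).

## Worked example

The reduced demo world (10° grid, 2,000-year past with five injected
0.5 °C/century warming events, two future scenarios at 0.8 and 1.6
°C/century) runs the whole pipeline in a few seconds:

```python
from oceanexposure import PipelineConfig, run_pipeline
import json, pathlib

run_pipeline(PipelineConfig.demo(master_seed=0), "out")
report = json.loads(pathlib.Path("out/report.json").read_text())
print(report["threshold_degc_per_century"])          # 0.00334
print(report["realm_overlap_by_band"]["future_scenario_a"])
# {'high': 0.546, 'tropical_mid': 0.060}
print(report["analogues"]["future_scenario_a_all"]["mean_distance_km"])   # 2224
print(report["analogues"]["future_scenario_a_eez"]["mean_distance_km"])   # 5424
print(report["analogues"]["future_scenario_a_all"]["mean_rate_km_per_yr"])  # 31.8
```

Reading the numbers: the calibrated extreme threshold is tiny
(0.0033 °C/century) because the demo control run's global-mean noise nearly
averages out across cells, so all five injected events are detected with a
huge margin. Tropical and mid-latitude realms retain only ~6% overlap
between past and future warming-rate densities versus ~55% at high
latitudes — the synthetic world's tropically amplified future warming makes
the most species-rich realms the most exposed. Hotspot communities would
need to shift ~2,200 km (≈32 km/yr over 2020–2090) to track their Holocene
upper temperatures, and ~5,400 km if constrained to near-shore EEZ
corridors.

The same run is available from the shell:

```sh
oceanexposure --seed 0 --out out run
```

## Layout

- `src/oceanexposure/grids.py` — grid geometry, area weighting, aggregation, NetCDF I/O
- `src/oceanexposure/synthetic.py` — the synthetic world generator and its ground truth
- `src/oceanexposure/extremes.py` — extreme-window detection and pattern-scaled SNR
- `src/oceanexposure/hotspots.py` — richness, hotspot delineation, Warren's I
- `src/oceanexposure/realms.py` — KS/BY tests, KDE overlap, exceedance accounting
- `src/oceanexposure/analogues.py` — bias correction, sea graph, analogue search, Hovmöller
- `src/oceanexposure/pipeline.py`, `cli.py` — orchestration, manifests, CLI
- `docs/methods.md` — model assumptions, parameter choices and limitations
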