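# Methods

This note records the models, parameter choices and numerical conventions
behind `oceanexposure`, and what the synthetic test world does and does not
establish about behaviour on real data.

## Grids and statistics

All fields live on regular cell-centred lat/lon grids (latitude ascending,
longitude in [−180, 180)). Area weights are cos(latitude) by default; exact
spherical band areas are available (`area_weighting="band"`) and every
statistic is invariant to the weights' overall scale. Land cells carry NaN
and are excluded from every statistic. Aggregation from the species grid to
the climate grid is a block mean over non-missing children, missing only
when every child is missing.

Per-window statistics use closed-form OLS: slope b = Σ(x−x̄)(y−ȳ)/Σ(x−x̄)²,
residual SD with n−2 degrees of freedom. A "century" is a 100-year window
stepped every 10 years, both endpoints inclusive; windows are assigned to
the pre- or post-industrial era by their start year (boundary 1850).
Overlapping extreme windows are all used, unmerged, and averaged with equal
weight.

The exposure metric pattern-scales *before* forming the signal-to-noise
ratio: SNR = |b/(Ḡ/100)|/σ with Ḡ the era mean of the extreme windows'
global rates. Scaling first makes past and future SNR comparable per degree
of global warming, which is the point of comparing eras with different
forcing; it divides both eras by their own realized global trend, so the
area-weighted mean scaled trend is 1 in every era and δSNR measures purely
spatial redistribution of warming rates relative to local noise.
Degenerate cells with variability ≤ 1e-12 °C (noise-free inputs leave
O(1e-16) rounding residue rather than exact zeros) get missing SNR and a
logged warning instead of ±∞. The unscaled ratio |b|/σ is kept alongside
(`snr_raw`).

Thresholds are inclusive throughout (rate ≥ threshold is extreme;
probability ≥ τ is presence; richness ≥ percentile is a hotspot), matching
the convention used for every other cut-off; the single exception is
hotspot *exceedance*, where "exceeds the realm's past 95th percentile" is
read strictly (future SNR > threshold), so ties at the threshold do not
count as unprecedented. Percentiles everywhere use linear interpolation
between order statistics.

## Kernel-density overlap

Realm overlap uses Gaussian KDEs with Silverman's bandwidth
(σ̂·(3n/4)^(−1/5), ddof=1), evaluated on a shared 512-point grid padded by
three bandwidths beyond the pooled sample range; the overlap coefficient is
the trapezoid integral of the pointwise minimum, so it lies in [0, 1] up to
O(10⁻³) quadrature error. A zero-variance sample falls back to a fixed tiny
bandwidth (10⁻⁶·|mean| + 10⁻⁹) with a warning. These estimator choices are
fixed and recorded here because the overlap value is estimator-dependent.
KS tests use the asymptotic two-sample p-value (realm samples are moderate
to large), adjusted across realms with Benjamini–Yekutieli, which is valid
under the spatial dependence between realm samples.

## Sea distances and analogues

The "nautical distance" graph connects ocean cells to their 8 neighbours
with haversine edge lengths (R = 6371 km), wrapping longitude at the
dateline but never across the poles. A diagonal edge requires at least one
of the two shared orthogonal neighbours to be ocean, so paths cannot cut
corners between diagonally touching land cells. Grid paths overestimate
true coastal geodesics by construction (they are sums of cell-centre
chords); all conclusions rest on relative distances, where this bias is
shared. "Upper temperature" is interpreted as the per-cell maximum of
annual means inside the stated window, applied identically to the Holocene
thermal maximum (9000–5000 yr BP) and future (2080–2100) sides; the
analogue condition is one-sided (future upper ≤ focal HTM upper, with an
optional tolerance in °C). Nearest-analogue ties break deterministically by
(distance, lower future upper temperature, row-major cell index). Cells
with no reachable qualifying analogue are reported as such, and summary
means are taken over cells that have one. Redistribution rates divide the
distance by the 70-year 2020–2090 horizon.

## The synthetic world

The generator produces the statistical structure the analysis assumes, at
a scale where the full pipeline runs in seconds, with a ground-truth record
for parameter-recovery tests. Reduced demo conditions (used by the tests
and the acceptance script; `WorldConfig.demo()`):

| parameter | value | why |
|---|---|---|
| grid | 10°, species on 2° | keeps Dijkstra and KDE work trivial while leaving ~600 ocean cells |
| past era | 2,000 yr ending 1950 | long enough for 5 well-separated events and a 100-yr bias-correction overlap with the scenario era (1851–1950) |
| control era | 1,000 yr, zero trend | 91 windows, comfortably above the ≥20 needed for calibration |
| events | 5 × (100 yr, 0.5 °C) | abrupt centennial warming episodes with rates ~150× the calibrated threshold |
| relaxation | 30% of each ΔT over the following gap | deglacial warming was punctuated by cooling reversals (e.g. the Younger Dryas); consequently off-event centuries have slightly *negative* global rates, so detection separates events from quiet centuries rather than from a coin-flip tail of the control distribution |
| future trends | 0.8 / 1.6 °C per century | moderate and high forcing scenarios with the ~2× ratio of the standard scenario pair |
| climatology | −1 + 29·cos²(lat) °C | smooth, monotone toward the equator |
| past amplification | 1 + 0.8·sin²(lat) | deglacial forced response amplified toward high latitudes |
| future amplification | past + tropical Gaussian bump (0.8, width 20°) − mid-latitude dip (centre 45°, width 12°), dip amplitude solved so the ocean-mean difference is zero | the future pattern is *relatively* stronger in the tropics; balancing the means makes the two eras' pattern-scaled fields directly comparable and places the compensating deficit at mid latitudes rather than at the poles |
| noise | per-cell AR(1), φ = 0.3, stationary SD 0.08 + 0.08·sin²(lat) °C | annual SST variability is smaller in the tropics; independence across cells makes the global-mean noise nearly vanish, as in reality where forced global signals dominate global means |
| species | 400 Gaussian ranges, peak latitudes Laplace(0, 15°), peak probability U(0.5, 0.95), 5% flagged data-scarce and discarded | tropical-peaked richness with clustered hotspots; the data-scarce flag emulates discarding ranges fitted from too few records |
| realms | 12 = six 30° latitude bands × two longitude sectors | contiguous regions split at the land barriers, giving both tropical/mid and high-latitude realms |
| land | two meridional continents (two are needed to split a cylindrical ocean), southern strait open below 60°S unless closed | a closed barrier produces genuinely unreachable basins for no-analogue tests; EEZ = ocean cells within one cell of land |

Design notes. With mean-balanced amplification fields, the expected change
in pattern-scaled SNR is (amp_future − amp_past)/σ: ≈ +13 near the equator
(bump over small σ), ≈ −3 at the mid-latitude dip, ≈ 0 poleward of ~65°.
Tropical and mid-latitude realm distributions therefore separate sharply
in both directions while high-latitude ones nearly coincide — the
directional pattern the analysis is designed to detect (most-speciose
realms most exposed). Had the tropical bump been balanced by a uniform or
polar deficit, pattern scaling (which renormalises each era by its own
global mean) would have pushed high-latitude future SNR well below its
past and made *every* realm look exposed, erasing the contrast.

What the demo world does **not** emulate: ocean dynamics and spatially
correlated variability (ENSO, AMOC), sea ice, marine heatwaves,
sub-annual variability, realistic coastline geometry or realm shapes, and
species-specific dispersal. Passing tests therefore demonstrate the
correctness and internal consistency of the statistical machinery and its
directional behaviour under the assumed structure — not the magnitude of
exposure numbers on real datasets, which depend on the real forcing
patterns and variability fields.

One structural caveat surfaced by the sensitivity analysis: with an
inclusive presence rule, τ = 0 marks every species present in every cell
(p ≥ 0 always holds), so the τ = 0 richness map is uniform and its Warren's
I against any tropically concentrated map is ~0.7 regardless of the
generator. Overlap between maps built at any two *positive* thresholds in
0.1–0.5 exceeds 0.93 on the demo generator, mirroring the near-identity of
real richness maps across this range.

## Problem sizes

The test suite and the acceptance script run everything at the demo scale
above (a full pipeline run takes ~3 s). Parameter-recovery checks use a
6° all-ocean grid (1,000+ replicate cells, 150-year past); the
sea-distance oracle sweeps 20 random land layouts on a 15-row (12°) grid
against a brute-force all-pairs shortest-path reference; null-calibration
checks use 100 replicates of 6–8 realms with 50–60 cells each. Full-scale
configurations (2.5°, 21,000-year past) are supported by the same code
paths via `WorldConfig()` defaults.
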