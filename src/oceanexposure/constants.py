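"""Analysis constants shared between stage defaults and the pipeline config.

Each constant is defined exactly once here; stage functions reference these
names for their defaults and the pipeline configuration validates against the
same values. Units are given per name.
"""

#: Global warming-rate threshold separating "extreme" centuries (°C/century).
#: The 95th percentile of pre-industrial control-run natural variability;
#: users may recalibrate from their own control run instead.
EXTREME_RATE_THRESHOLD = 0.18

#: Percentile of control-run rates used when recalibrating the threshold.
CONTROL_PERCENTILE = 95.0

#: Length of a "century" window (years) and the stride between window starts.
WINDOW_YEARS = 100
STEP_YEARS = 10

#: Calendar year splitting the pre-industrial era from the post-industrial
#: one; windows are assigned to an era by their start year.
ERA_BOUNDARY_YEAR = 1850

#: Occurrence-probability threshold turning per-species probabilities into
#: presence/absence before summing richness.
OCCURRENCE_TAU = 0.4

#: Sweep of occurrence thresholds for the richness sensitivity analysis.
SENSITIVITY_TAUS = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)

#: Richness percentile at or above which a cell is a biodiversity hotspot,
#: and the past-SNR percentile defining realm-level exceedance thresholds.
HOTSPOT_PERCENTILE = 95.0
EXCEEDANCE_PERCENTILE = 95.0

#: Sweep of exceedance percentiles for the sensitivity analysis (inclusive).
EXCEEDANCE_SWEEP = (90, 100)

#: Minimum number of ocean grid cells for a realm to enter the analysis.
REALM_MIN_CELLS = 3

#: Absolute centroid latitude (degrees) at or below which a realm counts as
#: tropical/mid-latitude rather than high-latitude.
TROPICAL_MID_LATITUDE = 50.0

#: Calendar-year overlap used for the delta bias correction between the
#: deglacial and the scenario SST series.
BIAS_OVERLAP = (1851, 1950)

#: Holocene-thermal-maximum window, years before present (present = 1950).
HTM_WINDOW_BP = (9000, 5000)

#: 21-year window centred on 2090 used for future upper temperatures.
FUTURE_UPPER_WINDOW = (2080, 2100)

#: Horizon (years, 2020 to 2090) converting analogue distances into
#: required redistribution rates.
REDISTRIBUTION_HORIZON_YEARS = 70

#: Mean Earth radius (km) for haversine distances.
EARTH_RADIUS_KM = 6371.0


def bp_to_ce(years_bp: float) -> float:
    """Convert years before present (present = 1950) to calendar years."""
    return 1950 - years_bp
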