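# Methods

## Model and definitions

The package treats each seafloor climate driver — potential temperature
(°C), dissolved oxygen (mol m⁻³), pH (total scale) and particulate-organic-
carbon flux to the seafloor (mgC m⁻² d⁻¹) — as an annual gridded time
series per (scenario, model). The internal time base is the calendar year:
monthly inputs are collapsed to annual means with **equal month weights**,
because "annual climate conditions" are the unit of the analysis and
Earth-System-Model calendars (360- or 365-day) make day-length weighting
ill-defined.

*Historical variability* is the per-cell sample SD (n−1 denominator) of
annual values over 1951–2000. *Hazard* is the ratio of the future-window
mean change (2041–2060 or 2081–2100, all years inclusive) to that SD.
*Harmful directions* are fixed per driver: warming is harmful as an
increase; oxygen, pH and POC flux as decreases. Beneficial-direction changes
contribute **zero** (clamped), not negative offsets, to the cumulative
negative hazard; an unclamped signed sum is available
(`cumulative_negative_hazard(..., clamp=False)`) for sensitivity analysis.

*Time of emergence* is operationalised as a one-sided exceedance of the
harmful-direction anomaly over k·σ_hist (default k = 1), with two
persistence rules: `"first"` (earliest single exceedance after 2000) and
`"sustained"` (default; earliest year from which every later year up to the
2100 horizon also exceeds — avoids single-spike emergence). The comparison
is **non-strict** (a(t) ≥ k·σ): for noise-free linear trends starting in
2001 this makes the emergence year exactly
`trend_start_year + ceil(k·σ/b)`, and for continuous noise the tie set has
probability zero, so the choice only affects idealised inputs. Both the rule
and k are recorded in output metadata. Censoring uses the sentinel
`horizon + 1` internally and renders as ">2100". Cells with σ_hist = 0 are
masked as undefined for hazard (unless the change is also zero) and emerge
at the first year of any harmful-direction change for ToE, with a logged
guard.

The all-driver ToE is the per-cell maximum of the four driver years; because
the censoring sentinel exceeds any real year, censoring propagates
automatically. Ensemble handling follows two supported paths — average the
per-model hazard *fields*, or compute ToE on the ensemble-mean annual
series — with provenance (member model list) recorded; averaging the cubes
first and then computing hazard deflates the historical SD by √n_members and
inflates hazard, which is why the hazard path averages fields.

Regional summaries (Table-1-shaped CSV) take **unweighted** min/max over
cells whose centres fall inside each region polygon; censored cells are
excluded from the minimum, counted separately, and force a ">2100" maximum.
Area weighting is available for overlap statistics but not needed for
min/max parity.

## Connectivity

Dispersal is 2-D at a fixed depth horizon (the analysis fixes dispersal
depth, e.g. 1,000 m), with no vertical migration, behaviour, or mortality.
Integration is RK4 at dt = 6 h (default) on velocities interpolated
bilinearly in space and linearly in time; geographic steps use local
metres-per-degree on a sphere of radius 6 371 008.8 m. Eddy diffusivity K
adds a per-step Gaussian displacement of SD √(2·K·dt) per axis. Particles
that would cross a solid boundary, or that sample undefined velocity, freeze
at their last valid position and are flagged; a periodic-longitude policy is
available. Halving dt changes 30-day positions by well under 1 km on smooth
synthetic fields (verified against a fine-step oracle).

A release event connects source→destination if **any** particle passes
within the capture radius at **any** time in the 180-day transport window
("can be connected" reads as potential transport); endpoint-only capture is
available as an option. Defaults: capture radius 50 km (the scale of a vent
field's mesoscale neighbourhood — reported in every output, since no
standard value exists), monthly releases, 10 particles per release. The
transport frequency P is the fraction of release events connected.
Scenario contrast: ratio = P_future/P_control; enhanced (> 2), reduced
(< 0.5), lost (control > 0, future = 0), novel (control = 0 < future),
otherwise unchanged. Pairs with P_control = 0 have no finite ratio and go
to "novel" rather than producing infinities.

## Refugia

MSS thresholding scans candidate thresholds at midpoints between
consecutive sorted unique calibration scores, plus 0 and 1, with the
classification rule score ≥ threshold ⇒ suitable. Ties (plateaus of equal
sensitivity + specificity) resolve to the plateau midpoint — deterministic,
and centred in the optimal score gap. A cell is a species' refugium when
suitable under both present (1951–2000) and future (2081–2100) conditions;
a future-only mode exists because the stacking could alternatively count
future suitability alone (default is present ∩ future). Stacks are integer
per-cell counts, permutation-invariant and additive over disjoint species
sets. The package consumes suitability rasters; it does not fit niche
models.

## Synthetic data: what it emulates, what it does not

`gen_climate_cube` produces value(t) = baseline_mean + trend·max(0, t −
trend_start_year) + AR(1) noise whose stationary SD equals `baseline_sd`;
the process is initialised from its stationary distribution so the
1951–2000 sample SD is unbiased — that window is the hazard denominator, so
initialisation bias would propagate into every hazard. Trends start in 2001
by default, keeping the baseline window trend-free (configurable to test
trend-contaminated baselines). Default trend signs follow the harmful
directions. Noise is white in space: the generator emulates the *temporal*
statistical structure the hazard/ToE analysis assumes, not spatially
correlated fields, mesoscale eddies, or 3-D flow — so passing tests certify
the estimators, not realism of any particular ocean region.

Velocity fields are analytic (uniform; the classic time-perturbed
double-gyre streamfunction, whose normal velocity vanishes on the domain
boundary; a Gaussian zonal jet), vent sites are placed in the grid interior,
and suitability rasters are smoothed random fields with calibration points
constructed so the MSS threshold is the midpoint of a known score gap —
uniquely optimal and exactly recoverable. The future raster is the present
one shifted poleward and reduced, emulating a range shift with habitat
loss.

Region layouts are exact unions of cell-edge rectangles, so cell counts and
the prescribed ridge/RFMO overlap (84 of 100 cells by default) are integer
ground truth.

## Numerical choices and conventions

- Longitudes are normalised to [−180, 180); latitude axes ascending
  internally; GeoTIFF rows are written north→south with minimal EPSG:4326
  tags; the documented raster fill value is −9999.
- Geodesy is spherical (R = 6 371 008.8 m): haversine distances, and
  geodesic buffering via a local azimuthal-equidistant projection (exact
  centre distances on the sphere) with shapely buffering in metres.
  Sphere-vs-WGS84 discrepancy is ≤ ~0.34%, inside the 0.5% tolerance used
  for buffers. The "mile" in buffer distances defaults to nautical miles
  (standard in maritime delimitation); statute miles and km are selectable
  and the unit is recorded.
- A cell is excluded from all statistics if any year of a required window
  is masked; ensemble cells are masked if masked in any member.
- Monthly→annual collapse, baseline statistics and future-window means are
  plain arithmetic means; no detrending is applied inside the baseline
  window.

## Estimator behaviour under noise

With noise, the emergence-year estimators are biased in opposite
directions: "first" emerges early (any noise spike triggers it) and
"sustained" late (one late dip postpones it). At signal-to-noise 0.05
σ/year the 10⁴-replicate Monte-Carlo median is ≈2004 ("first") and ≈2050
("sustained") against a noise-free crossing of 2021; at 0.5 σ/year both
medians sit within ±2 years of the analytic year. Tests therefore verify
the estimators against Monte-Carlo oracles at low signal-to-noise and
against the closed form at high signal-to-noise, and the package reports
the rule alongside every ToE field so users can interpret the bias
direction.

## Problem sizes

Default study conditions: 150-year annual series (1951–2100), 24×24
analysis grids (10⁴ cells for SD-calibration checks; 500 cells for
median-ToE checks), 3-member ensembles, 6 vent sites with monthly releases
and 180-day transport at dt = 6 h, and 6 species per refugia stack. These
sizes make every statistical check sharp enough to detect estimator errors
while keeping any full run to minutes on one CPU.

## Known limitations

- No curvilinear/unstructured native ESM grids; inputs are assumed
  regridded to regular lat/lon. No OPeNDAP.
- No climate-velocity metrics, bias correction, or downscaling.
- Connectivity omits larval behaviour, settlement competency, mortality,
  and 3-D circulation; it quantifies potential physical transport only.
- The GeoTIFF writer emits minimal georeferencing (pixel scale, tie point,
  EPSG:4326 key) sufficient for standard GIS ingestion, not full GeoTIFF
  metadata.
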