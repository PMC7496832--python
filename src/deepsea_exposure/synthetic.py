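"""Synthetic inputs with known ground truth for every analysis stage.

The generators emulate the statistical structure the hazard / emergence
analysis assumes: gridded annual driver fields that are a linear trend plus
stationary AR(1) interannual noise (so the analytic hazard and emergence year
are known in closed form), nested region rectangles with prescribed cell
counts and overlap, analytic velocity fields (uniform, double-gyre, zonal
jet), vent-site sets, and habitat-suitability rasters with a constructed
maximum-sensitivity-plus-specificity threshold.

Defaults mirror the study conditions of the analysis layers: a 1951-2000
trend-free historical window, trends starting in 2001, projection horizon
2100, and harmful default trend directions (warming +, oxygen loss -,
acidification -, declining POC flux -).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .grid import (
    DRIVERS,
    HARMFUL_SIGN,
    ClimateCube,
    Grid,
    Region,
    RegionSet,
    ValidationError,
)

#: default per-driver trend signs: the harmful direction for each driver
DEFAULT_TREND_SIGN = dict(HARMFUL_SIGN)


@dataclass
class TrendSpec:
    """Linear trend + AR(1) noise specification for one driver.

    value(t) = baseline_mean + trend_per_year * max(0, t - trend_start_year)
               + AR(1) noise with stationary SD = baseline_sd.

    The default trend start (2001) keeps the 1951-2000 historical window
    trend-free, so the analytic emergence year for the noise-free series is
    ``trend_start_year + ceil(k * sd / |trend|)``.
    """

    driver: str = "temperature"
    baseline_mean: float = 0.0
    baseline_sd: float = 1.0
    trend_per_year: float = 0.02
    trend_start_year: int = 2001
    ar1_phi: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.driver not in DRIVERS:
            raise ValidationError(f"unknown driver {self.driver!r}")
        if self.baseline_sd < 0:
            raise ValidationError("baseline_sd must be >= 0")
        if not abs(self.ar1_phi) < 1:
            raise ValidationError("|ar1_phi| must be < 1")


@dataclass
class FlowSpec:
    """Analytic velocity-field specification."""

    kind: str = "double_gyre"
    amplitude: float = 0.1           # m/s
    period_days: float = 30.0        # for the time-varying gyre
    epsilon: float = 0.1             # gyre asymmetry perturbation
    jet_lat: float = 0.0             # degrees, zonal-jet axis
    jet_width: float = 2.0           # degrees, Gaussian e-folding width
    seed: int = 0

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValidationError("amplitude must be >= 0")
        if self.kind not in ("uniform", "double_gyre", "zonal_jet"):
            raise ValidationError(
                f"unknown flow kind {self.kind!r}; "
                "allowed: uniform, double_gyre, zonal_jet")


def gen_climate_cube(spec: TrendSpec, grid: Grid,
                     years: Sequence[int] = range(1951, 2101),
                     scenario: str = "rcp85",
                     model_id: str = "synthetic") -> ClimateCube:
    """Generate an annual cube: linear trend plus stationary AR(1) noise.

    The AR(1) process is initialised from its stationary distribution, so the
    sample SD over any window is an unbiased estimate of ``baseline_sd`` —
    this matters because the 1951-2000 SD is the hazard denominator.
    """
    years = np.asarray(list(years), dtype=int)
    ny, (nlat, nlon) = years.size, grid.shape
    rng = np.random.default_rng(spec.seed)
    ramp = np.maximum(0, years - spec.trend_start_year).astype(float)
    signal = spec.baseline_mean + spec.trend_per_year * ramp

    noise = np.zeros((ny, nlat, nlon))
    if spec.baseline_sd > 0:
        phi, sd = spec.ar1_phi, spec.baseline_sd
        noise[0] = rng.normal(0.0, sd, size=(nlat, nlon))
        innov_sd = sd * np.sqrt(1.0 - phi ** 2)
        for i in range(1, ny):
            noise[i] = phi * noise[i - 1] + rng.normal(0.0, innov_sd, (nlat, nlon))

    values = signal[:, None, None] + noise
    return ClimateCube(driver=spec.driver, scenario=scenario, model_id=model_id,
                       grid=grid, years=years, values=values)


def default_trend_specs(seed: int = 0,
                        trend_magnitude: float = 0.02,
                        baseline_sd: float = 1.0,
                        ar1_phi: float = 0.3) -> dict[str, TrendSpec]:
    """One TrendSpec per driver with harmful-direction default trend signs."""
    specs = {}
    for i, driver in enumerate(DRIVERS):
        specs[driver] = TrendSpec(
            driver=driver,
            baseline_mean={"temperature": 2.0, "oxygen": 0.2,
                           "ph": 7.9, "poc_flux": 5.0}[driver],
            baseline_sd=baseline_sd,
            trend_per_year=DEFAULT_TREND_SIGN[driver] * trend_magnitude,
            ar1_phi=ar1_phi,
            seed=seed + i,
        )
    return specs


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------

def _index_box(grid: Grid, row0: int, row1: int, col0: int, col1: int):
    """Polygon covering cells [row0, row1] x [col0, col1] (inclusive) exactly."""
    from shapely.geometry import box

    lat_e, lon_e = grid.lat_edges(), grid.lon_edges()
    # rows index the (ascending) latitude axis, cols the longitude axis
    lo_lat, hi_lat = sorted((lat_e[row0], lat_e[row1 + 1]))
    lo_lon, hi_lon = sorted((lon_e[col0], lon_e[col1 + 1]))
    return box(lo_lon, lo_lat, hi_lon, hi_lat)


@dataclass
class RegionTruth:
    """Ground truth emitted alongside the synthetic region layout."""

    cell_counts: dict[str, int] = field(default_factory=dict)
    overlap_pair: tuple[str, str] = ("ridge_axis", "rfmo_managed")
    overlap_percent: float = 84.0


def gen_regions(grid: Grid, overlap_percent: float = 84.0
                ) -> tuple[RegionSet, RegionTruth]:
    """Nested contract/reserve/APEI-style rectangles with known cell counts.

    Includes a 100-cell ``ridge_axis`` region with a prescribed fraction of
    its cells (default 84%) inside the ``rfmo_managed`` region, mirroring a
    ridge-versus-fisheries-management overlap; and a ``vme_patch`` nested
    inside both.
    """
    nlat, nlon = grid.shape
    if nlat < 20 or nlon < 20:
        raise ValidationError("gen_regions needs a grid of at least 20x20 cells")
    from shapely.ops import unary_union

    n_overlap = int(round(overlap_percent))
    if not 0 <= n_overlap <= 100:
        raise ValidationError("overlap_percent must be in [0, 100]")

    regions = []
    counts = {}

    def add(name, category, row0, row1, col0, col1):
        geom = _index_box(grid, row0, row1, col0, col1)
        regions.append(Region(name=name, category=category, geometry=geom))
        counts[name] = (row1 - row0 + 1) * (col1 - col0 + 1)

    add("contract_A", "exploration_contract", 1, 6, 1, 8)      # 6 x 8 = 48
    add("reserve_A", "reserved_area", 1, 4, 10, 15)            # 4 x 6 = 24
    add("apei_1", "apei", 8, 13, 2, 7)                         # 6 x 6 = 36
    add("ridge_buffer_1", "ridge_buffer", 8, 12, 10, 18)       # 5 x 9 = 45

    # 100-cell ridge axis: rows 14..18 x cols 0..19
    add("ridge_axis", "custom", 14, 18, 0, 19)

    # RFMO-managed region covering exactly n_overlap of the ridge-axis cells:
    # full rows first, then a partial row.
    full_rows, rem = divmod(n_overlap, 20)
    parts = []
    if full_rows > 0:
        parts.append(_index_box(grid, 14, 14 + full_rows - 1, 0, 19))
    if rem > 0:
        parts.append(_index_box(grid, 14 + full_rows, 14 + full_rows, 0, rem - 1))
    if not parts:  # zero overlap: place the region off the ridge axis
        parts.append(_index_box(grid, 8, 12, 10, 18))
    rfmo_geom = unary_union(parts)
    regions.append(Region(name="rfmo_managed", category="rfmo_area",
                          geometry=rfmo_geom))
    counts["rfmo_managed"] = n_overlap if n_overlap > 0 else 45

    add("vme_patch", "vme", 14, 15, 2, 5)                      # 2 x 4 = 8

    truth = RegionTruth(cell_counts=counts,
                        overlap_pair=("ridge_axis", "rfmo_managed"),
                        overlap_percent=float(n_overlap))
    return RegionSet(regions=regions), truth


# ---------------------------------------------------------------------------
# Velocity fields
# ---------------------------------------------------------------------------

def gen_velocity_field(spec: FlowSpec, grid: Grid, times_days: Sequence[float]):
    """Analytic 2-D velocity-field series on the grid.

    uniform      : (u, v) = (amplitude, 0) everywhere.
    double_gyre  : classic two-cell streamfunction on the grid's bounding box,
                   time-perturbed when ``period_days`` > 0; the normal
                   velocity vanishes on the domain boundary.
    zonal_jet    : eastward jet, Gaussian in latitude about ``jet_lat``.
    """
    from .connectivity import VelocityFieldSeries

    times = np.asarray(list(times_days), dtype=float)
    if times.ndim != 1 or times.size == 0 or np.any(np.diff(times) <= 0):
        raise ValidationError("times must be 1-D and strictly increasing")
    nlat, nlon = grid.shape
    lon2d, lat2d = grid.mesh()
    u = np.zeros((times.size, nlat, nlon))
    v = np.zeros_like(u)

    if spec.kind == "uniform":
        u[:] = spec.amplitude
    elif spec.kind == "zonal_jet":
        u[:] = spec.amplitude * np.exp(
            -(((lat2d - spec.jet_lat) / spec.jet_width) ** 2))[None]
    elif spec.kind == "double_gyre":
        # normalized coordinates: x in [0, 2], y in [0, 1]
        lon0, lon1 = grid.lon_edges()[0], grid.lon_edges()[-1]
        lat0, lat1 = grid.lat_edges()[0], grid.lat_edges()[-1]
        x = 2.0 * (lon2d - lon0) / (lon1 - lon0)
        y = (lat2d - lat0) / (lat1 - lat0)
        A, eps = spec.amplitude, spec.epsilon
        for i, t in enumerate(times):
            if spec.period_days > 0:
                omega = 2.0 * np.pi / spec.period_days
                a = eps * np.sin(omega * t)
            else:
                a = 0.0
            b = 1.0 - 2.0 * a
            f = a * x ** 2 + b * x
            dfdx = 2.0 * a * x + b
            u[i] = -np.pi * A * np.sin(np.pi * f) * np.cos(np.pi * y)
            v[i] = np.pi * A * np.cos(np.pi * f) * np.sin(np.pi * y) * dfdx
    return VelocityFieldSeries(grid=grid, times_days=times, u=u, v=v)


@dataclass
class VentSite:
    id: str
    lon: float
    lat: float
    active: bool = True


def gen_vent_sites(grid: Grid, n_sites: int = 6, seed: int = 0) -> list[VentSite]:
    """Vent sites placed well inside the grid interior, unique ids."""
    rng = np.random.default_rng(seed)
    lat_lo, lat_hi = np.percentile(grid.lat, [15, 85])
    lon_lo, lon_hi = np.percentile(grid.lon, [15, 85])
    sites = []
    for i in range(n_sites):
        sites.append(VentSite(
            id=f"vent_{i:02d}",
            lon=float(rng.uniform(lon_lo, lon_hi)),
            lat=float(rng.uniform(lat_lo, lat_hi)),
            active=True,
        ))
    return sites


# ---------------------------------------------------------------------------
# Habitat suitability
# ---------------------------------------------------------------------------

@dataclass
class SpeciesTruth:
    """One synthetic species: probability rasters plus constructed truth."""

    species: str
    probability_present: np.ndarray
    probability_future: np.ndarray
    calibration_scores: np.ndarray
    calibration_labels: np.ndarray
    true_threshold: float
    true_binary_present: np.ndarray
    true_binary_future: np.ndarray
    true_refugium: np.ndarray


def _smooth_probability(rng, shape, smooth_sigma=2.0):
    raw = rng.normal(size=shape)
    smooth = ndimage.gaussian_filter(raw, smooth_sigma, mode="nearest")
    lo, hi = smooth.min(), smooth.max()
    return (smooth - lo) / (hi - lo) if hi > lo else np.full(shape, 0.5)


def gen_suitability(n_species: int, grid: Grid, seed: int = 0,
                    n_calibration: int = 200,
                    future_shift_cells: int = 3,
                    future_decline: float = 0.1) -> list[SpeciesTruth]:
    """Suitability rasters with a constructed, exactly recoverable threshold.

    Calibration labels are assigned by thresholding the sampled scores at the
    midpoint of a gap between two consecutive sorted scores, so the
    constructed threshold is the unique maximiser of sensitivity +
    specificity (perfect separation) and the plateau-midpoint rule recovers
    it exactly.

    The future raster is the present one shifted poleward by
    ``future_shift_cells`` rows and reduced by ``future_decline``, emulating a
    range shift with overall habitat loss; the per-species refugium truth is
    present AND future suitability.
    """
    if n_species < 1:
        raise ValidationError("n_species must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for s in range(n_species):
        prob_now = _smooth_probability(rng, grid.shape)
        prob_fut = np.roll(prob_now, future_shift_cells, axis=0) - future_decline
        prob_fut = np.clip(prob_fut, 0.0, 1.0)

        scores = rng.uniform(0.0, 1.0, size=n_calibration)
        scores = np.unique(np.round(scores, 6))
        # threshold at the midpoint of the gap nearest the middle of the
        # sorted scores -> perfect separation with a unique optimal plateau
        mid = scores.size // 2
        thr = 0.5 * (scores[mid - 1] + scores[mid])
        labels = (scores >= thr).astype(int)

        out.append(SpeciesTruth(
            species=f"species_{s:02d}",
            probability_present=prob_now,
            probability_future=prob_fut,
            calibration_scores=scores,
            calibration_labels=labels,
            true_threshold=float(thr),
            true_binary_present=prob_now >= thr,
            true_binary_future=prob_fut >= thr,
            true_refugium=(prob_now >= thr) & (prob_fut >= thr),
        ))
    return out


def gen_bathymetry(grid: Grid, seed: int = 0,
                   depth_range=(200.0, 5500.0)) -> np.ndarray:
    """Smooth synthetic bathymetry (metres, positive down)."""
    rng = np.random.default_rng(seed)
    field_ = _smooth_probability(rng, grid.shape, smooth_sigma=3.0)
    lo, hi = depth_range
    return lo + field_ * (hi - lo)
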