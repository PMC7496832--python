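"""Climate-change hazard and time-of-emergence statistics.

The climate-change hazard of a driver at a cell is the ratio of the modelled
change (future-window mean minus 1951-2000 mean) to the historical
variability, defined as the standard deviation of annual values modelled over
1951-2000:

    h = (mean_future - mean_hist) / sd_hist                     (dimensionless)

Its harmful magnitude clamps the signed hazard to the direction that harms
benthic fauna (warming +; oxygen, pH and POC-flux decline -), and the
cumulative negative hazard at a cell sums the four drivers' harmful
magnitudes, in units of "times historical variability".

The time of emergence (ToE) of a driver is the year in which the projected
signal moves beyond the historical variability envelope: with harmful-
direction anomaly a(t) = s * (value(t) - mean_hist), the default "sustained"
rule reports the earliest year t after the baseline window such that
a(t') >= k * sd_hist for every t' >= t up to the horizon (default 2100);
the "first" rule reports the earliest single exceedance year. Cells that
never qualify are censored and reported as ">horizon".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely

from .grid import (
    DRIVERS,
    HARMFUL_SIGN,
    ClimateCube,
    Field2D,
    Grid,
    RegionSet,
    ValidationError,
    censored_label,
)

logger = logging.getLogger(__name__)

BASELINE_WINDOW = (1951, 2000)
MID_CENTURY_WINDOW = (2041, 2060)
END_CENTURY_WINDOW = (2081, 2100)
DEFAULT_HORIZON = 2100


@dataclass
class BaselineStats:
    """Per-cell historical mean and sample SD over the baseline window."""

    driver: str
    window: tuple[int, int]
    mean_hist: np.ndarray
    sd_hist: np.ndarray
    grid: Grid
    mask: np.ndarray

    def __post_init__(self):
        if self.window[1] - self.window[0] < 1:
            raise ValidationError("baseline window must span at least 2 years")
        if np.any(self.sd_hist[~self.mask] < 0):
            raise ValidationError("sd_hist must be non-negative")


@dataclass
class HazardField:
    """Signed hazard and harmful magnitude for one driver and future window."""

    driver: str
    window: tuple[int, int]
    hazard_signed: np.ndarray
    harmful_magnitude: np.ndarray
    grid: Grid
    mask: np.ndarray
    scenario: str = ""

    def as_field(self, signed: bool = False) -> Field2D:
        vals = self.hazard_signed if signed else self.harmful_magnitude
        return Field2D(grid=self.grid, values=np.where(self.mask, np.nan, vals),
                       name=f"hazard_{self.driver}",
                       attrs={"driver": self.driver, "window": str(self.window),
                              "scenario": self.scenario})


@dataclass
class CumulativeHazardField:
    """Sum over the four drivers of harmful hazard magnitudes."""

    window: tuple[int, int]
    values: np.ndarray
    grid: Grid
    mask: np.ndarray
    scenario: str = ""

    def as_field(self) -> Field2D:
        return Field2D(grid=self.grid,
                       values=np.where(self.mask, np.nan, self.values),
                       name="cumulative_negative_hazard",
                       attrs={"window": str(self.window),
                              "scenario": self.scenario})


@dataclass
class ToEField:
    """Per-cell emergence years; censored cells hold ``horizon + 1``."""

    driver: str                      # one of DRIVERS or "all_drivers"
    years: np.ndarray                # integer years, sentinel horizon+1
    grid: Grid
    mask: np.ndarray
    k: float = 1.0
    rule: str = "sustained"
    horizon: int = DEFAULT_HORIZON
    scenario: str = ""

    @property
    def censored(self) -> np.ndarray:
        return (self.years > self.horizon) & ~self.mask

    def as_field(self) -> Field2D:
        vals = np.where(self.mask, np.nan, self.years.astype(float))
        return Field2D(grid=self.grid, values=vals, name=f"toe_{self.driver}",
                       censored=self.censored,
                       attrs={"driver": self.driver, "k": self.k,
                              "rule": self.rule, "horizon": self.horizon,
                              "scenario": self.scenario})


@dataclass
class RegionSummary:
    """Min/max of a metric over the cells of one region (Table-1-shaped)."""

    region: str
    category: str
    metric: str
    min: float | None
    max: float | str | None
    censored_n: int
    n_cells: int
    window: str = ""
    scenario: str = ""


# ---------------------------------------------------------------------------
# Core statistics
# ---------------------------------------------------------------------------

def baseline_stats(cube: ClimateCube,
                   window: tuple[int, int] = BASELINE_WINDOW) -> BaselineStats:
    """Per-cell mean and sample SD (n-1 denominator) of annual values."""
    sub = cube.select_years(*window)
    mean = sub.values.mean(axis=0)
    sd = sub.values.std(axis=0, ddof=1)
    return BaselineStats(driver=cube.driver, window=window, mean_hist=mean,
                         sd_hist=sd, grid=cube.grid, mask=cube.mask.copy())


def driver_hazard(cube: ClimateCube, baseline: BaselineStats,
                  window: tuple[int, int]) -> HazardField:
    """Signed hazard (change / historical SD) and its harmful magnitude.

    Cells with zero historical SD are masked as undefined unless the change
    is also zero, in which case the hazard is 0.
    """
    if cube.driver != baseline.driver:
        raise ValidationError(
            f"driver mismatch: cube {cube.driver!r} vs baseline {baseline.driver!r}")
    future_mean = cube.select_years(*window).values.mean(axis=0)
    delta = future_mean - baseline.mean_hist
    mask = cube.mask | baseline.mask
    zero_sd = (baseline.sd_hist == 0) & ~mask
    degenerate = zero_sd & (delta != 0)
    if np.any(degenerate):
        logger.warning("%d cells with sd_hist = 0 and nonzero change masked "
                       "as undefined (driver %s)", int(degenerate.sum()),
                       cube.driver)
    mask = mask | degenerate
    with np.errstate(divide="ignore", invalid="ignore"):
        signed = np.where(zero_sd, 0.0, delta / np.where(zero_sd, 1.0,
                                                         baseline.sd_hist))
    signed = np.where(mask, np.nan, signed)
    s = HARMFUL_SIGN[cube.driver]
    harmful = np.where(mask, np.nan, np.maximum(0.0, s * signed))
    return HazardField(driver=cube.driver, window=window, hazard_signed=signed,
                       harmful_magnitude=harmful, grid=cube.grid, mask=mask,
                       scenario=cube.scenario)


def cumulative_negative_hazard(hazards: Mapping[str, HazardField] | Iterable[HazardField],
                               window: tuple[int, int] | None = None,
                               clamp: bool = True) -> CumulativeHazardField:
    """Per-cell sum of harmful hazard magnitudes across the four drivers.

    With ``clamp=False`` the signed hazards (beneficial directions included
    as negative offsets) are summed instead — a sensitivity-analysis mode.
    """
    if isinstance(hazards, Mapping):
        by_driver = dict(hazards)
    else:
        by_driver = {h.driver: h for h in hazards}
    missing = [d for d in DRIVERS if d not in by_driver]
    if missing:
        raise ValidationError(f"missing hazard fields for drivers: {missing}")
    fields = [by_driver[d] for d in DRIVERS]
    window = window or fields[0].window
    for h in fields:
        if h.window != window:
            raise ValidationError("hazard windows differ across drivers")
        if h.grid != fields[0].grid:
            raise ValidationError("hazard grids differ across drivers")
    mask = np.logical_or.reduce([h.mask for h in fields])
    if clamp:
        total = np.nansum([np.where(h.mask, 0.0, h.harmful_magnitude)
                           for h in fields], axis=0)
    else:
        total = np.nansum([np.where(h.mask, 0.0,
                                    HARMFUL_SIGN[h.driver] * h.hazard_signed)
                           for h in fields], axis=0)
    total = np.where(mask, np.nan, total)
    return CumulativeHazardField(window=window, values=total,
                                 grid=fields[0].grid, mask=mask,
                                 scenario=fields[0].scenario)


def time_of_emergence(cube: ClimateCube, baseline: BaselineStats,
                      k: float = 1.0, rule: str = "sustained",
                      horizon: int = DEFAULT_HORIZON,
                      two_sided: bool = False) -> ToEField:
    """Per-cell emergence year of the projected signal beyond k x sd_hist.

    The anomaly is taken in the driver's harmful direction (one-sided) by
    default; ``two_sided=True`` uses |value - mean_hist| instead. A year t
    qualifies when a(t) >= k * sd_hist. Rule "first" returns the earliest
    qualifying year after the baseline window; rule "sustained" (default)
    returns the earliest year from which every later year up to the horizon
    also qualifies. Cells that never qualify are censored (horizon + 1).

    Cells with sd_hist = 0 emerge at the first year of any harmful-direction
    change; a guard message is logged for them.
    """
    if rule not in ("first", "sustained"):
        raise ValidationError(f"unknown persistence rule {rule!r}")
    if cube.driver != baseline.driver:
        raise ValidationError("cube/baseline driver mismatch")
    start = baseline.window[1] + 1
    if cube.years[-1] < horizon:
        raise ValidationError(
            f"cube ends {cube.years[-1]}, before the horizon {horizon}")
    sub = cube.select_years(start, horizon)
    s = HARMFUL_SIGN[cube.driver]
    anom = sub.values - baseline.mean_hist[None]
    a = np.abs(anom) if two_sided else s * anom
    mask = cube.mask | baseline.mask

    zero_sd = (baseline.sd_hist == 0) & ~mask
    if np.any(zero_sd):
        logger.warning("%d cells with sd_hist = 0: ToE taken as first year of "
                       "any harmful-direction change (driver %s)",
                       int(zero_sd.sum()), cube.driver)
        thresh = np.where(zero_sd, np.nextafter(0.0, 1.0), k * baseline.sd_hist)
    else:
        thresh = k * baseline.sd_hist
    exceed = a >= thresh[None]          # (nyears_future, nlat, nlon)

    ny = exceed.shape[0]
    if rule == "first":
        any_hit = exceed.any(axis=0)
        idx = exceed.argmax(axis=0)
    else:
        # earliest index i with exceed[i:] all True == ny - (length of the
        # trailing all-True run)
        trailing = np.cumprod(exceed[::-1], axis=0).sum(axis=0)
        any_hit = trailing > 0
        idx = ny - trailing
    years = np.where(any_hit, start + idx, horizon + 1).astype(int)
    years = np.where(mask, horizon + 1, years)
    return ToEField(driver=cube.driver, years=years, grid=cube.grid, mask=mask,
                    k=k, rule=rule, horizon=horizon, scenario=cube.scenario)


def toe_all_drivers(toes: Mapping[str, ToEField] | Iterable[ToEField]) -> ToEField:
    """Emergence of *all* drivers: per-cell maximum of the four years.

    Because the censoring sentinel is ``horizon + 1`` (larger than any real
    emergence year), the maximum propagates censoring automatically: a cell
    is censored whenever any driver is.
    """
    if isinstance(toes, Mapping):
        by_driver = dict(toes)
    else:
        by_driver = {t.driver: t for t in toes}
    missing = [d for d in DRIVERS if d not in by_driver]
    if missing:
        raise ValidationError(f"missing ToE fields for drivers: {missing}")
    fields = [by_driver[d] for d in DRIVERS]
    first = fields[0]
    for t in fields[1:]:
        if t.grid != first.grid:
            raise ValidationError("ToE grids differ across drivers")
        if (t.k, t.rule, t.horizon) != (first.k, first.rule, first.horizon):
            raise ValidationError("ToE fields differ in k / rule / horizon")
    years = np.max([t.years for t in fields], axis=0)
    mask = np.logical_or.reduce([t.mask for t in fields])
    years = np.where(mask, first.horizon + 1, years)
    return ToEField(driver="all_drivers", years=years, grid=first.grid,
                    mask=mask, k=first.k, rule=first.rule,
                    horizon=first.horizon, scenario=first.scenario)


def ensemble_average(cubes: Sequence[ClimateCube]) -> ClimateCube:
    """Per-cell arithmetic mean across ensemble members.

    A cell is masked if masked in any member; the member model ids are
    recorded in the result's ``model_id`` as a provenance list.
    """
    if len(cubes) < 1:
        raise ValidationError("need at least one ensemble member")
    first = cubes[0]
    for c in cubes[1:]:
        if c.grid != first.grid:
            raise ValidationError("ensemble members on different grids")
        if c.driver != first.driver or c.scenario != first.scenario:
            raise ValidationError("ensemble members mix drivers or scenarios")
        if not np.array_equal(c.years, first.years):
            raise ValidationError("ensemble members cover different years")
    mask = np.logical_or.reduce([c.mask for c in cubes])
    values = np.mean([c.values for c in cubes], axis=0)
    model_id = "ensemble(" + ",".join(c.model_id for c in cubes) + ")"
    return ClimateCube(driver=first.driver, scenario=first.scenario,
                       model_id=model_id, grid=first.grid, years=first.years,
                       values=values, mask=mask, units=first.units)


def ensemble_average_fields(fields: Sequence[Field2D]) -> Field2D:
    """Per-cell mean of 2-D fields across ensemble members (NaN-masking)."""
    if len(fields) < 1:
        raise ValidationError("need at least one field")
    grid = fields[0].grid
    for f in fields[1:]:
        if f.grid != grid:
            raise ValidationError("fields on different grids")
    stack = np.stack([f.values for f in fields])
    invalid = ~np.all(np.isfinite(stack), axis=0)
    mean = np.where(invalid, np.nan, stack.mean(axis=0))
    return Field2D(grid=grid, values=mean, name=fields[0].name,
                   units=fields[0].units,
                   attrs={"ensemble_n": len(fields)})


# ---------------------------------------------------------------------------
# Regional summaries
# ---------------------------------------------------------------------------

def _region_cell_mask(region_geom, grid: Grid) -> np.ndarray:
    lon2d, lat2d = grid.mesh()
    return shapely.contains_xy(region_geom, lon2d.ravel(), lat2d.ravel()
                               ).reshape(grid.shape)


def region_minmax(field_or_toe, regions: RegionSet,
                  metric: str | None = None) -> list[RegionSummary]:
    """Unweighted min/max over region member cells (cell-centre inclusion).

    For ToE fields, censored cells are excluded from the minimum and counted
    separately; the maximum is reported as ">horizon" whenever any member
    cell is censored (matching how regional emergence extrema are tabulated).
    Empty regions produce an empty summary with a logged warning.
    """
    is_toe = isinstance(field_or_toe, ToEField)
    if is_toe:
        grid = field_or_toe.grid
        values = field_or_toe.years.astype(float)
        invalid = field_or_toe.mask
        censored = field_or_toe.censored
        metric = metric or f"toe_{field_or_toe.driver}"
        scenario = field_or_toe.scenario
        window = f"->{field_or_toe.horizon}"
        horizon = field_or_toe.horizon
    elif isinstance(field_or_toe, CumulativeHazardField):
        grid = field_or_toe.grid
        values = field_or_toe.values
        invalid = field_or_toe.mask | ~np.isfinite(field_or_toe.values)
        censored = np.zeros(grid.shape, dtype=bool)
        metric = metric or "cumulative_negative_hazard"
        scenario = field_or_toe.scenario
        window = f"{field_or_toe.window[0]}-{field_or_toe.window[1]}"
        horizon = None
    else:  # plain Field2D
        grid = field_or_toe.grid
        values = field_or_toe.values
        censored = (field_or_toe.censored if field_or_toe.censored is not None
                    else np.zeros(grid.shape, dtype=bool))
        invalid = ~np.isfinite(values) & ~censored
        metric = metric or field_or_toe.name
        scenario = str(field_or_toe.attrs.get("scenario", ""))
        window = str(field_or_toe.attrs.get("window", ""))
        horizon = field_or_toe.attrs.get("horizon")

    out = []
    for region in regions:
        member = _region_cell_mask(region.geometry, grid) & ~invalid
        n_cells = int(member.sum())
        if n_cells == 0:
            logger.warning("region %r contains no valid cell centres", region.name)
            out.append(RegionSummary(region=region.name, category=region.category,
                                     metric=metric, min=None, max=None,
                                     censored_n=0, n_cells=0, window=window,
                                     scenario=scenario))
            continue
        cens = censored & member
        n_cens = int(cens.sum())
        numeric = values[member & ~censored]
        vmin = float(numeric.min()) if numeric.size else None
        if n_cens > 0:
            vmax: float | str = censored_label(horizon if horizon else DEFAULT_HORIZON)
        else:
            vmax = float(numeric.max()) if numeric.size else None
        if vmin is not None and isinstance(vmax, float) and vmin > vmax:
            raise ValidationError("min exceeds max — internal error")
        out.append(RegionSummary(region=region.name, category=region.category,
                                 metric=metric, min=vmin, max=vmax,
                                 censored_n=n_cens, n_cells=n_cells,
                                 window=window, scenario=scenario))
    return out


def summaries_to_frame(summaries: Sequence[RegionSummary]) -> pd.DataFrame:
    """Tabulate region summaries with the standard CSV column order."""
    return pd.DataFrame([
        {"region": s.region, "category": s.category, "scenario": s.scenario,
         "metric": s.metric, "window": s.window, "min": s.min, "max": s.max,
         "censored_n": s.censored_n, "n_cells": s.n_cells}
        for s in summaries
    ])
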