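"""Passive larval transport at a fixed dispersal depth and its scenario contrast.

Particles released at vent sites are advected for a fixed transport time
(default 180 days, long enough to cover larval development at deep-water
temperatures) through a 2-D velocity field at the dispersal-depth horizon
(the vertical dimension is collapsed: dispersal depth is fixed, e.g. 1,000 m).
Integration is 4th-order Runge-Kutta on velocities interpolated bilinearly in
space and linearly in time, optionally with a Brownian random-walk step of
per-axis displacement SD sqrt(2 K dt) for unresolved eddy diffusivity K.

A release event connects source s to destination d when any of its particles
passes within the capture radius of d at any time within the transport
window. The transport frequency P[s, d] is the fraction of release events
connected. Comparing a future scenario against a preindustrial control:

    ratio = P_future / P_control
    enhanced  : ratio > 2      (more than a 100% increase)
    reduced   : ratio < 0.5    (more than a 50% reduction)
    lost      : P_control > 0 and P_future = 0
    novel     : P_control = 0 and P_future > 0
    unchanged : otherwise
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from ._geo import M_PER_DEG_LAT, haversine_m, meters_per_degree_lon
from .grid import Grid, ValidationError

logger = logging.getLogger(__name__)

SECONDS_PER_DAY = 86400.0


@dataclass
class VelocityFieldSeries:
    """Time series of 2-D velocity fields (m/s) on a regular grid."""

    grid: Grid
    times_days: np.ndarray
    u: np.ndarray            # (ntime, nlat, nlon), m/s eastward
    v: np.ndarray            # (ntime, nlat, nlon), m/s northward
    boundary: str = "solid"  # or "periodic_lon"

    def __post_init__(self):
        self.times_days = np.asarray(self.times_days, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if np.any(np.diff(self.times_days) <= 0):
            raise ValidationError("times must be strictly increasing")
        expected = (self.times_days.size,) + self.grid.shape
        if self.u.shape != expected or self.v.shape != expected:
            raise ValidationError("u/v must have shape (time, lat, lon)")
        if self.boundary not in ("solid", "periodic_lon"):
            raise ValidationError(f"unknown boundary policy {self.boundary!r}")


@dataclass
class ReleaseSpec:
    """Release and integration configuration for one transport experiment."""

    particles_per_release: int = 10
    release_times_days: tuple[float, ...] = (0.0,)
    duration_days: float = 180.0
    dt_hours: float = 6.0
    diffusivity_m2s: float = 0.0
    capture_radius_km: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if self.duration_days <= 0 or self.dt_hours <= 0:
            raise ValidationError("duration and dt must be > 0")
        if self.capture_radius_km <= 0:
            raise ValidationError("capture_radius must be > 0")
        if self.particles_per_release < 1:
            raise ValidationError("need at least one particle per release")


@dataclass
class Trajectories:
    """Particle positions: (n_sources, n_releases, n_particles, n_steps+1)."""

    lon: np.ndarray
    lat: np.ndarray
    times_days: np.ndarray            # offsets within a release, length n_steps+1
    release_times_days: np.ndarray
    source_ids: list[str]
    flagged: np.ndarray               # particles frozen at a boundary / NaN velocity


@dataclass
class ConnectivityMatrix:
    """P[source, destination]: fraction of release events connected."""

    P: np.ndarray
    source_ids: list[str]
    destination_ids: list[str]
    n_releases: int
    spec: ReleaseSpec | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.source_ids):
            for j, d in enumerate(self.destination_ids):
                rows.append({"source": s, "destination": d,
                             "P": self.P[i, j], "n_releases": self.n_releases})
        return pd.DataFrame(rows)


@dataclass
class ConnectivityDelta:
    """Scenario-versus-control transport classification per site pair."""

    ratio: np.ndarray                 # NaN where P_control = 0
    classes: np.ndarray               # object array of class names
    source_ids: list[str]
    destination_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.source_ids):
            for j, d in enumerate(self.destination_ids):
                rows.append({"source": s, "destination": d,
                             "ratio": self.ratio[i, j],
                             "class": self.classes[i, j]})
        return pd.DataFrame(rows)

    def count(self, cls: str) -> int:
        return int(np.sum(self.classes == cls))


class _VelocitySampler:
    """Linear-in-time, bilinear-in-space velocity lookup (NaN outside)."""

    def __init__(self, field: VelocityFieldSeries):
        g = field.grid
        lat, lon = g.lat, g.lon
        u, v = field.u, field.v
        if lat[0] > lat[-1]:
            lat, u, v = lat[::-1], u[:, ::-1, :], v[:, ::-1, :]
        t = field.times_days
        if t.size == 1:  # single snapshot: pad to a constant-in-time series
            t = np.array([t[0], t[0] + 1.0])
            u = np.concatenate([u, u], axis=0)
            v = np.concatenate([v, v], axis=0)
        kwargs = dict(method="linear", bounds_error=False, fill_value=np.nan)
        self._ui = RegularGridInterpolator((t, lat, lon), u, **kwargs)
        self._vi = RegularGridInterpolator((t, lat, lon), v, **kwargs)
        self.t_span = (t[0], t[-1])

    def __call__(self, t_days, lon, lat):
        t = np.clip(t_days, *self.t_span)
        pts = np.column_stack([np.full(lon.shape, t), lat, lon])
        return self._ui(pts), self._vi(pts)


def _deg_velocity(u_ms, v_ms, lat):
    """Convert (m/s) to (deg lon / day, deg lat / day) at the given latitudes."""
    m_per_deg_lon = np.maximum(meters_per_degree_lon(lat), 1.0)
    dlon = u_ms * SECONDS_PER_DAY / m_per_deg_lon
    dlat = v_ms * SECONDS_PER_DAY / M_PER_DEG_LAT
    return dlon, dlat


def advect_particles(field: VelocityFieldSeries, sources: Sequence,
                     spec: ReleaseSpec) -> Trajectories:
    """Advect particles from each source for each release event.

    RK4 with step ``dt_hours`` on the interpolated velocity field; geographic
    steps use local metres-per-degree. Particles that would leave a solid
    boundary (or sample NaN velocity) are frozen at their last valid position
    and flagged. Reproducible under a fixed seed.
    """
    grid = field.grid
    sampler = _VelocitySampler(field)
    release_times = np.asarray(spec.release_times_days, dtype=float)
    t_lo, t_hi = field.times_days[0], field.times_days[-1]
    if field.times_days.size > 1:
        if release_times.min() < t_lo or (release_times.max() + spec.duration_days
                                          ) > t_hi + 1e-9:
            raise ValidationError(
                "release times + duration must lie within the velocity series")

    dt_days = spec.dt_hours / 24.0
    n_steps = int(round(spec.duration_days / dt_days))
    times = dt_days * np.arange(n_steps + 1)

    n_src, n_rel, n_par = len(sources), release_times.size, spec.particles_per_release
    src_lon = np.array([s.lon for s in sources], dtype=float)
    src_lat = np.array([s.lat for s in sources], dtype=float)

    lon = np.empty((n_src, n_rel, n_par, n_steps + 1))
    lat = np.empty_like(lon)
    flagged = np.zeros((n_src, n_rel, n_par), dtype=bool)

    rng = np.random.default_rng(spec.seed)
    lat_lo, lat_hi = grid.lat_edges()[0], grid.lat_edges()[-1]
    lon_lo, lon_hi = grid.lon_edges()[0], grid.lon_edges()[-1]
    if lat_lo > lat_hi:
        lat_lo, lat_hi = lat_hi, lat_lo

    for r, t0 in enumerate(release_times):
        # state arrays over (source, particle), flattened
        x = np.repeat(src_lon, n_par).astype(float)
        y = np.repeat(src_lat, n_par).astype(float)
        frozen = np.zeros(x.size, dtype=bool)
        lon[:, r, :, 0] = x.reshape(n_src, n_par)
        lat[:, r, :, 0] = y.reshape(n_src, n_par)
        for step in range(n_steps):
            t = t0 + times[step]
            xn, yn, bad = _rk4_step(sampler, t, x, y, dt_days)
            if spec.diffusivity_m2s > 0:
                sd_m = np.sqrt(2.0 * spec.diffusivity_m2s
                               * dt_days * SECONDS_PER_DAY)
                dx_m = rng.normal(0.0, sd_m, x.size)
                dy_m = rng.normal(0.0, sd_m, x.size)
                xn = xn + dx_m / np.maximum(meters_per_degree_lon(yn), 1.0)
                yn = yn + dy_m / M_PER_DEG_LAT
            if field.boundary == "periodic_lon":
                span = lon_hi - lon_lo
                xn = lon_lo + np.mod(xn - lon_lo, span)
            out = (xn < lon_lo) | (xn > lon_hi) | (yn < lat_lo) | (yn > lat_hi)
            newly_frozen = (bad | out) & ~frozen
            frozen |= newly_frozen
            x = np.where(frozen, x, xn)
            y = np.where(frozen, y, yn)
            lon[:, r, :, step + 1] = x.reshape(n_src, n_par)
            lat[:, r, :, step + 1] = y.reshape(n_src, n_par)
        flagged[:, r, :] |= frozen.reshape(n_src, n_par)

    return Trajectories(lon=lon, lat=lat, times_days=times,
                        release_times_days=release_times,
                        source_ids=[s.id for s in sources], flagged=flagged)


def _rk4_step(sampler, t, x, y, dt_days):
    """One RK4 step in degree coordinates; returns (x', y', nan_flag)."""
    def rhs(tt, xx, yy):
        u, v = sampler(tt, xx, yy)
        return _deg_velocity(u, v, yy)

    k1x, k1y = rhs(t, x, y)
    k2x, k2y = rhs(t + dt_days / 2, x + dt_days / 2 * k1x, y + dt_days / 2 * k1y)
    k3x, k3y = rhs(t + dt_days / 2, x + dt_days / 2 * k2x, y + dt_days / 2 * k2y)
    k4x, k4y = rhs(t + dt_days, x + dt_days * k3x, y + dt_days * k3y)
    dx = dt_days / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x)
    dy = dt_days / 6.0 * (k1y + 2 * k2y + 2 * k3y + k4y)
    bad = ~np.isfinite(dx) | ~np.isfinite(dy)
    return (np.where(bad, x, x + dx), np.where(bad, y, y + dy), bad)


def transport_frequency(traj: Trajectories, destinations: Sequence,
                        spec: ReleaseSpec,
                        endpoint_only: bool = False) -> ConnectivityMatrix:
    """Transport-frequency matrix from trajectories.

    A release connects s -> d when any of its particles comes within the
    capture radius of d at any recorded time (or only at the final position
    with ``endpoint_only=True``).
    """
    n_src, n_rel, n_par, n_t = traj.lon.shape
    if n_rel == 0:
        raise ValidationError("zero release events")
    radius_m = spec.capture_radius_km * 1000.0
    dest_ids = [d.id for d in destinations]
    P = np.zeros((n_src, len(destinations)))
    lon = traj.lon[..., -1:] if endpoint_only else traj.lon
    lat = traj.lat[..., -1:] if endpoint_only else traj.lat
    for j, d in enumerate(destinations):
        dist = haversine_m(lon, lat, d.lon, d.lat)
        connected = (dist <= radius_m).any(axis=(2, 3))   # (n_src, n_rel)
        P[:, j] = connected.mean(axis=1)
    return ConnectivityMatrix(P=P, source_ids=traj.source_ids,
                              destination_ids=dest_ids, n_releases=n_rel,
                              spec=spec)


CLASSES = ("enhanced", "reduced", "lost", "novel", "unchanged")


def compare_scenarios(P_future: ConnectivityMatrix,
                      P_control: ConnectivityMatrix) -> ConnectivityDelta:
    """Classify each site pair by future-vs-control transport frequency."""
    if (P_future.source_ids != P_control.source_ids
            or P_future.destination_ids != P_control.destination_ids):
        raise ValidationError("site sets differ between scenarios")
    pf, pc = P_future.P, P_control.P
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(pc > 0, pf / np.where(pc > 0, pc, 1.0), np.nan)
    classes = np.full(pf.shape, "unchanged", dtype=object)
    classes[(pc > 0) & (pf == 0)] = "lost"
    classes[(pc == 0) & (pf > 0)] = "novel"
    enhanced = (pc > 0) & (pf > 0) & (ratio > 2.0)
    reduced = (pc > 0) & (pf > 0) & (ratio < 0.5)
    classes[enhanced] = "enhanced"
    classes[reduced] = "reduced"
    return ConnectivityDelta(ratio=ratio, classes=classes,
                             source_ids=P_future.source_ids,
                             destination_ids=P_future.destination_ids)
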