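"""Particle advection, transport-frequency matrices, scenario classification."""

import numpy as np
import pytest
from scipy.interpolate import RegularGridInterpolator

import deepsea_exposure as dse
from deepsea_exposure._geo import M_PER_DEG_LAT, haversine_m, meters_per_degree_lon
from deepsea_exposure.connectivity import ConnectivityMatrix
from deepsea_exposure.synthetic import FlowSpec, VentSite


def _equatorial_grid(span_deg=40.0, n=41):
    return dse.Grid(lat=np.linspace(-10.0, 10.0, 21),
                    lon=np.linspace(-span_deg / 2, span_deg / 2, n))


def _uniform_field(grid, u_ms, days=240.0):
    spec = FlowSpec(kind="uniform", amplitude=u_ms)
    return dse.gen_velocity_field(spec, grid, np.arange(0.0, days + 1, 30.0))


def _spec(**kw):
    defaults = dict(particles_per_release=1, release_times_days=(0.0,),
                    duration_days=180.0, dt_hours=6.0, diffusivity_m2s=0.0,
                    capture_radius_km=10.0, seed=0)
    defaults.update(kw)
    return dse.ReleaseSpec(**defaults)


def test_zero_velocity_particles_stationary():
    grid = _equatorial_grid()
    field = _uniform_field(grid, 0.0)
    src = [VentSite("s", lon=0.0, lat=0.0)]
    traj = dse.advect_particles(field, src, _spec())
    np.testing.assert_allclose(traj.lon, 0.0, atol=1e-12)
    np.testing.assert_allclose(traj.lat, 0.0, atol=1e-12)


def test_uniform_flow_180day_displacement():
    """0.1 m/s east for 180 days must travel 1,555.2 km within 0.1%."""
    grid = _equatorial_grid()
    field = _uniform_field(grid, 0.1)
    src = [VentSite("s", lon=-8.0, lat=0.0)]
    traj = dse.advect_particles(field, src, _spec())
    end_lon, end_lat = traj.lon[0, 0, 0, -1], traj.lat[0, 0, 0, -1]
    dist_km = haversine_m(-8.0, 0.0, end_lon, end_lat) / 1000.0
    expected = 0.1 * 86400 * 180 / 1000.0     # 1555.2 km
    assert dist_km == pytest.approx(expected, rel=1e-3)


def test_rk4_deterministic_without_diffusion():
    grid = _equatorial_grid()
    spec = FlowSpec(kind="double_gyre", amplitude=0.2, period_days=30.0)
    field = dse.gen_velocity_field(spec, grid, np.arange(0.0, 200.0, 10.0))
    src = [VentSite("s", lon=-3.0, lat=2.0)]
    t1 = dse.advect_particles(field, src, _spec(seed=1))
    t2 = dse.advect_particles(field, src, _spec(seed=99))
    np.testing.assert_array_equal(t1.lon, t2.lon)
    np.testing.assert_array_equal(t1.lat, t2.lat)


def test_rk4_matches_fine_step_oracle_on_double_gyre():
    """dt = 6 h endpoints within 1 km of an independent RK4 at dt = 0.25 h
    after 30 days in a steady double-gyre."""
    grid = dse.Grid(lat=np.linspace(-10, 10, 81), lon=np.linspace(-10, 10, 81))
    spec = FlowSpec(kind="double_gyre", amplitude=0.2, period_days=0.0)
    field = dse.gen_velocity_field(spec, grid, [0.0, 40.0])
    start = (-4.0, -3.0)
    src = [VentSite("s", lon=start[0], lat=start[1])]
    traj = dse.advect_particles(field, src, _spec(duration_days=30.0))
    end = np.array([traj.lon[0, 0, 0, -1], traj.lat[0, 0, 0, -1]])

    # independent oracle: plain RK4 loop at dt = 0.25 h on its own
    # interpolators over the same velocity snapshot
    ui = RegularGridInterpolator((grid.lat, grid.lon), field.u[0])
    vi = RegularGridInterpolator((grid.lat, grid.lon), field.v[0])

    def rhs(p):
        u = float(ui((p[1], p[0])))
        v = float(vi((p[1], p[0])))
        return np.array([u * 86400 / meters_per_degree_lon(p[1]),
                         v * 86400 / M_PER_DEG_LAT])

    p = np.array(start, dtype=float)
    dt = 0.25 / 24.0
    for _ in range(int(30 / dt)):
        k1 = rhs(p)
        k2 = rhs(p + dt / 2 * k1)
        k3 = rhs(p + dt / 2 * k2)
        k4 = rhs(p + dt * k3)
        p = p + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)

    err_km = haversine_m(end[0], end[1], p[0], p[1]) / 1000.0
    assert err_km < 1.0


def test_transport_frequency_downstream_and_upstream():
    grid = _equatorial_grid()
    field = _uniform_field(grid, 0.1)
    # 180 days at 0.1 m/s ~ 14 degrees east at the equator
    src = [VentSite("src", lon=-8.0, lat=0.0)]
    sites = [VentSite("down", lon=-1.0, lat=0.0),    # on the path
             VentSite("up", lon=-12.0, lat=0.0),     # upstream
             VentSite("far", lon=9.0, lat=0.0)]      # beyond U*T + radius
    spec = _spec(capture_radius_km=10.0)
    traj = dse.advect_particles(field, src, spec)
    P = dse.transport_frequency(traj, sites, spec)
    assert P.P[0, 0] == 1.0
    assert P.P[0, 1] == 0.0
    assert P.P[0, 2] == 0.0


def test_geometric_reach_bound():
    """In uniform flow of speed U no site beyond U*T + radius connects."""
    grid = _equatorial_grid()
    u = 0.05
    field = _uniform_field(grid, u)
    spec = _spec(capture_radius_km=50.0, particles_per_release=3,
                 diffusivity_m2s=0.0)
    src = [VentSite("s", lon=-8.0, lat=0.0)]
    reach_km = u * 86400 * 180 / 1000.0 + 50.0
    sites = [VentSite(f"d{i}", lon=-8.0 + dlon, lat=0.0)
             for i, dlon in enumerate((2.0, 5.0, 9.0, 12.0))]
    traj = dse.advect_particles(field, src, spec)
    P = dse.transport_frequency(traj, sites, spec)
    for j, s in enumerate(sites):
        d_km = haversine_m(-8.0, 0.0, s.lon, s.lat) / 1000.0
        if d_km > reach_km + 1e-6:
            assert P.P[0, j] == 0.0


def test_diffusive_transport_within_binomial_interval_of_oracle():
    """With K > 0, the package's P lies inside the 95% binomial interval of
    an independent random-walk re-simulation (different seed, 10x particles)."""
    from scipy import stats

    grid = _equatorial_grid()
    u, K, radius_km, T_days = 0.1, 500.0, 30.0, 60.0
    field = _uniform_field(grid, u, days=120.0)
    dest = VentSite("d", lon=-8.0 + 4.0, lat=1.0)   # off-axis: diffusion-limited
    src = [VentSite("s", lon=-8.0, lat=0.0)]
    n_rel = 40
    spec = _spec(particles_per_release=5,
                 release_times_days=tuple(float(i) for i in range(n_rel)),
                 duration_days=T_days, diffusivity_m2s=K,
                 capture_radius_km=radius_km, seed=11)
    traj = dse.advect_particles(field, src, spec)
    P = dse.transport_frequency(traj, [dest], spec).P[0, 0]

    # independent brute-force random walk (Euler steps, own seed, 10x events)
    rng = np.random.default_rng(987654)
    dt_days = spec.dt_hours / 24.0
    n_steps = int(T_days / dt_days)
    n_events = 10 * n_rel
    hits = 0
    sd_deg_lat = np.sqrt(2 * K * dt_days * 86400) / M_PER_DEG_LAT
    for _ in range(n_events):
        lon = np.full(spec.particles_per_release, -8.0)
        lat = np.zeros(spec.particles_per_release)
        connected = False
        for _ in range(n_steps):
            lon = lon + (u * 86400 * dt_days) / meters_per_degree_lon(lat) \
                + rng.normal(0, np.sqrt(2 * K * dt_days * 86400), lon.size) \
                / meters_per_degree_lon(lat)
            lat = lat + rng.normal(0, sd_deg_lat, lat.size)
            if np.any(haversine_m(lon, lat, dest.lon, dest.lat)
                      <= radius_km * 1000.0):
                connected = True
                break
        hits += connected
    p_oracle = hits / n_events
    # binomial 95% interval for the package's n_rel release events at the
    # oracle-estimated connection probability
    lo, hi = stats.binom.interval(0.95, n_rel, max(min(p_oracle, 1 - 1e-9), 1e-9))
    assert lo / n_rel - 1e-9 <= P <= hi / n_rel + 1e-9


def test_p_nondecreasing_in_capture_radius():
    grid = _equatorial_grid()
    field = _uniform_field(grid, 0.1)
    src = [VentSite("s", lon=-8.0, lat=0.0)]
    dest = [VentSite("d", lon=-4.0, lat=0.7)]
    spec_small = _spec(particles_per_release=4, diffusivity_m2s=300.0,
                       release_times_days=tuple(range(10)), capture_radius_km=20.0)
    traj = dse.advect_particles(field, src, spec_small)
    p_small = dse.transport_frequency(traj, dest, spec_small).P[0, 0]
    spec_big = _spec(particles_per_release=4, diffusivity_m2s=300.0,
                     release_times_days=tuple(range(10)), capture_radius_km=80.0)
    p_big = dse.transport_frequency(traj, dest, spec_big).P[0, 0]
    assert p_big >= p_small
    assert 0.0 <= p_small <= 1.0 and 0.0 <= p_big <= 1.0


def test_solid_boundary_freezes_and_flags():
    grid = _equatorial_grid(span_deg=10.0, n=11)
    field = _uniform_field(grid, 0.5)          # exits the box well before 180 d
    src = [VentSite("s", lon=4.0, lat=0.0)]
    traj = dse.advect_particles(field, src, _spec())
    assert traj.flagged.all()
    assert traj.lon.max() <= grid.lon_edges()[-1] + 1e-9


def _matrix(P, ids=("a", "b")):
    return ConnectivityMatrix(P=np.asarray(P, float), source_ids=list(ids),
                              destination_ids=list(ids), n_releases=10)


def test_compare_scenarios_worked_examples():
    control = _matrix([[0.2, 0.4], [0.3, 0.5]])
    future = _matrix([[0.5, 0.15], [0.0, 0.6]])
    delta = dse.compare_scenarios(future, control)
    assert delta.classes[0, 0] == "enhanced"   # ratio 2.5 > 2
    assert delta.classes[0, 1] == "reduced"    # ratio 0.375 < 0.5
    assert delta.classes[1, 0] == "lost"       # 0.3 -> 0
    assert delta.classes[1, 1] == "unchanged"  # ratio 1.2
    assert delta.ratio[0, 0] == pytest.approx(2.5)


def test_compare_scenarios_novel_and_site_mismatch():
    control = _matrix([[0.0, 0.1], [0.2, 0.3]])
    future = _matrix([[0.4, 0.1], [0.2, 0.3]])
    delta = dse.compare_scenarios(future, control)
    assert delta.classes[0, 0] == "novel"
    assert np.isnan(delta.ratio[0, 0])
    with pytest.raises(dse.ValidationError):
        dse.compare_scenarios(future, _matrix([[0.0, 0.1], [0.2, 0.3]],
                                              ids=("x", "y")))


def test_every_control_positive_pair_gets_exactly_one_class():
    rng = np.random.default_rng(5)
    control = _matrix(rng.random((2, 2)))
    future = _matrix(rng.random((2, 2)))
    delta = dse.compare_scenarios(future, control)
    for c in delta.classes.ravel():
        assert c in ("enhanced", "reduced", "lost", "novel", "unchanged")
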