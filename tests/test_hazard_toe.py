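"""Hazard ratios, time of emergence, ensemble averaging, regional extrema."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import deepsea_exposure as dse
from deepsea_exposure.hazard import BaselineStats
from deepsea_exposure.synthetic import TrendSpec


def _cube_from_series(series, grid, driver="temperature", years_start=1951):
    """Cube whose every cell holds the same annual series."""
    series = np.asarray(series, dtype=float)
    vals = np.tile(series[:, None, None], (1,) + grid.shape)
    return dse.ClimateCube(driver=driver, scenario="rcp85", model_id="t",
                           grid=grid,
                           years=np.arange(years_start, years_start + series.size),
                           values=vals)


def _baseline(grid, mean=0.0, sd=1.0, driver="temperature"):
    return BaselineStats(driver=driver, window=(1951, 2000),
                         mean_hist=np.full(grid.shape, float(mean)),
                         sd_hist=np.full(grid.shape, float(sd)),
                         grid=grid, mask=np.zeros(grid.shape, bool))


# ---------------------------------------------------------------------------
# baseline statistics
# ---------------------------------------------------------------------------

def test_baseline_constant_series(tiny_grid):
    cube = _cube_from_series([10.0] * 50, tiny_grid)
    base = dse.baseline_stats(cube)
    np.testing.assert_allclose(base.mean_hist, 10.0)
    np.testing.assert_allclose(base.sd_hist, 0.0)


def test_baseline_two_level_series(tiny_grid):
    cube = _cube_from_series([9.0] * 25 + [11.0] * 25, tiny_grid)
    base = dse.baseline_stats(cube)
    np.testing.assert_allclose(base.mean_hist, 10.0)
    np.testing.assert_allclose(base.sd_hist, np.sqrt(50.0 / 49.0))


def test_baseline_linear_ramp(tiny_grid):
    cube = _cube_from_series(np.arange(50.0), tiny_grid)
    base = dse.baseline_stats(cube)
    np.testing.assert_allclose(base.mean_hist, 24.5)
    # sample variance of 0..n-1 is n(n+1)/12
    np.testing.assert_allclose(base.sd_hist, np.sqrt(50 * 51 / 12.0))


def test_baseline_window_not_covered(tiny_grid):
    cube = _cube_from_series(np.zeros(30), tiny_grid)  # 1951-1980 only
    with pytest.raises(dse.ValidationError):
        dse.baseline_stats(cube)


# ---------------------------------------------------------------------------
# hazard
# ---------------------------------------------------------------------------

def _hazard_for(driver, mean_hist, sd, future_value, grid):
    series = np.concatenate([np.full(50, mean_hist),
                             np.full(100, future_value)])
    cube = _cube_from_series(series, grid, driver=driver)
    base = _baseline(grid, mean=mean_hist, sd=sd, driver=driver)
    return dse.driver_hazard(cube, base, (2081, 2100))


def test_hazard_temperature_warming(tiny_grid):
    h = _hazard_for("temperature", 10.0, 0.5, 11.0, tiny_grid)
    np.testing.assert_allclose(h.hazard_signed, 2.0)
    np.testing.assert_allclose(h.harmful_magnitude, 2.0)


def test_hazard_ph_decline(tiny_grid):
    h = _hazard_for("ph", 8.0, 0.05, 7.9, tiny_grid)
    np.testing.assert_allclose(h.hazard_signed, -2.0)
    np.testing.assert_allclose(h.harmful_magnitude, 2.0)


def test_hazard_oxygen_gain_clamped(tiny_grid):
    h = _hazard_for("oxygen", 10.0, 2.5, 15.0, tiny_grid)
    np.testing.assert_allclose(h.hazard_signed, 2.0)
    np.testing.assert_allclose(h.harmful_magnitude, 0.0)


def test_hazard_zero_sd_cells(tiny_grid):
    # zero change -> hazard 0; nonzero change -> masked undefined
    h0 = _hazard_for("temperature", 10.0, 0.0, 10.0, tiny_grid)
    np.testing.assert_allclose(h0.hazard_signed, 0.0)
    h1 = _hazard_for("temperature", 10.0, 0.0, 11.0, tiny_grid)
    assert np.all(h1.mask)


def test_hazard_driver_mismatch(tiny_grid):
    cube = _cube_from_series(np.zeros(150), tiny_grid, driver="oxygen")
    with pytest.raises(dse.ValidationError):
        dse.driver_hazard(cube, _baseline(tiny_grid, driver="ph"), (2081, 2100))


def _four_hazards(tiny_grid, harmful=(2.0, 2.0, 2.0, 2.0)):
    out = {}
    for d, mag in zip(dse.DRIVERS, harmful):
        sign = dse.HARMFUL_SIGN[d]
        out[d] = _hazard_for(d, 10.0, 1.0, 10.0 + sign * mag, tiny_grid)
    return out


def test_cumulative_hazard_sum(tiny_grid):
    cum = dse.cumulative_negative_hazard(_four_hazards(tiny_grid))
    np.testing.assert_allclose(cum.values, 8.0)


def test_cumulative_hazard_beneficial_clamped(tiny_grid):
    hz = _four_hazards(tiny_grid)
    # oxygen increasing is beneficial -> clamped to 0
    hz["oxygen"] = _hazard_for("oxygen", 10.0, 1.0, 12.0, tiny_grid)
    cum = dse.cumulative_negative_hazard(hz)
    np.testing.assert_allclose(cum.values, 6.0)


def test_cumulative_hazard_zero_change(tiny_grid):
    cum = dse.cumulative_negative_hazard(_four_hazards(tiny_grid, (0, 0, 0, 0)))
    np.testing.assert_allclose(cum.values, 0.0)


def test_cumulative_hazard_missing_driver(tiny_grid):
    hz = _four_hazards(tiny_grid)
    del hz["ph"]
    with pytest.raises(dse.ValidationError, match="ph"):
        dse.cumulative_negative_hazard(hz)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(delta=st.floats(-5, 5, allow_nan=False), sd=st.floats(0.1, 4),
       driver=st.sampled_from(dse.DRIVERS))
def test_hazard_linearity(delta, sd, driver):
    """Doubling the change at fixed sd doubles the signed hazard."""
    grid = dse.regular_grid(2, 2)
    h1 = _hazard_for(driver, 10.0, sd, 10.0 + delta, grid)
    h2 = _hazard_for(driver, 10.0, sd, 10.0 + 2 * delta, grid)
    np.testing.assert_allclose(h2.hazard_signed, 2 * h1.hazard_signed,
                               rtol=1e-9, atol=1e-9)
    assert np.all(h1.harmful_magnitude <= np.abs(h1.hazard_signed) + 1e-12)


def test_cumulative_hazard_order_invariant_and_bounded(tiny_grid, rng):
    hz = {}
    for d in dse.DRIVERS:
        hz[d] = _hazard_for(d, 10.0, 1.0, 10.0 + rng.normal(), tiny_grid)
    c1 = dse.cumulative_negative_hazard(hz)
    reordered = {d: hz[d] for d in reversed(dse.DRIVERS)}
    c2 = dse.cumulative_negative_hazard(reordered)
    np.testing.assert_array_equal(c1.values, c2.values)
    bound = sum(np.abs(h.hazard_signed) for h in hz.values())
    assert np.all(c1.values <= bound + 1e-12)


# ---------------------------------------------------------------------------
# time of emergence
# ---------------------------------------------------------------------------

def _trend_cube(grid, b, years=range(1951, 2101), driver="temperature"):
    yrs = np.arange(years.start, years.stop)
    series = b * np.maximum(0, yrs - 2001)
    return _cube_from_series(series, grid, driver=driver)


def test_toe_noise_free_linear_trend(tiny_grid):
    cube = _trend_cube(tiny_grid, 0.1)
    toe = dse.time_of_emergence(cube, _baseline(tiny_grid, 0.0, 1.0), k=1.0)
    assert np.all(toe.years == 2011)
    assert not toe.censored.any()


def test_toe_zero_trend_censored(tiny_grid):
    cube = _trend_cube(tiny_grid, 0.0)
    toe = dse.time_of_emergence(cube, _baseline(tiny_grid, 0.0, 1.0))
    assert toe.censored.all()
    assert np.all(toe.years == 2101)


def test_toe_first_vs_sustained_on_spiky_series(tiny_grid):
    # single spike at 2010, sustained exceedance from 2050
    yrs = np.arange(1951, 2101)
    series = np.zeros(yrs.size)
    series[yrs == 2010] = 5.0
    series[yrs >= 2050] = 5.0
    cube = _cube_from_series(series, tiny_grid)
    base = _baseline(tiny_grid, 0.0, 1.0)
    first = dse.time_of_emergence(cube, base, rule="first")
    sustained = dse.time_of_emergence(cube, base, rule="sustained")
    assert np.all(first.years == 2010)
    assert np.all(sustained.years == 2050)
    assert np.all(sustained.years >= first.years)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(b1=st.floats(0.02, 0.3), scale=st.floats(1.0, 4.0),
       k=st.floats(0.5, 2.0), k2=st.floats(0.0, 1.5))
def test_toe_monotone_in_trend_and_k(b1, scale, k, k2):
    """Stronger trends never delay emergence; larger k never hastens it."""
    grid = dse.regular_grid(2, 2)
    base = _baseline(grid, 0.0, 1.0)
    t_weak = dse.time_of_emergence(_trend_cube(grid, b1), base, k=k)
    t_strong = dse.time_of_emergence(_trend_cube(grid, b1 * scale), base, k=k)
    assert np.all(t_strong.years <= t_weak.years)
    t_bigger_k = dse.time_of_emergence(_trend_cube(grid, b1), base, k=k + k2)
    assert np.all(t_bigger_k.years >= t_weak.years)


def test_sustained_never_before_first_on_noisy_cube(tiny_grid):
    cube = dse.gen_climate_cube(
        TrendSpec(baseline_sd=1.0, trend_per_year=0.05, ar1_phi=0.4, seed=3),
        tiny_grid)
    base = dse.baseline_stats(cube)
    first = dse.time_of_emergence(cube, base, rule="first")
    sustained = dse.time_of_emergence(cube, base, rule="sustained")
    assert np.all(sustained.years >= first.years)


def test_toe_all_drivers_max_and_censoring(tiny_grid):
    grid = tiny_grid
    base = _baseline(grid, 0.0, 1.0)
    years_by_driver = {"temperature": 2031, "oxygen": 2045,
                       "ph": 2050, "poc_flux": 2060}
    toes = {}
    for d, year in years_by_driver.items():
        yrs = np.arange(1951, 2101)
        series = np.where(yrs >= year, 5.0 * dse.HARMFUL_SIGN[d], 0.0)
        toes[d] = dse.time_of_emergence(
            _cube_from_series(series, grid, driver=d),
            _baseline(grid, 0.0, 1.0, driver=d))
        assert np.all(toes[d].years == year)
    combined = dse.toe_all_drivers(toes)
    assert np.all(combined.years == 2060)

    # censor one driver -> all-driver ToE censored
    toes["poc_flux"] = dse.time_of_emergence(
        _trend_cube(grid, 0.0, driver="poc_flux"),
        _baseline(grid, 0.0, 1.0, driver="poc_flux"))
    combined = dse.toe_all_drivers(toes)
    assert combined.censored.all()

    # idempotence: four identical fields -> the same field
    same = dse.toe_all_drivers({d: toes["temperature"] for d in dse.DRIVERS})
    np.testing.assert_array_equal(same.years, toes["temperature"].years)


# ---------------------------------------------------------------------------
# ensemble averaging
# ---------------------------------------------------------------------------

def test_ensemble_identity_and_mean(tiny_grid):
    cube = _cube_from_series(np.arange(150.0), tiny_grid)
    avg = dse.ensemble_average([cube, cube, cube])
    np.testing.assert_array_equal(avg.values, cube.values)

    cubes = [_cube_from_series(np.full(150, v), tiny_grid) for v in (1.0, 2.0, 3.0)]
    avg = dse.ensemble_average(cubes)
    np.testing.assert_allclose(avg.values, 2.0)
    assert "ensemble(" in avg.model_id


def test_ensemble_mean_matches_bruteforce(tiny_grid, rng):
    cubes = [_cube_from_series(rng.normal(size=150), tiny_grid) for _ in range(5)]
    avg = dse.ensemble_average(cubes)
    brute = np.zeros_like(avg.values)
    for c in cubes:
        brute += c.values
    brute /= len(cubes)
    np.testing.assert_allclose(avg.values, brute, atol=1e-12)


def test_ensemble_hazard_beats_single_members(small_grid):
    """Ensemble-averaged hazard has lower RMSE against the analytic truth
    than any single member, over replicated 3-member ensembles."""
    b, sd = 0.05, 1.0
    window = (2081, 2100)
    truth = b * (np.mean(range(2081, 2101)) - 2001) / sd
    wins = 0
    n_rep = 100
    grid = dse.regular_grid(6, 6)
    for rep in range(n_rep):
        members = [dse.gen_climate_cube(
            TrendSpec(baseline_sd=sd, trend_per_year=b, seed=1000 * rep + m),
            grid) for m in range(3)]
        hazards = []
        for c in members:
            base = dse.baseline_stats(c)
            hazards.append(dse.driver_hazard(c, base, window).as_field(signed=True))
        ens_h = dse.ensemble_average_fields(hazards).values
        rmse = lambda h: float(np.sqrt(np.mean((h - truth) ** 2)))
        if rmse(ens_h) < min(rmse(h.values) for h in hazards):
            wins += 1
    assert wins >= 0.9 * n_rep


# ---------------------------------------------------------------------------
# regional summaries
# ---------------------------------------------------------------------------

def _toe_from_years(years_2d, grid, horizon=2100):
    return dse.ToEField(driver="all_drivers",
                        years=np.asarray(years_2d, dtype=int), grid=grid,
                        mask=np.zeros(grid.shape, bool), horizon=horizon)


def test_region_minmax_censored_handling():
    grid = dse.Grid(lat=np.array([0.0]), lon=np.array([0.0, 1.0, 2.0]))
    toe = _toe_from_years([[2028, 2035, 2101]], grid)
    from shapely.geometry import box
    regions = dse.RegionSet([dse.Region("r", "custom", box(-0.5, -0.5, 2.5, 0.5))])
    (s,) = dse.region_minmax(toe, regions)
    assert s.min == 2028
    assert s.max == ">2100"
    assert s.censored_n == 1 and s.n_cells == 3


def test_region_minmax_single_cell():
    grid = dse.Grid(lat=np.array([0.0, 1.0]), lon=np.array([0.0, 1.0]))
    field = dse.Field2D(grid=grid, values=np.array([[3.0, 9.0], [1.0, 7.0]]))
    from shapely.geometry import box
    regions = dse.RegionSet([dse.Region("one", "custom",
                                        box(0.6, 0.6, 1.4, 1.4))])
    (s,) = dse.region_minmax(field, regions)
    assert s.min == s.max == 7.0 and s.n_cells == 1


def test_region_minmax_matches_bruteforce_scan(rng):
    grid = dse.regular_grid(15, 15, (0, 14), (0, 14))
    from shapely.geometry import box
    for _ in range(25):
        vals = rng.normal(size=grid.shape)
        field = dse.Field2D(grid=grid, values=vals)
        r0, r1 = sorted(rng.integers(0, 15, 2).tolist())
        c0, c1 = sorted(rng.integers(0, 15, 2).tolist())
        regions = dse.RegionSet([dse.Region(
            "rect", "custom", box(c0 - 0.5, r0 - 0.5, c1 + 0.5, r1 + 0.5))])
        (s,) = dse.region_minmax(field, regions)
        member = vals[r0:r1 + 1, c0:c1 + 1]
        assert s.min == pytest.approx(member.min())
        assert s.max == pytest.approx(member.max())
        assert s.n_cells == member.size


def test_region_minmax_empty_region_warns():
    grid = dse.Grid(lat=np.array([0.0, 1.0]), lon=np.array([0.0, 1.0]))
    field = dse.Field2D(grid=grid, values=np.zeros(grid.shape))
    from shapely.geometry import box
    regions = dse.RegionSet([dse.Region("off", "custom", box(10, 10, 11, 11))])
    (s,) = dse.region_minmax(field, regions)
    assert s.n_cells == 0 and s.min is None and s.max is None


def test_summaries_to_frame_columns(tiny_grid):
    toe = _toe_from_years(np.full(tiny_grid.shape, 2050), tiny_grid)
    from shapely.geometry import box
    regions = dse.RegionSet([dse.Region("r", "apei", box(-200, -100, 200, 100))])
    df = dse.summaries_to_frame(dse.region_minmax(toe, regions))
    assert list(df.columns) == ["region", "category", "scenario", "metric",
                                "window", "min", "max", "censored_n", "n_cells"]
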