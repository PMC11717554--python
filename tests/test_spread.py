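"""Suitability, kernel discretisation, convolution, stepping and evaluation."""

import numpy as np
import pytest
from shapely.geometry import LineString

from poppyspread.kernels import KernelFit
from poppyspread.spatial_core import GridSpec, OccurrenceRecord, Raster
from poppyspread.spread import (
    NEVER,
    OccupancyHistory,
    build_suitability,
    discretize_kernel,
    elevation_threshold,
    establishment_probability,
    run_simulation,
    sensitivity,
    step_year,
)
from poppyspread.synth import LandscapeBundle


def _rec(x, y, year=2014):
    return OccurrenceRecord(x, y, year, 1, "systematic_grid")


@pytest.fixture()
def spec():
    return GridSpec(0, 0, 5.0, 20, 20)


# ---------------------------------------------------------------------------
# Suitability
# ---------------------------------------------------------------------------


def test_elevation_threshold_is_max_observed(spec):
    dem = Raster(spec, np.tile(np.linspace(0, 137, 20), (20, 1)))
    recs = [_rec(*spec.cell_centre(3, c)) for c in (1, 10, 19)]
    assert elevation_threshold(recs, dem) == pytest.approx(137.0)
    assert elevation_threshold(recs + recs, dem) == pytest.approx(137.0)


def test_elevation_threshold_single_point(spec):
    dem = Raster(spec, np.full((20, 20), 42.0))
    assert elevation_threshold([_rec(50, 50)], dem) == 42.0


def test_all_water_is_unsuitable(spec):
    dem = Raster(spec, np.zeros((20, 20)))
    water = Raster(spec, np.ones((20, 20), dtype=bool))
    assert not build_suitability(dem, water, 137.0).raster.values.any()


def test_no_water_infinite_threshold_all_suitable(spec):
    dem = Raster(spec, np.random.default_rng(0).uniform(0, 500, (20, 20)))
    water = Raster(spec, np.zeros((20, 20), dtype=bool))
    assert build_suitability(dem, water, np.inf).raster.values.all()


def test_suitability_matches_boolean_formula(spec, rng):
    dem = Raster(spec, rng.uniform(0, 200, (20, 20)))
    water = Raster(spec, rng.random((20, 20)) < 0.3)
    got = build_suitability(dem, water, 137.0).raster.values
    expect = (~water.values) & (dem.values <= 137.0)
    np.testing.assert_array_equal(got, expect)


# ---------------------------------------------------------------------------
# Kernel discretisation
# ---------------------------------------------------------------------------


def test_discrete_kernel_dihedral_symmetry():
    fit = KernelFit("rayleigh", (0.0, 10.0))
    k = discretize_kernel(fit, 5.0, 0.99).weights
    np.testing.assert_allclose(k, k[::-1, :])
    np.testing.assert_allclose(k, k[:, ::-1])
    np.testing.assert_allclose(k, k.T)


def test_exponential_truncation_radius_closed_form():
    fit = KernelFit("exponential", (0.0, 2.26))
    k = discretize_kernel(fit, 5.0, 0.999)
    assert k.radius == int(np.ceil(2.26 * np.log(1000) / 5.0))


def test_truncation_radius_monotone_in_quantile():
    fit = KernelFit("exponential", (0.0, 20.0))
    r1 = discretize_kernel(fit, 5.0, 0.95).radius
    r2 = discretize_kernel(fit, 5.0, 0.999).radius
    assert r2 >= r1


def test_cauchy_infinite_quantile_capped_with_warning():
    fit = KernelFit("cauchy", (22.2, 10.0))
    with pytest.warns(UserWarning, match="capping"):
        k = discretize_kernel(fit, 5.0, 0.9999, max_radius=30)
    assert k.radius == 30


def test_kernel_weights_nonnegative_and_bounded():
    for fam, params in [("lognormal", (0.58, -9.96, 33.66)),
                        ("exponential", (0.0, 2.26))]:
        k = discretize_kernel(KernelFit(fam, params), 5.0, 0.99)
        assert (k.weights >= 0).all()
        assert k.weights.sum() <= 1.0 + 1e-12


# ---------------------------------------------------------------------------
# Establishment probability and stepping
# ---------------------------------------------------------------------------


def test_empty_state_zero_probability():
    k = discretize_kernel(KernelFit("exponential", (0.0, 5.0)), 5.0, 0.99)
    p = establishment_probability(np.zeros((20, 20), bool), k, None, None)
    assert np.all(p == 0)


def test_single_source_impulse_response():
    k = discretize_kernel(KernelFit("exponential", (0.0, 5.0)), 5.0, 0.99)
    state = np.zeros((21, 21), bool)
    state[10, 10] = True
    p = establishment_probability(state, k, None, None)
    r = k.radius
    np.testing.assert_allclose(
        p[10 - r : 10 + r + 1, 10 - r : 10 + r + 1], k.weights, atol=1e-12
    )


def test_fft_convolution_matches_direct_loop(rng):
    k = discretize_kernel(KernelFit("rayleigh", (0.0, 8.0)), 5.0, 0.99)
    state = rng.random((20, 20)) < 0.2
    p = establishment_probability(state, k, None, None)
    r = k.radius
    direct = np.zeros((20, 20))
    for i, j in zip(*np.nonzero(state)):
        for di in range(-r, r + 1):
            for dj in range(-r, r + 1):
                ii, jj = i + di, j + dj
                if 0 <= ii < 20 and 0 <= jj < 20:
                    direct[ii, jj] += k.weights[r + di, r + dj]
    np.testing.assert_allclose(p, np.clip(direct, 0, 1), atol=1e-9)


def test_trail_scenario_complement_product(rng):
    kl = discretize_kernel(KernelFit("exponential", (0.0, 4.0)), 5.0, 0.99)
    kt = discretize_kernel(KernelFit("exponential", (0.0, 12.0)), 5.0, 0.99)
    state = rng.random((30, 30)) < 0.15
    trail = np.zeros((30, 30), bool)
    trail[14, :] = True
    p_local = establishment_probability(state, kl, None, None)
    p_both = establishment_probability(state, kl, kt, trail, "trail_effect")
    assert np.all(p_both >= p_local - 1e-12)
    assert np.all((p_both >= 0) & (p_both <= 1))


def test_step_certain_establishment(rng):
    state = np.zeros((10, 10), bool)
    suit = np.ones((10, 10), bool)
    suit[0, 0] = False
    nxt = step_year(state, np.ones((10, 10)), suit, rng)
    assert nxt.sum() == 99 and not nxt[0, 0]


def test_step_zero_probability_is_identity(rng):
    state = np.random.default_rng(1).random((10, 10)) < 0.5
    nxt = step_year(state, np.zeros((10, 10)), np.ones((10, 10), bool), rng)
    np.testing.assert_array_equal(nxt, state)


def test_step_bernoulli_rate_within_3_sigma(rng):
    n = 100
    state = np.zeros((n, n), bool)
    p = np.full((n, n), 0.3)
    nxt = step_year(state, p, np.ones((n, n), bool), rng)
    frac = nxt.mean()
    assert abs(frac - 0.3) < 3 * np.sqrt(0.3 * 0.7 / n**2)


# ---------------------------------------------------------------------------
# Full simulation
# ---------------------------------------------------------------------------


def _flat_landscape(n=60, cell=5.0):
    spec = GridSpec(0, 0, cell, n, n)
    dem = Raster(spec, np.full((n, n), 10.0))
    water = Raster(spec, np.zeros((n, n), bool))
    mid = n * cell / 2
    trails = {"south": LineString([(mid, mid), (mid, 10.0)])}
    return LandscapeBundle(dem, water, trails, (mid, mid), spec)


LOCAL = KernelFit("lognormal", (0.8611, -0.0799, 1.3177), assumption="local")
TRAIL = KernelFit("lognormal", (0.5760, -9.9562, 33.6560), assumption="trail")


def test_zero_year_run_only_init_cell():
    land = _flat_landscape()
    h = run_simulation(land, LOCAL, None, "no_trail_effect", 1928, 1928,
                       land.station, n_replicates=2, base_seed=3)
    for arr in h.arrival_years:
        assert (arr != NEVER).sum() == 1
        assert arr[arr != NEVER][0] == 1928


def test_same_seed_reproduces_history():
    land = _flat_landscape()
    kw = dict(scenario="trail_effect", start_year=1928, end_year=1950,
              init_point=land.station, n_replicates=2, base_seed=11)
    h1 = run_simulation(land, LOCAL, TRAIL, **kw)
    h2 = run_simulation(land, LOCAL, TRAIL, **kw)
    for a, b in zip(h1.arrival_years, h2.arrival_years):
        np.testing.assert_array_equal(a, b)


def test_occupancy_monotone_and_respects_suitability():
    land = _flat_landscape()
    land.dem.values[:10, :] = 200.0  # unsuitable band above threshold
    h = run_simulation(land, LOCAL, TRAIL, "trail_effect", 1928, 1965,
                       land.station, n_replicates=3, base_seed=5,
                       elev_threshold=137.0)
    for rep in range(3):
        prev = None
        for year in range(1928, 1966):
            occ = h.occupied_by(year, rep)
            if prev is not None:
                assert not np.any(prev & ~occ)
            prev = occ
        assert not h.occupied_by(1965, rep)[:10, :].any()


def test_unsuitable_init_cell_errors():
    land = _flat_landscape()
    land.water_mask.values[:, :] = True
    with pytest.raises(ValueError):
        run_simulation(land, LOCAL, None, "no_trail_effect", 1928, 1930,
                       land.station, base_seed=0)


def test_trail_scenario_spreads_farther_than_local(landscape):
    """Paired-seed scenario ordering on the synthetic landscape."""
    wins = 0
    for k in range(4):
        ht = run_simulation(landscape, LOCAL, TRAIL, "trail_effect", 1928,
                            1978, landscape.station, n_replicates=1,
                            base_seed=100 + k)
        hl = run_simulation(landscape, LOCAL, None, "no_trail_effect", 1928,
                            1978, landscape.station, n_replicates=1,
                            base_seed=100 + k)
        wins += ht.occupied_by(1978).sum() > hl.occupied_by(1978).sum()
    assert wins >= 3


def test_mean_arrival_ignores_never_colonised():
    spec = GridSpec(0, 0, 5.0, 2, 2)
    a = np.array([[1930, NEVER], [1940, NEVER]])
    b = np.array([[1932, NEVER], [NEVER, NEVER]])
    h = OccupancyHistory(spec, 1928, 1950, [a, b], "test")
    mean = h.mean_arrival.values
    assert mean[0, 0] == pytest.approx(1931.0)
    assert mean[1, 0] == pytest.approx(1940.0)
    assert np.isnan(mean[0, 1])
    assert h.n_colonised.values[0, 0] == 2


# ---------------------------------------------------------------------------
# Sensitivity
# ---------------------------------------------------------------------------


def _history_with(spec, occupied_cells, year=2014):
    arr = np.full((spec.n_rows, spec.n_cols), NEVER, dtype=np.int64)
    for r, c in occupied_cells:
        arr[r, c] = 1930
    return OccupancyHistory(spec, 1928, year, [arr], "test")


def test_sensitivity_full_coverage(spec):
    h = _history_with(spec, [(r, c) for r in range(20) for c in range(20)])
    obs = [_rec(10, 10), _rec(60, 60)]
    assert sensitivity(h, obs, 2014, eval_block=50).sensitivity == 1.0


def test_sensitivity_empty_simulation(spec):
    h = _history_with(spec, [])
    res = sensitivity(h, [_rec(10, 10)], 2014, eval_block=50)
    assert res.sensitivity == 0.0 and res.tp + res.fa == 1


def test_sensitivity_two_thirds(spec):
    # occupied cells in blocks (0,0) and (1,1) of 25-m blocks
    h = _history_with(spec, [(1, 1), (6, 6)])
    obs = [_rec(10, 10), _rec(35, 35), _rec(85, 85)]
    res = sensitivity(h, obs, 2014, eval_block=25)
    assert res.tp == 2 and res.fa == 1
    assert res.sensitivity == pytest.approx(2 / 3)


def test_sensitivity_requires_observations(spec):
    with pytest.raises(ValueError):
        sensitivity(_history_with(spec, []), [], 2014)
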