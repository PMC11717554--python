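"""Synthetic coastal-strandflat datasets with the structure the pipeline assumes.

The generator emulates a Svalbard-like study area: a gently rising coastal
strandflat DEM (0-150 m) with sea to the west and a few low-lying lakes, a
station (introduction point) near the shore, and two trails leaving the
station — one running south along a beach ridge, one east along the coast.
On top of the landscape it produces (i) a ground-truth occupancy history by
running the spread simulator with known "true" establishment kernels,
(ii) systematic 1x1-km presence surveys and a T-shaped-transect abundance
survey with the field protocol's stop rule, and (iii) a 10-cm luminance /
RGB scene in which trail and gravel pixels are brighter than vegetated
ground, with poppy positions placed with a configurable terrain preference.

Every output is a pure function of (config, seed). The default true kernels
are the best fitted local and trail establishment kernels of the study this
package reproduces, so closed-loop parameter-recovery tests run under the
study's own conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString

from .kernels import KernelFit
from .spatial_core import GridSpec, OccurrenceRecord, Raster, points_to_cells
from . import spread as spread_mod

#: Rec. 709 channel weights used when synthesising RGB from luminance.
_LUM_WEIGHTS = np.array([0.2126, 0.7152, 0.0722])


def _default_local_kernel() -> KernelFit:
    return KernelFit("lognormal", (0.8611, -0.0799, 1.3177), assumption="local")


def _default_trail_kernel() -> KernelFit:
    return KernelFit("lognormal", (0.5760, -9.9562, 33.6560), assumption="trail")


@dataclass(frozen=True)
class SurveyProtocol:
    """T-shaped transect protocol walked along the trail from the trailhead."""

    transect_spacing: float = 50.0
    plot_length: float = 50.0
    plot_width: float = 2.0
    off_trail_length: float = 100.0
    stop_rule: int = 5  # consecutive empty trail plots before stopping
    off_trail_side: str = "east"

    def __post_init__(self) -> None:
        if min(self.transect_spacing, self.plot_length, self.plot_width,
               self.off_trail_length) <= 0:
            raise ValueError("protocol lengths must be positive")
        if self.stop_rule < 1:
            raise ValueError("stop_rule must be >= 1")


@dataclass
class SynthConfig:
    seed: int = 0
    n_rows: int = 240
    n_cols: int = 240
    cell_size: float = 5.0
    start_year: int = 1928
    end_year: int = 2018
    survey_years: tuple[int, ...] = (1994, 2014, 2018)
    true_local_kernel: KernelFit = field(default_factory=_default_local_kernel)
    true_trail_kernel: KernelFit = field(default_factory=_default_trail_kernel)
    elevation_threshold: float = 137.0
    #: Expected share of sampled individuals that fall on trail plots.
    trail_share: float = 0.869
    #: Expected number of 50-cm clusters per transect at unit local density;
    #: with mean cluster abundance 2 this reproduces the contemporary
    #: survey's scale of ~28 individuals per transect.
    transect_intensity: float = 14.0
    #: Mean of the Poisson part of cluster abundance (abundance = 1 + Poisson).
    cluster_abundance_mean: float = 1.0
    #: exp(strength * luminance) weighting of poppy placement in the UAV scene;
    #: 0 means no terrain association (null model of the randomisation test).
    terrain_preference_strength: float = 4.0
    n_terrain_points: int = 60
    #: UAV scene geometry: along-trail length and half-width (m), 10-cm pixels.
    scene_length: float = 120.0
    scene_half_width: float = 15.0
    scene_pixel: float = 0.1


@dataclass
class LandscapeBundle:
    dem: Raster
    water_mask: Raster
    trails: dict[str, LineString]
    station: tuple[float, float]
    spec: GridSpec


@dataclass
class TransectSurvey:
    """Records plus per-transect paired abundances for rank tests."""

    records: list[OccurrenceRecord]
    n_transects: int
    on_trail_abundance: np.ndarray
    off_trail_abundance: np.ndarray


@dataclass
class TerrainScene:
    """10-cm luminance + RGB scene with placed poppy positions."""

    luminance: Raster
    rgb: np.ndarray  # (H, W, 3) float in [0, 1], row 0 = southernmost
    points: np.ndarray  # (n, 2) projected metres
    records: list[OccurrenceRecord]


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------


def make_landscape(config: SynthConfig) -> LandscapeBundle:
    """Generate the DEM, water mask, station and two trails.

    Sea lies west of the 0-m contour of the raw elevation field; 2-5 lakes
    are carved into low ground (raw elevation < 25 m), so no water cell sits
    above 60 m. The station is a land cell near the coast; both trails start
    exactly at the station.
    """
    if config.n_rows < 50 or config.n_cols < 50:
        raise ValueError("landscape generation needs a grid of at least 50x50")
    rng = np.random.default_rng(config.seed)
    spec = GridSpec(0.0, 0.0, config.cell_size, config.n_rows, config.n_cols)
    X, Y = spec.centre_mesh()
    extent_x = spec.width

    base = -6.0 + 55.0 * (X / extent_x)
    ridges = 4.0 * np.sin(2.0 * np.pi * X / 180.0)
    noise = gaussian_filter(rng.standard_normal(X.shape), sigma=5.0)
    noise *= 3.0 / max(noise.std(), 1e-12)
    # Coherent coastline: the sea is the western band below the 0-contour of
    # the smooth (alongshore-varying) component, so small-scale relief never
    # punches isolated sea pockets into the strandflat.
    alongshore = gaussian_filter(rng.standard_normal(config.n_rows), sigma=12.0)
    alongshore *= 5.0 / max(alongshore.std(), 1e-12)
    coast_field = base + alongshore[:, None]
    sea = coast_field < 0.0
    raw = base + ridges + noise + alongshore[:, None]
    dem_values = np.where(sea, 0.0, np.clip(raw, 0.0, 150.0))
    water = sea.copy()

    # Station: first persistent-land cell scanning east at 60% of the height.
    st_row = int(0.6 * config.n_rows)
    st_col = None
    for c in range(config.n_cols - 5):
        if np.all(~sea[st_row, c : c + 4]) and np.all(raw[st_row, c : c + 4] > 1.0):
            st_col = c + 1
            break
    if st_col is None:
        raise RuntimeError("no land found for the station; widen the grid")
    station = spec.cell_centre(st_row, st_col)

    # Lakes: 2-5 discs on low ground, kept away from the station.
    n_lakes = int(rng.integers(2, 6))
    low = ~sea & (raw > 1.0) & (raw < 25.0)
    low_rows, low_cols = np.nonzero(low)
    placed = 0
    attempts = 0
    while placed < n_lakes and attempts < 200 and low_rows.size:
        attempts += 1
        i = int(rng.integers(low_rows.size))
        cx, cy = spec.cell_centre(int(low_rows[i]), int(low_cols[i]))
        if math.hypot(cx - station[0], cy - station[1]) < 100.0:
            continue
        radius = float(rng.uniform(15.0, 40.0))
        disc = (X - cx) ** 2 + (Y - cy) ** 2 < radius**2
        water |= disc
        placed += 1

    south = _south_trail(spec, station, rng, water)
    east = _east_trail(spec, station, rng, water)
    dem = Raster(spec, dem_values)
    if water[st_row, st_col]:
        raise RuntimeError("station cell unexpectedly flooded")
    return LandscapeBundle(
        dem=dem,
        water_mask=Raster(spec, water),
        trails={"south": south, "east": east},
        station=station,
        spec=spec,
    )


def _snap_inland(x: float, y: float, spec: GridSpec, water: np.ndarray) -> float:
    """Move a trail vertex east (inland, away from the western sea) until it
    sits on a land cell; returns the adjusted x."""
    step = spec.cell_size
    limit = spec.origin_x + spec.width - 10.0
    while x < limit:
        cells, inside = points_to_cells(np.array([[x, y]]), spec)
        r, c = cells[0]
        if inside[0] and not water[r, c]:
            return x
        x += step
    return x


def _south_trail(spec: GridSpec, station, rng, water: np.ndarray) -> LineString:
    sx, sy = station
    ys = np.arange(sy, spec.origin_y + 30.0, -60.0)
    if ys.size < 2:
        ys = np.array([sy, sy - 60.0])
    xs = sx + 20.0 * np.sin((sy - ys) / 300.0) + rng.normal(0.0, 3.0, ys.size)
    xs[0] = sx
    xs = np.clip(xs, spec.origin_x + 15.0, spec.origin_x + spec.width - 15.0)
    xs = np.array([_snap_inland(x, y, spec, water) for x, y in zip(xs, ys)])
    xs[0] = sx  # trailhead stays at the station
    return LineString(np.column_stack([xs, ys]))


def _east_trail(spec: GridSpec, station, rng, water: np.ndarray) -> LineString:
    sx, sy = station
    xs = np.arange(sx, spec.origin_x + spec.width - 30.0, 60.0)
    if xs.size < 2:
        xs = np.array([sx, sx + 60.0])
    ys = sy + 15.0 * np.sin((xs - sx) / 250.0) + rng.normal(0.0, 3.0, xs.size)
    ys[0] = sy
    ys = np.clip(ys, spec.origin_y + 15.0, spec.origin_y + spec.height - 15.0)
    xs = np.array([_snap_inland(x, y, spec, water) for x, y in zip(xs, ys)])
    xs[0], ys[0] = sx, sy
    return LineString(np.column_stack([xs, ys]))


# ---------------------------------------------------------------------------
# Ground truth and surveys
# ---------------------------------------------------------------------------


def simulate_truth(
    landscape: LandscapeBundle,
    config: SynthConfig,
    n_replicates: int = 1,
) -> spread_mod.OccupancyHistory:
    """Ground-truth occupancy under the trail-effect scenario with the
    configured true kernels (delegates to the spread simulator)."""
    return spread_mod.run_simulation(
        landscape,
        local_fit=config.true_local_kernel,
        trail_fit=config.true_trail_kernel,
        scenario="trail_effect",
        start_year=config.start_year,
        end_year=config.end_year,
        init_point=landscape.station,
        n_replicates=n_replicates,
        base_seed=config.seed,
        elev_threshold=config.elevation_threshold,
    )


def sample_systematic_survey(
    truth: spread_mod.OccupancyHistory,
    year: int,
    block: float = 1000.0,
) -> list[OccurrenceRecord]:
    """Presence per 1-km block: one record at the centre of every block that
    contains at least one occupied cell (replicate 0)."""
    if not (truth.start_year <= year <= truth.end_year):
        raise ValueError(f"year {year} outside simulated range")
    spec = truth.spec
    occ = truth.occupied_by(year)
    rows, cols = np.nonzero(occ)
    if rows.size == 0:
        return []
    xs = spec.origin_x + (cols + 0.5) * spec.cell_size
    ys = spec.origin_y + (rows + 0.5) * spec.cell_size
    blocks = sorted(
        set(
            zip(
                np.floor((xs - spec.origin_x) / block).astype(int),
                np.floor((ys - spec.origin_y) / block).astype(int),
            )
        )
    )
    return [
        OccurrenceRecord(
            x=spec.origin_x + (bx + 0.5) * block,
            y=spec.origin_y + (by + 0.5) * block,
            year=year,
            abundance=1,
            plot_class="systematic_grid",
        )
        for bx, by in blocks
    ]


def _local_density(truth, year: int | None) -> np.ndarray:
    if isinstance(truth, spread_mod.OccupancyHistory):
        occ = truth.occupied_by(year if year is not None else truth.end_year)
        return gaussian_filter(occ.astype(float), sigma=1.0)
    if isinstance(truth, Raster):
        return np.asarray(truth.values, dtype=float)
    return np.asarray(truth, dtype=float)


def sample_transect_survey(
    truth,
    landscape: LandscapeBundle,
    protocol: SurveyProtocol,
    config: SynthConfig,
    seed: int,
    survey_year: int = 2023,
) -> TransectSurvey:
    """Walk the south trail placing T-shaped transects every 50 m.

    Each transect draws a Poisson number of 50-cm clusters proportional to
    the local truth density; each cluster lands on the 2x50-m trail plot
    with probability ``config.trail_share`` and otherwise on the eastward
    100-m off-trail plot. Sampling stops after ``protocol.stop_rule``
    consecutive empty trail plots (or at the end of the trail). Detection
    within plots is perfect.
    """
    rng = np.random.default_rng(seed)
    trail = landscape.trails["south"]
    spacing = protocol.transect_spacing
    if trail.length < 3 * spacing:
        raise ValueError("protocol infeasible: south trail shorter than 3 transects")
    density = _local_density(truth, survey_year if isinstance(
        truth, spread_mod.OccupancyHistory) else None)
    spec = landscape.spec

    records: list[OccurrenceRecord] = []
    on_ab: list[int] = []
    off_ab: list[int] = []
    consecutive_empty = 0
    n_transects = 0
    t = 0
    while True:
        s0 = t * spacing
        if s0 + protocol.plot_length > trail.length:
            break
        t += 1
        n_transects += 1
        s_mid = s0 + protocol.plot_length / 2.0
        pm = trail.interpolate(s_mid)
        tangent = _tangent(trail, s_mid)
        east_normal = _east_normal(tangent)

        cells, inside = points_to_cells(np.array([[pm.x, pm.y]]), spec)
        local = float(density[cells[0, 0], cells[0, 1]]) if inside[0] else 0.0
        lam = config.transect_intensity * local
        n_clusters = int(rng.poisson(lam)) if lam > 0 else 0

        n_on_t = 0
        n_off_t = 0
        for _ in range(n_clusters):
            abundance = 1 + int(rng.poisson(config.cluster_abundance_mean))
            if rng.random() < config.trail_share:
                s_pos = s0 + rng.uniform(0.0, protocol.plot_length)
                p = trail.interpolate(s_pos)
                lateral = rng.uniform(-protocol.plot_width / 2, protocol.plot_width / 2)
                nvec = _east_normal(_tangent(trail, s_pos))
                records.append(
                    OccurrenceRecord(
                        x=p.x + nvec[0] * lateral,
                        y=p.y + nvec[1] * lateral,
                        year=survey_year,
                        abundance=abundance,
                        plot_class="trail",
                    )
                )
                n_on_t += abundance
            else:
                # Distance along the eastward perpendicular plot; declining
                # with distance like the trail kernel, truncated at 100 m.
                d = protocol.plot_width / 2 + min(
                    rng.exponential(30.0), protocol.off_trail_length - 1.0
                )
                along = rng.uniform(-protocol.plot_width / 2, protocol.plot_width / 2)
                records.append(
                    OccurrenceRecord(
                        x=pm.x + east_normal[0] * d + tangent[0] * along,
                        y=pm.y + east_normal[1] * d + tangent[1] * along,
                        year=survey_year,
                        abundance=abundance,
                        plot_class="off_trail",
                    )
                )
                n_off_t += abundance
        on_ab.append(n_on_t)
        off_ab.append(n_off_t)
        if n_on_t == 0:
            consecutive_empty += 1
            if consecutive_empty >= protocol.stop_rule:
                break
        else:
            consecutive_empty = 0
    return TransectSurvey(
        records=records,
        n_transects=n_transects,
        on_trail_abundance=np.array(on_ab, dtype=int),
        off_trail_abundance=np.array(off_ab, dtype=int),
    )


def _tangent(line: LineString, s: float) -> np.ndarray:
    eps = 0.5
    a = line.interpolate(max(s - eps, 0.0))
    b = line.interpolate(min(s + eps, line.length))
    v = np.array([b.x - a.x, b.y - a.y])
    norm = np.linalg.norm(v)
    return v / norm if norm > 0 else np.array([0.0, -1.0])


def _east_normal(tangent: np.ndarray) -> np.ndarray:
    """Unit normal to the trail pointing east (positive x component)."""
    n = np.array([-tangent[1], tangent[0]])
    if n[0] < 0 or (n[0] == 0 and n[1] < 0):
        n = -n
    return n


# ---------------------------------------------------------------------------
# UAV scene (10-cm luminance + RGB) with terrain-weighted point placement
# ---------------------------------------------------------------------------


def render_luminance(
    landscape: LandscapeBundle,
    config: SynthConfig,
    seed: int | None = None,
    n_points: int | None = None,
    max_shift_margin: float = 10.0,
) -> TerrainScene:
    """Render a fine-resolution scene along the south trail and place poppies.

    Luminance is in [0, 1]; the trail band and gravel patches are brighter
    than the vegetated background. Poppy positions are drawn with
    probability proportional to exp(terrain_preference_strength * luminance)
    over pixels at least ``max_shift_margin`` metres inside the scene (so
    every joint shift up to that distance keeps all points on the raster);
    a strength of 0 places points uniformly (no terrain association). The
    RGB image is built so its Rec. 709 relative luminance equals the
    luminance channel exactly.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = n_points if n_points is not None else config.n_terrain_points
    trail = landscape.trails["south"]
    seg = [trail.interpolate(s) for s in np.linspace(
        10.0, min(10.0 + config.scene_length, trail.length - 1.0), 25)]
    xs = np.array([p.x for p in seg])
    ys = np.array([p.y for p in seg])
    hw = config.scene_half_width
    px = config.scene_pixel
    x0 = math.floor((xs.min() - hw) / px) * px
    y0 = math.floor((ys.min() - hw) / px) * px
    n_cols = int(math.ceil((xs.max() + hw - x0) / px))
    n_rows = int(math.ceil((ys.max() + hw - y0) / px))
    spec = GridSpec(x0, y0, px, n_rows, n_cols)

    seg_line = LineString(np.column_stack([xs, ys]))
    X, Y = spec.centre_mesh()
    import shapely

    dist = shapely.distance(
        shapely.points(X.ravel(), Y.ravel()), seg_line
    ).reshape(n_rows, n_cols)

    background = 0.25 + 0.10 * gaussian_filter(
        rng.standard_normal((n_rows, n_cols)), sigma=40.0
    ) / 0.02
    background = 0.25 + 0.08 * np.tanh(background - 0.25)
    fine = 0.03 * gaussian_filter(rng.standard_normal((n_rows, n_cols)), sigma=3.0) * 8
    gravel_field = gaussian_filter(rng.standard_normal((n_rows, n_cols)), sigma=60.0)
    gravel_field /= max(gravel_field.std(), 1e-12)
    patches = gravel_field > 1.3

    lum = background + fine
    lum[patches] = 0.60 + fine[patches]
    trail_blend = np.clip((2.0 - dist) / 1.5, 0.0, 1.0)
    lum = lum * (1 - trail_blend) + (0.80 + fine) * trail_blend
    lum = np.clip(lum, 0.02, 0.98)

    lum_raster = Raster(spec, lum)
    points = place_terrain_points(
        lum_raster, n, config.terrain_preference_strength, rng,
        margin=max_shift_margin,
    )
    records = [
        OccurrenceRecord(x=float(x), y=float(y), year=2023, abundance=1,
                         plot_class="unsystematic")
        for x, y in points
    ]

    rgb = _luminance_to_rgb(lum)
    return TerrainScene(
        luminance=lum_raster, rgb=rgb, points=points, records=records
    )


def place_terrain_points(
    lum: Raster,
    n: int,
    strength: float,
    rng: np.random.Generator | int,
    margin: float = 10.0,
) -> np.ndarray:
    """Sample n point positions on a luminance raster with probability
    proportional to exp(strength * luminance); strength 0 is uniform.

    Candidate pixels are inset ``margin`` metres from the raster edges so a
    rigid shift up to that distance keeps every point on the raster.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    spec = lum.spec
    values = np.asarray(lum.values, dtype=float)
    m = int(math.ceil((margin + 0.5) / spec.cell_size))
    if 2 * m >= min(values.shape):
        raise ValueError("margin leaves no candidate pixels")
    candidate = np.zeros_like(values, dtype=bool)
    candidate[m:-m, m:-m] = True
    weights = np.exp(strength * values) * candidate
    p = (weights / weights.sum()).ravel()
    idx = rng.choice(values.size, size=n, replace=True, p=p)
    rows, cols = np.unravel_index(idx, values.shape)
    xs = spec.origin_x + (cols + rng.uniform(0, 1, n)) * spec.cell_size
    ys = spec.origin_y + (rows + rng.uniform(0, 1, n)) * spec.cell_size
    return np.column_stack([xs, ys])


def _luminance_to_rgb(lum: np.ndarray) -> np.ndarray:
    """Blend grey gravel and green vegetation hues whose Rec. 709 luminance
    both equal 1, so Y(rgb) == lum exactly."""
    veg = np.array([0.35, 1.25, 0.30])
    veg = veg / float(_LUM_WEIGHTS @ veg)
    grey = np.ones(3)
    w = np.clip((lum - 0.35) / 0.30, 0.0, 1.0)[..., None]
    direction = w * grey + (1.0 - w) * veg
    return lum[..., None] * direction
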