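"""Stochastic, spatially explicit occupancy spread on a raster grid.

Each cell of a 5-m grid is occupied (1) or unoccupied (0). Every simulated
year, the per-cell establishment probability P_e is the convolution of the
occupied state with a discretised establishment kernel; a cell establishes
when P_e exceeds an independent Uniform(0, 1) threshold drawn per cell per
year (equivalently Bernoulli(P_e)). Establishment is restricted to a
topographic suitability mask (no water, elevation at or below the highest
observed occurrence) and is irreversible: occupied cells never revert.

Two scenarios are compared: ``no_trail_effect`` applies only the local-spread
kernel from every occupied cell; ``trail_effect`` additionally applies the
trail-spread kernel from occupied cells lying on a trail, the two sources
combining as independent complements, P_e = 1 - (1 - P_local)(1 - P_trail).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve

from .kernels import KernelFit
from .spatial_core import (
    GridSpec,
    OccurrenceRecord,
    Raster,
    points_to_cells,
    rasterize_trail,
)

#: Year sentinel for cells never colonised within the simulated horizon.
NEVER = -1

#: Hard cap (cells) on the kernel truncation radius when the requested
#: quantile is unbounded (Cauchy tails).
DEFAULT_MAX_RADIUS = 80


@dataclass
class SuitabilityMask:
    raster: Raster  # boolean
    elevation_threshold: float


@dataclass
class DiscreteKernel:
    """Establishment kernel sampled on the cell grid, centred on the source."""

    weights: np.ndarray  # (2r+1, 2r+1), non-negative, sum <= 1
    radius: int
    assumption: str | None = None


@dataclass
class OccupancyHistory:
    """Per-replicate first-establishment years plus replicate averages.

    ``arrival_years`` holds one integer raster per replicate (NEVER where a
    cell was not colonised); ``mean_arrival`` averages arrival over the
    replicates that colonised each cell (NaN if none did); ``n_colonised``
    counts colonising replicates per cell.
    """

    spec: GridSpec
    start_year: int
    end_year: int
    arrival_years: list[np.ndarray]
    scenario: str

    @property
    def n_replicates(self) -> int:
        return len(self.arrival_years)

    def occupied_by(self, year: int, replicate: int = 0) -> np.ndarray:
        arr = self.arrival_years[replicate]
        return (arr != NEVER) & (arr <= year)

    def majority_occupied_by(self, year: int) -> np.ndarray:
        """Cells occupied by ``year`` in more than half of the replicates."""
        counts = sum(
            ((arr != NEVER) & (arr <= year)).astype(int) for arr in self.arrival_years
        )
        return counts > self.n_replicates / 2.0

    @property
    def mean_arrival(self) -> Raster:
        stack = np.stack(self.arrival_years).astype(float)
        stack[stack == NEVER] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            mean = np.nanmean(stack, axis=0)
        return Raster(self.spec, mean, nodata=np.nan)

    @property
    def n_colonised(self) -> Raster:
        counts = sum((arr != NEVER).astype(np.int64) for arr in self.arrival_years)
        return Raster(self.spec, counts)


@dataclass
class SensitivityResult:
    tp: int
    fa: int
    year: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fa)


# ---------------------------------------------------------------------------
# Suitability
# ---------------------------------------------------------------------------


def elevation_threshold(
    occurrences: Sequence[OccurrenceRecord], dem: Raster
) -> float:
    """Maximum DEM elevation sampled at occurrence locations."""
    cells, inside = points_to_cells(occurrences, dem.spec)
    nodata = dem.nodata_mask()
    values = [
        float(dem.values[r, c])
        for (r, c), ok in zip(cells, inside)
        if ok and not nodata[r, c]
    ]
    if not values:
        raise ValueError("no occurrence falls on a valid DEM cell")
    return max(values)


def build_suitability(
    dem: Raster, water_mask: Raster, threshold: float
) -> SuitabilityMask:
    """Suitable iff not water and elevation <= threshold."""
    if dem.spec != water_mask.spec:
        raise ValueError("DEM and water mask are on different grids")
    ok = (~water_mask.values.astype(bool)) & (dem.values <= threshold)
    ok &= ~dem.nodata_mask()
    return SuitabilityMask(Raster(dem.spec, ok), threshold)


# ---------------------------------------------------------------------------
# Kernel discretisation and convolution
# ---------------------------------------------------------------------------


def discretize_kernel(
    fit: KernelFit,
    cell_size: float,
    truncation_q: float = 0.99,
    max_radius: int = DEFAULT_MAX_RADIUS,
    ring_correction: bool = False,
) -> DiscreteKernel:
    """Sample a fitted 1-D distance pdf onto the 2-D cell grid.

    The weight of a cell at centre-to-centre offset distance z is
    ``pdf(z) * cell_size`` (the fitted 1-D density read as a per-cell annual
    establishment probability along any bearing; set ``ring_correction`` to
    divide by the ring circumference 2*pi*z and multiply by the cell area
    instead). The centre cell is evaluated at z = cell_size/2 so families
    with a pole at zero stay finite. Weights are rescaled only if their sum
    exceeds 1.
    """
    if not (0.9 < truncation_q < 1.0):
        raise ValueError("truncation_q must lie in (0.9, 1)")
    frozen = fit.frozen()
    q = float(frozen.ppf(truncation_q))
    if not np.isfinite(q) or q / cell_size > max_radius:
        warnings.warn(
            f"{fit.family}: truncation quantile {truncation_q} gives radius "
            f"{q:.3g} m; capping at {max_radius} cells",
            stacklevel=2,
        )
        r = max_radius
    else:
        r = max(1, int(np.ceil(q / cell_size)))
    offsets = np.arange(-r, r + 1) * cell_size
    dx, dy = np.meshgrid(offsets, offsets)
    z = np.hypot(dx, dy)
    z[r, r] = cell_size / 2.0
    with np.errstate(all="ignore"):
        pdf = frozen.pdf(z)
    pdf = np.where(np.isfinite(pdf), pdf, 0.0)
    pdf = np.maximum(pdf, 0.0)
    if ring_correction:
        weights = pdf * cell_size**2 / (2.0 * np.pi * z)
    else:
        weights = pdf * cell_size
    total = weights.sum()
    if total > 1.0:
        weights = weights / total
    return DiscreteKernel(weights, r, fit.assumption)


def establishment_probability(
    state: np.ndarray,
    kernel_local: DiscreteKernel,
    kernel_trail: DiscreteKernel | None,
    trail_mask: np.ndarray | None,
    scenario: str = "no_trail_effect",
) -> np.ndarray:
    """Per-cell establishment probability from the occupied state.

    FFT convolution (zero-padded, 'same' output) of the state with the
    kernel; under ``trail_effect`` the trail kernel convolves the on-trail
    occupied cells and the two probabilities combine as independent
    complements. The result is clipped to [0, 1].
    """
    state = state.astype(float)
    if kernel_local.weights.shape[0] > min(state.shape):
        raise ValueError("kernel is larger than the simulation grid")
    p_local = np.minimum(fftconvolve(state, kernel_local.weights, mode="same"), 1.0)
    if scenario == "no_trail_effect":
        p = p_local
    elif scenario == "trail_effect":
        if kernel_trail is None or trail_mask is None:
            raise ValueError("trail_effect scenario needs a trail kernel and mask")
        if kernel_trail.weights.shape[0] > min(state.shape):
            raise ValueError("kernel is larger than the simulation grid")
        on_trail = state * trail_mask.astype(float)
        p_trail = np.minimum(
            fftconvolve(on_trail, kernel_trail.weights, mode="same"), 1.0
        )
        p = 1.0 - (1.0 - p_local) * (1.0 - p_trail)
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return np.clip(p, 0.0, 1.0)


def step_year(
    state: np.ndarray,
    p_e: np.ndarray,
    suitability: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One annual update: Bernoulli establishment on unoccupied suitable cells.

    A cell establishes iff P_e exceeds its fresh Uniform(0,1) threshold
    (strict comparison); occupied cells never revert, unsuitable cells never
    establish.
    """
    if not (state.shape == p_e.shape == suitability.shape):
        raise ValueError("state, P_e and suitability must share one grid")
    t_e = rng.random(state.shape)
    new = (~state) & suitability & (p_e > t_e)
    return state | new


def run_simulation(
    landscape,
    local_fit: KernelFit,
    trail_fit: KernelFit | None,
    scenario: str,
    start_year: int,
    end_year: int,
    init_point: tuple[float, float],
    n_replicates: int = 10,
    base_seed: int = 0,
    elev_threshold: float = 137.0,
    truncation_q: float = 0.99,
    trail_mask_width: float | None = None,
    ring_correction: bool = False,
) -> OccupancyHistory:
    """Simulate annual establishment from a single introduction point.

    Replicate k runs on its own RNG stream seeded ``base_seed + k``. The
    trail source band is rasterized at ``trail_mask_width`` (defaults to the
    cell size so the band is contiguous at grid resolution).
    """
    spec: GridSpec = landscape.spec
    suit = build_suitability(landscape.dem, landscape.water_mask, elev_threshold)
    suitable = suit.raster.values
    cells, ok = points_to_cells(np.array([init_point]), spec)
    row, col = cells[0]
    if not ok[0]:
        raise ValueError("initial point lies outside the grid")
    if not suitable[row, col]:
        raise ValueError("initial cell is unsuitable for establishment")
    kernel_local = discretize_kernel(
        local_fit, spec.cell_size, truncation_q, ring_correction=ring_correction
    )
    kernel_trail = None
    trail_mask = None
    if scenario == "trail_effect":
        if trail_fit is None:
            raise ValueError("trail_effect scenario needs a trail kernel fit")
        kernel_trail = discretize_kernel(
            trail_fit, spec.cell_size, truncation_q, ring_correction=ring_correction
        )
        width = trail_mask_width if trail_mask_width is not None else spec.cell_size
        trail_mask = rasterize_trail(
            spec, list(landscape.trails.values()), width
        ).values
    arrivals: list[np.ndarray] = []
    for k in range(n_replicates):
        rng = np.random.default_rng(base_seed + k)
        state = np.zeros((spec.n_rows, spec.n_cols), dtype=bool)
        state[row, col] = True
        arrival = np.full(state.shape, NEVER, dtype=np.int64)
        arrival[row, col] = start_year
        for year in range(start_year + 1, end_year + 1):
            p_e = establishment_probability(
                state, kernel_local, kernel_trail, trail_mask, scenario
            )
            new_state = step_year(state, p_e, suitable, rng)
            arrival[new_state & (arrival == NEVER)] = year
            state = new_state
        arrivals.append(arrival)
    return OccupancyHistory(spec, start_year, end_year, arrivals, scenario)


# ---------------------------------------------------------------------------
# Evaluation against observed presences
# ---------------------------------------------------------------------------


def sensitivity(
    history: OccupancyHistory,
    observations: Sequence[OccurrenceRecord],
    year: int,
    eval_block: float = 1000.0,
) -> SensitivityResult:
    """TP/(TP+FA) of observed presences covered by the simulated spread.

    Presences are aggregated into square evaluation blocks of side
    ``eval_block`` metres (1 km for systematic grid surveys; use the cell
    size for point records). A block counts as TP when any
    replicate-majority-occupied cell by ``year`` falls inside it.
    """
    if not observations:
        raise ValueError("sensitivity needs at least one observed presence")
    spec = history.spec
    occ = history.majority_occupied_by(year)
    rows, cols = np.nonzero(occ)
    xs = spec.origin_x + (cols + 0.5) * spec.cell_size
    ys = spec.origin_y + (rows + 0.5) * spec.cell_size
    occ_blocks = set(
        zip(
            np.floor((xs - spec.origin_x) / eval_block).astype(int),
            np.floor((ys - spec.origin_y) / eval_block).astype(int),
        )
    )
    obs_blocks = set()
    for r in observations:
        bx = int(np.floor((r.x - spec.origin_x) / eval_block))
        by = int(np.floor((r.y - spec.origin_y) / eval_block))
        obs_blocks.add((bx, by))
    tp = sum(1 for b in obs_blocks if b in occ_blocks)
    fa = len(obs_blocks) - tp
    return SensitivityResult(tp=tp, fa=fa, year=year)
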