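"""Terrain preference from fine-scale brightness: luminance + joint-shift test.

Bright pixels in a low-altitude orthomosaic indicate gravelly terrain with
sparse vegetation; dark pixels indicate denser plant or soil cover. The
Rec. 709 relative luminance of the RGB channels serves as the brightness
index. Terrain preference of the observed point pattern is tested with a
spatial-structure-preserving randomisation: the whole pattern is shifted
rigidly by random offsets (preserving every pairwise distance) and the
median luminance under the points is compared between the observed and the
shifted patterns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .spatial_core import GridSpec, Raster, _point_array, points_to_cells

#: Rec. 709 luminance weights for (R, G, B).
REC709_WEIGHTS = (0.2126, 0.7152, 0.0722)


@dataclass
class RandomisationResult:
    """Observed and null median luminances with the randomisation p-value.

    ``n`` counts all iterations including the observed one (iteration 0),
    and the observed iteration counts itself in the numerator, so the
    p-value is conservative: p >= 1/n.
    """

    observed_median: float
    null_medians: np.ndarray  # n - 1 values
    n: int
    p_value: float
    seed: int


def relative_luminance(
    rgb: np.ndarray,
    spec: GridSpec | None = None,
    weights: Sequence[float] = REC709_WEIGHTS,
) -> np.ndarray | Raster:
    """Relative luminance Y in [0, 1] from a 3-band RGB image.

    Channels may be scaled [0, 1] or [0, 255] (8-bit values are rescaled).
    Returns a Raster when a grid spec is supplied, else a plain array.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError(
            f"expected an (H, W, 3) RGB image, got shape {rgb.shape}"
        )
    if rgb.max() > 1.5:
        rgb = rgb / 255.0
    w = np.asarray(weights, dtype=float)
    lum = rgb @ w
    if spec is not None:
        return Raster(spec, lum)
    return lum


def sample_luminance(points, lum: Raster) -> np.ndarray:
    """Nearest-pixel luminance at each point; NaN for points off the raster.

    Warns when some points fall outside the extent and raises when all do.
    """
    xy = _point_array(points)
    cells, inside = points_to_cells(xy, lum.spec)
    if not inside.any():
        raise ValueError("all points lie outside the luminance raster")
    if not inside.all():
        warnings.warn(
            f"{int((~inside).sum())} of {len(inside)} points fall outside "
            "the luminance raster; their values are NaN",
            stacklevel=2,
        )
    values = np.full(xy.shape[0], np.nan)
    values[inside] = lum.values[cells[inside, 0], cells[inside, 1]]
    return values


def joint_shift(points, dx: float, dy: float) -> np.ndarray:
    """Translate every point by the same (dx, dy) — a rigid shift that
    preserves all pairwise distances."""
    return _point_array(points) + np.array([dx, dy])


def shift_admissible(points, dx: float, dy: float, spec: GridSpec) -> bool:
    """A shift is admissible iff every shifted point stays on the raster."""
    xy = _point_array(points)
    x = xy[:, 0] + dx
    y = xy[:, 1] + dy
    return bool(
        (x.min() >= spec.origin_x)
        and (x.max() < spec.origin_x + spec.width)
        and (y.min() >= spec.origin_y)
        and (y.max() < spec.origin_y + spec.height)
    )


def randomisation_test(
    points,
    lum: Raster,
    n: int = 1000,
    max_shift: float = 10.0,
    seed: int = 0,
    max_draws: int = 10_000,
) -> RandomisationResult:
    """Joint-shift randomisation test for terrain-brightness preference.

    Iteration 0 is the observed pattern; each of the remaining n - 1
    iterations shifts all points rigidly by dx, dy ~ Uniform(-max_shift,
    +max_shift) drawn independently per axis, rejecting and redrawing any
    shift that would move a point off the raster. The p-value is the
    proportion of all n iterations (observed included) whose median sampled
    luminance is >= the observed median.
    """
    xy = _point_array(points)
    if xy.shape[0] < 10:
        raise ValueError("randomisation test needs at least 10 points")
    spec = lum.spec
    if not shift_admissible(xy, 0.0, 0.0, spec):
        raise ValueError("observed points must lie inside the raster extent")
    rng = np.random.default_rng(seed)

    shifts = np.zeros((n, 2))
    for i in range(1, n):
        for attempt in range(max_draws):
            dx, dy = rng.uniform(-max_shift, max_shift, size=2)
            if shift_admissible(xy, dx, dy, spec):
                shifts[i] = (dx, dy)
                break
        else:
            raise RuntimeError(
                f"no admissible shift found in {max_draws} draws "
                f"(max_shift={max_shift})"
            )

    # All iterations at once: (n, n_points) luminance lookups.
    xs = xy[:, 0][None, :] + shifts[:, 0][:, None]
    ys = xy[:, 1][None, :] + shifts[:, 1][:, None]
    cols = np.floor((xs - spec.origin_x) / spec.cell_size).astype(np.int64)
    rows = np.floor((ys - spec.origin_y) / spec.cell_size).astype(np.int64)
    meds = np.median(lum.values[rows, cols], axis=1)
    p = float(np.sum(meds >= meds[0]) / n)
    return RandomisationResult(
        observed_median=float(meds[0]),
        null_medians=meds[1:],
        n=n,
        p_value=p,
        seed=seed,
    )
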