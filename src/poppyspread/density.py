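"""Density attribution: KDE surface, distance profiles, rank test, GLM.

The occurrence density over the study grid is a 2-D Gaussian kernel density
estimate evaluated at cell centres and min-max normalised to [0, 1]. The
normalised density is then attributed to anthropogenic and topographic
predictors — distance from the station, distance from the closest trail,
elevation, and the station x trail interaction — with a generalised linear
model on z-scored predictors, and the contribution of each predictor is
quantified by partial R² from leave-one-predictor-out refits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg, stats

from .spatial_core import (
    GridSpec,
    OccurrenceRecord,
    Raster,
    _point_array,
    distance_to_point,
    distance_to_trails,
)

GLM_TERMS = ("intercept", "dist_station", "dist_trail", "elevation",
             "dist_station:dist_trail")


@dataclass
class DensitySurface:
    """Min-max normalised KDE surface (max exactly 1, min 0)."""

    raster: Raster
    bandwidth: np.ndarray  # 2x2 covariance of the Gaussian kernel
    n_points: int


@dataclass
class DistanceProfile:
    bin_edges: np.ndarray
    mass: np.ndarray  # probability per bin, sums to 1
    weight_mode: str


@dataclass
class TrailClassSummary:
    """Occurrence counts by trail-distance class (0-100 m, 0.1-1 km, >1 km)."""

    class_edges: tuple[float, ...]
    counts: dict[str, int]
    per_year: pd.DataFrame  # rows: year, columns: class label, values: counts
    median_per_year: dict[str, float]


@dataclass
class GlmResult:
    terms: tuple[str, ...]
    estimates: np.ndarray
    std_errors: np.ndarray
    z_values: np.ndarray
    p_values: np.ndarray
    family: str
    mcfadden_adj_r2: float
    r2_kind: str
    n_obs: int
    partial_r2: dict[str, float] | None = None
    _design: np.ndarray | None = field(default=None, repr=False)
    _response: np.ndarray | None = field(default=None, repr=False)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.estimates,
                "std_error": self.std_errors,
                "z_value": self.z_values,
                "p_value": self.p_values,
            },
            index=list(self.terms),
        )


# ---------------------------------------------------------------------------
# KDE
# ---------------------------------------------------------------------------


def kde_density(
    points: Sequence[OccurrenceRecord] | np.ndarray,
    spec: GridSpec,
    bandwidth: str | float = "scott",
) -> DensitySurface:
    """Gaussian KDE of occurrence points evaluated at every cell centre.

    ``bandwidth="scott"`` uses Scott's rule on the point scatter (kernel
    covariance = sample covariance * n^(-1/3), the gaussian_kde convention
    in two dimensions); a scalar bandwidth is the isotropic kernel standard
    deviation in metres. The surface is min-max normalised to [0, 1].
    """
    xy = _point_array(points)
    n = xy.shape[0]
    if isinstance(bandwidth, str):
        if bandwidth != "scott":
            raise ValueError(f"unknown bandwidth rule {bandwidth!r}")
        if n < 2 or np.unique(xy, axis=0).shape[0] < 2:
            raise ValueError("Scott's rule needs >= 2 distinct points")
        cov = np.cov(xy.T) * n ** (-1.0 / 3.0)
    else:
        h = float(bandwidth)
        if h <= 0:
            raise ValueError("scalar bandwidth must be > 0")
        cov = np.eye(2) * h**2
    try:
        chol = linalg.cholesky(cov, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError(
            "singular KDE bandwidth (identical or collinear points); "
            "pass a scalar bandwidth"
        ) from exc

    X, Y = spec.centre_mesh()
    grid = np.column_stack([X.ravel(), Y.ravel()])
    dens = np.zeros(grid.shape[0])
    for p in xy:
        diff = (grid - p).T  # (2, m)
        u = linalg.solve_triangular(chol, diff, lower=True)
        dens += np.exp(-0.5 * np.sum(u * u, axis=0))
    det = float(np.prod(np.diag(chol))) ** 2
    dens /= n * 2.0 * np.pi * np.sqrt(det)
    dens = dens.reshape(spec.n_rows, spec.n_cols)
    lo, hi = dens.min(), dens.max()
    if hi > lo:
        dens = (dens - lo) / (hi - lo)
    else:
        dens = np.ones_like(dens)
    return DensitySurface(Raster(spec, dens), cov, n)


# ---------------------------------------------------------------------------
# Distance profiles and trail-distance classes
# ---------------------------------------------------------------------------


def distance_profile(
    points: Sequence[OccurrenceRecord],
    ref: tuple[float, float],
    bin_width: float,
    weight_mode: str = "occurrence",
) -> DistanceProfile:
    """Probability distribution of (abundance-weighted) points by distance
    from a reference point, in bins of ``bin_width`` metres."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if not points:
        raise ValueError("distance profile needs at least one point")
    if weight_mode not in ("occurrence", "abundance"):
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    xy = _point_array(points)
    d = np.hypot(xy[:, 0] - ref[0], xy[:, 1] - ref[1])
    w = (
        np.array([p.abundance for p in points], dtype=float)
        if weight_mode == "abundance"
        else np.ones(len(points))
    )
    n_bins = max(1, int(np.ceil(d.max() / bin_width))) if d.max() > 0 else 1
    edges = np.arange(0, n_bins + 1) * bin_width
    hist, edges = np.histogram(d, bins=edges, weights=w)
    return DistanceProfile(edges, hist / hist.sum(), weight_mode)


def trail_distance_classes(
    points: Sequence[OccurrenceRecord],
    trails,
    class_edges: tuple[float, ...] = (0.0, 100.0, 1000.0, np.inf),
) -> TrailClassSummary:
    """Assign each point to a trail-distance class and summarise counts.

    Default classes: on/near the trail (0-100 m from the trail centre line),
    0.1-1 km away, and more than 1 km away. Reports total counts per class
    and the median of per-year counts.
    """
    if class_edges[0] != 0.0 or not np.isinf(class_edges[-1]):
        raise ValueError("class edges must cover [0, inf)")
    import shapely
    from shapely.geometry import MultiLineString

    from .spatial_core import _as_linestrings

    lines = _as_linestrings(trails)
    geom = MultiLineString(lines) if len(lines) > 1 else lines[0]
    xy = _point_array(points)
    d = shapely.distance(shapely.points(xy[:, 0], xy[:, 1]), geom)
    labels = [
        f"{class_edges[i]:g}-{class_edges[i + 1]:g} m"
        for i in range(len(class_edges) - 1)
    ]
    idx = np.clip(np.searchsorted(class_edges, d, side="right") - 1, 0,
                  len(labels) - 1)
    df = pd.DataFrame(
        {
            "year": [p.year for p in points],
            "cls": [labels[i] for i in idx],
        }
    )
    per_year = (
        df.groupby(["year", "cls"]).size().unstack(fill_value=0)
        .reindex(columns=labels, fill_value=0)
    )
    counts = {lab: int((df["cls"] == lab).sum()) for lab in labels}
    medians = {lab: float(per_year[lab].median()) for lab in labels}
    return TrailClassSummary(class_edges, counts, per_year, medians)


def paired_rank_test(
    on_trail: Sequence[float], off_trail: Sequence[float]
) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired per-transect abundances.

    Zero differences are dropped; the null is exact for small samples
    without ties and a tie-corrected normal approximation otherwise;
    two-sided p-value. Raises if every pairwise difference is zero.
    """
    x = np.asarray(on_trail, dtype=float)
    y = np.asarray(off_trail, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    if x.size < 5:
        raise ValueError("paired rank test needs n >= 5 pairs")
    if np.all(x == y):
        raise ValueError("all paired differences are zero; test undefined")
    res = stats.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided",
                         method="auto")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# GLM with McFadden adjusted R^2 and partial R^2
# ---------------------------------------------------------------------------


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError("constant predictor cannot be z-scored")
    return (v - v.mean()) / sd


def fit_density_glm(
    density: DensitySurface,
    dem: Raster,
    station: tuple[float, float],
    trails,
    family: str = "gaussian",
    include_interaction: bool = True,
) -> GlmResult:
    """Regress the normalised density surface on distance from the station,
    distance from the closest trail, elevation and (optionally) the
    station x trail interaction, all predictors z-scored per cell.

    ``family`` is ``"gaussian"`` or ``"poisson"``; the proportion of
    variance explained is the classical adjusted R² for the gaussian family
    and the adjusted McFadden pseudo-R², 1 - (logL_full - k)/logL_null, for
    the poisson family.
    """
    spec = density.raster.spec
    if dem.spec != spec:
        raise ValueError("density and DEM are on different grids")
    valid = ~dem.nodata_mask()
    d_station = distance_to_point(spec, station).values[valid]
    d_trail = distance_to_trails(spec, trails).values[valid]
    elev = np.asarray(dem.values, dtype=float)[valid]
    y = density.raster.values[valid]

    z_st = _zscore(d_station)
    z_tr = _zscore(d_trail)
    z_el = _zscore(elev)
    cols = [np.ones_like(z_st), z_st, z_tr, z_el]
    terms = ["intercept", "dist_station", "dist_trail", "elevation"]
    if include_interaction:
        cols.append(z_st * z_tr)
        terms.append("dist_station:dist_trail")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        corr = np.corrcoef(X[:, 1:].T)
        bad = [
            f"{terms[i + 1]}~{terms[j + 1]}"
            for i in range(corr.shape[0])
            for j in range(i + 1, corr.shape[0])
            if abs(corr[i, j]) > 0.999
        ]
        raise ValueError(f"rank-deficient design; collinear terms: {bad}")
    return _fit_glm(X, y, tuple(terms), family)


def _fit_glm(X: np.ndarray, y: np.ndarray, terms: tuple[str, ...],
             family: str) -> GlmResult:
    if family == "gaussian":
        fam = sm.families.Gaussian()
    elif family == "poisson":
        fam = sm.families.Poisson()
    else:
        raise ValueError(f"unknown GLM family {family!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # non-integer poisson endog
        fit = sm.GLM(y, X, family=fam).fit()
        null = sm.GLM(y, X[:, :1], family=fam).fit()
    k = X.shape[1] - 1  # predictors, excluding the intercept
    if family == "poisson":
        r2 = 1.0 - (fit.llf - k) / null.llf
        kind = "adjusted_mcfadden"
    else:
        sse = float(np.sum(fit.resid_response**2))
        sst = float(np.sum((y - y.mean()) ** 2))
        r2_plain = 1.0 - sse / sst
        n = y.size
        r2 = 1.0 - (1.0 - r2_plain) * (n - 1) / (n - k - 1)
        kind = "adjusted_classical"
    return GlmResult(
        terms=terms,
        estimates=np.asarray(fit.params),
        std_errors=np.asarray(fit.bse),
        z_values=np.asarray(fit.tvalues),
        p_values=np.asarray(fit.pvalues),
        family=family,
        mcfadden_adj_r2=float(r2),
        r2_kind=kind,
        n_obs=int(y.size),
        _design=X,
        _response=np.asarray(y, dtype=float),
    )


def partial_r2(full: GlmResult) -> dict[str, float]:
    """Leave-one-predictor-out partial R² for every non-intercept term.

    Gaussian family: (SSE_reduced - SSE_full) / SSE_reduced; poisson family:
    the deviance analogue. Values lie in [0, 1] and are 0 when dropping the
    predictor leaves the fit unchanged.
    """
    if full._design is None or full._response is None:
        raise ValueError("GlmResult does not carry its design matrix")
    X, y = full._design, full._response
    fam = sm.families.Gaussian() if full.family == "gaussian" else sm.families.Poisson()

    def _badness(design: np.ndarray) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, design, family=fam).fit()
        if full.family == "gaussian":
            return float(np.sum(fit.resid_response**2))
        return float(fit.deviance)

    full_bad = _badness(X)
    out: dict[str, float] = {}
    for j, term in enumerate(full.terms):
        if term == "intercept":
            continue
        reduced = np.delete(X, j, axis=1)
        red_bad = _badness(reduced)
        if red_bad == 0:
            raise ValueError(f"reduced model dropping {term!r} fits perfectly; "
                             "partial R² undefined")
        out[term] = max(0.0, (red_bad - full_bad) / red_bad)
    full.partial_r2 = out
    return out


def on_trail_share(records: Sequence[OccurrenceRecord]) -> float:
    """Share (%) of surveyed individuals located on trail plots,
    abundance-weighted."""
    on = sum(r.abundance for r in records if r.plot_class == "trail")
    off = sum(r.abundance for r in records if r.plot_class == "off_trail")
    total = on + off
    if total == 0:
        raise ValueError("no trail/off-trail individuals in the survey")
    return 100.0 * on / total
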