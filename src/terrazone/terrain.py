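"""Terrain and soil feature construction on a regular field grid.

The sampling pipeline starts from a gridded digital elevation model (DEM)
of the field and point records of apparent electrical conductivity (EMI,
mS/m) gathered along sled transects.  This module derives the slope, aspect
and plan-curvature layers from the DEM, interpolates the EMI points to the
DEM grid with inverse distance weighting, and assembles the per-location
feature matrix (one row per valid grid cell, one column per attribute) that
feeds the self-organizing map.

Conventions
-----------
* Grids are cell-center registered; row 0 is the *southernmost* row, column
  0 the westernmost; x increases east, y north, both in planar metres.
* Slope is reported in percent, aspect as the downslope direction in
  degrees clockwise from north in [0, 360).
* Plan curvature (m^-1) uses the 3x3 quadratic-surface (Zevenbergen-Thorne)
  coefficients; **positive values mean convergent (concave-in-plan)**
  terrain such as potholes and swales, negative means divergent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import binary_dilation
from scipy.spatial import cKDTree

#: canonical feature-column order used throughout the pipeline
FEATURE_ORDER = (
    "elevation",
    "slope",
    "aspect",
    "plan_curvature",
    "emi_hh",
    "emi_vv",
)

_FLAT_SLOPE_PCT = 1e-8  # below this the downslope direction is undefined


class GridGeometryError(ValueError):
    """Raised when grid layers do not share shape/origin/cell size."""


@dataclass
class GridField:
    """One attribute on the regular field grid.

    ``values[r, c]`` is the attribute at the cell center
    ``(origin_x + c*cell_size, origin_y + r*cell_size)``.
    """

    values: np.ndarray
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 10.0
    nodata_mask: np.ndarray | None = None
    attribute_name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("GridField values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.values)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.values.shape:
                raise ValueError("nodata_mask shape must match values")
            self.nodata_mask = self.nodata_mask | ~np.isfinite(self.values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def x_coords(self) -> np.ndarray:
        return self.origin_x + self.cell_size * np.arange(self.shape[1])

    def y_coords(self) -> np.ndarray:
        return self.origin_y + self.cell_size * np.arange(self.shape[0])

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) meshgrids of cell-center coordinates."""
        return np.meshgrid(self.x_coords(), self.y_coords())

    def same_geometry(self, other: "GridField", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and abs(self.origin_x - other.origin_x) <= tol
            and abs(self.origin_y - other.origin_y) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )


@dataclass
class PointSamples:
    """Scattered point observations of one attribute (e.g. an EMI transect)."""

    x: np.ndarray
    y: np.ndarray
    values: np.ndarray
    attribute_name: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).ravel()
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not (len(self.x) == len(self.y) == len(self.values)):
            raise ValueError("x, y, values must have equal length")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("point coordinates must be finite")

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# DEM derivatives
# ---------------------------------------------------------------------------


def _check_dem(dem: GridField) -> np.ndarray:
    if dem.shape[0] < 3 or dem.shape[1] < 3:
        raise ValueError("DEM must be at least 3x3 to derive terrain attributes")
    z = dem.values.copy()
    z[dem.nodata_mask] = np.nan
    return z


def _derivative_mask(dem: GridField) -> np.ndarray:
    # any nodata cell poisons its 3x3 neighbourhood
    return binary_dilation(dem.nodata_mask, structure=np.ones((3, 3), dtype=bool))


def _gradients(z: np.ndarray, cell: float) -> tuple[np.ndarray, np.ndarray]:
    # axis 0 is y (south->north), axis 1 is x (west->east); np.gradient uses
    # central differences in the interior and one-sided ones on the edges.
    fy, fx = np.gradient(z, cell, cell)
    return fx, fy


def derive_slope(dem: GridField) -> GridField:
    """Slope magnitude in percent from 3x3 finite differences.

    slope% = 100 * sqrt(fx^2 + fy^2) with central differences in the
    interior and one-sided differences on grid edges.
    """
    z = _check_dem(dem)
    fx, fy = _gradients(z, dem.cell_size)
    slope = 100.0 * np.hypot(fx, fy)
    mask = _derivative_mask(dem) | ~np.isfinite(slope)
    slope[mask] = np.nan
    return GridField(
        slope, dem.origin_x, dem.origin_y, dem.cell_size,
        nodata_mask=mask, attribute_name="slope", units="%",
    )


def derive_aspect(dem: GridField) -> GridField:
    """Downslope direction in degrees clockwise from north, in [0, 360).

    Cells with slope below a flat threshold have no defined downslope
    direction and are returned as nodata.
    """
    z = _check_dem(dem)
    fx, fy = _gradients(z, dem.cell_size)
    # the gradient points uphill, so the downslope vector is (-fx, -fy);
    # azimuth of an (east, north) vector is atan2(east, north)
    aspect = np.degrees(np.arctan2(-fx, -fy)) % 360.0
    flat = 100.0 * np.hypot(fx, fy) < _FLAT_SLOPE_PCT
    mask = _derivative_mask(dem) | flat | ~np.isfinite(aspect)
    aspect[mask] = np.nan
    return GridField(
        aspect, dem.origin_x, dem.origin_y, dem.cell_size,
        nodata_mask=mask, attribute_name="aspect", units="deg",
    )


def _second_derivatives(z: np.ndarray, cell: float):
    c2 = cell * cell
    r = np.empty_like(z)
    r[:, 1:-1] = (z[:, 2:] - 2.0 * z[:, 1:-1] + z[:, :-2]) / c2
    r[:, 0], r[:, -1] = r[:, 1], r[:, -2]
    t = np.empty_like(z)
    t[1:-1, :] = (z[2:, :] - 2.0 * z[1:-1, :] + z[:-2, :]) / c2
    t[0, :], t[-1, :] = t[1, :], t[-2, :]
    s_int = (z[2:, 2:] - z[2:, :-2] - z[:-2, 2:] + z[:-2, :-2]) / (4.0 * c2)
    s = np.pad(s_int, 1, mode="edge")
    return r, s, t


def derive_plan_curvature(dem: GridField) -> GridField:
    """Plan curvature (m^-1) from the 3x3 quadratic-surface coefficients.

    With p, q the first and r, s, t the second partial derivatives of
    elevation, plan curvature is

        kappa_p = (q^2 r - 2 p q s + p^2 t) / (p^2 + q^2)

    Sign convention: positive = convergent (concave in plan); a circular
    paraboloid bowl ``z = a (x^2 + y^2)`` with a > 0 yields the constant
    ``2 a`` everywhere.  Flat cells (zero gradient) are returned as 0.
    """
    z = _check_dem(dem)
    p, q = _gradients(z, dem.cell_size)
    r, s, t = _second_derivatives(z, dem.cell_size)
    g2 = p * p + q * q
    with np.errstate(invalid="ignore", divide="ignore"):
        curv = (q * q * r - 2.0 * p * q * s + p * p * t) / g2
    curv = np.where(g2 < 1e-20, 0.0, curv)
    mask = _derivative_mask(dem) | ~np.isfinite(curv)
    curv = np.asarray(curv, dtype=float)
    curv[mask] = np.nan
    return GridField(
        curv, dem.origin_x, dem.origin_y, dem.cell_size,
        nodata_mask=mask, attribute_name="plan_curvature", units="1/m",
    )


# ---------------------------------------------------------------------------
# Inverse distance weighting
# ---------------------------------------------------------------------------


def idw_interpolate(
    points: PointSamples,
    template: GridField,
    power: float = 2.0,
    max_neighbors: int = 12,
    attribute_name: str | None = None,
) -> GridField:
    """Interpolate scattered points to the template grid by IDW.

    Each cell gets ``sum(w_i v_i) / sum(w_i)`` with ``w_i = d_i**-power``
    over the ``max_neighbors`` nearest observations; a cell coincident with
    an observation (d < 1e-9 m) takes that observation's value exactly.
    """
    if len(points) == 0:
        raise ValueError("IDW requires at least one point")
    if power <= 0:
        raise ValueError("IDW power must be positive")
    tree = cKDTree(np.column_stack([points.x, points.y]))
    xx, yy = template.cell_centers()
    queries = np.column_stack([xx.ravel(), yy.ravel()])
    k = min(max_neighbors, len(points))
    dist, idx = tree.query(queries, k=k)
    dist = np.atleast_2d(dist.reshape(len(queries), k))
    idx = np.atleast_2d(idx.reshape(len(queries), k))
    vals = points.values[idx]
    exact = dist[:, 0] < 1e-9
    with np.errstate(divide="ignore", invalid="ignore"):
        w = dist ** (-power)
        out = np.einsum("ij,ij->i", w, vals) / w.sum(axis=1)
    out[exact] = vals[exact, 0]
    grid = out.reshape(template.shape)
    return GridField(
        grid, template.origin_x, template.origin_y, template.cell_size,
        nodata_mask=template.nodata_mask.copy(),
        attribute_name=attribute_name or points.attribute_name, units="",
    )


# ---------------------------------------------------------------------------
# Feature matrix
# ---------------------------------------------------------------------------


@dataclass
class FeatureMatrix:
    """n locations x k attributes, with its grid bookkeeping.

    ``location_index[i]`` is the (row, col) grid cell of record i, so
    cluster labels can be mapped back onto the field.  ``normalization``
    is ``None`` for raw values, or a dict with per-column ``mean``/``std``
    arrays once z-scored.
    """

    data: np.ndarray
    columns: tuple[str, ...]
    location_index: np.ndarray
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 10.0
    normalization: dict | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.columns = tuple(self.columns)
        self.location_index = np.asarray(self.location_index, dtype=int)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.columns):
            raise ValueError("data must be n x k with k == len(columns)")
        if len(self.location_index) != len(self.data):
            raise ValueError("location_index length must equal row count")
        if not np.isfinite(self.data).all():
            raise ValueError("feature matrix must not contain missing entries")

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def k(self) -> int:
        return self.data.shape[1]

    @property
    def is_normalized(self) -> bool:
        return self.normalization is not None

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) metre coordinates of each record's cell center."""
        x = self.origin_x + self.cell_size * self.location_index[:, 1]
        y = self.origin_y + self.cell_size * self.location_index[:, 0]
        return x, y


def build_feature_matrix(layers: list[GridField]) -> FeatureMatrix:
    """Stack grid layers into one row per cell valid in *every* layer."""
    if not layers:
        raise ValueError("at least one layer required")
    ref = layers[0]
    for g in layers[1:]:
        if not g.same_geometry(ref):
            raise GridGeometryError(
                f"layer {g.attribute_name!r} does not share the grid geometry"
            )
    valid = ~np.logical_or.reduce([g.nodata_mask for g in layers])
    loc = np.argwhere(valid)  # row-major: south rows first
    data = np.column_stack([g.values[valid] for g in layers])
    cols = tuple(g.attribute_name or f"layer{i}" for i, g in enumerate(layers))
    return FeatureMatrix(
        data, cols, loc, ref.origin_x, ref.origin_y, ref.cell_size,
    )


def normalize_features(fm: FeatureMatrix) -> FeatureMatrix:
    """Z-score every column (mean 0, SD 1), remembering the scaling.

    Raises if a column is constant, naming it, since its z-score is
    undefined.
    """
    if fm.is_normalized:
        raise ValueError("feature matrix is already normalized")
    mean = fm.data.mean(axis=0)
    std = fm.data.std(axis=0, ddof=0)
    bad = [c for c, s in zip(fm.columns, std) if s == 0]
    if bad:
        raise ValueError(f"cannot normalize constant column(s): {', '.join(bad)}")
    data = (fm.data - mean) / std
    return replace(fm, data=data, normalization={"mean": mean, "std": std})


def denormalize_features(fm: FeatureMatrix) -> FeatureMatrix:
    """Invert :func:`normalize_features`."""
    if not fm.is_normalized:
        raise ValueError("feature matrix is not normalized")
    norm = fm.normalization
    data = fm.data * norm["std"] + norm["mean"]
    return replace(fm, data=data, normalization=None)


def denormalize_vector(vec: np.ndarray, fm: FeatureMatrix) -> np.ndarray:
    """Map one vector (e.g. a cluster centroid) back to raw attribute units."""
    if not fm.is_normalized:
        raise ValueError("feature matrix is not normalized")
    return np.asarray(vec) * fm.normalization["std"] + fm.normalization["mean"]
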