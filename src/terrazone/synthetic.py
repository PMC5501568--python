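"""Synthetic prairie-pothole field generator.

Emulates the kind of low-relief central-Iowa row-crop field the pipeline is
designed for: roughly 6 m of total relief on a 10 m grid, a gentle ridge
whose two faces dip south and northeast, and closed depressions
("potholes") with their surrounding toe slopes.  Apparent electrical
conductivity (EMI) is generated as a noisy, negatively elevation-dependent
surface sampled along sled-like transects, elevated in the pothole zone
(wetter, higher clay).  Microbial indicators are drawn per sampling site
from zone-dependent normal distributions in which the pothole/toe-slope
zone exceeds the upslope zones by configurable multipliers (defaults:
MBC x1.6, MBN x1.75, %TN x1.8, %TC x1.6, EOC x1.3; mass-specific
mineralization rates inverted, i.e. lowest in the pothole zone).

Every cell carries a planted ground-truth zone id (1 = pothole/toe slope,
2 = south-facing upslope, 3 = northeast-facing upslope) so cluster and
effect-size recovery can be scored against the construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .cluster import SamplingDesign
from .terrain import FEATURE_ORDER, FeatureMatrix, GridField, PointSamples

ZONE_POTHOLE, ZONE_SOUTH, ZONE_NORTHEAST = 1, 2, 3


class SyntheticConfigError(ValueError):
    pass


@dataclass
class IndicatorSpec:
    """Normal model for one indicator: upslope mean/SD and the pothole-zone
    multiplier applied to the mean (multiplier < 1 inverts the contrast)."""

    mean: float
    sd: float
    zone1_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.zone1_multiplier <= 0:
            raise SyntheticConfigError("multipliers must be > 0")
        if self.sd < 0:
            raise SyntheticConfigError("noise SDs must be >= 0")


def default_indicators() -> dict[str, IndicatorSpec]:
    return {
        "eoc": IndicatorSpec(60.0, 12.0, 1.3),
        "mbc": IndicatorSpec(250.0, 50.0, 1.6),
        "mbn": IndicatorSpec(30.0, 6.0, 1.75),
        "total_c_pct": IndicatorSpec(2.0, 0.35, 1.6),
        "total_n_pct": IndicatorSpec(0.17, 0.03, 1.8),
        "specific_c_min": IndicatorSpec(0.005, 0.001, 0.625),
        "specific_n_min": IndicatorSpec(0.02, 0.005, 0.7),
        "nitrate": IndicatorSpec(12.0, 4.0, 1.0),
        "ammonium": IndicatorSpec(6.0, 2.0, 1.0),
        "n_min": IndicatorSpec(15.0, 5.0, 1.0),
        "c_min": IndicatorSpec(20.0, 6.0, 1.0),
        "ph": IndicatorSpec(6.5, 0.3, 1.0),
        "moisture": IndicatorSpec(0.22, 0.04, 1.25),
        "fw_dw_ratio": IndicatorSpec(1.28, 0.05, 1.06),
    }


@dataclass
class SyntheticFieldConfig:
    """Study-condition defaults: ~70x100 cells of 10 m (~7000 locations),
    6 m relief, EMI centered near H-H 47 / V-V 32.6 mS/m."""

    rows: int = 70
    cols: int = 100
    cell_size: float = 10.0
    base_elevation: float = 309.8
    relief: float = 6.0
    # gentle ridge trend (south face a little steeper than the NE face);
    # most of the relief sits in the closed depressions, as in prairie
    # pothole terrain where upslope flats are broad and even
    slope_south: float = 0.002
    slope_ne: float = 0.0017
    smooth_sigma_cells: float = 1.0
    microrelief_sd: float = 0.015
    # closed depressions: flat-bottomed bowls with a compact tanh shoulder,
    # so each pothole has a distinct rim and a narrow toe-slope apron
    n_potholes: int = 8
    pothole_depth: tuple[float, float] = (2.9, 3.1)
    pothole_radius: tuple[float, float] = (30.0, 55.0)
    pothole_shoulder: float = 10.0
    pothole_zone_depth: float = 0.2  # pit influence (m) that counts as zone 1
    # EMI model (mS/m)
    hh_base: float = 47.0
    hh_elev_coef: float = -8.5
    hh_noise_sd: float = 5.0
    hh_zone1_offset: float = 8.0
    vv_base: float = 32.6
    vv_elev_coef: float = -7.0
    vv_noise_sd: float = 4.0
    vv_zone1_offset: float = 6.5
    emi_floor: float = 0.5
    # sled transects: dense along track, sparser between passes
    transect_spacing: float = 20.0
    along_track_spacing: float = 5.0
    # sanity envelopes the generated EMI points should land in
    hh_mean_range: tuple[float, float] = (40.0, 54.0)
    hh_sd_range: tuple[float, float] = (8.0, 20.0)
    vv_mean_range: tuple[float, float] = (26.0, 40.0)
    vv_sd_range: tuple[float, float] = (7.0, 16.0)
    indicators: dict[str, IndicatorSpec] = field(default_factory=default_indicators)
    rng_seed: int = 0


@dataclass
class GroundTruth:
    """Planted per-cell zone ids and the pit-influence depth field."""

    zone: np.ndarray       # (rows, cols) ints in {1, 2, 3}
    pit_depth: np.ndarray  # (rows, cols) metres of depression influence

    def zone_at(self, location_index: np.ndarray) -> np.ndarray:
        return self.zone[location_index[:, 0], location_index[:, 1]]


def _rng(cfg: SyntheticFieldConfig, seed: int | None) -> np.random.Generator:
    return np.random.default_rng(cfg.rng_seed if seed is None else seed)


def generate_dem(
    cfg: SyntheticFieldConfig, seed: int | None = None
) -> tuple[GridField, GroundTruth]:
    """Build the DEM and its planted zone truth.

    Trend = the upper envelope of a south-dipping and a NE-dipping plane
    (a rounded ridge), smoothed, plus smoothed micro-relief noise, minus
    Gaussian potholes; the result is rescaled so max-min elevation equals
    the configured relief exactly.
    """
    rng = _rng(cfg, seed)
    yy, xx = np.meshgrid(
        cfg.cell_size * np.arange(cfg.rows),
        cfg.cell_size * np.arange(cfg.cols),
        indexing="ij",
    )
    plane_s = cfg.slope_south * yy
    plane_ne = -cfg.slope_ne * (xx + yy) / np.sqrt(2.0)
    plane_s = plane_s - plane_s.mean()
    plane_ne = plane_ne - plane_ne.mean()
    trend = np.maximum(plane_s, plane_ne)
    if cfg.smooth_sigma_cells > 0:
        trend = gaussian_filter(trend, cfg.smooth_sigma_cells, mode="nearest")
    noise = rng.standard_normal((cfg.rows, cfg.cols))
    if cfg.microrelief_sd > 0:
        noise = gaussian_filter(noise, 3.0, mode="nearest")
        sd = noise.std()
        noise = cfg.microrelief_sd * (noise / sd if sd > 0 else noise)
    else:
        noise = np.zeros_like(trend)
    pit = np.zeros_like(trend)
    for _ in range(cfg.n_potholes):
        cx = rng.uniform(0.05, 0.95) * cfg.cell_size * (cfg.cols - 1)
        cy = rng.uniform(0.05, 0.95) * cfg.cell_size * (cfg.rows - 1)
        depth = rng.uniform(*cfg.pothole_depth)
        radius = rng.uniform(*cfg.pothole_radius)
        d = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
        # flat-bottomed bowl: full depth inside the rim, decaying to ~0
        # within a couple of shoulder widths outside it
        pit += depth * 0.5 * (1.0 - np.tanh((d - radius) / cfg.pothole_shoulder))
    z = trend + noise - pit
    ptp = float(np.ptp(z))
    if ptp > 0:
        scale = cfg.relief / ptp
        z = cfg.base_elevation + (z - z.min()) * scale
        pit_scaled = pit * scale
    else:
        z = np.full_like(z, cfg.base_elevation)
        pit_scaled = pit
    zone = np.where(
        pit_scaled > cfg.pothole_zone_depth,
        ZONE_POTHOLE,
        np.where(plane_s >= plane_ne, ZONE_SOUTH, ZONE_NORTHEAST),
    )
    if cfg.n_potholes > 0 and not np.any(zone == ZONE_POTHOLE):
        raise SyntheticConfigError("pothole configuration produced an empty zone 1")
    if (cfg.slope_south > 0 or cfg.slope_ne > 0):
        for z_id in (ZONE_SOUTH, ZONE_NORTHEAST):
            if cfg.slope_south > 0 and cfg.slope_ne > 0 and not np.any(zone == z_id):
                raise SyntheticConfigError(f"trend configuration left zone {z_id} empty")
    dem = GridField(
        z, 0.0, 0.0, cfg.cell_size, attribute_name="elevation", units="m"
    )
    return dem, GroundTruth(zone.astype(int), pit_scaled)


def generate_emi(
    dem: GridField,
    cfg: SyntheticFieldConfig,
    truth: GroundTruth | None = None,
    seed: int | None = None,
) -> tuple[PointSamples, PointSamples]:
    """H-H and V-V EMI point transects over the DEM.

    EMI = base + coef * (elevation - mean elevation) + pothole-zone offset
    + Gaussian noise, sampled along parallel sled passes (dense along
    track, ``transect_spacing`` apart); draws below the floor are clipped.
    """
    rng = _rng(cfg, seed)
    width = dem.cell_size * (dem.shape[1] - 1)
    height = dem.cell_size * (dem.shape[0] - 1)
    line_xs = np.arange(cfg.transect_spacing / 2.0, width, cfg.transect_spacing)
    ys = np.arange(0.0, height + 1e-9, cfg.along_track_spacing)
    px = np.repeat(line_xs, len(ys))
    py = np.tile(ys, len(line_xs))
    col = np.clip(np.rint(px / dem.cell_size).astype(int), 0, dem.shape[1] - 1)
    row = np.clip(np.rint(py / dem.cell_size).astype(int), 0, dem.shape[0] - 1)
    z = dem.values[row, col]
    dz = z - dem.values[~dem.nodata_mask].mean()
    in_zone1 = (
        (truth.zone[row, col] == ZONE_POTHOLE).astype(float)
        if truth is not None else np.zeros_like(z)
    )
    out = []
    for base, coef, sd, offs, name in (
        (cfg.hh_base, cfg.hh_elev_coef, cfg.hh_noise_sd, cfg.hh_zone1_offset, "emi_hh"),
        (cfg.vv_base, cfg.vv_elev_coef, cfg.vv_noise_sd, cfg.vv_zone1_offset, "emi_vv"),
    ):
        vals = base + coef * dz + offs * in_zone1 + rng.normal(0.0, sd, len(z))
        vals = np.maximum(vals, cfg.emi_floor)
        out.append(PointSamples(px, py, vals, attribute_name=name))
    return out[0], out[1]


def generate_sample_table(
    truth: GroundTruth,
    design: SamplingDesign | None,
    cfg: SyntheticFieldConfig,
    fm: FeatureMatrix | None = None,
    n_per_zone: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw a per-site indicator table (the stand-in for a field campaign).

    Two modes:

    * with a ``design`` (and its ``fm``): one row per selected site, the
      ``cluster`` column carrying the pipeline's cluster ids and ``role``
      marking each cluster's BMU; landscape attributes are copied from the
      feature matrix;
    * with ``n_per_zone``: sites stratified directly by the planted truth
      (``cluster`` = true zone), for testing the indicator statistics in
      isolation.

    Each indicator is drawn Normal(zone mean, SD), the zone-1 mean being
    ``mean * zone1_multiplier``.
    """
    rng = _rng(cfg, seed)
    rows: list[dict] = []
    if design is not None:
        if fm is None:
            raise ValueError("a feature matrix is required to place design sites")
        x, y = fm.coords()
        zones = truth.zone_at(fm.location_index)
        for cs in design.clusters:
            for j, r in enumerate(cs.site_rows):
                rec = {
                    "sample_id": f"c{cs.cluster}_s{j}",
                    "x": x[r], "y": y[r],
                    "cluster": cs.cluster,
                    "role": "BMU" if j == 0 else "additional",
                    "true_zone": int(zones[r]),
                }
                for col in fm.columns:
                    vals = fm.data[:, fm.columns.index(col)]
                    rec[col] = vals[r]
                rows.append(rec)
    elif n_per_zone is not None:
        for z_id in sorted(np.unique(truth.zone)):
            cells = np.argwhere(truth.zone == z_id)
            take = rng.choice(len(cells), size=min(n_per_zone, len(cells)),
                              replace=False)
            for j, ci in enumerate(take):
                r, c = cells[ci]
                rows.append({
                    "sample_id": f"z{z_id}_s{j}",
                    "x": c * cfg.cell_size, "y": r * cfg.cell_size,
                    "cluster": int(z_id),
                    "role": "BMU" if j == 0 else "additional",
                    "true_zone": int(z_id),
                })
    else:
        raise ValueError("provide either a design or n_per_zone")
    table = pd.DataFrame(rows)
    zone1 = (table["true_zone"] == ZONE_POTHOLE).to_numpy()
    for name, spec in cfg.indicators.items():
        mean = np.where(zone1, spec.mean * spec.zone1_multiplier, spec.mean)
        table[name] = rng.normal(mean, spec.sd)
    if {"mbc", "mbn"} <= set(cfg.indicators):
        with np.errstate(divide="ignore", invalid="ignore"):
            table["mbc_mbn_ratio"] = table["mbc"] / table["mbn"]
    return table


def score_zone_recovery(
    labels: np.ndarray, truth: GroundTruth, location_index: np.ndarray
) -> float:
    """Fraction of locations whose cluster matches its planted zone,
    maximized over all assignments of cluster ids to zone ids."""
    labels = np.asarray(labels)
    true_zones = truth.zone_at(np.asarray(location_index))
    zone_ids = sorted(np.unique(true_zones))
    label_ids = sorted(np.unique(labels))
    size = max(len(zone_ids), len(label_ids))
    best = 0.0
    for perm in permutations(range(size), len(label_ids)):
        mapped = np.full(len(labels), -1)
        for li, pi in zip(label_ids, perm):
            if pi < len(zone_ids):
                mapped[labels == li] = zone_ids[pi]
        best = max(best, float(np.mean(mapped == true_zones)))
    return best
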