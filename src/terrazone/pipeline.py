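"""End-to-end zone-delineation pipeline.

Wires the stages together: DEM -> terrain attributes, EMI points -> IDW
grids, feature matrix -> normalized, SOM training -> U-matrix, K-means on
the codebook -> field zones, and BMU + spread sampling sites.  This is the
programmatic equivalent of the ``terrazone run-all`` command.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import cluster as _cluster
from . import som as _som
from .terrain import (
    FeatureMatrix,
    GridField,
    PointSamples,
    build_feature_matrix,
    derive_aspect,
    derive_plan_curvature,
    derive_slope,
    idw_interpolate,
    normalize_features,
)


@dataclass
class PipelineResult:
    layers: dict[str, GridField]
    fm_raw: FeatureMatrix
    fm: FeatureMatrix  # normalized
    codebook: _som.SOMCodebook
    umatrix: _som.UMatrix
    cluster_model: _cluster.ClusterModel
    design: _cluster.SamplingDesign
    seed: int

    def cluster_raster(self) -> GridField:
        """Integer cluster labels on the field grid (nodata preserved)."""
        shape = self.layers["elevation"].shape
        vals = np.full(shape, np.nan)
        idx = self.fm.location_index
        vals[idx[:, 0], idx[:, 1]] = self.cluster_model.location_labels
        ref = self.layers["elevation"]
        return GridField(
            vals, ref.origin_x, ref.origin_y, ref.cell_size,
            attribute_name="cluster", units="",
        )


def build_features(
    dem: GridField,
    emi_hh: PointSamples,
    emi_vv: PointSamples,
    idw_power: float = 2.0,
    idw_neighbors: int = 12,
) -> tuple[dict[str, GridField], FeatureMatrix]:
    """Terrain derivatives + IDW EMI grids -> raw feature matrix."""
    layers = {
        "elevation": dem,
        "slope": derive_slope(dem),
        "aspect": derive_aspect(dem),
        "plan_curvature": derive_plan_curvature(dem),
        "emi_hh": idw_interpolate(emi_hh, dem, idw_power, idw_neighbors, "emi_hh"),
        "emi_vv": idw_interpolate(emi_vv, dem, idw_power, idw_neighbors, "emi_vv"),
    }
    fm_raw = build_feature_matrix([layers[name] for name in (
        "elevation", "slope", "aspect", "plan_curvature", "emi_hh", "emi_vv",
    )])
    return layers, fm_raw


def run_pipeline(
    dem: GridField,
    emi_hh: PointSamples,
    emi_vv: PointSamples,
    k: int = 3,
    n_additional: int = 11,
    som_shape: tuple[int, int] | None = None,
    topology: str = "hexagonal",
    seed: int = 0,
    idw_power: float = 2.0,
    idw_neighbors: int = 12,
    schedule: _som.TrainingSchedule | None = None,
) -> PipelineResult:
    """Run the whole delineation and site-selection pipeline.

    One integer ``seed`` drives SOM input sampling and the K-means
    restarts, so results are reproducible end to end.
    """
    layers, fm_raw = build_features(dem, emi_hh, emi_vv, idw_power, idw_neighbors)
    fm = normalize_features(fm_raw)
    rows, cols = som_shape if som_shape is not None else _som.default_grid_shape(fm)
    cb0 = _som.init_codebook(fm, rows, cols, topology, seed=seed)
    sched = schedule or _som.TrainingSchedule.default(fm.n, rows, cols, seed=seed)
    cb = _som.train(cb0, fm, sched)
    um = _som.compute_umatrix(cb)
    cm = _cluster.cluster_field(cb, fm, k, seed=seed)
    design = _cluster.select_additional_sites(cm, fm, n_additional)
    return PipelineResult(layers, fm_raw, fm, cb, um, cm, design, seed)


def run_recovery_trial(cfg=None, seed: int = 0, k: int = 3, **pipeline_kwargs):
    """Simulate a field, run the pipeline, score planted-zone recovery.

    Returns ``(result, truth, accuracy)`` where ``accuracy`` is the
    fraction of grid locations assigned to their generating zone under the
    best cluster-to-zone relabeling.
    """
    from .synthetic import SyntheticFieldConfig, generate_dem, generate_emi
    from .synthetic import score_zone_recovery

    cfg = cfg or SyntheticFieldConfig()
    dem, truth = generate_dem(cfg, seed=seed)
    hh, vv = generate_emi(dem, cfg, truth, seed=seed + 10_000)
    result = run_pipeline(dem, hh, vv, k=k, seed=seed, **pipeline_kwargs)
    acc = score_zone_recovery(
        result.cluster_model.location_labels, truth, result.fm.location_index
    )
    return result, truth, acc
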