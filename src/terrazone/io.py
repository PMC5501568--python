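"""Readers and writers for the pipeline's interchange formats.

* ESRI ASCII grids (.asc) for all raster layers, cell-center registered
  internally (row 0 = southernmost) and flipped to the format's
  north-first row order on disk.
* CSV point files for EMI transects (columns x, y, emi_hh, emi_vv).
* The per-sample assay/indicator table (CSV or XLSX) with a synonym map
  for the column vocabulary of typical deposited spreadsheets.
* A versioned JSON bundle for trained codebooks, so clustering and site
  selection can be re-run without retraining.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .som import Phase, SOMCodebook, TrainingSchedule
from .terrain import FeatureMatrix, GridField, PointSamples


class ParseError(ValueError):
    pass


class SchemaError(ValueError):
    pass


# ---------------------------------------------------------------------------
# ESRI ASCII grids
# ---------------------------------------------------------------------------

_ESRI_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_esri_ascii(path, attribute_name: str = "", units: str = "") -> GridField:
    """Read an ESRI ASCII grid (6-line header + north-first rows)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _ESRI_HEADER_KEYS + ("nodata_value",):
            header[parts[0].lower()] = float(parts[1])
        else:
            break
    missing = [k for k in _ESRI_HEADER_KEYS if k not in header]
    if missing:
        raise ParseError(f"{path}: malformed header, missing {missing} (line {i + 1})")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    nodata = header.get("nodata_value")
    rows = []
    for j, line in enumerate(lines[i:], start=i + 1):
        if line.strip():
            vals = line.split()
            if len(vals) != ncols:
                raise ParseError(f"{path}: line {j} has {len(vals)} values, expected {ncols}")
            rows.append([float(v) for v in vals])
    if len(rows) != nrows:
        raise ParseError(f"{path}: {len(rows)} data rows, header says {nrows}")
    values = np.flipud(np.array(rows, dtype=float))  # file is north-first
    mask = None
    if nodata is not None:
        mask = values == nodata
        values = np.where(mask, np.nan, values)
    cell = header["cellsize"]
    return GridField(
        values,
        origin_x=header["xllcorner"] + cell / 2.0,
        origin_y=header["yllcorner"] + cell / 2.0,
        cell_size=cell,
        nodata_mask=mask,
        attribute_name=attribute_name or path.stem,
        units=units,
    )


def write_esri_ascii(gf: GridField, path, nodata_value: float = -9999.0,
                     fmt: str = "%.8g") -> None:
    path = Path(path)
    vals = np.where(gf.nodata_mask, nodata_value, gf.values)
    with path.open("w") as fh:
        fh.write(f"ncols {gf.shape[1]}\n")
        fh.write(f"nrows {gf.shape[0]}\n")
        fh.write(f"xllcorner {gf.origin_x - gf.cell_size / 2.0:.8g}\n")
        fh.write(f"yllcorner {gf.origin_y - gf.cell_size / 2.0:.8g}\n")
        fh.write(f"cellsize {gf.cell_size:.8g}\n")
        fh.write(f"NODATA_value {nodata_value:.8g}\n")
        for row in np.flipud(vals):
            fh.write(" ".join(fmt % v for v in row) + "\n")


# ---------------------------------------------------------------------------
# EMI point CSV
# ---------------------------------------------------------------------------


def read_emi_points(path) -> tuple[PointSamples, PointSamples]:
    """CSV with header x, y, emi_hh, emi_vv -> two PointSamples."""
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    need = ["x", "y", "emi_hh", "emi_vv"]
    missing = [c for c in need if c not in cols]
    if missing:
        raise SchemaError(f"{path}: missing EMI column(s) {missing}")
    hh = PointSamples(df[cols["x"]], df[cols["y"]], df[cols["emi_hh"]], "emi_hh")
    vv = PointSamples(df[cols["x"]], df[cols["y"]], df[cols["emi_vv"]], "emi_vv")
    return hh, vv


def write_emi_points(hh: PointSamples, vv: PointSamples, path) -> None:
    pd.DataFrame({"x": hh.x, "y": hh.y, "emi_hh": hh.values, "emi_vv": vv.values}
                 ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Feature matrix CSV
# ---------------------------------------------------------------------------


def write_feature_matrix(fm: FeatureMatrix, path) -> None:
    x, y = fm.coords()
    df = pd.DataFrame({
        "grid_row": fm.location_index[:, 0],
        "grid_col": fm.location_index[:, 1],
        "x": x, "y": y,
    })
    for j, c in enumerate(fm.columns):
        df[c] = fm.data[:, j]
    if fm.is_normalized:
        for j, c in enumerate(fm.columns):
            df[f"{c}_raw"] = (
                fm.data[:, j] * fm.normalization["std"][j]
                + fm.normalization["mean"][j]
            )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Sample table (deposited-spreadsheet vocabulary)
# ---------------------------------------------------------------------------

#: canonical column -> recognized header synonyms (matched after lowering
#: and stripping non-alphanumerics); extend via the ``synonyms`` argument.
SAMPLE_TABLE_SYNONYMS: dict[str, tuple[str, ...]] = {
    "x": ("x", "easting", "eastingm", "utmeasting"),
    "y": ("y", "northing", "northingm", "utmnorthing"),
    "cluster": ("cluster", "assignedcluster", "somcluster", "group", "zone"),
    "role": ("role", "sitetype", "sitetypebmu"),
    "sample_id": ("sampleid", "id", "sample", "site"),
    "moisture": ("moisture", "moisturegg", "gravimetricwatercontent", "watercontentgg"),
    "fw_dw_ratio": ("fwdwratio", "fwdw", "freshweightdryweightratio"),
    "ph": ("ph", "soilph"),
    "mbc": ("mbc", "mbcugcgdw", "microbialbiomasscarbon", "microbialbiomassc"),
    "mbn": ("mbn", "mbnugngdw", "microbialbiomassnitrogen", "microbialbiomassn"),
    "eoc": ("eoc", "doc", "extractableorganiccarbon", "eocugcg1soil"),
    "specific_c_min": ("specificcmin", "specificcmineralization",
                       "specificcarbonmineralization", "cminspecific"),
    "specific_n_min": ("specificnmin", "specificnmineralization",
                       "specificnitrogenmineralization", "nminspecific"),
    "c_min": ("cmin", "cmineralization", "carbonmineralization"),
    "n_min": ("nmin", "nmineralization", "nitrogenmineralization"),
    "nitrate": ("nitrate", "no3", "no3n"),
    "ammonium": ("ammonium", "nh4", "nh4n", "ammonia"),
    "total_c_pct": ("totalcpct", "tc", "percenttotalcarbon", "totalcarbon", "ptc"),
    "total_n_pct": ("totalnpct", "tn", "percenttotalnitrogen", "totalnitrogen", "ptn"),
    "mbc_mbn_ratio": ("mbcmbnratio", "mbcmbn", "mbctombn"),
    "elevation": ("elevation", "elevationm", "elevm"),
    "slope": ("slope", "slopepct", "slopepercent"),
    "aspect": ("aspect", "aspectdegrees", "slopeaspect"),
    "plan_curvature": ("plancurvature", "planarcurvature", "plancurv"),
    "emi_hh": ("emihh", "hhemi", "hhemimsm", "horizontalemi",
               "horizontalpolarizationemi"),
    "emi_vv": ("emivv", "vvemi", "vvemimsm", "verticalemi",
               "verticalpolarizationemi"),
}

INDICATOR_COLUMNS = (
    "eoc", "mbc", "total_c_pct", "mbn", "total_n_pct", "specific_c_min",
    "specific_n_min", "nitrate", "ammonium", "n_min", "c_min",
    "mbc_mbn_ratio", "ph", "moisture",
)


def _squash(name: str) -> str:
    return re.sub(r"[^a-z0-9]", "", str(name).lower())


def read_sample_table(path, synonyms: dict | None = None) -> pd.DataFrame:
    """Read the per-sample table, mapping headers to canonical names.

    Requires coordinates, a cluster id, and at least one indicator column;
    unrecognized columns are preserved untouched.  Accepts CSV or XLSX.
    """
    path = Path(path)
    df = pd.read_excel(path) if path.suffix.lower() in (".xlsx", ".xls") \
        else pd.read_csv(path)
    lookup: dict[str, str] = {}
    table = {**SAMPLE_TABLE_SYNONYMS, **(synonyms or {})}
    for canonical, names in table.items():
        squashed = {_squash(n) for n in names} | {_squash(canonical)}
        for col in df.columns:
            if _squash(col) in squashed and canonical not in lookup.values():
                lookup[col] = canonical
                break
    df = df.rename(columns=lookup)
    missing = [c for c in ("x", "y", "cluster") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    if not any(c in df.columns for c in INDICATOR_COLUMNS):
        raise SchemaError(f"{path}: no recognizable indicator column found")
    return df


# ---------------------------------------------------------------------------
# Codebook bundle
# ---------------------------------------------------------------------------

_CODEBOOK_FORMAT = 1


def save_codebook(cb: SOMCodebook, path, fm: FeatureMatrix | None = None,
                  schedule: TrainingSchedule | None = None) -> None:
    doc = {
        "format": _CODEBOOK_FORMAT,
        "rows": cb.rows,
        "cols": cb.cols,
        "topology": cb.topology,
        "columns": list(cb.columns),
        "vectors": cb.vectors.tolist(),
    }
    if fm is not None and fm.is_normalized:
        doc["normalization"] = {
            "mean": fm.normalization["mean"].tolist(),
            "std": fm.normalization["std"].tolist(),
        }
    if schedule is not None:
        doc["schedule"] = {
            "rng_seed": schedule.rng_seed,
            "phases": [vars(p) for p in schedule.phases],
        }
    Path(path).write_text(json.dumps(doc))


def load_codebook(path) -> tuple[SOMCodebook, dict]:
    """Returns the codebook and the rest of the bundle (normalization, schedule)."""
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != _CODEBOOK_FORMAT:
        raise ParseError(f"{path}: unsupported codebook format {doc.get('format')}")
    cb = SOMCodebook(
        doc["rows"], doc["cols"], doc["topology"],
        np.array(doc["vectors"], dtype=float), tuple(doc.get("columns", ())),
    )
    extras = {k: doc[k] for k in ("normalization", "schedule") if k in doc}
    if "schedule" in extras:
        sched = extras["schedule"]
        extras["schedule"] = TrainingSchedule(
            [Phase(**p) for p in sched["phases"]], rng_seed=sched["rng_seed"]
        )
    return cb, extras
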