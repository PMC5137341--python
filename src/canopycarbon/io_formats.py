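"""Readers and writers for every external representation the pipeline touches.

Coordinate conventions used throughout the package:

* all planimetric coordinates are metres in a single projected CRS;
* raster row 0 is the northernmost row; pixel ``(r, c)`` covers the half-open
  square ``[origin_x + c*res, origin_x + (c+1)*res) x
  (origin_y - (r+1)*res, origin_y - r*res]`` with the origin anchored at the
  top-left pixel *corner*;
* distances and areas are metres / m2, stem diameters cm, biomass kg, carbon
  density Mg C per hectare — conversions happen only at module boundaries.

Supported formats: XYZ-CSV and LAS 1.2 point clouds, single-band GeoTIFF
rasters, multi-band GeoTIFF hyperspectral cubes, GeoJSON crown polygons and
UTF-8 CSV tables.
"""

from __future__ import annotations

import json
import logging
import struct
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Polygon, mapping

logger = logging.getLogger(__name__)

# GeoTIFF tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GDAL_NODATA = 42113


class FormatError(ValueError):
    """A file could not be parsed under the named dialect."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class PointCloud:
    """Height-normalized laser returns.

    ``z`` is metres above ground; small negative noise (>= -0.5 m) is
    tolerated.  ``return_number`` and ``num_returns`` follow LAS semantics
    (1-based, return_number <= num_returns).
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    return_number: np.ndarray
    num_returns: np.ndarray
    is_ground: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.return_number = np.asarray(self.return_number, dtype=np.int32)
        self.num_returns = np.asarray(self.num_returns, dtype=np.int32)
        if self.is_ground is None:
            self.is_ground = np.zeros(self.x.shape, dtype=bool)
        self.is_ground = np.asarray(self.is_ground, dtype=bool)
        self.validate()

    def __len__(self) -> int:
        return self.x.size

    def validate(self) -> None:
        n = self.x.size
        for name in ("y", "z", "return_number", "num_returns", "is_ground"):
            if getattr(self, name).size != n:
                raise ValueError(f"field {name!r} length mismatch")
        if n == 0:
            raise FormatError("empty point cloud")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()
                and np.isfinite(self.z).all()):
            raise FormatError("non-finite coordinates in point cloud")
        if self.z.min() < -0.5:
            raise FormatError(
                f"z below -0.5 m ({self.z.min():.3f}); cloud must be height-normalized")
        if (self.return_number < 1).any():
            raise FormatError("return_number must be >= 1")
        if (self.return_number > self.num_returns).any():
            raise FormatError("return_number exceeds num_returns")

    def first_returns(self) -> "PointCloud":
        m = self.return_number == 1
        return PointCloud(self.x[m], self.y[m], self.z[m],
                          self.return_number[m], self.num_returns[m],
                          self.is_ground[m])


@dataclass
class RasterGrid:
    """Georeferenced single-band grid (CHM, label map, carbon map)."""

    origin_x: float
    origin_y: float
    resolution: float
    values: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def world_to_pixel(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map world coordinates to (row, col) under the half-open convention."""
        col = np.floor((np.asarray(x) - self.origin_x) / self.resolution).astype(int)
        row = np.floor((self.origin_y - np.asarray(y)) / self.resolution - 1e-12).astype(int)
        return row, col

    def pixel_center(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        x = self.origin_x + (np.asarray(col) + 0.5) * self.resolution
        y = self.origin_y - (np.asarray(row) + 0.5) * self.resolution
        return x, y

    def copy_with(self, values: np.ndarray) -> "RasterGrid":
        return RasterGrid(self.origin_x, self.origin_y, self.resolution,
                          np.asarray(values, dtype=float), self.nodata)


@dataclass
class HyperCube:
    """Multi-band reflectance raster sharing RasterGrid geometry.

    ``band_values`` has shape (n_bands, n_rows, n_cols); ``wavelengths`` is
    nm per band.
    """

    origin_x: float
    origin_y: float
    resolution: float
    band_values: np.ndarray
    wavelengths: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.band_values = np.asarray(self.band_values, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.band_values.ndim != 3:
            raise ValueError("band_values must be (bands, rows, cols)")
        if self.wavelengths.size != self.band_values.shape[0]:
            raise ValueError("one wavelength per band required")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        valid = self.band_values != self.nodata
        if (self.band_values[valid] < 0).any():
            raise ValueError("negative reflectances")

    @property
    def n_bands(self) -> int:
        return self.band_values.shape[0]

    @property
    def n_rows(self) -> int:
        return self.band_values.shape[1]

    @property
    def n_cols(self) -> int:
        return self.band_values.shape[2]

    def geometry(self) -> RasterGrid:
        return RasterGrid(self.origin_x, self.origin_y, self.resolution,
                          np.zeros(self.band_values.shape[1:]), self.nodata)


# ---------------------------------------------------------------------------
# point clouds
# ---------------------------------------------------------------------------

_XYZ_REQUIRED = ("x", "y", "z")


def read_point_cloud(path, fmt: str = "xyz_csv") -> PointCloud:
    """Read a height-normalized point cloud from ``path``.

    ``fmt`` is ``"xyz_csv"`` (header row with columns
    ``x,y,z[,return_number,num_returns,classification]``) or ``"las"``
    (LAS 1.2, point formats 0/1).  Records without return numbers get
    ``return_number = num_returns = 1`` with a logged warning.
    """
    if fmt == "xyz_csv":
        return _read_xyz_csv(path)
    if fmt == "las":
        return _read_las(path)
    raise ValueError(f"unknown point-cloud format {fmt!r}")


def _read_xyz_csv(path) -> PointCloud:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - message path
        raise FormatError(f"unreadable XYZ-CSV {path}: {exc}") from exc
    missing = [c for c in _XYZ_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if len(df) == 0:
        raise FormatError(f"{path}: empty point cloud")
    if "return_number" in df.columns and "num_returns" in df.columns:
        rn = df["return_number"].to_numpy()
        nr = df["num_returns"].to_numpy()
    else:
        logger.warning("%s: no return numbers; assuming single returns", path)
        rn = np.ones(len(df), dtype=int)
        nr = np.ones(len(df), dtype=int)
    is_ground = (df["classification"].to_numpy() == 2
                 if "classification" in df.columns else None)
    return PointCloud(df["x"].to_numpy(), df["y"].to_numpy(), df["z"].to_numpy(),
                      rn, nr, is_ground)


def write_point_cloud(cloud: PointCloud, path, fmt: str = "xyz_csv") -> None:
    if fmt == "xyz_csv":
        pd.DataFrame({
            "x": cloud.x, "y": cloud.y, "z": cloud.z,
            "return_number": cloud.return_number,
            "num_returns": cloud.num_returns,
            "classification": np.where(cloud.is_ground, 2, 1),
        }).to_csv(path, index=False)
    elif fmt == "las":
        _write_las(cloud, path)
    else:
        raise ValueError(f"unknown point-cloud format {fmt!r}")


# Minimal LAS 1.2 support (point record format 0).  Only the fields the
# pipeline uses are kept: XYZ, return number / number of returns and the
# ground-classification bit.  Scale 0.001 m preserves millimetre precision.

_LAS_HEADER = struct.Struct("<4sHHLHH8sBB32s32sHHHLLBHL5L12d")
_LAS_POINT0 = struct.Struct("<lllHBBbBH")


def _write_las(cloud: PointCloud, path) -> None:
    scale = 0.001
    off = (float(cloud.x.min()), float(cloud.y.min()), float(cloud.z.min()))
    n = len(cloud)
    header_size = 227
    body = bytearray()
    for i in range(n):
        flags = (int(cloud.return_number[i]) & 0x7) | ((int(cloud.num_returns[i]) & 0x7) << 3)
        cls = 2 if cloud.is_ground[i] else 1
        body += _LAS_POINT0.pack(
            int(round((cloud.x[i] - off[0]) / scale)),
            int(round((cloud.y[i] - off[1]) / scale)),
            int(round((cloud.z[i] - off[2]) / scale)),
            0, flags, cls, 0, 0, 0)
    header = _LAS_HEADER.pack(
        b"LASF", 0, 0, 0, 0, 0, b"\0" * 8, 1, 2,
        b"canopycarbon".ljust(32, b"\0"), b"canopycarbon".ljust(32, b"\0"),
        1, 2026, header_size, header_size, 0, 0, _LAS_POINT0.size, n,
        n, 0, 0, 0, 0,
        scale, scale, scale, off[0], off[1], off[2],
        float(cloud.x.max()), float(cloud.x.min()),
        float(cloud.y.max()), float(cloud.y.min()),
        float(cloud.z.max()), float(cloud.z.min()))
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(bytes(body))


def _read_las(path) -> PointCloud:
    with open(path, "rb") as fh:
        raw = fh.read()
    if raw[:4] != b"LASF":
        raise FormatError(f"{path}: not a LAS file (bad signature)")
    try:
        hdr = _LAS_HEADER.unpack_from(raw, 0)
    except struct.error as exc:
        raise FormatError(f"{path}: truncated LAS header") from exc
    offset_to_points, point_fmt, rec_len, n = hdr[14], hdr[16], hdr[17], hdr[18]
    if point_fmt not in (0, 1):
        raise FormatError(f"{path}: unsupported LAS point format {point_fmt}")
    if n == 0:
        raise FormatError(f"{path}: empty point cloud")
    sx, sy, sz, ox, oy, oz = hdr[24:30]
    xs = np.empty(n); ys = np.empty(n); zs = np.empty(n)
    rn = np.empty(n, dtype=int); nr = np.empty(n, dtype=int)
    cls = np.empty(n, dtype=int)
    for i in range(n):
        base = offset_to_points + i * rec_len
        try:
            X, Y, Z, _inten, flags, c, _sa, _ud, _ps = _LAS_POINT0.unpack_from(raw, base)
        except struct.error as exc:
            raise FormatError(f"{path}: truncated at point record {i}") from exc
        xs[i] = X * sx + ox
        ys[i] = Y * sy + oy
        zs[i] = Z * sz + oz
        rn[i] = flags & 0x7
        nr[i] = (flags >> 3) & 0x7
        cls[i] = c & 0x1F
    if (rn == 0).any():
        logger.warning("%s: records without return numbers; assuming single returns", path)
        nr[rn == 0] = 1
        rn[rn == 0] = 1
    return PointCloud(xs, ys, zs, rn, nr, cls == 2)


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------


def write_raster(grid: RasterGrid, path) -> None:
    """Write a single-band GeoTIFF with pixel-scale/tiepoint georeferencing."""
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (grid.resolution, grid.resolution, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.origin_x, grid.origin_y, 0.0)),
        (_GDAL_NODATA, "s", 0, str(grid.nodata)),
    ]
    tifffile.imwrite(path, grid.values.astype(np.float64), extratags=extratags)


def read_raster(path) -> RasterGrid:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray()
        tags = page.tags
        scale = tags[_MODEL_PIXEL_SCALE].value
        tie = tags[_MODEL_TIEPOINT].value
        nodata = float(tags[_GDAL_NODATA].value) if _GDAL_NODATA in tags else -9999.0
    if values.ndim == 3:
        raise FormatError(f"{path}: expected single-band raster")
    return RasterGrid(float(tie[3]), float(tie[4]), float(scale[0]),
                      values.astype(float), nodata)


def write_hypercube(cube: HyperCube, path) -> None:
    """Write a multi-band GeoTIFF; band wavelengths stored in the description."""
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (cube.resolution, cube.resolution, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, cube.origin_x, cube.origin_y, 0.0)),
        (_GDAL_NODATA, "s", 0, str(cube.nodata)),
    ]
    desc = json.dumps({"wavelengths_nm": list(map(float, cube.wavelengths))})
    tifffile.imwrite(path, cube.band_values.astype(np.float64),
                     extratags=extratags, description=desc,
                     metadata=None, photometric="minisblack")


def read_hypercube(path) -> HyperCube:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = tif.asarray()
        tags = page.tags
        scale = tags[_MODEL_PIXEL_SCALE].value
        tie = tags[_MODEL_TIEPOINT].value
        nodata = float(tags[_GDAL_NODATA].value) if _GDAL_NODATA in tags else -9999.0
        desc = page.tags.get("ImageDescription")
        meta = json.loads(desc.value) if desc is not None else {}
    if values.ndim == 2:
        values = values[None]
    wl = np.asarray(meta.get("wavelengths_nm", np.arange(values.shape[0])), dtype=float)
    return HyperCube(float(tie[3]), float(tie[4]), float(scale[0]),
                     values.astype(float), wl, nodata)


# ---------------------------------------------------------------------------
# vectors and tables
# ---------------------------------------------------------------------------


def write_itc_polygons(itcs, path) -> None:
    """Write delineated crowns as a GeoJSON FeatureCollection.

    Attributes per feature: id, species, height_m, crown_area_m2, dbh_cm,
    agb_kg, carbon_kg.  Self-intersecting rings are rejected.
    """
    features = []
    for itc in itcs:
        poly = itc.polygon if isinstance(itc.polygon, Polygon) else Polygon(itc.polygon)
        if not poly.is_valid:
            raise ValueError(f"ITC {itc.id}: self-intersecting or invalid polygon")
        features.append({
            "type": "Feature",
            "geometry": mapping(poly),
            "properties": {
                "id": int(itc.id),
                "species": itc.species,
                "height_m": float(itc.height),
                "crown_area_m2": float(itc.crown_area),
                "dbh_cm": None if itc.dbh_cm is None else float(itc.dbh_cm),
                "agb_kg": None if itc.agb_kg is None else float(itc.agb_kg),
                "carbon_kg": None if itc.carbon_kg is None else float(itc.carbon_kg),
            },
        })
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_itc_polygons(path):
    """Read crowns back from GeoJSON into ITC records."""
    from .delineation import ITC, TreeTop

    with open(path, encoding="utf-8") as fh:
        fc = json.load(fh)
    itcs = []
    for feat in fc["features"]:
        poly = Polygon(feat["geometry"]["coordinates"][0])
        props = feat["properties"]
        cx, cy = poly.representative_point().x, poly.representative_point().y
        seed = TreeTop(row=-1, col=-1, x=cx, y=cy, apex_height=props["height_m"])
        itcs.append(ITC(id=props["id"], seed=seed, polygon=poly,
                        crown_area=props["crown_area_m2"], height=props["height_m"],
                        species=props.get("species"),
                        dbh_cm=props.get("dbh_cm"), agb_kg=props.get("agb_kg"),
                        carbon_kg=props.get("carbon_kg")))
    return itcs


def read_field_trees(path) -> pd.DataFrame:
    """Read a field-inventory table (tree id, plot id, x, y, species, dbh_cm, height_m)."""
    df = pd.read_csv(path)
    required = {"id", "x", "y", "species", "dbh_cm", "height_m"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    return df
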