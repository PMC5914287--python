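"""Raster data model, I/O and zonal aggregation.

The spatial universe is a single planar, equal-area grid (row-major,
north-up). Everything downstream — label rasters for administrative units,
elevation, masks, per-pixel population — lives on one shared
:class:`GridSpec`. Distances are Euclidean between pixel centers, in
projected kilometres; areas are pixel counts times the cell area. Real data
must be pre-projected to such a grid; synthetic worlds are natively planar.

Two raster dialects are supported: the Esri ASCII grid (plain text, the
format the published historical-population product ships in) and TIFF via
``tifffile`` (no geo-tags; the grid origin/cell size travel in the session
GridSpec).

Label rasters use 1-based positive integers, with 0 reserved for "outside
the universe". Value rasters use NaN off-universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigError

__all__ = [
    "GridSpec",
    "LabelRaster",
    "ValueRaster",
    "CensusTable",
    "read_raster",
    "write_raster",
    "zonal_sum",
    "zonal_mean",
    "pixel_centers",
]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the shared 1-km analysis grid.

    Parameters
    ----------
    n_rows, n_cols
        Grid shape; must be >= 1.
    cell_size_km
        Side of a square pixel in projected km (default 1, i.e. 1 km² pixels).
    origin
        (x, y) of the lower-left corner in projected km.
    nodata_value
        Sentinel written to files for off-universe pixels.
    """

    n_rows: int
    n_cols: int
    cell_size_km: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_value: float = -9999.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ConfigError(f"grid shape must be >=1, got {self.n_rows}x{self.n_cols}")
        if self.cell_size_km <= 0:
            raise ConfigError(f"cell_size_km must be positive, got {self.cell_size_km}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size_km**2


def pixel_centers(spec: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """(x, y) coordinates of every pixel center, each of shape (n_rows, n_cols).

    Row 0 is the northern edge; centers sit at origin + (col+0.5, row+0.5)·cell
    measured from the lower-left corner.
    """
    cs = spec.cell_size_km
    x0, y0 = spec.origin
    cols = np.arange(spec.n_cols)
    rows = np.arange(spec.n_rows)
    x = x0 + (cols + 0.5) * cs
    y = y0 + (spec.n_rows - 1 - rows + 0.5) * cs
    return np.meshgrid(x, y)


@dataclass
class LabelRaster:
    """Integer zone raster (county, tract, division, region, urban ...).

    ``labels`` holds 1-based unit ids; 0 marks pixels outside the universe.
    ``level`` is a free-form tag ('county', 'tract', 'division', ...).
    """

    spec: GridSpec
    labels: np.ndarray
    level: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.spec.shape:
            raise AlignmentError(
                f"label grid shape {self.labels.shape} != spec {self.spec.shape}"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.all(np.mod(self.labels[np.isfinite(self.labels)], 1) == 0):
                raise ConfigError("label raster holds non-integer values")
            self.labels = self.labels.astype(np.int64)
        if self.labels.min() < 0:
            raise ConfigError("labels must be >= 0 (0 = outside universe)")

    def ids(self) -> np.ndarray:
        """Sorted distinct nonzero labels present in the raster."""
        u = np.unique(self.labels)
        return u[u > 0]


@dataclass
class ValueRaster:
    """Real-valued raster (elevation in m, weight, or persons per pixel)."""

    spec: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise AlignmentError(
                f"value grid shape {self.values.shape} != spec {self.spec.shape}"
            )


def _check_aligned(a: LabelRaster | ValueRaster, b: LabelRaster | ValueRaster) -> None:
    if a.spec.shape != b.spec.shape or a.spec.cell_size_km != b.spec.cell_size_km:
        raise AlignmentError(f"rasters not aligned: {a.spec} vs {b.spec}")


# ---------------------------------------------------------------------------
# I/O

_ASCII_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def _read_ascii_grid(path: Path) -> tuple[GridSpec, np.ndarray]:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in _ASCII_HEADER_KEYS:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        data = np.loadtxt(fh, ndmin=2)
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise IOError(f"{path}: missing ASCII grid header field {key!r}")
    spec = GridSpec(
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
        cell_size_km=header["cellsize"],
        origin=(header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
        nodata_value=header.get("nodata_value", -9999.0),
    )
    if data.shape != spec.shape:
        raise IOError(f"{path}: data shape {data.shape} != declared {spec.shape}")
    return spec, data


def read_raster(
    path: str | Path,
    kind: str = "value",
    spec: GridSpec | None = None,
    level: str = "",
) -> LabelRaster | ValueRaster:
    """Read an Esri ASCII grid (.asc/.txt) or TIFF raster.

    Parameters
    ----------
    kind
        'label' -> :class:`LabelRaster` with nodata mapped to 0;
        'value' -> :class:`ValueRaster` with nodata mapped to NaN.
    spec
        Session grid to validate against; a shape or cell-size mismatch
        raises :class:`AlignmentError`.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"raster file not found: {path}")
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        data = np.asarray(tifffile.imread(path))
        fspec = spec or GridSpec(*data.shape)
        nodata = fspec.nodata_value
    else:
        fspec, data = _read_ascii_grid(path)
        nodata = fspec.nodata_value
    if spec is not None:
        if data.shape != spec.shape or fspec.cell_size_km != spec.cell_size_km:
            raise AlignmentError(
                f"{path}: grid {data.shape}/{fspec.cell_size_km} km does not match "
                f"session spec {spec.shape}/{spec.cell_size_km} km"
            )
        fspec = spec
    mask = data == nodata
    if kind == "label":
        labels = data.copy()
        labels[mask] = 0
        return LabelRaster(fspec, labels.astype(np.int64), level=level)
    values = data.astype(float)
    values[mask] = np.nan
    return ValueRaster(fspec, values)


def write_raster(raster: LabelRaster | ValueRaster, path: str | Path) -> None:
    """Write to Esri ASCII grid or TIFF, chosen by file suffix.

    Off-universe pixels (label 0 / NaN) are written as the spec's nodata
    sentinel; a read back through :func:`read_raster` round-trips bit-exactly.
    """
    path = Path(path)
    spec = raster.spec
    if isinstance(raster, LabelRaster):
        data = raster.labels.astype(float)
        data[raster.labels == 0] = spec.nodata_value
    else:
        data = raster.values.copy()
        data[~np.isfinite(data)] = spec.nodata_value
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, data)
        return
    with open(path, "w") as fh:
        fh.write(f"ncols {spec.n_cols}\n")
        fh.write(f"nrows {spec.n_rows}\n")
        fh.write(f"xllcorner {spec.origin[0]!r}\n")
        fh.write(f"yllcorner {spec.origin[1]!r}\n")
        fh.write(f"cellsize {spec.cell_size_km!r}\n")
        fh.write(f"NODATA_value {spec.nodata_value!r}\n")
        np.savetxt(fh, data, fmt="%.17g")


# ---------------------------------------------------------------------------
# Zonal statistics

def zonal_sum(values: ValueRaster, zones: LabelRaster) -> dict[int, float]:
    """Sum of ``values`` over each nonzero zone label.

    Off-universe value pixels (NaN) are ignored. Labels absent from the
    raster are simply omitted from the result.
    """
    _check_aligned(values, zones)
    lab = zones.labels.ravel()
    val = values.values.ravel()
    ok = (lab > 0) & np.isfinite(val)
    sums = np.bincount(lab[ok], weights=val[ok])
    present = np.unique(lab[lab > 0])
    return {int(z): float(sums[z]) if z < len(sums) else 0.0 for z in present}


def zonal_mean(values: ValueRaster, zones: LabelRaster) -> dict[int, float]:
    """Arithmetic mean of ``values`` over on-universe pixels of each zone.

    Zones whose every pixel is off-universe are flagged missing (NaN),
    never silently reported as zero.
    """
    _check_aligned(values, zones)
    lab = zones.labels.ravel()
    val = values.values.ravel()
    ok = (lab > 0) & np.isfinite(val)
    sums = np.bincount(lab[ok], weights=val[ok])
    counts = np.bincount(lab[ok])
    out: dict[int, float] = {}
    for z in np.unique(lab[lab > 0]):
        z = int(z)
        if z < len(counts) and counts[z] > 0:
            out[z] = float(sums[z] / counts[z])
        else:
            out[z] = float("nan")
    return out


# ---------------------------------------------------------------------------
# Census tables

@dataclass
class CensusTable:
    """Long-format census ledger: one row per (unit_id, decade).

    Columns: ``unit_id`` (int), ``decade`` (int year), ``population``
    (persons, >= 0) and optionally ``area_km2`` (counties only).
    """

    df: pd.DataFrame = field(repr=False)

    REQUIRED = ("unit_id", "decade", "population")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ConfigError(f"census table missing columns {missing}")
        if (self.df["population"] < 0).any():
            raise ConfigError("census populations must be >= 0")

    @classmethod
    def read_csv(cls, path: str | Path) -> "CensusTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    def population(self, unit_id: int, decade: int) -> float:
        sel = self.df[(self.df.unit_id == unit_id) & (self.df.decade == decade)]
        if sel.empty:
            raise KeyError(f"no census row for unit {unit_id}, decade {decade}")
        return float(sel.population.iloc[0])

    def populations(self, decade: int) -> dict[int, float]:
        sel = self.df[self.df.decade == decade]
        return dict(zip(sel.unit_id.astype(int), sel.population.astype(float)))

    def area(self, unit_id: int) -> float:
        if "area_km2" not in self.df.columns:
            raise KeyError("census table has no area_km2 column")
        sel = self.df[self.df.unit_id == unit_id]
        if sel.empty:
            raise KeyError(f"no census row for unit {unit_id}")
        return float(sel.area_km2.iloc[0])

    def decades(self) -> list[int]:
        return sorted(self.df.decade.unique().tolist())
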