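"""Raster grids and co-registered environmental predictor stacks.

Rasters are stored as ESRI ASCII grids (``.asc``), a plain-text single-band
format. Row 0 of the array is the *northernmost* row, following the ASCII-grid
convention. All layers of an :class:`EnvStack` share one :class:`GridSpec` and
one nodata mask.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Georeferencing of a regular lon/lat grid (WGS84 degrees)."""

    nrows: int
    ncols: int
    xll: float
    yll: float
    cellsize: float
    nodata: float = NODATA

    @property
    def xur(self) -> float:
        return self.xll + self.ncols * self.cellsize

    @property
    def yur(self) -> float:
        return self.yll + self.nrows * self.cellsize

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of the center of cell ``(row, col)``; row 0 is the top."""
        lon = self.xll + (col + 0.5) * self.cellsize
        lat = self.yll + (self.nrows - row - 0.5) * self.cellsize
        return lon, lat

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays of shape (nrows, ncols) with lon and lat of every center."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        lon = self.xll + (cols + 0.5) * self.cellsize
        lat = self.yll + (self.nrows - rows - 0.5) * self.cellsize
        return np.broadcast_to(lon, (self.nrows, self.ncols)).copy(), np.broadcast_to(
            lat[:, None], (self.nrows, self.ncols)
        ).copy()

    def index_of(self, lon: float, lat: float) -> tuple[int, int]:
        """(row, col) of the cell containing a point; raises if outside."""
        col = int(math.floor((lon - self.xll) / self.cellsize))
        row = int(math.floor((self.yur - lat) / self.cellsize))
        # points exactly on the top/right edge belong to the edge cell
        if lon == self.xur:
            col = self.ncols - 1
        if lat == self.yll + self.nrows * self.cellsize:
            row = 0
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise ValueError(f"point ({lon}, {lat}) outside grid extent")
        return row, col

    def contains(self, lon: float, lat: float) -> bool:
        return self.xll <= lon <= self.xur and self.yll <= lat <= self.yur

    @property
    def cell_area_deg2(self) -> float:
        return self.cellsize**2


def read_ascii(path: str | Path) -> tuple[GridSpec, np.ndarray]:
    """Read an ESRI ASCII grid; nodata cells become NaN."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        nheader = 0
        for _ in range(6):
            line = fh.readline()
            key, _, val = line.partition(" ")
            key = key.strip().lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                header[key] = float(val)
                nheader += 1
            else:
                break
        fh.seek(pos)
        for _ in range(nheader):
            fh.readline()
        data = np.loadtxt(fh, dtype=float)
    spec = GridSpec(
        nrows=int(header["nrows"]),
        ncols=int(header["ncols"]),
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata=header.get("nodata_value", NODATA),
    )
    data = data.reshape(spec.nrows, spec.ncols)
    data[data == spec.nodata] = np.nan
    return spec, data


def write_ascii(path: str | Path, spec: GridSpec, values: np.ndarray, fmt: str = "%.6g") -> None:
    """Write a single-band ASCII grid; NaN cells become the nodata value."""
    values = np.asarray(values, dtype=float)
    if values.shape != (spec.nrows, spec.ncols):
        raise ValueError(f"array shape {values.shape} does not match grid {spec.nrows}x{spec.ncols}")
    out = np.where(np.isnan(values), spec.nodata, values)
    with open(path, "w") as fh:
        fh.write(f"ncols {spec.ncols}\n")
        fh.write(f"nrows {spec.nrows}\n")
        fh.write(f"xllcorner {spec.xll:.10g}\n")
        fh.write(f"yllcorner {spec.yll:.10g}\n")
        fh.write(f"cellsize {spec.cellsize:.10g}\n")
        fh.write(f"NODATA_value {spec.nodata:.10g}\n")
        np.savetxt(fh, out, fmt=fmt)


class EnvStack:
    """Named predictor layers on one grid with a shared nodata mask.

    Parameters
    ----------
    spec : GridSpec
        Shared georeferencing.
    layers : mapping of name -> 2D array
        Each array of shape ``(nrows, ncols)``; NaN marks nodata. A cell is
        valid only where *every* layer has data.
    """

    def __init__(self, spec: GridSpec, layers: Mapping[str, np.ndarray]):
        if not layers:
            raise ValueError("EnvStack requires at least one layer")
        self.spec = spec
        self.layers: dict[str, np.ndarray] = {}
        for name, arr in layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (spec.nrows, spec.ncols):
                raise ValueError(f"layer {name!r} shape {arr.shape} mismatches grid")
            if name in self.layers:
                raise ValueError(f"duplicate layer name {name!r}")
            self.layers[name] = arr
        mask = np.ones((spec.nrows, spec.ncols), dtype=bool)
        for arr in self.layers.values():
            mask &= ~np.isnan(arr)
        self.mask = mask

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def subset(self, names: Sequence[str]) -> "EnvStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"missing layers: {missing}")
        return EnvStack(self.spec, {n: self.layers[n] for n in names})

    def table(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Values of valid cells as an (n_valid, n_layers) matrix, row-major cell order."""
        names = list(names) if names is not None else self.names
        cols = [self.layers[n][self.mask] for n in names]
        return np.column_stack(cols)

    def valid_indices(self) -> np.ndarray:
        """(n_valid, 2) array of (row, col) of valid cells, row-major order."""
        rows, cols = np.nonzero(self.mask)
        return np.column_stack([rows, cols])

    def values_at(self, lons: Iterable[float], lats: Iterable[float],
                  names: Sequence[str] | None = None) -> np.ndarray:
        """Layer values at the cells containing the given points (NaN outside/nodata)."""
        names = list(names) if names is not None else self.names
        lons = np.asarray(list(lons), float)
        lats = np.asarray(list(lats), float)
        out = np.full((lons.size, len(names)), np.nan)
        for i, (lo, la) in enumerate(zip(lons, lats)):
            if not self.spec.contains(lo, la):
                continue
            r, c = self.spec.index_of(lo, la)
            out[i] = [self.layers[n][r, c] for n in names]
        return out

    def crop(self, xmin: float, ymin: float, xmax: float, ymax: float) -> "EnvStack":
        """Crop to the cells whose centers fall inside the bounding box."""
        lon, lat = self.spec.cell_centers()
        rows = np.nonzero((lat[:, 0] >= ymin) & (lat[:, 0] <= ymax))[0]
        cols = np.nonzero((lon[0] >= xmin) & (lon[0] <= xmax))[0]
        if rows.size == 0 or cols.size == 0:
            raise ValueError("crop box contains no cell centers")
        r0, r1 = rows.min(), rows.max() + 1
        c0, c1 = cols.min(), cols.max() + 1
        spec = GridSpec(
            nrows=int(r1 - r0),
            ncols=int(c1 - c0),
            xll=self.spec.xll + c0 * self.spec.cellsize,
            yll=self.spec.yll + (self.spec.nrows - r1) * self.spec.cellsize,
            cellsize=self.spec.cellsize,
            nodata=self.spec.nodata,
        )
        return EnvStack(spec, {n: a[r0:r1, c0:c1] for n, a in self.layers.items()})

    def mask_outside(self, geometry) -> "EnvStack":
        """Set cells whose centers fall outside a shapely geometry to nodata."""
        from shapely import contains_xy
        from shapely.prepared import prep  # noqa: F401  (shapely 2 vectorized path below)

        lon, lat = self.spec.cell_centers()
        inside = contains_xy(geometry, lon.ravel(), lat.ravel()).reshape(lon.shape)
        new = {}
        for n, a in self.layers.items():
            b = a.copy()
            b[~inside] = np.nan
            new[n] = b
        return EnvStack(self.spec, new)

    @classmethod
    def from_ascii_dir(cls, directory: str | Path, names: Sequence[str] | None = None) -> "EnvStack":
        """Load every ``*.asc`` in a directory (or a named subset) as one stack."""
        directory = Path(directory)
        paths = sorted(directory.glob("*.asc"))
        if names is not None:
            paths = [directory / f"{n}.asc" for n in names]
        if not paths:
            raise FileNotFoundError(f"no .asc layers in {directory}")
        spec = None
        layers = {}
        for p in paths:
            s, arr = read_ascii(p)
            if spec is None:
                spec = s
            elif s != spec:
                raise ValueError(f"layer {p.name} grid mismatch: {s} vs {spec}")
            layers[p.stem] = arr
        return cls(spec, layers)

    def to_ascii_dir(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for n, a in self.layers.items():
            write_ascii(directory / f"{n}.asc", self.spec, a)
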