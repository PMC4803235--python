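"""Categorical land-cover rasters and circular-buffer composition extraction.

The raster is a single-band integer grid in geographic coordinates with a
GlobCover-style legend (integer code -> class label).  Compositions are
percentages of valid cells whose *centres* fall inside a circular buffer
around a point; the buffer radius may be quoted in degrees (the 0.2 deg
home-range surrogate) or metres (the 1500-21000 m sensitivity sweep) and
the unit is carried through, never silently converted.

I/O uses the ESRI ASCII grid format (plain text) plus a JSON legend file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geo import haversine_km

#: GlobCover 2009 codes for the classes observed along the flyway
#: (cropland, mosaic, forest, shrub/grass, sparse, flooded, urban, bare, water).
GLOBCOVER_LEGEND: dict[int, str] = {
    11: "CRO1",
    14: "CRO2",
    20: "MOS1",
    30: "MOS2",
    50: "BFO2",
    70: "NFO1",
    90: "NFO2",
    100: "MFO1",
    110: "MOS3",
    120: "MOS4",
    130: "SHRU",
    140: "GRAS",
    150: "SVEG",
    180: "FVE2",
    190: "URBA",
    200: "BARE",
    210: "WATE",
}

#: Classes counted as cropland or cropland-bearing mosaic when scoring
#: habitat suitability in the synthetic world.
CROPLAND_MOSAIC_LABELS = ("CRO1", "CRO2", "MOS1", "MOS2")

DEFAULT_NODATA = 255


class EmptyCompositionError(ValueError):
    """Buffer misses the raster entirely or contains only nodata cells."""


@dataclass
class LandCoverRaster:
    """Integer class-code grid; row 0 is the northernmost row (ASCII-grid order)."""

    data: np.ndarray  # 2-D int array
    xll: float  # west edge (deg lon)
    yll: float  # south edge (deg lat)
    cellsize: float  # deg
    nodata: int = DEFAULT_NODATA
    legend: dict[int, str] = field(default_factory=lambda: dict(GLOBCOVER_LEGEND))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.size == 0:
            raise ValueError("raster data must be a non-empty 2-D array")
        codes = np.unique(self.data)
        illegal = [c for c in codes if c != self.nodata and int(c) not in self.legend]
        if illegal:
            raise ValueError(f"raster contains codes not in legend: {illegal}")

    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    def cell_center(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lon = self.xll + (np.asarray(col) + 0.5) * self.cellsize
        lat = self.yll + (self.nrows - 1 - np.asarray(row) + 0.5) * self.cellsize
        return lon, lat

    def write_ascii(self, path: str | Path, legend_path: str | Path | None = None) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"ncols {self.ncols}\n")
            fh.write(f"nrows {self.nrows}\n")
            fh.write(f"xllcorner {self.xll:.10g}\n")
            fh.write(f"yllcorner {self.yll:.10g}\n")
            fh.write(f"cellsize {self.cellsize:.10g}\n")
            fh.write(f"NODATA_value {self.nodata}\n")
            np.savetxt(fh, self.data, fmt="%d")
        if legend_path is not None:
            Path(legend_path).write_text(json.dumps({str(k): v for k, v in self.legend.items()}, indent=1))

    @classmethod
    def read_ascii(cls, path: str | Path, legend_path: str | Path | None = None) -> "LandCoverRaster":
        path = Path(path)
        header: dict[str, float] = {}
        with path.open() as fh:
            pos = fh.tell()
            for _ in range(6):
                line = fh.readline()
                key, _, val = line.partition(" ")
                key = key.strip().lower()
                if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                    header[key] = float(val)
                    pos = fh.tell()
                else:
                    break
            fh.seek(pos)
            data = np.loadtxt(fh, dtype=np.int64).reshape(int(header["nrows"]), int(header["ncols"]))
        legend = dict(GLOBCOVER_LEGEND)
        if legend_path is not None:
            legend = {int(k): v for k, v in json.loads(Path(legend_path).read_text()).items()}
        return cls(
            data,
            xll=header["xllcorner"],
            yll=header["yllcorner"],
            cellsize=header["cellsize"],
            nodata=int(header.get("nodata_value", DEFAULT_NODATA)),
            legend=legend,
        )


@dataclass
class HabitatComposition:
    point_id: str
    radius: float
    radius_unit: str  # "deg" or "m"
    percentages: dict[int, float]  # class code -> % of valid cells
    n_valid: int
    n_nodata: int


def _buffer_mask(raster: LandCoverRaster, lon: float, lat: float, radius: float, unit: str):
    """Rows/cols window plus boolean in-circle mask of cell centres."""
    if unit == "deg":
        dlat = dlon = radius
    elif unit == "m":
        dlat = radius / 111_320.0
        dlon = radius / (111_320.0 * max(np.cos(np.radians(lat)), 1e-6))
    else:
        raise ValueError(f"unknown radius unit {unit!r} (use 'deg' or 'm')")
    col_lo = int(np.floor((lon - dlon - raster.xll) / raster.cellsize - 0.5))
    col_hi = int(np.ceil((lon + dlon - raster.xll) / raster.cellsize + 0.5))
    north = raster.yll + raster.nrows * raster.cellsize
    row_lo = int(np.floor((north - (lat + dlat)) / raster.cellsize - 0.5))
    row_hi = int(np.ceil((north - (lat - dlat)) / raster.cellsize + 0.5))
    col_lo, col_hi = max(col_lo, 0), min(col_hi, raster.ncols)
    row_lo, row_hi = max(row_lo, 0), min(row_hi, raster.nrows)
    if col_lo >= col_hi or row_lo >= row_hi:
        return None
    rows, cols = np.meshgrid(np.arange(row_lo, row_hi), np.arange(col_lo, col_hi), indexing="ij")
    clon, clat = raster.cell_center(rows, cols)
    if unit == "deg":
        inside = (clon - lon) ** 2 + (clat - lat) ** 2 <= radius**2
    else:
        inside = haversine_km(clon, clat, lon, lat) * 1000.0 <= radius
    return rows, cols, inside


def extract_composition(
    raster: LandCoverRaster,
    lon: float,
    lat: float,
    radius: float,
    unit: str = "deg",
    point_id: str = "",
) -> HabitatComposition:
    """Per-class percentage cover of valid cells whose centre lies in the buffer."""
    win = _buffer_mask(raster, lon, lat, radius, unit)
    if win is None:
        raise EmptyCompositionError(f"point {point_id or (lon, lat)}: buffer outside raster")
    rows, cols, inside = win
    values = raster.data[rows[inside], cols[inside]]
    valid = values[values != raster.nodata]
    n_nodata = int(values.size - valid.size)
    if valid.size == 0:
        raise EmptyCompositionError(f"point {point_id or (lon, lat)}: no valid cells in buffer")
    pct = {
        code: 100.0 * float(np.count_nonzero(valid == code)) / valid.size for code in sorted(raster.legend)
    }
    return HabitatComposition(point_id, radius, unit, pct, int(valid.size), n_nodata)


def buffer_sweep_radii(min_m: float = 1500.0, step_m: float = 1500.0, max_m: float = 21000.0) -> list[float]:
    """Arithmetic radius ladder min, min+step, ... <= max (defaults give 14 radii)."""
    if not (0 < min_m <= max_m) or step_m <= 0:
        raise ValueError("need 0 < min <= max and step > 0")
    n = int(np.floor((max_m - min_m) / step_m + 1e-9)) + 1
    return [min_m + i * step_m for i in range(n)]


def composition_table(
    points: list[dict],
    raster: LandCoverRaster,
    radius: float,
    unit: str = "deg",
) -> pd.DataFrame:
    """Extract compositions for labelled use/availability points.

    ``points`` rows need keys point_id, bird_id, label ('use'/'available'),
    replicate (0 for use rows), lon, lat.  Returns one row per point with
    the percentage columns in fixed legend order; every row sums to 100.
    """
    codes = sorted(raster.legend)
    labels = [raster.legend[c] for c in codes]
    rows = []
    for p in points:
        comp = extract_composition(raster, p["lon"], p["lat"], radius, unit, point_id=str(p["point_id"]))
        row = {
            "point_id": p["point_id"],
            "bird_id": p["bird_id"],
            "label": p["label"],
            "replicate": p.get("replicate", 0),
            "lon": p["lon"],
            "lat": p["lat"],
            "radius": radius,
            "radius_unit": unit,
        }
        row.update({lab: comp.percentages[c] for c, lab in zip(codes, labels)})
        rows.append(row)
    return pd.DataFrame(rows)


def composition_columns(df: pd.DataFrame, legend: dict[int, str] | None = None) -> list[str]:
    """Names of the percentage columns present in a composition table."""
    labels = set((legend or GLOBCOVER_LEGEND).values())
    return [c for c in df.columns if c in labels]
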