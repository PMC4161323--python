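"""Grid construction, coastal covariates and tabular I/O.

All geometry is planar Euclidean in a single projected CRS with coordinates
in metres (an OSGB-style easting/northing frame).  The coastline is a land
polygon (or multipolygon) in that CRS; "sea" is everything outside it.
Grid indexing is row-major from the lower-left corner, coordinates refer to
cell centres.

Tabular data are plain delimited text (CSV with a header row); bathymetry is
an ESRI ASCII grid.  Depth is stored as positive metres below sea level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Point, box
from shapely.geometry.base import BaseGeometry
from shapely.prepared import prep

__all__ = [
    "GridCell",
    "SurveySegment",
    "AsciiRaster",
    "make_grid",
    "coast_distance",
    "depth_at",
    "read_ascii_grid",
    "filter_by_species_coverage",
    "season_of_month",
    "grid_to_frame",
    "read_grid_csv",
    "write_grid_csv",
    "read_segments_csv",
    "write_segments_csv",
    "read_observations_csv",
    "write_observations_csv",
]

M2_PER_KM2 = 1e6

SEGMENT_COLUMNS = [
    "segment_id", "platform", "season", "x", "y", "length_m",
    "strip_halfwidth_m", "covered_area_km2", "cdist_km", "depth_m",
    "species_recorded",
]
OBSERVATION_COLUMNS = [
    "segment_id", "species", "count", "behaviour", "perp_distance_m",
    "band_index", "sea_state",
]


@dataclass(frozen=True)
class GridCell:
    """One 3 km × 3 km (or coastal fraction) prediction cell."""

    cell_id: int
    x: float          # centroid easting, m
    y: float          # centroid northing, m
    area_km2: float   # sea area, <= full cell area
    cdist_km: float   # min distance from centroid to the coastline
    region: str = "main"
    is_sea: bool = True


@dataclass
class SurveySegment:
    """One unit of survey effort (a boat recording period or an aerial ~1 km leg)."""

    segment_id: str
    platform: str                 # "boat" | "aerial"
    season: str                   # "summer" | "winter"
    x: float
    y: float
    length_m: float
    covered_area_km2: float
    cdist_km: float = np.nan
    depth_m: float = np.nan
    strip_halfwidth_m: float = 300.0
    band_edges_m: tuple[float, ...] | None = None
    species_recorded: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.length_m <= 0:
            raise ValueError(f"segment {self.segment_id}: length must be > 0")
        if self.covered_area_km2 <= 0:
            raise ValueError(f"segment {self.segment_id}: covered_area must be > 0")


def season_of_month(month: int) -> str:
    """April–September is summer, October–March winter."""
    if not 1 <= month <= 12:
        raise ValueError(f"month {month} outside 1..12")
    return "summer" if 4 <= month <= 9 else "winter"


# ---------------------------------------------------------------------------
# Grid
# ---------------------------------------------------------------------------

def make_grid(bbox: tuple[float, float, float, float], cellsize: float,
              coastline: BaseGeometry | None = None,
              region: str = "main") -> list[GridCell]:
    """Tile ``bbox`` (xmin, ymin, xmax, ymax) with square cells and clip to sea.

    ``coastline`` is the land polygon; cells fully on land get
    ``is_sea=False`` and zero area, coastal cells get the sea fraction of the
    full cell area.  Cell ids run row-major from the lower-left.
    """
    if cellsize <= 0:
        raise ValueError("cellsize must be > 0")
    xmin, ymin, xmax, ymax = bbox
    nx = int(np.floor((xmax - xmin) / cellsize + 1e-9))
    ny = int(np.floor((ymax - ymin) / cellsize + 1e-9))
    if nx < 1 or ny < 1:
        raise ValueError("bounding box smaller than one cell")
    if coastline is not None and not coastline.is_valid:
        raise ValueError("coastline polygon is not valid geometry")
    full_area = cellsize * cellsize / M2_PER_KM2
    land = coastline
    prepared = prep(land) if land is not None else None
    cells: list[GridCell] = []
    cid = 0
    for j in range(ny):          # rows, lower-left first
        for i in range(nx):
            x0 = xmin + i * cellsize
            y0 = ymin + j * cellsize
            cx, cy = x0 + cellsize / 2, y0 + cellsize / 2
            if land is None:
                area, sea = full_area, True
            else:
                cell_geom = box(x0, y0, x0 + cellsize, y0 + cellsize)
                if prepared.disjoint(cell_geom):
                    area, sea = full_area, True
                elif prepared.contains_properly(cell_geom):
                    area, sea = 0.0, False
                else:
                    sea_area = cell_geom.difference(land).area / M2_PER_KM2
                    sea = sea_area > 1e-9
                    area = sea_area
            cd = coast_distance(cx, cy, land, warn_on_land=False) if land is not None else np.inf
            cells.append(GridCell(cell_id=cid, x=cx, y=cy, area_km2=area,
                                  cdist_km=cd, region=region, is_sea=sea))
            cid += 1
    return cells


def coast_distance(x: float, y: float, coastline: BaseGeometry | None,
                   warn_on_land: bool = True) -> float:
    """Minimum Euclidean distance (km) from the point to the coastline boundary.

    Points inside the land polygon return 0 with a warning rather than
    raising: survey positions occasionally digitise just onshore.
    """
    if coastline is None:
        return np.inf
    p = Point(x, y)
    if coastline.covers(p):
        if warn_on_land:
            warnings.warn(f"point ({x:.0f}, {y:.0f}) lies on land; cdist set to 0",
                          stacklevel=2)
        return 0.0
    return p.distance(coastline.boundary) / 1000.0


# ---------------------------------------------------------------------------
# Bathymetry (ESRI ASCII grid)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AsciiRaster:
    """A simple single-band raster: row 0 of ``values`` is the top (north) row."""

    values: np.ndarray       # (nrows, ncols)
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata: float = -9999.0

    @property
    def extent(self) -> tuple[float, float, float, float]:
        nr, nc = self.values.shape
        return (self.xllcorner, self.yllcorner,
                self.xllcorner + nc * self.cellsize,
                self.yllcorner + nr * self.cellsize)


def read_ascii_grid(path: str | Path) -> AsciiRaster:
    """Read an ESRI ASCII grid (6-line header + whitespace-separated values)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                    "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                    "nodata_value"}:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    values = values.reshape(nrows, ncols)
    return AsciiRaster(values=values, xllcorner=header["xllcorner"],
                       yllcorner=header["yllcorner"],
                       cellsize=header["cellsize"],
                       nodata=header.get("nodata_value", -9999.0))


def depth_at(x: float, y: float, raster: AsciiRaster) -> float:
    """Nearest-cell depth lookup (positive metres below sea level).

    Outside the raster extent, or on a nodata cell, returns NaN.
    """
    xmin, ymin, xmax, ymax = raster.extent
    if not (xmin <= x <= xmax and ymin <= y <= ymax):
        return np.nan
    nr, nc = raster.values.shape
    col = min(int((x - xmin) / raster.cellsize), nc - 1)
    row_from_bottom = min(int((y - ymin) / raster.cellsize), nr - 1)
    row = nr - 1 - row_from_bottom
    v = raster.values[row, col]
    return np.nan if v == raster.nodata else float(v)


# ---------------------------------------------------------------------------
# Species-coverage filtering
# ---------------------------------------------------------------------------

def filter_by_species_coverage(observations: pd.DataFrame,
                               segments: pd.DataFrame,
                               species: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep only effort from surveys that recorded ``species``.

    Surveys restricted to a subset of species (e.g. auk-only boat surveys)
    would otherwise contribute spurious zero effort for the other species and
    deflate their densities.  ``species_recorded`` is a ``;``-separated list,
    with ``"all"`` meaning every species was recorded.
    """
    def records(spp: str) -> bool:
        toks = {t.strip() for t in str(spp).split(";")}
        return "all" in toks or species in toks

    keep = segments["species_recorded"].map(records)
    segs = segments.loc[keep].copy()
    obs = observations[(observations["species"] == species)
                       & observations["segment_id"].isin(segs["segment_id"])].copy()
    return obs, segs


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def grid_to_frame(cells: list[GridCell]) -> pd.DataFrame:
    return pd.DataFrame([{
        "cell_id": c.cell_id, "x": c.x, "y": c.y, "area_km2": c.area_km2,
        "cdist_km": c.cdist_km, "region": c.region, "is_sea": c.is_sea,
    } for c in cells])


def write_grid_csv(cells: list[GridCell] | pd.DataFrame, path: str | Path) -> None:
    df = cells if isinstance(cells, pd.DataFrame) else grid_to_frame(cells)
    df.to_csv(path, index=False)


def read_grid_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def segments_to_frame(segments: list[SurveySegment]) -> pd.DataFrame:
    return pd.DataFrame([{
        "segment_id": s.segment_id, "platform": s.platform, "season": s.season,
        "x": s.x, "y": s.y, "length_m": s.length_m,
        "strip_halfwidth_m": s.strip_halfwidth_m,
        "covered_area_km2": s.covered_area_km2, "cdist_km": s.cdist_km,
        "depth_m": s.depth_m,
        "species_recorded": ";".join(sorted(s.species_recorded)) or "all",
    } for s in segments])


def write_segments_csv(segments: list[SurveySegment] | pd.DataFrame,
                       path: str | Path) -> None:
    df = (segments if isinstance(segments, pd.DataFrame)
          else segments_to_frame(segments))
    df.to_csv(path, index=False)


def read_segments_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SEGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"segment table missing columns: {sorted(missing)}")
    return df


def write_observations_csv(obs: pd.DataFrame, path: str | Path) -> None:
    obs.to_csv(path, index=False)


def read_observations_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"segment_id", "species", "count", "behaviour"} - set(df.columns)
    if missing:
        raise ValueError(f"observation table missing columns: {sorted(missing)}")
    return df
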