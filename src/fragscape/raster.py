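"""Raster containers, IO, and reclassification.

Every stage of the pipeline operates on simple in-memory rasters: a 2-D
array plus the geometry needed to relate pixels to projected coordinates
(cell size in meters, top-left origin). Two grids are *aligned* when they
share shape, cell size and origin; all cross-grid operations require
alignment and never resample.

Supported on-disk formats are the ESRI ASCII grid (plain text, the
interchange format used throughout the test-suite) and single-band TIFF,
where the grid geometry travels in the ImageDescription tag as JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "TargetClass",
    "LandCoverGrid",
    "CovariateGrid",
    "ReclassTable",
    "read_grid",
    "write_grid",
    "reclassify",
    "align_check",
    "URBAN_MEMBER_CODES",
]


class TargetClass:
    """Integer codes of the harmonised land-cover vocabulary.

    HIGH_DENSITY_URBAN is a subclass of URBAN: every metric computed for
    the urban class includes both codes (see :data:`URBAN_MEMBER_CODES`).
    """

    URBAN = 1
    HIGH_DENSITY_URBAN = 2
    FOREST = 3
    WETLAND = 4
    PASTURE = 5
    AGRICULTURE = 6
    OTHER = 7

    NAMES = {
        "URBAN": URBAN,
        "HIGH_DENSITY_URBAN": HIGH_DENSITY_URBAN,
        "FOREST": FOREST,
        "WETLAND": WETLAND,
        "PASTURE": PASTURE,
        "AGRICULTURE": AGRICULTURE,
        "OTHER": OTHER,
    }
    CODES = {v: k for k, v in NAMES.items()}


#: codes folded into the urban class for every patch metric
URBAN_MEMBER_CODES = frozenset(
    {TargetClass.URBAN, TargetClass.HIGH_DENSITY_URBAN}
)

DEFAULT_NODATA = -9999
DEFAULT_VOCABULARY = frozenset(TargetClass.NAMES.values())


def class_members(focal_class: int) -> frozenset[int]:
    """Codes counted as the focal class (urban absorbs high-density urban)."""
    if focal_class == TargetClass.URBAN:
        return URBAN_MEMBER_CODES
    return frozenset({int(focal_class)})


@dataclass
class _BaseGrid:
    values: np.ndarray
    cell_size: float = 30.0
    nodata: float = DEFAULT_NODATA
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("grid values must be a non-empty 2-D array")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def land_mask(self) -> np.ndarray:
        """Boolean mask of non-nodata pixels."""
        return self.values != self.nodata

    def aligned_with(self, other: "_BaseGrid") -> bool:
        return (
            self.shape == other.shape
            and self.cell_size == other.cell_size
            and self.origin == other.origin
        )

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Projected (x, y) center coordinates of every pixel.

        Pixel (r, c) has its center at origin + ((c + 0.5), -(r + 0.5)) *
        cell_size, i.e. rows run southwards from the top-left origin.
        """
        rows, cols = self.shape
        x0, y0 = self.origin
        x = x0 + (np.arange(cols) + 0.5) * self.cell_size
        y = y0 - (np.arange(rows) + 0.5) * self.cell_size
        return np.meshgrid(x, y)


@dataclass
class LandCoverGrid(_BaseGrid):
    """Categorical raster of integer class codes."""

    vocabulary: frozenset[int] = field(default_factory=lambda: DEFAULT_VOCABULARY)

    def __post_init__(self) -> None:
        super().__post_init__()
        self.values = self.values.astype(np.int64, copy=False)
        self.nodata = int(self.nodata)
        self.vocabulary = frozenset(int(c) for c in self.vocabulary)

    def validate(self) -> None:
        present = np.unique(self.values[self.land_mask])
        illegal = sorted(set(present.tolist()) - self.vocabulary)
        if illegal:
            raise ValueError(f"codes outside vocabulary: {illegal}")

    def class_mask(self, focal_class: int) -> np.ndarray:
        return np.isin(self.values, list(class_members(focal_class)))

    def with_values(self, values: np.ndarray, **kw) -> "LandCoverGrid":
        return replace(self, values=values, **kw)


@dataclass
class CovariateGrid(_BaseGrid):
    """Continuous raster (elevation m, slope degrees, density, distance m)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.values = self.values.astype(np.float64, copy=False)
        self.nodata = float(self.nodata)

    @property
    def land_mask(self) -> np.ndarray:
        return ~np.isclose(self.values, self.nodata) & ~np.isnan(self.values)


class ReclassTable:
    """Total mapping from source class codes to the harmonised vocabulary.

    The crosswalk between a map product's native legend and the urban /
    forest / wetland / pasture / agriculture vocabulary is map-specific
    and must be supplied by the user (two-column CSV
    ``source_code,target_class``); synthetic landscapes use the identity
    mapping.
    """

    def __init__(self, mapping: dict[int, int]):
        bad = {c for c in mapping.values() if c not in DEFAULT_VOCABULARY}
        if bad:
            raise ValueError(f"unknown target codes: {sorted(bad)}")
        self.mapping = {int(k): int(v) for k, v in mapping.items()}

    @classmethod
    def from_names(cls, named: dict[int, str]) -> "ReclassTable":
        return cls({k: TargetClass.NAMES[v.strip().upper()] for k, v in named.items()})

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReclassTable":
        named: dict[int, str] = {}
        with open(path) as fh:
            header = fh.readline().strip().lower().replace(" ", "")
            if header != "source_code,target_class":
                raise ValueError(
                    "reclass table must have header 'source_code,target_class'"
                )
            for line in fh:
                if not line.strip():
                    continue
                src, tgt = line.strip().split(",")
                named[int(src)] = tgt
        return cls.from_names(named)

    @classmethod
    def identity(cls) -> "ReclassTable":
        return cls({c: c for c in DEFAULT_VOCABULARY})

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("source_code,target_class\n")
            for src in sorted(self.mapping):
                fh.write(f"{src},{TargetClass.CODES[self.mapping[src]]}\n")


def reclassify(grid: LandCoverGrid, table: ReclassTable) -> LandCoverGrid:
    """Map every source code through the table; nodata stays nodata.

    Raises ``ValueError`` naming any land code the table does not cover.
    """
    land = grid.land_mask
    present = set(np.unique(grid.values[land]).tolist())
    missing = sorted(present - set(table.mapping))
    if missing:
        raise ValueError(f"reclass table does not map codes: {missing}")
    out = np.full(grid.shape, grid.nodata, dtype=np.int64)
    lut = {**table.mapping, grid.nodata: grid.nodata}
    # vectorized lookup over the (small) set of distinct codes
    for src, tgt in lut.items():
        out[grid.values == src] = tgt
    return LandCoverGrid(
        out,
        cell_size=grid.cell_size,
        nodata=grid.nodata,
        origin=grid.origin,
        vocabulary=DEFAULT_VOCABULARY,
    )


def align_check(grids: list[_BaseGrid]) -> bool:
    """True iff all grids share shape, cell size and origin."""
    if len(grids) < 2:
        raise ValueError("alignment is defined for two or more grids")
    first = grids[0]
    return all(first.aligned_with(g) for g in grids[1:])


def require_aligned(*grids: _BaseGrid) -> None:
    if not align_check(list(grids)):
        raise ValueError("grids are not aligned (shape/cell_size/origin differ)")


# ---------------------------------------------------------------------------
# IO — ESRI ASCII grid and single-band TIFF
# ---------------------------------------------------------------------------

_ASC_SUFFIXES = {".asc", ".agr", ".grd", ".txt"}
_TIF_SUFFIXES = {".tif", ".tiff"}


def read_grid(path: str | Path, kind: str = "categorical"):
    """Read a raster file into a :class:`LandCoverGrid` or :class:`CovariateGrid`.

    Parameters
    ----------
    path:
        ESRI ASCII grid (``.asc``) or single-band TIFF (``.tif``) written
        by :func:`write_grid`.
    kind:
        ``"categorical"`` (land cover) or ``"continuous"`` (covariate).
    """
    if kind not in ("categorical", "continuous"):
        raise ValueError("kind must be 'categorical' or 'continuous'")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in _TIF_SUFFIXES:
        values, meta = _read_tiff(path)
    else:
        values, meta = _read_ascii(path)
    if kind == "categorical":
        return LandCoverGrid(
            np.rint(values).astype(np.int64),
            cell_size=meta["cell_size"],
            nodata=int(meta["nodata"]),
            origin=meta["origin"],
        )
    return CovariateGrid(
        values.astype(np.float64),
        cell_size=meta["cell_size"],
        nodata=float(meta["nodata"]),
        origin=meta["origin"],
    )


def write_grid(grid: _BaseGrid, path: str | Path) -> Path:
    """Write a grid to ESRI ASCII (``.asc``) or TIFF (``.tif``)."""
    path = Path(path)
    if path.suffix.lower() in _TIF_SUFFIXES:
        _write_tiff(grid, path)
    else:
        _write_ascii(grid, path)
    return path


def _read_ascii(path: Path) -> tuple[np.ndarray, dict]:
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if not data_lines and key in (
                "ncols",
                "nrows",
                "xllcorner",
                "yllcorner",
                "cellsize",
                "nodata_value",
            ):
                header[key] = float(parts[1])
            else:
                data_lines.append(line)
    for required in ("ncols", "nrows", "cellsize"):
        if required not in header:
            raise ValueError(f"ASCII grid header missing '{required}': {path}")
    if "nodata_value" not in header:
        raise ValueError(f"ASCII grid does not declare NODATA_value: {path}")
    values = np.loadtxt(data_lines, ndmin=2)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (nrows, ncols):
        raise ValueError(
            f"grid body {values.shape} does not match header ({nrows}, {ncols})"
        )
    cell = header["cellsize"]
    xll = header.get("xllcorner", 0.0)
    yll = header.get("yllcorner", 0.0)
    # ASCII grids are anchored at the lower-left corner; our origin is top-left
    origin = (xll, yll + nrows * cell)
    return values, {"cell_size": cell, "nodata": header["nodata_value"], "origin": origin}


def _write_ascii(grid: _BaseGrid, path: Path) -> None:
    nrows, ncols = grid.shape
    x0, y0 = grid.origin
    is_int = np.issubdtype(grid.values.dtype, np.integer)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {x0}\n")
        fh.write(f"yllcorner {y0 - nrows * grid.cell_size}\n")
        fh.write(f"cellsize {grid.cell_size}\n")
        nodata = int(grid.nodata) if is_int else grid.nodata
        fh.write(f"NODATA_value {nodata}\n")
        fmt = "%d" if is_int else "%.8g"
        np.savetxt(fh, grid.values, fmt=fmt)


def _read_tiff(path: Path) -> tuple[np.ndarray, dict]:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        values = page.asarray()
        desc = page.tags.get("ImageDescription")
        if desc is None:
            raise ValueError(f"TIFF lacks the geometry description tag: {path}")
        try:
            meta = json.loads(desc.value)
        except json.JSONDecodeError as exc:
            raise ValueError(f"unparseable TIFF geometry metadata: {path}") from exc
    for key in ("cell_size", "nodata", "origin"):
        if key not in meta:
            raise ValueError(f"TIFF geometry metadata missing '{key}': {path}")
    meta["origin"] = tuple(meta["origin"])
    return np.asarray(values), meta


def _write_tiff(grid: _BaseGrid, path: Path) -> None:
    import tifffile

    meta = {
        "cell_size": grid.cell_size,
        "nodata": grid.nodata,
        "origin": list(grid.origin),
    }
    tifffile.imwrite(path, grid.values, description=json.dumps(meta))
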