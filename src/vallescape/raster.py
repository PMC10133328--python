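"""Land-cover raster model, Esri ASCII grid I/O, and patch geometry.

The land-cover legend is fixed to the four habitat classes used throughout
the assessment of the lagoon management units, plus a nodata code:

====  ==================
code  class
====  ==================
0     nodata
1     terrestrial land
2     saltmarsh
3     brackish water
4     freshwater
====  ==================

Conventions: grids are row-major with the origin at the upper-left corner
and 0-based indices; areas are reported in m^2, perimeters in m.  A pixel
edge is "exposed" (contributes to a perimeter) when it faces a pixel of a
different class, a nodata pixel, or the grid boundary — the embankment of a
valle da pesca is a real boundary, so the grid edge counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

NODATA = 0
LAND = 1
SALTMARSH = 2
BRACKISH = 3
FRESHWATER = 4

CLASS_CODES = (NODATA, LAND, SALTMARSH, BRACKISH, FRESHWATER)
CLASS_NAMES = {
    NODATA: "nodata",
    LAND: "terrestrial land",
    SALTMARSH: "saltmarsh",
    BRACKISH: "brackish water",
    FRESHWATER: "freshwater",
}
#: Water classes (brackish + freshwater) used by the landscape indicators.
WATER_CLASSES = (BRACKISH, FRESHWATER)


class RasterError(ValueError):
    """Malformed raster content (unknown class code, bad shape, bad header)."""


@dataclass
class LandCoverRaster:
    """A categorical land-cover grid for one management unit.

    Parameters
    ----------
    grid
        2-D integer array of legend class codes.
    pixel_size
        Cell side length in metres (> 0).
    origin
        ``(x, y)`` of the upper-left grid corner in projected metres.
    """

    grid: np.ndarray
    pixel_size: float = 25.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise RasterError(f"grid must be 2-D, got ndim={self.grid.ndim}")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise RasterError("grid must hold integer class codes")
        if self.pixel_size <= 0:
            raise RasterError(f"pixel_size must be > 0, got {self.pixel_size}")
        bad = np.setdiff1d(np.unique(self.grid), CLASS_CODES)
        if bad.size:
            raise RasterError(f"unknown class code(s) {bad.tolist()}; legend is {CLASS_CODES}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def pixel_area(self) -> float:
        return self.pixel_size**2

    def mask(self, class_code: int) -> np.ndarray:
        _check_code(class_code)
        return self.grid == class_code

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LandCoverRaster):
            return NotImplemented
        return (
            np.array_equal(self.grid, other.grid)
            and self.pixel_size == other.pixel_size
            and self.origin == other.origin
        )


def _check_code(class_code: int) -> None:
    if class_code not in CLASS_CODES:
        raise RasterError(f"unknown class code {class_code}; legend is {CLASS_CODES}")


def class_area(raster: LandCoverRaster, class_code: int) -> float:
    """Area of one legend class in m^2 (pixel count x pixel area)."""
    _check_code(class_code)
    return float(np.count_nonzero(raster.grid == class_code)) * raster.pixel_area


def write_raster(raster: LandCoverRaster, path) -> None:
    """Write a land-cover raster as an Esri ASCII grid (text)."""
    nrows, ncols = raster.grid.shape
    x_ul, y_ul = raster.origin
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {x_ul!r}\n"
        f"yllcorner {(y_ul - nrows * raster.pixel_size)!r}\n"
        f"cellsize {raster.pixel_size!r}\n"
        f"NODATA_value {NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.grid, fmt="%d")


def read_raster(path) -> LandCoverRaster:
    """Read an Esri ASCII grid written by :func:`write_raster`.

    Raises
    ------
    RasterError
        On a malformed header, a ragged grid, or class codes outside the
        legend (the offending codes are named in the message).
    """
    header: dict[str, float] = {}
    rows: list[list[int]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"):
                try:
                    header[key] = float(parts[1])
                except (IndexError, ValueError) as exc:
                    raise RasterError(f"malformed header line {line!r}") from exc
            else:
                try:
                    rows.append([int(v) for v in parts])
                except ValueError as exc:
                    raise RasterError(f"non-integer grid value in line {line!r}") from exc
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise RasterError(f"missing header field {req!r}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if len(rows) != nrows or any(len(r) != ncols for r in rows):
        raise RasterError(f"grid does not match declared shape {nrows}x{ncols}")
    grid = np.array(rows, dtype=np.int16)
    cellsize = header["cellsize"]
    y_ul = header.get("yllcorner", 0.0) + nrows * cellsize
    return LandCoverRaster(grid, pixel_size=cellsize, origin=(header.get("xllcorner", 0.0), y_ul))


@dataclass
class PatchSet:
    """Connected components of one class: patch id per pixel + per-patch geometry.

    ``labels`` is 0 where the pixel does not belong to the class; patch ids
    run from 1 to ``n_patches``.  ``pixel_counts[i]`` and ``edge_counts[i]``
    refer to patch id ``i + 1``.
    """

    labels: np.ndarray
    class_code: int
    pixel_size: float
    connectivity: int
    n_patches: int
    pixel_counts: np.ndarray = field(repr=False)
    edge_counts: np.ndarray = field(repr=False)

    def patch_ids(self) -> np.ndarray:
        return np.arange(1, self.n_patches + 1)


def label_patches(raster: LandCoverRaster, class_code: int, connectivity: int = 4) -> PatchSet:
    """Label connected patches of one class.

    Connectivity 4 (edge adjacency, the default) or 8 (edges + corners).
    Perimeters always use edge counting regardless of the labeling
    connectivity.
    """
    _check_code(class_code)
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    structure = ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)
    mask = raster.grid == class_code
    labels, n = ndimage.label(mask, structure=structure)
    pixel_counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    # exposed edges per pixel = 4 - number of 4-neighbours in the same patch
    same = np.zeros(labels.shape, dtype=np.int8)
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        shifted = np.roll(labels, shift, axis=axis)
        if shift == 1:
            index = [slice(None)] * 2
            index[axis] = 0
        else:
            index = [slice(None)] * 2
            index[axis] = -1
        shifted[tuple(index)] = 0
        same += (shifted == labels) & mask
    exposed = np.where(mask, 4 - same, 0)
    edge_counts = np.bincount(labels.ravel(), weights=exposed.ravel(), minlength=n + 1)[1:]
    return PatchSet(
        labels=labels,
        class_code=class_code,
        pixel_size=raster.pixel_size,
        connectivity=connectivity,
        n_patches=n,
        pixel_counts=pixel_counts,
        edge_counts=edge_counts.astype(np.int64),
    )


def patch_area(patchset: PatchSet, patch_id: int) -> float:
    """Area of one patch in m^2."""
    _check_patch(patchset, patch_id)
    return float(patchset.pixel_counts[patch_id - 1]) * patchset.pixel_size**2


def patch_perimeter(patchset: PatchSet, patch_id: int) -> float:
    """Perimeter of one patch in m (exposed pixel edges x pixel size)."""
    _check_patch(patchset, patch_id)
    return float(patchset.edge_counts[patch_id - 1]) * patchset.pixel_size


def class_perimeter(patchset: PatchSet) -> float:
    """Total exposed perimeter of the class in m (sum over patches)."""
    return float(patchset.edge_counts.sum()) * patchset.pixel_size


def _check_patch(patchset: PatchSet, patch_id: int) -> None:
    if not 1 <= patch_id <= patchset.n_patches:
        raise KeyError(f"patch id {patch_id} not in 1..{patchset.n_patches}")


def ndvi(red_band: np.ndarray, nir_band: np.ndarray) -> np.ndarray:
    """Normalized difference vegetation index (NIR - Red)/(NIR + Red).

    Pixels where both reflectances are zero are nodata (NaN).
    """
    red = np.asarray(red_band, dtype=float)
    nir = np.asarray(nir_band, dtype=float)
    if red.shape != nir.shape:
        raise RasterError(f"band shapes differ: {red.shape} vs {nir.shape}")
    if (red < 0).any() or (nir < 0).any():
        raise RasterError("reflectances must be >= 0")
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (nir - red) / denom
    out[denom == 0] = np.nan
    return out


def detect_vegetation_patches(annual_ndvi_stack, ndvi_range) -> np.ndarray:
    """Boolean mask of pixels whose across-years mean NDVI falls in a range.

    The interval is closed on both ends; pixels with an undefined mean
    (nodata in any aggregation) are False.
    """
    lo, hi = ndvi_range
    if lo > hi:
        raise ValueError(f"ndvi range lower bound {lo} exceeds upper bound {hi}")
    stack = np.asarray(annual_ndvi_stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.shape[0] == 0:
        raise ValueError("empty NDVI stack")
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(np.where(np.isnan(stack), np.nan, stack), axis=0)
    return (mean >= lo) & (mean <= hi) & ~np.isnan(mean)
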