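"""Georeferenced NDVI grids and the patch tensors fed to the refinement network.

An :class:`NDVIMap` is a plain 2-D grid of NDVI values with a validity mask
and a minimal north-up affine transform.  GeoTIFF round-tripping is done with
:mod:`tifffile`, writing the ModelPixelScale / ModelTiepoint GeoTIFF tags and
the GDAL nodata tag so files open correctly in GIS software.

The network consumes 3x3x2 patch tensors: layer 0 is the NDVI neighbourhood
of a pixel (zero-padded at raster boundaries), layer 1 carries the row-major
linear index of each neighbour, by default rescaled into [0, 1] so that both
input layers live on comparable ranges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

DEFAULT_NODATA = -9999.0

#: GeoTIFF / GDAL private tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class InvalidPixelError(ValueError):
    """Raised when a patch is requested for a nodata / out-of-range centre pixel."""


@dataclass(frozen=True)
class GridTransform:
    """North-up affine grid geometry: origin of the (0, 0) cell corner and square pixel size in metres."""

    x_origin: float = 0.0
    y_origin: float = 0.0
    pixel_size: float = 1.0

    def __eq__(self, other) -> bool:
        if not isinstance(other, GridTransform):
            return NotImplemented
        return (
            np.isclose(self.x_origin, other.x_origin)
            and np.isclose(self.y_origin, other.y_origin)
            and np.isclose(self.pixel_size, other.pixel_size)
        )


@dataclass
class NDVIMap:
    """A 2-D NDVI grid with per-pixel validity mask.

    Valid values are dimensionless NDVI in [-1, 1]; invalid cells may hold
    anything (they are ignored and written as nodata).
    """

    values: np.ndarray
    mask: np.ndarray
    transform: GridTransform = field(default_factory=GridTransform)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.dtype not in (np.float32, np.float64):
            self.values = self.values.astype(np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {self.values.shape}")
        if self.mask.shape != self.values.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} != values shape {self.values.shape}"
            )
        valid = self.values[self.mask]
        if valid.size and (np.nanmin(valid) < -1.0 - 1e-9 or np.nanmax(valid) > 1.0 + 1e-9):
            raise ValueError("valid NDVI values must lie in [-1, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def pixel_count(self) -> int:
        return self.values.size

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def same_geometry(self, other: "NDVIMap") -> bool:
        return self.shape == other.shape and self.transform == other.transform


@dataclass
class PatchTensor:
    """The 3x3x2 input tensor of one map pixel.

    ``patch`` is the NDVI neighbourhood (centre = the pixel itself), and
    ``locations`` the row-major linear indices of the nine cells, scaled by
    ``1 / (pixel_count - 1)`` when normalised.  Out-of-bounds neighbours are
    zero in both layers.
    """

    patch: np.ndarray
    locations: np.ndarray
    center_index: int

    @property
    def array(self) -> np.ndarray:
        """Channel-first (2, 3, 3) array view used by the network."""
        return np.stack([self.patch, self.locations]).astype(np.float64)


@dataclass
class SamplePair:
    """One supervised training sample: a satellite patch tensor and its reference NDVI."""

    x: PatchTensor
    y: float


def compute_ndvi(red: np.ndarray, nir: np.ndarray,
                 transform: GridTransform | None = None) -> NDVIMap:
    """NDVI = (NIR - red) / (NIR + red) from co-registered reflectance grids.

    Cells where ``nir + red == 0`` carry no radiometric information and are
    flagged nodata.
    """
    red = np.asarray(red, dtype=np.float64)
    nir = np.asarray(nir, dtype=np.float64)
    if red.shape != nir.shape:
        raise ValueError(f"band shape mismatch: red {red.shape} vs nir {nir.shape}")
    if red.ndim != 2:
        raise ValueError("reflectance bands must be 2-D grids")
    if (red < 0).any() or (nir < 0).any():
        raise ValueError("reflectance values must be non-negative")
    denom = nir + red
    mask = denom > 0
    values = np.zeros_like(denom)
    np.divide(nir - red, denom, out=values, where=mask)
    return NDVIMap(values, mask, transform or GridTransform())


def write_ndvi_raster(ndvi_map: NDVIMap, path: str | Path,
                      nodata: float = DEFAULT_NODATA) -> None:
    """Write a single-band float32 GeoTIFF with nodata and geo tags."""
    data = np.where(ndvi_map.mask, ndvi_map.values, nodata).astype(np.float32)
    t = ndvi_map.transform
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (t.pixel_size, t.pixel_size, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.x_origin, t.y_origin, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata)),
    ]
    tifffile.imwrite(str(path), data, extratags=extratags)


def read_ndvi_raster(path: str | Path) -> NDVIMap:
    """Read a single-band GeoTIFF written by :func:`write_ndvi_raster` (or compatible)."""
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        data = page.asarray()
        if data.ndim != 2:
            raise ValueError(
                f"expected a single-band raster, got array of shape {data.shape}; "
                "select a band before loading"
            )
        nodata = None
        tag = page.tags.get(_TAG_GDAL_NODATA)
        if tag is not None:
            nodata = float(str(tag.value).strip("\x00 "))
        transform = GridTransform()
        scale = page.tags.get(_TAG_MODEL_PIXEL_SCALE)
        tiepoint = page.tags.get(_TAG_MODEL_TIEPOINT)
        if scale is not None and tiepoint is not None:
            transform = GridTransform(
                x_origin=float(tiepoint.value[3]),
                y_origin=float(tiepoint.value[4]),
                pixel_size=float(scale.value[0]),
            )
    values = np.asarray(data, dtype=np.float64)
    mask = np.isfinite(values)
    if nodata is not None:
        mask &= values != nodata
    values = np.where(mask, values, 0.0)
    return NDVIMap(values, mask, transform)


def extract_patch_tensor(ndvi_map: NDVIMap, index: int,
                         normalize_locations: bool = True) -> PatchTensor:
    """Extract the 3x3x2 tensor centred on the pixel with row-major linear ``index``.

    Out-of-bounds neighbours are zero in both layers; in-bounds nodata
    neighbours are zeroed in the NDVI layer (counted and logged) but keep
    their location value.

    Raises
    ------
    InvalidPixelError
        If the centre pixel itself is nodata (callers should skip it).
    """
    nrows, ncols = ndvi_map.shape
    n = ndvi_map.pixel_count
    if not 0 <= index < n:
        raise IndexError(f"pixel index {index} outside [0, {n})")
    r, c = divmod(int(index), ncols)
    if not ndvi_map.mask[r, c]:
        raise InvalidPixelError(f"centre pixel {index} is nodata")

    scale = 1.0 / (n - 1) if (normalize_locations and n > 1) else 1.0
    patch = np.zeros((3, 3), dtype=np.float64)
    locations = np.zeros((3, 3), dtype=np.float64)
    n_invalid = 0
    for a in range(3):
        rr = r + a - 1
        for b in range(3):
            cc = c + b - 1
            if 0 <= rr < nrows and 0 <= cc < ncols:
                locations[a, b] = (rr * ncols + cc) * scale
                if ndvi_map.mask[rr, cc]:
                    patch[a, b] = ndvi_map.values[rr, cc]
                else:
                    n_invalid += 1
    if n_invalid:
        logger.debug("patch at %d: zeroed %d nodata neighbours", index, n_invalid)
    return PatchTensor(patch=patch, locations=locations, center_index=int(index))


def pair_datasets(sat: NDVIMap, uav: NDVIMap,
                  normalize_locations: bool = True) -> list[SamplePair]:
    """Pair satellite patch tensors with reference NDVI values, cell by cell.

    One :class:`SamplePair` per cell valid in *both* maps, in deterministic
    row-major order.  Returns an empty list when the valid sets are disjoint.
    """
    if not sat.same_geometry(uav):
        raise ValueError("satellite and reference rasters have different grid geometry")
    joint = sat.mask & uav.mask
    pairs: list[SamplePair] = []
    flat_ref = uav.values.ravel()
    for index in np.flatnonzero(joint.ravel()):
        x = extract_patch_tensor(sat, int(index), normalize_locations)
        pairs.append(SamplePair(x=x, y=float(flat_ref[index])))
    return pairs


def pairs_to_arrays(pairs: list[SamplePair]) -> tuple[np.ndarray, np.ndarray]:
    """Stack sample pairs into network-ready arrays ``(n, 2, 3, 3)`` and ``(n,)``."""
    if not pairs:
        return np.zeros((0, 2, 3, 3)), np.zeros((0,))
    X = np.stack([p.x.array for p in pairs])
    y = np.array([p.y for p in pairs], dtype=np.float64)
    return X, y
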