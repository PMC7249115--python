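"""Synthetic vineyard scenes for end-to-end testing of the refinement pipeline.

A scene is a centimetric NDVI raster of parallel vine rows over bare
inter-row soil.  Canopy pixels draw from one of three vigor-level means
arranged in smooth spatial blocks (a thresholded low-frequency Gaussian
field at the decametric grid), soil pixels from a soil mean plus a
spatially-correlated inter-row vegetation ("weed") signal that is
independent of vine vigor — the contamination that biases coarse mixed
pixels in row crops.

Two decametric downsamplings emulate the data sources:

* a canopy-masked mean per cell (the UAV-style reference, nodata where a
  cell holds no canopy), and
* an all-pixel mean plus Gaussian sensor noise and a radiometric offset
  (the raw satellite-style map), clipped to the NDVI range.

With all noise terms at zero the raw cell value equals
``fraction * canopy_mean + (1 - fraction) * soil_mean + offset`` exactly —
the mixed-pixel bias the refinement network is asked to remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .raster_io import GridTransform, NDVIMap


@dataclass(frozen=True)
class SceneConfig:
    """Geometry, radiometry and noise of one synthetic vineyard scene.

    Distances in metres, NDVI dimensionless.  Defaults give a 320 m x 320 m
    scene — 32 x 32 decametric cells, about 1k training tensors — at a 5 cm
    ground sample distance, with vineyard-plausible row geometry and three
    canopy vigor levels.
    """

    width_m: float = 320.0
    height_m: float = 320.0
    gsd: float = 0.05
    cell_size: float = 10.0
    row_spacing: float = 2.7
    canopy_width: float = 1.1
    row_azimuth_deg: float = 15.0
    vigor_means: tuple[float, float, float] = (0.45, 0.65, 0.85)
    sigma_canopy: float = 0.05
    soil_ndvi: float = 0.15
    sigma_soil: float = 0.03
    weed_sigma: float = 0.08
    weed_corr_cells: float = 0.7
    vigor_corr_cells: float = 3.0
    sigma_sat: float = 0.02
    offset_sat: float = -0.05
    misregistration_shift: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gsd >= self.cell_size:
            raise ValueError("highres GSD must be finer than the decametric cell size")
        ratio = self.cell_size / self.gsd
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("cell_size must be an integer multiple of the GSD")
        if self.canopy_width >= self.row_spacing:
            raise ValueError("canopy width must be smaller than the row spacing")
        ndvi_levels = (*self.vigor_means, self.soil_ndvi)
        if min(ndvi_levels) < -1 or max(ndvi_levels) > 1:
            raise ValueError("all NDVI level means must lie in [-1, 1]")
        if min(self.sigma_canopy, self.sigma_soil, self.weed_sigma,
               self.sigma_sat) < 0:
            raise ValueError("noise levels must be non-negative")

    @property
    def cells_per_axis(self) -> tuple[int, int]:
        return (int(round(self.height_m / self.cell_size)),
                int(round(self.width_m / self.cell_size)))

    @property
    def pixels_per_cell(self) -> int:
        return int(round(self.cell_size / self.gsd))


@dataclass
class Scene:
    """A generated scene: centimetric NDVI, canopy mask and latent vigor truth."""

    highres: NDVIMap
    canopy_mask: np.ndarray
    vigor_truth: np.ndarray       # (cells_y, cells_x) labels 0/1/2
    config: SceneConfig
    _sat_seed: np.random.SeedSequence = field(repr=False, default=None)


def _smooth_labels(rng: np.random.Generator, shape: tuple[int, int],
                   corr: float) -> np.ndarray:
    """Three spatially coherent, roughly equal-area classes on a coarse grid."""
    g = gaussian_filter(rng.normal(size=shape), corr, mode="reflect")
    lo, hi = np.percentile(g, [100 / 3, 200 / 3])
    return ((g > lo).astype(np.int8) + (g > hi).astype(np.int8))


def generate_scene(config: SceneConfig | None = None) -> Scene:
    """Rasterise a vineyard scene; deterministic for a fixed ``config.seed``."""
    config = config or SceneConfig()
    ncy, ncx = config.cells_per_axis
    f = config.pixels_per_cell
    h, w = ncy * f, ncx * f
    ss = np.random.SeedSequence(config.seed)
    s_vigor, s_canopy, s_soil, s_weed, s_sat = ss.spawn(5)

    vigor = _smooth_labels(np.random.default_rng(s_vigor), (ncy, ncx),
                           config.vigor_corr_cells)

    # row geometry: signed distance across rows, rows every `row_spacing` m
    theta = np.deg2rad(config.row_azimuth_deg)
    xs = ((np.arange(w, dtype=np.float32) + 0.5) * config.gsd) * np.cos(theta)
    ys = ((np.arange(h, dtype=np.float32) + 0.5) * config.gsd) * np.sin(theta)
    across = np.add.outer(ys, xs)
    canopy_mask = (across % config.row_spacing) < config.canopy_width
    del across, xs, ys

    level = np.asarray(config.vigor_means, dtype=np.float32)[
        np.repeat(np.repeat(vigor, f, axis=0), f, axis=1)]
    rng_canopy = np.random.default_rng(s_canopy)
    if config.sigma_canopy > 0:
        level += config.sigma_canopy * rng_canopy.standard_normal((h, w), dtype=np.float32)

    soil = np.full((h, w), config.soil_ndvi, dtype=np.float32)
    if config.weed_sigma > 0:
        weed = gaussian_filter(
            np.random.default_rng(s_weed).normal(size=(ncy, ncx)),
            config.weed_corr_cells, mode="reflect")
        weed *= config.weed_sigma / weed.std()
        soil += np.repeat(np.repeat(weed.astype(np.float32), f, axis=0), f, axis=1)
    if config.sigma_soil > 0:
        soil += config.sigma_soil * np.random.default_rng(s_soil).standard_normal(
            (h, w), dtype=np.float32)

    values = np.clip(np.where(canopy_mask, level, soil), -1.0, 1.0)
    highres = NDVIMap(values, np.ones((h, w), dtype=bool),
                      GridTransform(0.0, 0.0, config.gsd))
    return Scene(highres=highres, canopy_mask=canopy_mask, vigor_truth=vigor,
                 config=config, _sat_seed=s_sat)


def _block_view(a: np.ndarray, f: int) -> np.ndarray:
    ncy, ncx = a.shape[0] // f, a.shape[1] // f
    return a.reshape(ncy, f, ncx, f)


def downsample_uav_reference(scene: Scene, cell_size: float | None = None) -> NDVIMap:
    """Canopy-only mean NDVI per decametric cell; nodata where no canopy."""
    f = _cell_factor(scene, cell_size)
    v = _block_view(scene.highres.values.astype(np.float64), f)
    m = _block_view(scene.canopy_mask, f)
    count = m.sum(axis=(1, 3))
    total = (v * m).sum(axis=(1, 3))
    mask = count > 0
    values = np.zeros_like(total)
    np.divide(total, count, out=values, where=mask)
    return NDVIMap(values, mask, GridTransform(0.0, 0.0, f * scene.config.gsd))


def downsample_satellite_raw(scene: Scene, cell_size: float | None = None) -> NDVIMap:
    """All-pixel mean per cell plus sensor noise and radiometric offset.

    The additive Gaussian noise is seeded from the scene, so repeated calls
    on the same scene return an identical map.  A configured sub-cell
    misregistration shift displaces the sampling grid before aggregation.
    """
    f = _cell_factor(scene, cell_size)
    cfg = scene.config
    values = scene.highres.values.astype(np.float64)
    dy, dx = (int(round(s / cfg.gsd)) for s in cfg.misregistration_shift)
    if dy or dx:
        values = np.roll(values, (dy, dx), axis=(0, 1))
    cell = _block_view(values, f).mean(axis=(1, 3))
    cell = cell + cfg.offset_sat
    if cfg.sigma_sat > 0:
        rng = np.random.default_rng(scene._sat_seed)
        cell = cell + cfg.sigma_sat * rng.standard_normal(cell.shape)
    cell = np.clip(cell, -1.0, 1.0)
    return NDVIMap(cell, np.ones(cell.shape, dtype=bool),
                   GridTransform(0.0, 0.0, f * scene.config.gsd))


def canopy_fraction(scene: Scene, cell_size: float | None = None) -> np.ndarray:
    """Fraction of canopy pixels per decametric cell (always in (0, 1))."""
    f = _cell_factor(scene, cell_size)
    return _block_view(scene.canopy_mask, f).mean(axis=(1, 3))


def scene_maps(scene: Scene) -> tuple[NDVIMap, NDVIMap]:
    """Convenience: the (raw satellite, UAV reference) decametric map pair."""
    return downsample_satellite_raw(scene), downsample_uav_reference(scene)


def transfer_scene_config(config: SceneConfig, seed: int) -> SceneConfig:
    """Same geometry and radiometry, different random arrangement (new epoch)."""
    return replace(config, seed=seed)


def _cell_factor(scene: Scene, cell_size: float | None) -> int:
    cfg = scene.config
    cell_size = cfg.cell_size if cell_size is None else cell_size
    ratio = cell_size / cfg.gsd
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("cell size must be an integer multiple of the GSD")
    f = int(round(ratio))
    h, w = scene.highres.shape
    if h % f or w % f:
        raise ValueError("scene extent is not an integer number of cells")
    return f
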