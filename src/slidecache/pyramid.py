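"""Multi-resolution tile pyramid with nearest-neighbour magnification synthesis.

A whole-slide image is stored at its highest scanned magnification plus a
small set of intermediate magnifications (e.g. 40x, 10x, 1x), each level
cut into fixed-size tiles.  Any other magnification at or below the base
is synthesised on demand: the stored level with the smallest
magnification >= the request is nearest-neighbour reduced by the ratio of
the two magnifications.  Requesting 5.4x from a {40, 10, 1} pyramid, for
example, reads the 10x level and reduces it by 0.54.

Level dimensions obey width = ceil(base_width * mag / base_mag) (same for
height).  The nearest-neighbour convention is half-pixel-centre: output
pixel i samples source index floor((i + 0.5) * source_size / target_size),
so a request at a stored magnification is bit-identical to the stored
tiles.  Coordinates are 0-based, top-left origin, half-open [x, x+w);
pixels outside a level are filled white, matching the blank background a
viewer shows for off-slide areas.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .exceptions import LevelNotFoundError
from .synthetic_slide import SlideImage

WHITE = 255
_MAG_ATOL = 1e-9


def level_dimensions(base_width: int, base_height: int, base_magnification: float,
                     magnification: float) -> tuple[int, int]:
    """(width, height) of the level at ``magnification``."""
    # tiny epsilon so exact ratios (4096 * 10 / 40) don't round up on
    # float representation error
    w = math.ceil(base_width * magnification / base_magnification - 1e-9)
    h = math.ceil(base_height * magnification / base_magnification - 1e-9)
    return w, h


def nn_indices(n_target: int, n_source: int, offset: int = 0, count: int | None = None) -> np.ndarray:
    """Half-pixel-centre nearest-neighbour source indices.

    For a target axis of ``n_target`` pixels drawn from a source axis of
    ``n_source`` pixels, target pixel g samples source index
    floor((g + 0.5) * n_source / n_target).  ``offset``/``count`` select a
    sub-range of target pixels.
    """
    if count is None:
        count = n_target
    g = np.arange(offset, offset + count, dtype=np.int64)
    return ((g * 2 + 1) * n_source) // (2 * n_target)


@dataclass
class PyramidLevel:
    """One stored magnification, cut into tiles.

    Interior tiles are ``tile_size`` square; right/bottom edge tiles are
    smaller but never empty.
    """

    magnification: float
    width_px: int
    height_px: int
    tile_size: int
    tiles: dict[tuple[int, int], np.ndarray] = field(repr=False)

    @property
    def n_tile_rows(self) -> int:
        return math.ceil(self.height_px / self.tile_size)

    @property
    def n_tile_cols(self) -> int:
        return math.ceil(self.width_px / self.tile_size)

    def raster(self) -> np.ndarray:
        """Stitch all tiles back into the level's full raster."""
        out = np.empty((self.height_px, self.width_px, 3), dtype=np.uint8)
        ts = self.tile_size
        for (tr, tc), tile in self.tiles.items():
            out[tr * ts: tr * ts + tile.shape[0], tc * ts: tc * ts + tile.shape[1]] = tile
        return out


@dataclass
class TilePyramid:
    """All stored levels of one slide, ordered by decreasing magnification."""

    slide_id: str
    base_width: int
    base_height: int
    base_magnification: float
    tile_size: int
    levels: list[PyramidLevel]

    def __post_init__(self):
        mags = [lv.magnification for lv in self.levels]
        if not mags:
            raise ValueError("a pyramid needs at least one level")
        if abs(mags[0] - self.base_magnification) > _MAG_ATOL:
            raise ValueError("the first level must be the base magnification")
        if any(mags[i] <= mags[i + 1] for i in range(len(mags) - 1)):
            raise ValueError("level magnifications must be strictly decreasing")

    @property
    def magnifications(self) -> list[float]:
        return [lv.magnification for lv in self.levels]

    def level(self, magnification: float) -> PyramidLevel:
        for lv in self.levels:
            if abs(lv.magnification - magnification) <= _MAG_ATOL:
                return lv
        raise LevelNotFoundError(
            f"magnification {magnification} is not stored; levels are {self.magnifications}")

    def source_level_for(self, magnification: float) -> PyramidLevel:
        """Smallest stored magnification >= the request."""
        if magnification > self.base_magnification + _MAG_ATOL:
            raise ValueError(
                f"requested magnification {magnification} exceeds the highest "
                f"scanned magnification {self.base_magnification}")
        if magnification <= 0:
            raise ValueError("magnification must be positive")
        candidates = [lv for lv in self.levels
                      if lv.magnification >= magnification - _MAG_ATOL]
        return min(candidates, key=lambda lv: lv.magnification)


def _cut_tiles(raster: np.ndarray, tile_size: int) -> dict[tuple[int, int], np.ndarray]:
    h, w = raster.shape[:2]
    tiles = {}
    for tr in range(math.ceil(h / tile_size)):
        for tc in range(math.ceil(w / tile_size)):
            tiles[(tr, tc)] = np.ascontiguousarray(
                raster[tr * tile_size:(tr + 1) * tile_size,
                       tc * tile_size:(tc + 1) * tile_size])
    return tiles


def build_pyramid(slide: SlideImage, magnifications, tile_size: int = 256,
                  slide_id: str = "slide") -> TilePyramid:
    """Down-sample the base raster to each requested magnification and tile it.

    ``magnifications`` must include the slide's base magnification as its
    maximum; anything above it cannot be synthesised from the scan and is
    rejected.
    """
    if tile_size < 16:
        raise ValueError("tile size must be at least 16")
    requested = [float(m) for m in magnifications]
    mags = sorted(set(requested), reverse=True)
    if len(mags) != len(requested):
        raise ValueError("magnifications must be unique")
    if not mags:
        raise ValueError("at least one magnification is required")
    for m in mags:
        if m <= 0:
            raise ValueError("magnifications must be positive")
        if m > slide.base_magnification + _MAG_ATOL:
            raise ValueError(
                f"magnification {m} exceeds the slide's base magnification "
                f"{slide.base_magnification}")
    if abs(mags[0] - slide.base_magnification) > _MAG_ATOL:
        raise ValueError("the base magnification must be among the stored levels")

    levels = []
    for m in mags:
        w, h = level_dimensions(slide.width_px, slide.height_px,
                                slide.base_magnification, m)
        if abs(m - slide.base_magnification) <= _MAG_ATOL:
            raster = slide.pixels
        else:
            rows = nn_indices(h, slide.height_px)
            cols = nn_indices(w, slide.width_px)
            raster = slide.pixels[np.ix_(rows, cols)]
        levels.append(PyramidLevel(magnification=m, width_px=w, height_px=h,
                                   tile_size=tile_size,
                                   tiles=_cut_tiles(raster, tile_size)))
    return TilePyramid(slide_id=slide_id, base_width=slide.width_px,
                       base_height=slide.height_px,
                       base_magnification=slide.base_magnification,
                       tile_size=tile_size, levels=levels)


def read_level_region(pyramid: TilePyramid, magnification: float,
                      x: int, y: int, w: int, h: int) -> np.ndarray:
    """Crop [x, x+w) x [y, y+h) from a stored level, stitching tiles.

    Pixels outside the level bounds come back white.
    """
    if w < 1 or h < 1:
        raise ValueError("region width and height must be positive")
    level = pyramid.level(magnification)
    out = np.full((h, w, 3), WHITE, dtype=np.uint8)
    ix0, ix1 = max(x, 0), min(x + w, level.width_px)
    iy0, iy1 = max(y, 0), min(y + h, level.height_px)
    if ix0 >= ix1 or iy0 >= iy1:
        return out
    ts = level.tile_size
    for tr in range(iy0 // ts, (iy1 - 1) // ts + 1):
        for tc in range(ix0 // ts, (ix1 - 1) // ts + 1):
            tile = level.tiles[(tr, tc)]
            # overlap of this tile with the requested region, level frame
            ox0, ox1 = max(ix0, tc * ts), min(ix1, tc * ts + tile.shape[1])
            oy0, oy1 = max(iy0, tr * ts), min(iy1, tr * ts + tile.shape[0])
            out[oy0 - y: oy1 - y, ox0 - x: ox1 - x] = \
                tile[oy0 - tr * ts: oy1 - tr * ts, ox0 - tc * ts: ox1 - tc * ts]
    return out


def region_at_magnification(pyramid: TilePyramid, magnification: float,
                            x: int, y: int, w: int, h: int) -> np.ndarray:
    """Render [x, x+w) x [y, y+h) at any magnification <= the base.

    Coordinates are in the pixel frame of the requested magnification.  A
    stored magnification is served bit-identically from its tiles; any
    other is nearest-neighbour reduced from the closest stored level
    above it.
    """
    if magnification > pyramid.base_magnification + _MAG_ATOL:
        raise ValueError(
            f"requested magnification {magnification} exceeds the highest "
            f"scanned magnification {pyramid.base_magnification}")
    if magnification <= 0:
        raise ValueError("magnification must be positive")
    if w < 1 or h < 1:
        raise ValueError("region width and height must be positive")
    source = pyramid.source_level_for(magnification)
    if abs(source.magnification - magnification) <= _MAG_ATOL:
        return read_level_region(pyramid, source.magnification, x, y, w, h)

    tw, th = level_dimensions(pyramid.base_width, pyramid.base_height,
                              pyramid.base_magnification, magnification)
    cols = nn_indices(tw, source.width_px, offset=x, count=w)
    rows = nn_indices(th, source.height_px, offset=y, count=h)
    # Read the bounding source region once (white-filled out of bounds),
    # then gather; cheaper than per-pixel tile lookups.
    sx0, sx1 = int(cols.min()), int(cols.max()) + 1
    sy0, sy1 = int(rows.min()), int(rows.max()) + 1
    block = read_level_region(pyramid, source.magnification,
                              sx0, sy0, sx1 - sx0, sy1 - sy0)
    return block[np.ix_(rows - sy0, cols - sx0)]


# --------------------------------------------------------------------------
# On-disk layout: pyramid.json + level_<i>/<row>_<col>.png  (DZI-like)


def save_pyramid(pyramid: TilePyramid, directory) -> None:
    """Write metadata and one PNG per tile under ``directory``."""
    root = Path(directory)
    root.mkdir(parents=True, exist_ok=True)
    meta = {
        "slide_id": pyramid.slide_id,
        "base_width": pyramid.base_width,
        "base_height": pyramid.base_height,
        "base_magnification": pyramid.base_magnification,
        "tile_size": pyramid.tile_size,
        "levels": [{"magnification": lv.magnification,
                    "width_px": lv.width_px, "height_px": lv.height_px}
                   for lv in pyramid.levels],
    }
    (root / "pyramid.json").write_text(json.dumps(meta, indent=2))
    for i, lv in enumerate(pyramid.levels):
        level_dir = root / f"level_{i}"
        level_dir.mkdir(exist_ok=True)
        for (tr, tc), tile in lv.tiles.items():
            Image.fromarray(tile).save(level_dir / f"{tr}_{tc}.png")


def load_pyramid(directory) -> TilePyramid:
    root = Path(directory)
    meta = json.loads((root / "pyramid.json").read_text())
    ts = int(meta["tile_size"])
    levels = []
    for i, lvm in enumerate(meta["levels"]):
        w, h = int(lvm["width_px"]), int(lvm["height_px"])
        tiles = {}
        for tr in range(math.ceil(h / ts)):
            for tc in range(math.ceil(w / ts)):
                path = root / f"level_{i}" / f"{tr}_{tc}.png"
                tiles[(tr, tc)] = np.asarray(Image.open(path).convert("RGB"),
                                             dtype=np.uint8)
        levels.append(PyramidLevel(magnification=float(lvm["magnification"]),
                                   width_px=w, height_px=h, tile_size=ts,
                                   tiles=tiles))
    return TilePyramid(slide_id=meta["slide_id"],
                       base_width=int(meta["base_width"]),
                       base_height=int(meta["base_height"]),
                       base_magnification=float(meta["base_magnification"]),
                       tile_size=ts, levels=levels)
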