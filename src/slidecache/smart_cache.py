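"""Multi-resolution prefetch cache for pan/zoom slide viewing.

The viewer keeps a grid of square cells around the current field of view
— by default 9 rows x 12 columns of 256 px cells (3072 x 2304 px), with
the central 3 x 4 block exactly covering a 1024 x 768 screen.  The 12
central cells are loaded at full resolution; the 96 peripheral cells are
prefetched as down-sampled blocks and enlarged for display, the fraction
of full-resolution data falling off towards the grid edge::

    col:    1     2     3..10              11    12
    row 1   6.25  12.5  12.5 ...           12.5  6.25   (percent of a
    row 2   6.25  12.5  12.5 ...           12.5  6.25    full-resolution
    row 3   6.25  12.5  25 ...             12.5  6.25    cell's pixels)
    row 4-6 6.25  12.5  25 25 100x4 25 25  12.5  6.25
    row 7   6.25  12.5  25 ...             12.5  6.25
    row 8-9 6.25  12.5  12.5 ...           12.5  6.25

Summed over the grid this is 26.375 cell-equivalents out of 108, i.e.
24.42% of the naive all-full-resolution cost — a 75.58% saving.  The
margin of peripheral cells (1024 px left/right, 768 px top/bottom at
default geometry) absorbs any single pan up to a full screen without
exposing unloaded background; cells that enter the screen are promoted
to full resolution in place, and the whole grid is re-anchored and
refilled only when the screen is no longer covered by the grid.

Cell loads go through the region-serving zoom mechanism: a cell with
fraction f requests a round(cell_px * sqrt(f))-sized block at the
correspondingly reduced magnification (e.g. a 25% cell at 40x fetches a
128 x 128 block at 20x) and enlarges it by nearest neighbour for
display.  Savings accounting uses the nominal fractions of the pattern.

Grid rows/columns are 1-based in the public API, matching the pattern
table above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .manipulation import Rect, ViewportState
from .pyramid import TilePyramid, nn_indices
from .region_server import RegionRequest, handle_request

DEFAULT_ROWS = 9
DEFAULT_COLS = 12
DEFAULT_CELL_PX = 256

_EPS = 1e-6

#: Per-cell percent of full-resolution pixel data for the default 9x12
#: grid.  Not a simple radial function of distance from the centre — the
#: pattern is configuration, stored verbatim.
_DEFAULT_PATTERN_PERCENT = [
    [6.25, 12.5, 12.5, 12.5, 12.5, 12.5, 12.5, 12.5, 12.5, 12.5, 12.5, 6.25],
    [6.25, 12.5, 12.5, 12.5, 12.5, 12.5, 12.5, 12.5, 12.5, 12.5, 12.5, 6.25],
    [6.25, 12.5, 25.0, 25.0, 25.0, 25.0, 25.0, 25.0, 25.0, 25.0, 12.5, 6.25],
    [6.25, 12.5, 25.0, 25.0, 100.0, 100.0, 100.0, 100.0, 25.0, 25.0, 12.5, 6.25],
    [6.25, 12.5, 25.0, 25.0, 100.0, 100.0, 100.0, 100.0, 25.0, 25.0, 12.5, 6.25],
    [6.25, 12.5, 25.0, 25.0, 100.0, 100.0, 100.0, 100.0, 25.0, 25.0, 12.5, 6.25],
    [6.25, 12.5, 25.0, 25.0, 25.0, 25.0, 25.0, 25.0, 25.0, 25.0, 12.5, 6.25],
    [6.25, 12.5, 12.5, 12.5, 12.5, 12.5, 12.5, 12.5, 12.5, 12.5, 12.5, 6.25],
    [6.25, 12.5, 12.5, 12.5, 12.5, 12.5, 12.5, 12.5, 12.5, 12.5, 12.5, 6.25],
]


def default_pattern() -> np.ndarray:
    """The default 9x12 resolution-fraction pattern (values in (0, 1])."""
    return np.asarray(_DEFAULT_PATTERN_PERCENT, dtype=float) / 100.0


def naive_pattern(rows: int = DEFAULT_ROWS, cols: int = DEFAULT_COLS) -> np.ndarray:
    """All-full-resolution pattern: what a cache without down-sampling loads."""
    return np.ones((rows, cols), dtype=float)


def resolution_fraction(row: int, col: int) -> float:
    """Fraction of full-resolution pixel data for cell (row, col), 1-based,
    of the default 9x12 pattern."""
    if not (1 <= row <= DEFAULT_ROWS) or not (1 <= col <= DEFAULT_COLS):
        raise ValueError(
            f"cell ({row}, {col}) out of range 1..{DEFAULT_ROWS} x 1..{DEFAULT_COLS}")
    return _DEFAULT_PATTERN_PERCENT[row - 1][col - 1] / 100.0


@dataclass
class CacheStats:
    """Pixel accounting for cache activity.

    ``pixels_naive_equivalent`` is what loading the same cells at full
    resolution would have cost, so 1 - loaded/naive is the data saving.
    """

    pixels_loaded: int = 0
    pixels_naive_equivalent: int = 0
    cells_loaded: int = 0
    promotions: int = 0
    grid_reloads: int = 0

    def __add__(self, other: "CacheStats") -> "CacheStats":
        return CacheStats(*(a + b for a, b in zip(self._tuple(), other._tuple())))

    def __iadd__(self, other: "CacheStats") -> "CacheStats":
        for name, value in asdict(other).items():
            setattr(self, name, getattr(self, name) + value)
        return self

    def _tuple(self):
        return (self.pixels_loaded, self.pixels_naive_equivalent,
                self.cells_loaded, self.promotions, self.grid_reloads)

    @property
    def savings_fraction(self) -> float:
        """1 - loaded/naive; 0 when nothing was loaded."""
        if self.pixels_naive_equivalent == 0:
            return 0.0
        return 1.0 - self.pixels_loaded / self.pixels_naive_equivalent

    def as_dict(self) -> dict:
        d = asdict(self)
        d["savings_fraction"] = self.savings_fraction
        return d


@dataclass
class CacheCell:
    """One grid cell: its target fraction and what is currently held."""

    target_fraction: float
    loaded_fraction: float = 0.0
    state: str = "empty"               # empty | queued | loaded
    raster: np.ndarray | None = field(default=None, repr=False)


@dataclass
class CacheGrid:
    """The prefetch grid, anchored in the pixel frame of one magnification.

    ``anchor`` is the frame coordinate of the top-left corner of cell
    (1, 1).  The central block of cells covering a centred screen is
    fully determined by the margins between grid and screen extent.
    """

    rows: int
    cols: int
    cell_px: int
    anchor_x: int
    anchor_y: int
    magnification: float
    base_magnification: float
    pattern: np.ndarray = field(repr=False)
    cells: list[list[CacheCell]] = field(repr=False, default=None)

    def __post_init__(self):
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_px < 16:
            raise ValueError("cell size must be at least 16 px")
        pat = np.asarray(self.pattern, dtype=float)
        if pat.shape != (self.rows, self.cols):
            raise ValueError(
                f"pattern shape {pat.shape} does not match grid {self.rows}x{self.cols}")
        if np.any(pat <= 0) or np.any(pat > 1):
            raise ValueError("pattern fractions must lie in (0, 1]")
        self.pattern = pat
        if self.cells is None:
            self.cells = [[CacheCell(target_fraction=float(pat[r, c]))
                           for c in range(self.cols)] for r in range(self.rows)]

    # -- geometry ----------------------------------------------------------

    @property
    def width_px(self) -> int:
        return self.cols * self.cell_px

    @property
    def height_px(self) -> int:
        return self.rows * self.cell_px

    def cell(self, row: int, col: int) -> CacheCell:
        """Cell accessor, 1-based indices."""
        if not (1 <= row <= self.rows) or not (1 <= col <= self.cols):
            raise ValueError(f"cell ({row}, {col}) out of range")
        return self.cells[row - 1][col - 1]

    def cell_rect(self, row: int, col: int) -> Rect:
        """Cell extent in the grid's magnification frame, 1-based indices."""
        x0 = self.anchor_x + (col - 1) * self.cell_px
        y0 = self.anchor_y + (row - 1) * self.cell_px
        return Rect(x0, y0, x0 + self.cell_px, y0 + self.cell_px)

    def extent(self) -> Rect:
        return Rect(self.anchor_x, self.anchor_y,
                    self.anchor_x + self.width_px, self.anchor_y + self.height_px)

    def central_block(self, screen_width: int, screen_height: int):
        """1-based (row_lo, row_hi, col_lo, col_hi) of the cells covering a
        centred screen of the given size."""
        mcols = (self.width_px - screen_width) / (2 * self.cell_px)
        mrows = (self.height_px - screen_height) / (2 * self.cell_px)
        c_lo = int(math.floor(mcols)) + 1
        r_lo = int(math.floor(mrows)) + 1
        return (r_lo, self.rows - r_lo + 1, c_lo, self.cols - c_lo + 1)

    # -- frame conversions -------------------------------------------------

    def screen_rect_in_frame(self, viewport: ViewportState) -> Rect:
        """The screen rectangle expressed in this grid's magnification frame."""
        inv = viewport.cumulative.inverse()
        k = self.magnification / self.base_magnification
        x0, y0 = inv.apply((0.0, 0.0)) * k
        x1, y1 = inv.apply((float(viewport.screen_width),
                            float(viewport.screen_height))) * k
        return Rect(x0, y0, x1, y1)

    def frame_to_screen_rect(self, viewport: ViewportState, rect: Rect) -> Rect:
        """Project a rectangle in this grid's frame onto the screen."""
        k = self.base_magnification / self.magnification
        x0, y0 = viewport.cumulative.apply((rect.x0 * k, rect.y0 * k))
        x1, y1 = viewport.cumulative.apply((rect.x1 * k, rect.y1 * k))
        return Rect(x0, y0, x1, y1)


def make_grid(viewport: ViewportState, pyramid: TilePyramid, *,
              rows: int = DEFAULT_ROWS, cols: int = DEFAULT_COLS,
              cell_px: int = DEFAULT_CELL_PX, pattern: np.ndarray | None = None,
              magnification: float | None = None) -> CacheGrid:
    """Anchor a fresh (empty) grid centred on the current viewport.

    The magnification defaults to the viewport's effective magnification
    (viewport scale x base power), clamped to the base — the frame in
    which screen pixels map 1:1 to slide pixels.
    """
    base = pyramid.base_magnification
    if magnification is None:
        magnification = min(base, viewport.cumulative.scale * base)
    pat = default_pattern() if pattern is None else np.asarray(pattern, dtype=float)
    inv = viewport.cumulative.inverse()
    k = magnification / base
    sx0, sy0 = inv.apply((0.0, 0.0)) * k
    margin_x = (cols * cell_px - viewport.screen_width) / 2.0
    margin_y = (rows * cell_px - viewport.screen_height) / 2.0
    return CacheGrid(rows=rows, cols=cols, cell_px=cell_px,
                     anchor_x=int(round(sx0 - margin_x)),
                     anchor_y=int(round(sy0 - margin_y)),
                     magnification=float(magnification),
                     base_magnification=base, pattern=pat)


def fill_order(grid: CacheGrid, screen_width: int = 1024,
               screen_height: int = 768) -> list[tuple[int, int]]:
    """Deterministic load queue: central (on-screen) cells first, then
    rings outward; row-major within a ring.  1-based indices.

    Cells become displayable one by one in this order — the model of
    asynchronous per-block display.
    """
    r_lo, r_hi, c_lo, c_hi = grid.central_block(screen_width, screen_height)

    def ring(rc):
        r, c = rc
        dr = max(0, r_lo - r, r - r_hi)
        dc = max(0, c_lo - c, c - c_hi)
        return max(dr, dc)

    cells = [(r, c) for r in range(1, grid.rows + 1) for c in range(1, grid.cols + 1)]
    return sorted(cells, key=lambda rc: (ring(rc), rc[0], rc[1]))


def _load_cell(grid: CacheGrid, pyramid: TilePyramid, row: int, col: int,
               fraction: float) -> np.ndarray:
    """Fetch one cell at the given area fraction and enlarge for display."""
    rect = grid.cell_rect(row, col)
    side = int(round(grid.cell_px * math.sqrt(fraction)))
    side = max(1, min(side, grid.cell_px))
    if side == grid.cell_px:
        req = RegionRequest(int(rect.x0), int(rect.y0), grid.cell_px, grid.cell_px,
                            zoom=pyramid.base_magnification / grid.magnification)
        return handle_request(pyramid, req).pixels
    ratio = side / grid.cell_px
    m_src = grid.magnification * ratio
    req = RegionRequest(int(round(rect.x0 * ratio)), int(round(rect.y0 * ratio)),
                        side, side, zoom=pyramid.base_magnification / m_src)
    small = handle_request(pyramid, req).pixels
    idx = nn_indices(grid.cell_px, side)
    return small[np.ix_(idx, idx)]


def fill_grid(grid: CacheGrid, pyramid: TilePyramid,
              screen_width: int = 1024, screen_height: int = 768) -> CacheStats:
    """Load every unloaded cell at its pattern fraction, central cells first.

    Returns the pixel-accounting delta; nominal fractions are used for
    the accounting so the pattern's arithmetic is exact.
    """
    stats = CacheStats()
    area = grid.cell_px * grid.cell_px
    order = fill_order(grid, screen_width, screen_height)
    for row, col in order:
        cell = grid.cell(row, col)
        if cell.state == "empty":
            cell.state = "queued"
    for row, col in order:
        cell = grid.cell(row, col)
        if cell.state == "loaded":
            continue
        cell.raster = _load_cell(grid, pyramid, row, col, cell.target_fraction)
        cell.loaded_fraction = cell.target_fraction
        cell.state = "loaded"
        stats.cells_loaded += 1
        stats.pixels_loaded += int(round(cell.target_fraction * area))
        stats.pixels_naive_equivalent += area
    return stats


def visible_cells(grid: CacheGrid, viewport: ViewportState) -> set[tuple[int, int]]:
    """1-based (row, col) of cells whose screen projection intersects the
    screen rectangle (strict overlap; abutting cells do not count)."""
    screen = grid.screen_rect_in_frame(viewport)
    out = set()
    for row in range(1, grid.rows + 1):
        for col in range(1, grid.cols + 1):
            inter = grid.cell_rect(row, col).intersect(screen)
            if inter.width > _EPS and inter.height > _EPS:
                out.add((row, col))
    return out


def promote_visible(grid: CacheGrid, pyramid: TilePyramid,
                    viewport: ViewportState) -> CacheStats:
    """Replace every down-sampled cell now on screen with its
    full-resolution counterpart; off-screen cells are untouched.
    Idempotent: already-sharp cells cost nothing."""
    stats = CacheStats()
    area = grid.cell_px * grid.cell_px
    for row, col in sorted(visible_cells(grid, viewport)):
        cell = grid.cell(row, col)
        if cell.state == "loaded" and cell.loaded_fraction >= 1.0:
            continue
        cell.raster = _load_cell(grid, pyramid, row, col, 1.0)
        cell.loaded_fraction = 1.0
        cell.state = "loaded"
        stats.promotions += 1
        stats.pixels_loaded += area
        stats.pixels_naive_equivalent += area
    return stats


def grid_covers_screen(grid: CacheGrid, viewport: ViewportState) -> bool:
    """True while every screen pixel still falls inside the grid footprint."""
    screen = Rect(0.0, 0.0, float(viewport.screen_width), float(viewport.screen_height))
    footprint = grid.frame_to_screen_rect(viewport, grid.extent())
    return footprint.contains(screen, eps=_EPS)


def maybe_reanchor(grid: CacheGrid, pyramid: TilePyramid, viewport: ViewportState,
                   ) -> tuple[CacheGrid, CacheStats]:
    """Re-anchor and refill the grid only when part of the screen has left
    the grid footprint (large cumulative pan, or zoom-out shrinking the
    footprint); otherwise return the grid unchanged.

    A zoom-in only expands the footprint outward and never triggers a
    reload — newly visible blurred cells are handled by promotion.
    """
    if grid_covers_screen(grid, viewport):
        return grid, CacheStats()
    fresh = make_grid(viewport, pyramid, rows=grid.rows, cols=grid.cols,
                      cell_px=grid.cell_px, pattern=grid.pattern)
    stats = fill_grid(fresh, pyramid, viewport.screen_width, viewport.screen_height)
    stats.grid_reloads += 1
    return fresh, stats


def render_screen(grid: CacheGrid, viewport: ViewportState) -> np.ndarray:
    """Paint the screen from cached cells (nearest neighbour), white where
    nothing is loaded.  Used to check coverage and promotion fidelity."""
    w, h = viewport.screen_width, viewport.screen_height
    mosaic = np.full((grid.height_px, grid.width_px, 3), 255, dtype=np.uint8)
    cp = grid.cell_px
    for r in range(grid.rows):
        for c in range(grid.cols):
            cell = grid.cells[r][c]
            if cell.state == "loaded" and cell.raster is not None:
                mosaic[r * cp:(r + 1) * cp, c * cp:(c + 1) * cp] = cell.raster
    # screen pixel centres -> grid frame
    inv = viewport.cumulative.inverse()
    k = grid.magnification / grid.base_magnification
    s = inv.scale * k
    tx, ty = (np.asarray(inv.translation) * k)
    xs = np.floor((np.arange(w) + 0.5) * s + tx).astype(np.int64) - grid.anchor_x
    ys = np.floor((np.arange(h) + 0.5) * s + ty).astype(np.int64) - grid.anchor_y
    out = np.full((h, w, 3), 255, dtype=np.uint8)
    vx = (xs >= 0) & (xs < grid.width_px)
    vy = (ys >= 0) & (ys < grid.height_px)
    if vx.any() and vy.any():
        out[np.ix_(np.nonzero(vy)[0], np.nonzero(vx)[0])] = mosaic[np.ix_(ys[vy], xs[vx])]
    return out


def screen_fully_loaded(grid: CacheGrid, viewport: ViewportState) -> bool:
    """True when every visible screen pixel is backed by a loaded cell."""
    screen = grid.screen_rect_in_frame(viewport)
    if not grid.extent().contains(screen, eps=_EPS):
        return False
    for row, col in visible_cells(grid, viewport):
        if grid.cell(row, col).state != "loaded":
            return False
    return True
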