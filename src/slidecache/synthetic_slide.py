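"""Deterministic generator of histology-like test rasters.

Real haematoxylin-and-eosin tissue scans are gigapixel images with
structure at every scale: broad eosinophilic washes of cytoplasm and
stroma, clusters of dark basophilic nuclei a few microns across, and
fine per-pixel grain.  The generator emulates exactly that three-band
composition — a low-frequency background wash, mid-frequency dark
elliptical "nuclei", and per-pixel noise — so that renderings of the
same region at different magnifications are measurably different.  That
property is what makes pyramid, caching and blur/promotion behaviour
testable without downloading a scanned slide.

Everything is a pure function of (width, height, magnification, seed):
the same arguments always give a byte-identical raster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image, ImageDraw

MIN_DIMENSION = 64

# H&E-ish palette, 8-bit RGB.
_BACKGROUND = np.array([236.0, 222.0, 230.0])   # pale eosin wash
_STROMA = np.array([225.0, 180.0, 205.0])        # deeper pink regions
_NUCLEUS = np.array([88.0, 58.0, 132.0])         # haematoxylin purple


@dataclass(frozen=True)
class SlideImage:
    """An in-memory RGB slide raster with its nominal objective power."""

    pixels: np.ndarray            # (height, width, 3) uint8
    base_magnification: float

    def __post_init__(self):
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 3 or p.dtype != np.uint8:
            raise ValueError("pixels must be a (h, w, 3) uint8 array")
        if self.base_magnification <= 0:
            raise ValueError("base magnification must be positive")
        p.flags.writeable = False
        object.__setattr__(self, "pixels", p)

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]


def _background_wash(rng: np.random.Generator, width: int, height: int) -> np.ndarray:
    """Low-frequency mix between the pale and deep-pink field colours."""
    coarse = max(2, width // 256), max(2, height // 256)
    field = rng.random((coarse[1], coarse[0]))
    img = Image.fromarray((field * 255).astype(np.uint8), mode="L")
    weight = np.asarray(img.resize((width, height), Image.BILINEAR), dtype=float) / 255.0
    return _BACKGROUND[None, None, :] * (1 - weight[..., None]) + _STROMA[None, None, :] * weight[..., None]


def _draw_nuclei(rng: np.random.Generator, width: int, height: int) -> np.ndarray:
    """Clustered dark ellipses; returns a float coverage mask in [0, 1]."""
    mask = Image.new("L", (width, height), 0)
    draw = ImageDraw.Draw(mask)
    n_clusters = max(1, (width * height) // 80_000)
    for _ in range(n_clusters):
        cx = rng.uniform(0, width)
        cy = rng.uniform(0, height)
        spread = rng.uniform(20, 80)
        for _ in range(rng.integers(8, 30)):
            x = cx + rng.normal(0, spread)
            y = cy + rng.normal(0, spread)
            rx = rng.uniform(2.5, 9.0)
            ry = rx * rng.uniform(0.6, 1.4)
            draw.ellipse((x - rx, y - ry, x + rx, y + ry), fill=255)
    return np.asarray(mask, dtype=float) / 255.0


def generate_slide(width_px: int, height_px: int, base_magnification: float = 40.0,
                   seed: int = 0) -> SlideImage:
    """Generate a deterministic H&E-like test slide.

    Parameters
    ----------
    width_px, height_px
        Raster size in pixels; at least 64 each so the multi-scale
        structure is actually present.
    base_magnification
        Nominal objective power recorded in the slide descriptor
        (40 is a typical diagnostic scan).
    seed
        Seeds every random choice; identical arguments are pixel-identical.
    """
    if width_px < MIN_DIMENSION or height_px < MIN_DIMENSION:
        raise ValueError(
            f"slide dimensions must be at least {MIN_DIMENSION}x{MIN_DIMENSION}, "
            f"got {width_px}x{height_px}")
    if base_magnification <= 0:
        raise ValueError("base magnification must be positive")

    rng = np.random.default_rng(seed)
    img = _background_wash(rng, width_px, height_px)
    nuclei = _draw_nuclei(rng, width_px, height_px)
    img = img * (1 - nuclei[..., None]) + _NUCLEUS[None, None, :] * nuclei[..., None]
    img += rng.normal(0.0, 5.0, size=img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return SlideImage(pixels=pixels, base_magnification=float(base_magnification))


def save_slide(slide: SlideImage, path) -> None:
    """Write the raster as PNG or TIFF (chosen by file extension)."""
    Image.fromarray(slide.pixels).save(path)


def load_slide(path, base_magnification: float = 40.0) -> SlideImage:
    """Read any raster Pillow understands as a slide at the given power."""
    img = Image.open(path).convert("RGB")
    return SlideImage(pixels=np.asarray(img, dtype=np.uint8),
                      base_magnification=float(base_magnification))
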