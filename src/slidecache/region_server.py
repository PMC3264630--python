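"""Region-on-demand serving: the instruction contract between viewer and store.

A request names a rectangle (x, y, width, height) and a ``zoom`` divisor
>= 1, where zoom 1 is the highest scanned magnification; the effective
magnification served is base_magnification / zoom.  Coordinates and the
response raster are in the effective-magnification pixel frame, so the
response is always exactly width x height pixels — areas falling outside
the slide come back white, the viewer's blank background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pyramid import TilePyramid, region_at_magnification


@dataclass(frozen=True)
class RegionRequest:
    """One region instruction: upper-left corner, size, zoom divisor."""

    x: int
    y: int
    width: int
    height: int
    zoom: float = 1.0

    def __post_init__(self):
        if self.width < 1 or self.height < 1:
            raise ValueError(
                f"width and height must be >= 1, got {self.width}x{self.height}")
        if self.zoom < 1.0:
            raise ValueError(
                f"zoom must be >= 1 (1 = highest magnification), got {self.zoom}")


@dataclass(frozen=True)
class RegionResponse:
    """The served raster plus what actually backed it."""

    pixels: np.ndarray                 # (height, width, 3) uint8
    effective_magnification: float     # base_magnification / zoom
    source_magnification: float        # stored level the data came from
    request: RegionRequest


def handle_request(pyramid: TilePyramid, request: RegionRequest) -> RegionResponse:
    """Serve one region instruction from the pyramid.

    Deterministic: identical requests return bit-identical rasters.
    """
    effective = pyramid.base_magnification / request.zoom
    source = pyramid.source_level_for(effective)
    pixels = region_at_magnification(pyramid, effective, request.x, request.y,
                                     request.width, request.height)
    return RegionResponse(pixels=pixels, effective_magnification=effective,
                          source_magnification=source.magnification,
                          request=request)
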