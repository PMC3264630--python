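"""Affine pan/zoom processing for a slide viewport.

A viewer session manipulates the field of view with translations (panning)
and uniform scalings about an arbitrary focal point (zooming towards a
pinch centre).  Every manipulation is a 3x3 homogeneous matrix; the
cumulative slide->screen mapping is the product of the individual
transforms in application order, and intermediate prefix products give the
states rendered while a gesture is still in progress.

Scaling about a focal point ``p`` decomposes into translate(-p), uniform
scale, translate(+p); composing only translations and positive uniform
scalings keeps every matrix of the shape::

    [ s  0  tx ]
    [ 0  s  ty ]
    [ 0  0  1  ]

with s > 0, so the group is closed, invertible, and axis-aligned
rectangles map to axis-aligned rectangles (no rotation or shear is ever
introduced; the viewer does not support rotation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Tolerance for transform equality checks (matrix entries are products of
#: screen-pixel-scale numbers, so absolute comparison is appropriate).
ATOL = 1e-9


def _as_matrix(m) -> np.ndarray:
    a = np.asarray(m, dtype=float)
    if a.shape != (3, 3):
        raise ValueError(f"affine matrix must be 3x3, got shape {a.shape}")
    return a


@dataclass(frozen=True)
class AffineTransform:
    """A translation + uniform-scaling transform in homogeneous form."""

    matrix: np.ndarray

    def __post_init__(self):
        m = _as_matrix(self.matrix)
        m.flags.writeable = False
        object.__setattr__(self, "matrix", m)
        if not np.allclose(m[2], (0.0, 0.0, 1.0), atol=ATOL):
            raise ValueError("last row of a homogeneous affine must be [0, 0, 1]")
        if abs(m[0, 1]) > ATOL or abs(m[1, 0]) > ATOL or abs(m[0, 0] - m[1, 1]) > ATOL:
            raise ValueError("only translations and uniform scalings are supported")
        if m[0, 0] <= 0:
            raise ValueError("scale factor must be positive")

    @property
    def scale(self) -> float:
        """The uniform scale factor of the transform."""
        return float(self.matrix[0, 0])

    @property
    def translation(self) -> tuple[float, float]:
        return float(self.matrix[0, 2]), float(self.matrix[1, 2])

    def apply(self, point) -> np.ndarray:
        """Map a point ``(x, y)`` or an (n, 2) array of points."""
        p = np.atleast_2d(np.asarray(point, dtype=float))
        hom = np.hstack([p, np.ones((p.shape[0], 1))])
        out = (self.matrix @ hom.T).T[:, :2]
        return out[0] if np.asarray(point).ndim == 1 else out

    def then(self, other: "AffineTransform") -> "AffineTransform":
        """The transform applying ``self`` first, then ``other``."""
        return AffineTransform(other.matrix @ self.matrix)

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    def almost_equals(self, other: "AffineTransform", atol: float = ATOL) -> bool:
        return bool(np.allclose(self.matrix, other.matrix, atol=atol))


def identity() -> AffineTransform:
    return AffineTransform(np.eye(3))


def translate(dx: float, dy: float) -> AffineTransform:
    """Pan by (dx, dy): maps (x, y) -> (x + dx, y + dy)."""
    m = np.eye(3)
    m[0, 2] = dx
    m[1, 2] = dy
    return AffineTransform(m)


def scaling(s: float) -> AffineTransform:
    """Uniform scaling about the origin by factor ``s`` > 0."""
    if s <= 0:
        raise ValueError(f"scale factor must be positive, got {s}")
    m = np.diag([float(s), float(s), 1.0])
    return AffineTransform(m)


def scale_about(s: float, px: float, py: float) -> AffineTransform:
    """Uniform scaling by ``s`` keeping the focal point (px, py) fixed.

    Decomposes as translate(px, py) after scale(s) after translate(-px, -py),
    so (px, py) is a fixed point for every s.
    """
    if s <= 0:
        raise ValueError(f"scale factor must be positive, got {s}")
    return compose([translate(-px, -py), scaling(s), translate(px, py)])


def compose(transforms: Sequence[AffineTransform]) -> AffineTransform:
    """Product of transforms in application order (first applied first).

    ``compose([])`` is the identity; ``compose([a, b])`` applies ``a`` then
    ``b`` (matrix product b @ a).
    """
    out = identity()
    for t in transforms:
        out = out.then(t)
    return out


def intermediate_states(transforms: Sequence[AffineTransform], j: int) -> AffineTransform:
    """Prefix product of the first ``j`` transforms (the state rendered
    after ``j`` steps of an in-progress gesture).

    j = 0 gives the identity; j = len(transforms) equals the full
    composition.
    """
    n = len(transforms)
    if not 0 <= j <= n:
        raise ValueError(f"prefix length {j} out of range [0, {n}]")
    return compose(transforms[:j])


# --------------------------------------------------------------------------
# Viewport and manipulation events


@dataclass(frozen=True)
class ViewportState:
    """The cumulative slide-base -> screen mapping plus the screen size."""

    cumulative: AffineTransform = field(default_factory=identity)
    screen_width: int = 1024
    screen_height: int = 768

    def __post_init__(self):
        if self.screen_width < 1 or self.screen_height < 1:
            raise ValueError("screen dimensions must be positive")


_EVENT_KINDS = ("pan", "zoom", "pan_and_zoom")


@dataclass(frozen=True)
class ManipulationEvent:
    """One recorded pan / zoom / combined gesture, in screen pixels.

    ``scale`` must be 1 for a pure pan; (dx, dy) must be (0, 0) for a pure
    zoom.  ``focal_x, focal_y`` is the screen-frame fixed point of the
    scaling part (the pinch centre).
    """

    kind: str
    dx: float = 0.0
    dy: float = 0.0
    scale: float = 1.0
    focal_x: float = 0.0
    focal_y: float = 0.0

    def __post_init__(self):
        if self.kind not in _EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}; expected one of {_EVENT_KINDS}")
        if self.scale <= 0:
            raise ValueError(f"event scale must be positive, got {self.scale}")
        if self.kind == "pan" and self.scale != 1.0:
            raise ValueError("a pure pan must have scale == 1")
        if self.kind == "zoom" and (self.dx != 0.0 or self.dy != 0.0):
            raise ValueError("a pure zoom must have (dx, dy) == (0, 0)")

    def transform(self) -> AffineTransform:
        """The screen-frame transform of the event: scale about the focal
        point, then translate."""
        return compose([scale_about(self.scale, self.focal_x, self.focal_y),
                        translate(self.dx, self.dy)])


def apply_event(viewport: ViewportState, event: ManipulationEvent) -> ViewportState:
    """Fold one event into the cumulative viewport transform."""
    new = viewport.cumulative.then(event.transform())
    return ViewportState(new, viewport.screen_width, viewport.screen_height)


def slide_to_screen(viewport: ViewportState, point) -> np.ndarray:
    """Map a slide-base-frame point to the screen frame."""
    return viewport.cumulative.apply(point)


def screen_to_slide(viewport: ViewportState, point) -> np.ndarray:
    """Map a screen-frame point back to the slide base frame."""
    return viewport.cumulative.inverse().apply(point)


# --------------------------------------------------------------------------
# Rectangle geometry (axis-aligned; the transform group preserves this)


@dataclass(frozen=True)
class Rect:
    """Half-open axis-aligned rectangle [x0, x1) x [y0, y1)."""

    x0: float
    y0: float
    x1: float
    y1: float

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    def is_empty(self, eps: float = 1e-9) -> bool:
        return self.width <= eps or self.height <= eps

    def intersect(self, other: "Rect") -> "Rect":
        return Rect(max(self.x0, other.x0), max(self.y0, other.y0),
                    min(self.x1, other.x1), min(self.y1, other.y1))

    def contains(self, other: "Rect", eps: float = 1e-6) -> bool:
        """True when ``other`` lies inside self (within eps slack)."""
        return (self.x0 <= other.x0 + eps and self.y0 <= other.y0 + eps
                and self.x1 >= other.x1 - eps and self.y1 >= other.y1 - eps)


def transform_rect(t: AffineTransform, r: Rect) -> Rect:
    """Image of a rectangle; exact because the group is rotation-free
    with positive scale (corner order is preserved)."""
    x0, y0 = t.apply((r.x0, r.y0))
    x1, y1 = t.apply((r.x1, r.y1))
    return Rect(x0, y0, x1, y1)


def rect_difference(outer: Rect, inner: Rect) -> list[Rect]:
    """``outer`` minus ``inner`` as up to 4 disjoint rectangles
    (top and bottom strips full width, left/right strips between)."""
    inner = outer.intersect(inner)
    if inner.is_empty():
        return [] if outer.is_empty() else [outer]
    out = []
    if inner.y0 > outer.y0:  # top strip
        out.append(Rect(outer.x0, outer.y0, outer.x1, inner.y0))
    if inner.y1 < outer.y1:  # bottom strip
        out.append(Rect(outer.x0, inner.y1, outer.x1, outer.y1))
    if inner.x0 > outer.x0:  # left strip
        out.append(Rect(outer.x0, inner.y0, inner.x0, inner.y1))
    if inner.x1 < outer.x1:  # right strip
        out.append(Rect(inner.x1, inner.y0, outer.x1, inner.y1))
    return [r for r in out if not r.is_empty()]


def uncovered_screen_region(before: ViewportState, after: ViewportState,
                            slide_extent: tuple[int, int]) -> list[Rect]:
    """Screen rectangles that were covered by on-screen content before a
    manipulation but are uncovered after it (the "white" areas a viewer
    must re-fill from the server).

    ``slide_extent`` is (width, height) of the slide in base pixels.  A
    pan slides the old content off one edge and exposes a strip on the
    opposite edge; a zoom-in about an interior point pushes content
    outward and exposes nothing.
    """
    if (before.screen_width, before.screen_height) != (after.screen_width, after.screen_height):
        raise ValueError("viewports must share screen dimensions")
    screen = Rect(0.0, 0.0, float(after.screen_width), float(after.screen_height))
    slide = Rect(0.0, 0.0, float(slide_extent[0]), float(slide_extent[1]))

    # What the screen showed before the event: the slide's projection
    # clipped to the screen.
    covered_before = screen.intersect(transform_rect(before.cumulative, slide))
    if covered_before.is_empty():
        covered_now = Rect(0, 0, 0, 0)
    else:
        # Where that same content sits after the event.
        delta = before.cumulative.inverse().then(after.cumulative)
        covered_now = transform_rect(delta, covered_before)

    exposed = rect_difference(screen, covered_now)
    # Only areas where slide content should actually appear need filling.
    slide_now = transform_rect(after.cumulative, slide)
    out = [r.intersect(slide_now) for r in exposed]
    return [r for r in out if not r.is_empty()]
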