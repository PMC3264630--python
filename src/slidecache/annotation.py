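"""Slide-anchored annotations: circles and rectangles with text labels.

Geometry is stored in base-slide pixel coordinates, never in screen
pixels, so an annotation is "fixed within the slide": panning and
zooming transform its screen projection through exactly the same
cumulative transform as the slide itself, and slide and annotations
appear bonded together.  Because the viewport group contains only
translations and uniform scalings, circles project to circles (radius
multiplied by the viewport scale) and axis-aligned rectangles stay
axis-aligned.

Editing follows a two-state session machine: while an annotation is
being created/edited the viewer's gesture control of the slide is
halted, and it is restored when the annotation is committed with its
label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

from .exceptions import AnnotationFileError, AnnotationStateError
from .manipulation import ViewportState, slide_to_screen

#: Smallest radius / edge length (base-slide pixels) an edit may shrink to.
MIN_EXTENT = 1.0

DEFAULT_COLOUR = "#808080"
DEFAULT_CIRCLE_RADIUS = 100.0
DEFAULT_RECT_SIZE = (200.0, 150.0)


@dataclass(frozen=True)
class Annotation:
    """A circle (centre + radius) or rectangle (top-left + size), in
    base-slide pixels, with a free-text label."""

    id: str
    kind: str                       # "circle" | "rectangle"
    x: float                        # circle centre x / rectangle left
    y: float                        # circle centre y / rectangle top
    radius: float = 0.0             # circles only
    width: float = 0.0              # rectangles only
    height: float = 0.0
    label: str = ""
    colour: str = DEFAULT_COLOUR

    def __post_init__(self):
        if self.kind == "circle":
            if self.radius <= 0:
                raise ValueError("circle radius must be positive")
        elif self.kind == "rectangle":
            if self.width <= 0 or self.height <= 0:
                raise ValueError("rectangle width and height must be positive")
        else:
            raise ValueError(f"unknown annotation kind {self.kind!r}")

    @property
    def centroid(self) -> tuple[float, float]:
        if self.kind == "circle":
            return self.x, self.y
        return self.x + self.width / 2.0, self.y + self.height / 2.0

    @property
    def bottom_y(self) -> float:
        """Slide y of the shape's bottom edge (labels render below it)."""
        return self.y + (self.radius if self.kind == "circle" else self.height)


@dataclass(frozen=True)
class ProjectedAnnotation:
    """An annotation's screen-frame shape for a renderer to draw."""

    id: str
    kind: str
    x: float                        # screen centre x (circle) / left (rect)
    y: float
    radius: float
    width: float
    height: float
    label: str
    colour: str
    label_anchor: tuple[float, float]   # screen point below the shape


class AnnotationSession:
    """Mutable store of annotations plus the navigate/editing mode switch.

    At most one annotation is being edited at a time; while editing,
    viewport manipulation must be gated by the caller (``is_editing``).
    """

    def __init__(self, annotations=()):
        self._store: dict[str, Annotation] = {}
        for a in annotations:
            self._add(a)
        self._editing: str | None = None
        self._counter = len(self._store)

    def _add(self, a: Annotation) -> None:
        if a.id in self._store:
            raise ValueError(f"duplicate annotation id {a.id!r}")
        self._store[a.id] = a

    @property
    def is_editing(self) -> bool:
        return self._editing is not None

    @property
    def mode(self) -> str:
        return "navigate" if self._editing is None else f"editing:{self._editing}"

    @property
    def store(self) -> list[Annotation]:
        """Annotations in stable id order."""
        return sorted(self._store.values(), key=lambda a: a.id)

    def __len__(self) -> int:
        return len(self._store)

    # -- state machine -----------------------------------------------------

    def begin_annotation(self, kind: str, at: tuple[float, float] = (0.0, 0.0),
                         colour: str = DEFAULT_COLOUR) -> Annotation:
        """Create a default-geometry annotation at ``at`` (base-slide
        coordinates) and enter editing mode; slide gestures are halted
        until commit."""
        if self._editing is not None:
            raise AnnotationStateError(
                f"already editing annotation {self._editing!r}; commit it first")
        self._counter += 1
        aid = f"a{self._counter:04d}"
        if kind == "circle":
            a = Annotation(id=aid, kind="circle", x=at[0], y=at[1],
                           radius=DEFAULT_CIRCLE_RADIUS, colour=colour)
        else:
            w, h = DEFAULT_RECT_SIZE
            a = Annotation(id=aid, kind="rectangle", x=at[0], y=at[1],
                           width=w, height=h, colour=colour)
        self._add(a)
        self._editing = aid
        return a

    def edit_annotation(self, viewport: ViewportState,
                        move: tuple[float, float] = (0.0, 0.0),
                        resize: tuple[float, float] = (0.0, 0.0)) -> Annotation:
        """Apply move/resize deltas given in *screen* pixels.

        Deltas are divided by the viewport scale to become slide-frame
        deltas (a 100 px screen drag at 2x zoom moves the anchor 50
        slide pixels).  Extents are clamped at a minimum size rather
        than inverting.
        """
        if self._editing is None:
            raise AnnotationStateError("no annotation is being edited")
        a = self._store[self._editing]
        k = viewport.cumulative.scale
        dx, dy = move[0] / k, move[1] / k
        dw, dh = resize[0] / k, resize[1] / k
        if a.kind == "circle":
            a = replace(a, x=a.x + dx, y=a.y + dy,
                        radius=max(MIN_EXTENT, a.radius + dw))
        else:
            a = replace(a, x=a.x + dx, y=a.y + dy,
                        width=max(MIN_EXTENT, a.width + dw),
                        height=max(MIN_EXTENT, a.height + dh))
        self._store[a.id] = a
        return a

    def commit_annotation(self, label: str = "") -> Annotation:
        """Store the label and restore navigate mode (empty labels allowed)."""
        if self._editing is None:
            raise AnnotationStateError("no annotation is being edited")
        a = replace(self._store[self._editing], label=label)
        self._store[a.id] = a
        self._editing = None
        return a


def project_annotations(store, viewport: ViewportState) -> list[ProjectedAnnotation]:
    """Map every annotation's geometry through the slide->screen transform.

    Circles stay circles (radius scaled by the viewport factor); the
    label anchor is the screen point at the shape's bottom edge.
    """
    k = viewport.cumulative.scale
    out = []
    for a in sorted(store, key=lambda a: a.id):
        if a.kind == "circle":
            cx, cy = slide_to_screen(viewport, (a.x, a.y))
            proj = ProjectedAnnotation(
                id=a.id, kind=a.kind, x=float(cx), y=float(cy),
                radius=a.radius * k, width=0.0, height=0.0,
                label=a.label, colour=a.colour,
                label_anchor=(float(cx), float(cy) + a.radius * k))
        else:
            x0, y0 = slide_to_screen(viewport, (a.x, a.y))
            proj = ProjectedAnnotation(
                id=a.id, kind=a.kind, x=float(x0), y=float(y0),
                radius=0.0, width=a.width * k, height=a.height * k,
                label=a.label, colour=a.colour,
                label_anchor=(float(x0) + a.width * k / 2.0,
                              float(y0) + a.height * k))
        out.append(proj)
    return out


# --------------------------------------------------------------------------
# Persistence: a JSON list of records, stable id order


def save_annotations(store, path) -> None:
    records = []
    for a in sorted(store, key=lambda a: a.id):
        rec = {"id": a.id, "kind": a.kind, "label": a.label, "colour": a.colour}
        if a.kind == "circle":
            rec["geometry"] = {"x": a.x, "y": a.y, "radius": a.radius}
        else:
            rec["geometry"] = {"x": a.x, "y": a.y, "width": a.width, "height": a.height}
        records.append(rec)
    Path(path).write_text(json.dumps(records, indent=2))


def load_annotations(path) -> list[Annotation]:
    try:
        records = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise AnnotationFileError(f"invalid JSON in annotation file: {e}") from e
    if not isinstance(records, list):
        raise AnnotationFileError("annotation file must contain a JSON list")
    seen: set[str] = set()
    out = []
    for i, rec in enumerate(records):
        try:
            aid = rec["id"]
            if aid in seen:
                raise AnnotationFileError(f"duplicate annotation id {aid!r}", record=i)
            seen.add(aid)
            geom = rec["geometry"]
            out.append(Annotation(
                id=aid, kind=rec["kind"],
                x=float(geom["x"]), y=float(geom["y"]),
                radius=float(geom.get("radius", 0.0)),
                width=float(geom.get("width", 0.0)),
                height=float(geom.get("height", 0.0)),
                label=rec.get("label", ""), colour=rec.get("colour", DEFAULT_COLOUR)))
        except AnnotationFileError:
            raise
        except (KeyError, TypeError, ValueError) as e:
            raise AnnotationFileError(f"bad annotation record {i}: {e}", record=i) from e
    return sorted(out, key=lambda a: a.id)
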