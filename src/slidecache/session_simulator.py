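"""Replay manipulation/annotation traces against the full viewing stack.

A trace is an ordered list of steps — pan/zoom gestures and annotation
directives (begin/edit/commit).  The simulator drives pyramid -> region
server -> viewport -> smart cache -> annotations for each step, enforcing
the annotation state machine (slide gestures are ignored while an
annotation is being edited) and aggregating pixel-accounting statistics
across the initial grid fill, promotions and grid reloads.

``compare_strategies`` replays the same trace under the graded
resolution pattern and under all-full-resolution loading, reporting the
percentage of image data the graded cache saves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotation import Annotation, AnnotationSession
from .config import ViewerConfig
from .exceptions import AnnotationStateError, TraceError
from .manipulation import ManipulationEvent, ViewportState, apply_event, identity
from .pyramid import TilePyramid
from .smart_cache import (CacheGrid, CacheStats, fill_grid, make_grid,
                          maybe_reanchor, naive_pattern, promote_visible,
                          screen_fully_loaded)

_MANIPULATION_KINDS = {"pan", "zoom", "pan_and_zoom"}
_ANNOTATION_KINDS = {"begin_annotation", "edit_annotation", "commit_annotation"}


@dataclass(frozen=True)
class AnnotationDirective:
    """One annotation step of a trace."""

    op: str                               # begin_annotation | edit_annotation | commit_annotation
    shape: str = "circle"                 # begin only
    at: tuple[float, float] = (0.0, 0.0)  # begin only, base-slide coords
    move: tuple[float, float] = (0.0, 0.0)    # edit only, screen px
    resize: tuple[float, float] = (0.0, 0.0)  # edit only, screen px
    label: str = ""                       # commit only


TraceStep = ManipulationEvent | AnnotationDirective


def parse_trace(lines) -> list[TraceStep]:
    """Parse JSON-lines trace text (an iterable of lines) into steps.

    Raises :class:`TraceError` naming the 1-based offending line for
    malformed JSON or unknown step kinds.
    """
    steps: list[TraceStep] = []
    for lineno, raw in enumerate(lines, start=1):
        raw = raw.strip()
        if not raw or raw.startswith("#"):
            continue
        try:
            obj = json.loads(raw)
        except json.JSONDecodeError as e:
            raise TraceError(f"invalid JSON: {e}", line=lineno) from e
        if not isinstance(obj, dict) or "kind" not in obj:
            raise TraceError("each trace step must be an object with a 'kind'",
                             line=lineno)
        kind = obj["kind"]
        try:
            if kind in _MANIPULATION_KINDS:
                steps.append(ManipulationEvent(
                    kind=kind, dx=float(obj.get("dx", 0.0)), dy=float(obj.get("dy", 0.0)),
                    scale=float(obj.get("scale", 1.0)),
                    focal_x=float(obj.get("focal_x", 0.0)),
                    focal_y=float(obj.get("focal_y", 0.0))))
            elif kind in _ANNOTATION_KINDS:
                steps.append(AnnotationDirective(
                    op=kind, shape=obj.get("shape", "circle"),
                    at=tuple(obj.get("at", (0.0, 0.0))),
                    move=tuple(obj.get("move", (0.0, 0.0))),
                    resize=tuple(obj.get("resize", (0.0, 0.0))),
                    label=obj.get("label", "")))
            else:
                raise TraceError(f"unknown step kind {kind!r}", line=lineno)
        except TraceError:
            raise
        except (TypeError, ValueError) as e:
            raise TraceError(str(e), line=lineno) from e
    return steps


def load_trace(path) -> list[TraceStep]:
    return parse_trace(Path(path).read_text().splitlines())


@dataclass
class LoadEvent:
    """One accounting entry of the per-step load log."""

    step: int            # -1 for the initial fill
    phase: str           # fill | promote | reload
    stats: CacheStats


@dataclass
class SessionResult:
    stats: CacheStats
    viewport: ViewportState
    annotations: list[Annotation]
    grid: CacheGrid
    log: list[LoadEvent] = field(repr=False, default_factory=list)
    coverage_ok: bool = True


def run_session(pyramid: TilePyramid, trace, config: ViewerConfig | None = None,
                pattern: np.ndarray | None = None) -> SessionResult:
    """Replay a trace and return aggregated stats, final viewport,
    annotation store and the per-step load log.

    Deterministic in (pyramid, trace, config).  After every manipulation
    the cache is re-anchored if needed and visible cells are promoted, so
    coverage (no unloaded pixel on screen) is checked and reported.
    Structural annotation-state violations raise :class:`TraceError`
    naming the offending step; manipulation while editing is ignored, as
    gesture control is halted during annotation.
    """
    config = config or ViewerConfig()
    if pattern is None:
        pattern = config.pattern_array()
    viewport = ViewportState(identity(), config.screen_width, config.screen_height)
    session = AnnotationSession()
    stats = CacheStats()
    log: list[LoadEvent] = []

    grid = make_grid(viewport, pyramid, rows=config.grid_rows, cols=config.grid_cols,
                     cell_px=config.cell_px, pattern=pattern)
    d = fill_grid(grid, pyramid, config.screen_width, config.screen_height)
    stats += d
    log.append(LoadEvent(step=-1, phase="fill", stats=d))

    coverage_ok = screen_fully_loaded(grid, viewport)

    for i, step in enumerate(trace):
        if isinstance(step, ManipulationEvent):
            if session.is_editing:
                continue  # gesture control is halted while annotating
            viewport = apply_event(viewport, step)
            grid, d = maybe_reanchor(grid, pyramid, viewport)
            if d.grid_reloads:
                stats += d
                log.append(LoadEvent(step=i, phase="reload", stats=d))
            d = promote_visible(grid, pyramid, viewport)
            if d.promotions:
                stats += d
                log.append(LoadEvent(step=i, phase="promote", stats=d))
            coverage_ok = coverage_ok and screen_fully_loaded(grid, viewport)
        elif isinstance(step, AnnotationDirective):
            try:
                if step.op == "begin_annotation":
                    session.begin_annotation(step.shape, at=step.at)
                elif step.op == "edit_annotation":
                    session.edit_annotation(viewport, move=step.move, resize=step.resize)
                else:
                    session.commit_annotation(step.label)
            except AnnotationStateError as e:
                raise TraceError(str(e), line=i + 1) from e
        else:
            raise TraceError(f"unsupported trace step {type(step).__name__}", line=i + 1)

    return SessionResult(stats=stats, viewport=viewport,
                         annotations=session.store, grid=grid, log=log,
                         coverage_ok=coverage_ok)


@dataclass
class StrategyReport:
    """Smart-vs-naive pixel totals for one trace."""

    smart_pixels: int
    naive_pixels: int
    smart_stats: CacheStats
    naive_stats: CacheStats

    @property
    def reduction_fraction(self) -> float:
        if self.naive_pixels == 0:
            return 0.0
        return 1.0 - self.smart_pixels / self.naive_pixels

    @property
    def reduction_percent(self) -> float:
        return 100.0 * self.reduction_fraction

    def as_dict(self) -> dict:
        return {
            "smart_pixels": self.smart_pixels,
            "naive_pixels": self.naive_pixels,
            "reduction_percent": round(self.reduction_percent, 2),
            "smart": self.smart_stats.as_dict(),
            "naive": self.naive_stats.as_dict(),
        }


def compare_strategies(pyramid: TilePyramid, trace,
                       config: ViewerConfig | None = None) -> StrategyReport:
    """Replay the trace under the graded pattern and under
    all-full-resolution loading; report total pixels and the reduction."""
    config = config or ViewerConfig()
    smart = run_session(pyramid, trace, config, pattern=config.pattern_array())
    naive = run_session(pyramid, trace, config,
                        pattern=naive_pattern(config.grid_rows, config.grid_cols))
    return StrategyReport(smart_pixels=smart.stats.pixels_loaded,
                          naive_pixels=naive.stats.pixels_loaded,
                          smart_stats=smart.stats, naive_stats=naive.stats)


def random_trace(n_events: int, seed: int, screen_width: int = 1024,
                 screen_height: int = 768, max_pan_fraction: float = 0.5,
                 zoom_probability: float = 0.25) -> list[ManipulationEvent]:
    """A seeded random navigation trace for simulation studies.

    Pans are uniform within +/- ``max_pan_fraction`` of the screen in
    each axis; with probability ``zoom_probability`` an event is instead
    a zoom by a factor in [0.8, 1.25] about a random on-screen focal
    point.  Deterministic in the seed.
    """
    rng = np.random.default_rng(seed)
    events = []
    for _ in range(n_events):
        if rng.random() < zoom_probability:
            events.append(ManipulationEvent(
                kind="zoom", scale=float(np.exp(rng.uniform(np.log(0.8), np.log(1.25)))),
                focal_x=float(rng.uniform(0, screen_width)),
                focal_y=float(rng.uniform(0, screen_height))))
        else:
            events.append(ManipulationEvent(
                kind="pan",
                dx=float(rng.uniform(-max_pan_fraction, max_pan_fraction) * screen_width),
                dy=float(rng.uniform(-max_pan_fraction, max_pan_fraction) * screen_height)))
    return events
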