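"""Validated viewer configuration.

Defaults are the reference setup this engine models: 256 px tiles and
cache cells, a 9x12 cache grid around a 1024x768 screen, stored pyramid
magnifications {40, 10, 1}, and the default graded resolution pattern.
Other screen sizes and grid shapes are expressible by overriding fields.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .smart_cache import DEFAULT_CELL_PX, DEFAULT_COLS, DEFAULT_ROWS, default_pattern


class ViewerConfig(BaseModel):
    """All tunable engine parameters with their standard defaults."""

    tile_size: int = Field(default=256, ge=16)
    grid_rows: int = Field(default=DEFAULT_ROWS, ge=1)
    grid_cols: int = Field(default=DEFAULT_COLS, ge=1)
    cell_px: int = Field(default=DEFAULT_CELL_PX, ge=16)
    screen_width: int = Field(default=1024, ge=1)
    screen_height: int = Field(default=768, ge=1)
    magnifications: list[float] = Field(default_factory=lambda: [40.0, 10.0, 1.0])
    #: Per-cell fraction of full-resolution data, grid_rows x grid_cols,
    #: values in (0, 1].  None selects the default graded pattern when the
    #: grid is the default 9x12, or all-full-resolution otherwise.
    resolution_pattern: list[list[float]] | None = None
    seed: int = 0

    @field_validator("magnifications")
    @classmethod
    def _mags_positive_decreasing(cls, v):
        if not v:
            raise ValueError("at least one magnification is required")
        if any(m <= 0 for m in v):
            raise ValueError("magnifications must be positive")
        if sorted(set(v), reverse=True) != list(v):
            raise ValueError("magnifications must be strictly decreasing and unique")
        return v

    @model_validator(mode="after")
    def _pattern_matches_grid(self):
        if self.resolution_pattern is not None:
            arr = np.asarray(self.resolution_pattern, dtype=float)
            if arr.shape != (self.grid_rows, self.grid_cols):
                raise ValueError(
                    f"resolution_pattern shape {arr.shape} does not match "
                    f"grid {self.grid_rows}x{self.grid_cols}")
            if np.any(arr <= 0) or np.any(arr > 1):
                raise ValueError("resolution_pattern values must lie in (0, 1]")
        return self

    def pattern_array(self) -> np.ndarray:
        if self.resolution_pattern is not None:
            return np.asarray(self.resolution_pattern, dtype=float)
        if (self.grid_rows, self.grid_cols) == (DEFAULT_ROWS, DEFAULT_COLS):
            return default_pattern()
        return np.ones((self.grid_rows, self.grid_cols), dtype=float)


def load_config(path) -> ViewerConfig:
    """Read a JSON config file; pydantic reports the offending field."""
    return ViewerConfig.model_validate(json.loads(Path(path).read_text()))
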