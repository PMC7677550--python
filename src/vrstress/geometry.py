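"""Scene geometry for the two exploration scenes.

The empty room is a 3.5 m x 6.0 m rectangle (the physical testing-room
footprint).  The elevated alley reuses the same footprint but is divided
longitudinally into successively narrower patches, with a starting board at
the near end.  All coordinates are metric, origin at the starting-board
corner, ``x`` lateral in ``[0, room_width]`` and ``y`` longitudinal in
``[0, room_length]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

__all__ = ["SceneGeometry", "DEFAULT_GEOMETRY"]


@dataclass(frozen=True)
class SceneGeometry:
    """Dimensions and derived zones of the virtual scenes."""

    room_width: float = 3.5
    room_length: float = 6.0
    #: linear scale of the centered inner rectangle counted as "center"
    center_fraction: float = 0.5
    #: alley patch widths, wide (start) to narrow (far end), metres
    patch_widths: tuple[float, ...] = (3.5, 2.5, 1.5, 0.5)
    #: longitudinal extent of each alley patch, metres
    patch_length: float = 1.5
    #: longitudinal extent of the starting board, metres
    board_length: float = 1.0

    def __post_init__(self) -> None:
        if self.room_width <= 0 or self.room_length <= 0:
            raise InvalidArgumentError("room dimensions must be positive")
        if not 0 < self.center_fraction < 1:
            raise InvalidArgumentError("center_fraction must be in (0, 1)")
        widths = np.asarray(self.patch_widths, dtype=float)
        if np.any(np.diff(widths) >= 0):
            raise InvalidArgumentError("patch widths must be strictly decreasing")
        if widths[0] > self.room_width + 1e-9:
            raise InvalidArgumentError("widest patch exceeds room width")
        if len(widths) * self.patch_length > self.room_length + 1e-9:
            raise InvalidArgumentError("alley patches do not fit in the room")

    # ------------------------------------------------------------------ room
    @property
    def corners(self) -> np.ndarray:
        """Four room corners, shape (4, 2)."""
        w, l = self.room_width, self.room_length
        return np.array([[0.0, 0.0], [w, 0.0], [0.0, l], [w, l]])

    @property
    def center_zone(self) -> tuple[float, float, float, float]:
        """Centered inner rectangle as (x0, y0, x1, y1)."""
        cw = self.room_width * self.center_fraction
        cl = self.room_length * self.center_fraction
        x0 = (self.room_width - cw) / 2.0
        y0 = (self.room_length - cl) / 2.0
        return (x0, y0, x0 + cw, y0 + cl)

    @property
    def center_area_fraction(self) -> float:
        return self.center_fraction**2

    def contains(self, x, y, tol: float = 1e-6) -> np.ndarray:
        x = np.asarray(x)
        y = np.asarray(y)
        return (
            (x >= -tol)
            & (x <= self.room_width + tol)
            & (y >= -tol)
            & (y <= self.room_length + tol)
        )

    def in_center(self, x, y) -> np.ndarray:
        x0, y0, x1, y1 = self.center_zone
        x = np.asarray(x)
        y = np.asarray(y)
        return (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)

    def wall_distance(self, x, y) -> np.ndarray:
        """Distance to the nearest wall (0 on a wall)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return np.minimum.reduce(
            [x, self.room_width - x, y, self.room_length - y]
        )

    def corner_distance(self, x, y) -> np.ndarray:
        """Distance to the nearest room corner."""
        x = np.asarray(x, dtype=float)[..., None]
        y = np.asarray(y, dtype=float)[..., None]
        c = self.corners
        d = np.sqrt((x - c[:, 0]) ** 2 + (y - c[:, 1]) ** 2)
        return d.min(axis=-1)

    # ----------------------------------------------------------------- alley
    @property
    def patch_edges(self) -> np.ndarray:
        """Longitudinal boundaries of the alley patches, length n_patches+1."""
        n = len(self.patch_widths)
        return np.arange(n + 1, dtype=float) * self.patch_length

    @property
    def alley_end(self) -> float:
        return float(self.patch_edges[-1])

    def patch_index(self, y) -> np.ndarray:
        """Index of the patch containing longitudinal position y (clipped)."""
        y = np.asarray(y, dtype=float)
        idx = np.floor(y / self.patch_length).astype(int)
        return np.clip(idx, 0, len(self.patch_widths) - 1)

    def alley_half_width(self, y) -> np.ndarray:
        """Half-width of the alley at longitudinal position y."""
        widths = np.asarray(self.patch_widths, dtype=float)
        return widths[self.patch_index(y)] / 2.0


DEFAULT_GEOMETRY = SceneGeometry()
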