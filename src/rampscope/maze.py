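"""L-maze geometry with a triangular ramp.

The arena is an L-shaped track: a long horizontal arm carrying an isosceles
triangular ramp, joined at a corner to a shorter vertical arm.  Food wells sit
at the two arm ends, so a mouse shuttles back and forth crossing the ramp on
every trial.  All analysis happens on the *linearized path coordinate*: the
distance walked along the track, with the ramp base replaced by its two slope
surfaces (the mouse walks the hypotenuses, not the base).

Path frame convention
---------------------
``path = 0`` at the outer end of the horizontal arm, increasing over the ramp
and the corner to ``total_path_length`` at the outer end of the vertical arm.
"Right" trials run toward the horizontal-arm end (path decreasing), "left"
trials toward the vertical-arm end (path increasing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["MazeModel", "ramp_height"]


def ramp_height(base_length: float, angle_deg: float) -> float:
    """Peak height of an isosceles triangular ramp.

    Parameters
    ----------
    base_length : float
        Length of the ramp base in cm.
    angle_deg : float
        Base angle of the triangle in degrees; must satisfy ``0 <= angle < 90``.

    Returns
    -------
    float
        Height of the apex above the floor, ``(base_length / 2) * tan(angle)``.
    """
    if base_length <= 0:
        raise ValueError(f"base_length must be positive, got {base_length}")
    if not 0 <= angle_deg < 90:
        raise ValueError(f"angle must be in [0, 90) degrees, got {angle_deg}")
    return (base_length / 2.0) * math.tan(math.radians(angle_deg))


@dataclass(frozen=True)
class MazeModel:
    """Geometry of the L maze and its ramp.

    Defaults follow the standard configuration: 80-cm horizontal arm, 40-cm
    vertical arm, 48-cm ramp base at a 45° base angle (24-cm apex), with the
    ramp centered in the horizontal arm.  15° and 30° base angles are the
    shallow-incline variants.
    """

    horizontal_arm_length: float = 80.0
    vertical_arm_length: float = 40.0
    ramp_base_length: float = 48.0
    ramp_base_angle: float = 45.0
    ramp_base_offset: float = 16.0  # cm from horizontal-arm outer end to ramp base

    def __post_init__(self) -> None:
        for name in ("horizontal_arm_length", "vertical_arm_length", "ramp_base_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.ramp_base_angle < 90:
            raise ValueError(
                f"ramp_base_angle must be in (0, 90) degrees, got {self.ramp_base_angle}"
            )
        if self.ramp_base_offset < 0:
            raise ValueError("ramp_base_offset must be non-negative")
        if self.ramp_base_offset + self.ramp_base_length > self.horizontal_arm_length:
            raise ValueError("ramp does not fit within the horizontal arm")

    # -- derived geometry ---------------------------------------------------

    @property
    def half_base(self) -> float:
        return self.ramp_base_length / 2.0

    @property
    def peak_height(self) -> float:
        """Apex height above the floor, cm."""
        return ramp_height(self.ramp_base_length, self.ramp_base_angle)

    @property
    def slope_side_length(self) -> float:
        """Walked length of one slope surface (hypotenuse), cm."""
        return self.half_base / math.cos(math.radians(self.ramp_base_angle))

    @property
    def horizontal_path_length(self) -> float:
        """Walked path along the horizontal arm: base replaced by the slopes."""
        return (
            self.horizontal_arm_length
            - self.ramp_base_length
            + 2.0 * self.slope_side_length
        )

    @property
    def total_path_length(self) -> float:
        return self.horizontal_path_length + self.vertical_arm_length

    # Path coordinates of ramp landmarks (path 0 = horizontal-arm outer end).

    @property
    def ramp_path_start(self) -> float:
        """Path coordinate where the ramp surface begins (horizontal-end side)."""
        return self.ramp_base_offset

    @property
    def apex_path(self) -> float:
        return self.ramp_base_offset + self.slope_side_length

    @property
    def ramp_path_end(self) -> float:
        """Path coordinate where the ramp surface ends (corner side)."""
        return self.ramp_base_offset + 2.0 * self.slope_side_length

    # -- coordinate mapping -------------------------------------------------

    def path_to_xy(self, path: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map linearized path coordinates to top-view (x, y) in cm.

        x runs along the horizontal arm (0 at the outer end, increasing toward
        the corner); y runs along the vertical arm.  On the slopes the
        top-view x advances by ``cos(angle)`` per cm walked.
        """
        path = np.asarray(path, dtype=float)
        if np.any(path < -1e-9) or np.any(path > self.total_path_length + 1e-9):
            raise ValueError("path coordinate outside the maze")
        cos_a = math.cos(math.radians(self.ramp_base_angle))
        off, ss = self.ramp_base_offset, self.slope_side_length
        hp = self.horizontal_path_length

        x = np.empty_like(path)
        y = np.zeros_like(path)

        seg0 = path < off
        x[seg0] = path[seg0]
        seg1 = (path >= off) & (path < off + ss)
        x[seg1] = off + (path[seg1] - off) * cos_a
        seg2 = (path >= off + ss) & (path < off + 2 * ss)
        x[seg2] = off + self.half_base + (path[seg2] - off - ss) * cos_a
        seg3 = (path >= off + 2 * ss) & (path < hp)
        x[seg3] = path[seg3] - 2 * ss + self.ramp_base_length
        seg4 = path >= hp
        x[seg4] = self.horizontal_arm_length
        y[seg4] = np.minimum(path[seg4] - hp, self.vertical_arm_length)
        return x, y

    def path_to_elevation(self, path: np.ndarray) -> np.ndarray:
        """Height above the floor at each path coordinate, cm."""
        path = np.asarray(path, dtype=float)
        sin_a = math.sin(math.radians(self.ramp_base_angle))
        off, ss = self.ramp_base_offset, self.slope_side_length
        z = np.zeros_like(path)
        up = (path >= off) & (path < off + ss)
        z[up] = (path[up] - off) * sin_a
        down = (path >= off + ss) & (path < off + 2 * ss)
        z[down] = (2 * ss - (path[down] - off)) * sin_a
        return z

    def arm_of_path(self, path: np.ndarray) -> np.ndarray:
        """Label each path coordinate 'horizontal' or 'vertical'."""
        path = np.asarray(path, dtype=float)
        return np.where(path < self.horizontal_path_length, "horizontal", "vertical")

    def on_ramp(self, path: np.ndarray) -> np.ndarray:
        path = np.asarray(path, dtype=float)
        return (path >= self.ramp_path_start) & (path < self.ramp_path_end)
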