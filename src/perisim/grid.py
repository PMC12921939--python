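"""The 10-2 test-location pattern and eye-laterality conventions.

The 10-2 pattern tests the central 10 degrees of the visual field at 68
locations on a 2-degree lattice offset 1 degree from the horizontal and
vertical meridians.  Coordinates are visual-field coordinates in degrees:
positive x to the right of the printout, positive y up.  Left/right eye
(OS/OD) affects only where the physiological blind spot is drawn — it lies
outside the tested field and serves as a laterality mark on plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TestGrid", "generate_10_2", "blind_spot_position"]

# Odd-lattice eccentricity bound that yields exactly the 68 locations of
# the 10-2 pattern: x, y in {+-1, ..., +-9} with x^2 + y^2 <= 82.
_ECC2_MAX = 82


@dataclass(frozen=True)
class TestGrid:
    """An ordered set of visual-field test locations for one eye."""

    xy: np.ndarray  # (n, 2) int degrees
    eye: str = "OD"
    pattern_name: str = "10-2"

    def __post_init__(self) -> None:
        if self.eye not in ("OD", "OS"):
            raise ValueError(f"eye must be 'OD' or 'OS', got {self.eye!r}")
        object.__setattr__(self, "xy", np.asarray(self.xy, dtype=int))

    def __len__(self) -> int:
        return len(self.xy)

    @property
    def x(self) -> np.ndarray:
        return self.xy[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xy[:, 1]

    @property
    def eccentricity(self) -> np.ndarray:
        """Radial distance of each location from fixation, in degrees."""
        return np.hypot(self.xy[:, 0], self.xy[:, 1]).astype(float)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"x_deg": self.x, "y_deg": self.y}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, eye: str = "OD",
                 pattern_name: str = "custom") -> "TestGrid":
        df = pd.read_csv(path)
        return cls(df[["x_deg", "y_deg"]].to_numpy(), eye=eye,
                   pattern_name=pattern_name)


def generate_10_2(eye: str = "OD") -> TestGrid:
    """Generate the 68-location 10-2 grid in deterministic order.

    Locations are all odd-integer lattice points with ``x^2 + y^2 <= 82``,
    ordered row-major from superior to inferior (y descending), left to
    right (x ascending).
    """
    coords = [
        (x, y)
        for y in range(9, -10, -2)
        for x in range(-9, 10, 2)
        if x * x + y * y <= _ECC2_MAX
    ]
    return TestGrid(np.array(coords, dtype=int), eye=eye, pattern_name="10-2")


def blind_spot_position(eye: str) -> tuple[float, float]:
    """Plotting position of the physiological blind spot for an eye.

    (+15, -2) degrees for right eyes (OD), (-15, -2) for left (OS) — outside
    the 10-degree tested field; its side identifies the eye on printouts.
    """
    if eye == "OD":
        return (15.0, -2.0)
    if eye == "OS":
        return (-15.0, -2.0)
    raise ValueError(f"eye must be 'OD' or 'OS', got {eye!r}")
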