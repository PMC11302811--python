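"""Panel geometry and the pixel <-> isocenter-plane coordinate mapping.

The amorphous-silicon portal imager sits at the source-to-detector distance
(SDD, 160 cm) while all leaf positions and field dimensions are quoted in the
isocenter plane at the source-to-axis distance (SAD, 100 cm).  The panel
magnification SDD/SAD therefore maps the 0.4 mm physical pixel pitch to
0.25 mm in the isocenter plane, and a 1024 x 1024 panel images up to
26 x 26 cm^2 at the isocenter.

Conventions: continuous isocenter-plane millimetres, origin on the beam axis;
the leaf-motion axis is the image x axis (columns), leaf pairs stack along y
(rows); 0-based pixel indices with pixel centers at integer indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GeometryModel", "pixel_to_iso", "iso_to_pixel"]


@dataclass
class GeometryModel:
    """Imaging geometry of the portal imager.

    Parameters
    ----------
    sdd, sad : float
        Source-to-detector and source-to-axis distances in cm.
    pixel_pitch_panel : float
        Physical pixel pitch of the panel in mm.
    rows, cols : int
        Panel dimensions in pixels.
    origin_row, origin_col : float
        Beam-axis pixel index (may be fractional).  Defaults to the panel
        center.  The beam-axis location is not discoverable from the image
        alone, so it must be carried in configuration; the simulator writes
        it into the image metadata.
    """

    sdd: float = 160.0
    sad: float = 100.0
    pixel_pitch_panel: float = 0.4
    rows: int = 1024
    cols: int = 1024
    origin_row: float | None = field(default=None)
    origin_col: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.sdd <= self.sad or self.sad <= 0:
            raise ValueError("require sdd > sad > 0")
        if self.pixel_pitch_panel <= 0:
            raise ValueError("pixel_pitch_panel must be positive")
        if self.rows < 1 or self.cols < 1:
            raise ValueError("panel must have at least one pixel")
        if self.origin_row is None:
            self.origin_row = (self.rows - 1) / 2.0
        if self.origin_col is None:
            self.origin_col = (self.cols - 1) / 2.0

    @property
    def magnification(self) -> float:
        return self.sdd / self.sad

    @property
    def pixel_pitch_iso(self) -> float:
        """Pixel pitch projected to the isocenter plane, mm."""
        return self.pixel_pitch_panel / self.magnification

    # -- axis mappings (vectorised) -------------------------------------
    def x_of_col(self, col):
        return (np.asarray(col, dtype=float) - self.origin_col) * self.pixel_pitch_iso

    def y_of_row(self, row):
        return (np.asarray(row, dtype=float) - self.origin_row) * self.pixel_pitch_iso

    def col_of_x(self, x):
        return np.asarray(x, dtype=float) / self.pixel_pitch_iso + self.origin_col

    def row_of_y(self, y):
        return np.asarray(y, dtype=float) / self.pixel_pitch_iso + self.origin_row


def pixel_to_iso(index, geometry: GeometryModel):
    """Map a pixel index (row, col) to isocenter-plane (y, x) in mm."""
    row, col = index
    return geometry.y_of_row(row), geometry.x_of_col(col)


def iso_to_pixel(position, geometry: GeometryModel):
    """Inverse of :func:`pixel_to_iso`; returns fractional (row, col)."""
    y, x = position
    return geometry.row_of_y(y), geometry.col_of_x(x)
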