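"""Acquisition geometry of the motorized slide scanner.

A fixed volume of microspore concentrate is mounted under a square coverslip,
forming a shallow water chamber that keeps every cell in one focal plane.
The scanner acquires square tiles whose physical extent fixes the pixel
pitch used to convert pixel measurements to micrometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Mounting-chamber and tiling geometry of a scan.

    Parameters
    ----------
    coverslip_side : float
        Side of the square coverslip, mm.
    drop_volume : float
        Mounted sample volume, µL (1 µL = 1 mm³).
    tile_px : int
        Side of an acquired square tile, px.
    tile_area : float
        Physical area covered by one tile, mm².
    """

    coverslip_side: float = 11.0
    drop_volume: float = 20.0
    tile_px: int = 512
    tile_area: float = 0.26

    def __post_init__(self):
        if min(self.coverslip_side, self.drop_volume, self.tile_area) <= 0:
            raise ValueError("geometry dimensions must be positive")
        if self.tile_px < 8:
            raise ValueError("tile_px too small")

    @property
    def chamber_height(self) -> float:
        """Water-column height under the coverslip, mm (volume / area)."""
        return self.drop_volume / self.coverslip_side**2

    @property
    def pixel_pitch(self) -> float:
        """Physical size of one pixel, µm/px."""
        return 1000.0 * math.sqrt(self.tile_area) / self.tile_px


DEFAULT_GEOMETRY = AcquisitionGeometry()
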