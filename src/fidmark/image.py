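"""2D image container with physical spacing and value-unit tag."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import DataError, DomainError

__all__ = ["Image2D"]


@dataclass
class Image2D:
    """A 2D pixel array with metric pixel spacing.

    ``pixels`` is indexed ``[iy, ix]``; ``spacing`` is (dy, dx) in mm/pixel;
    ``origin`` is the physical (y, x) position [mm] of the *center* of pixel
    (0, 0). ``units`` tags the value scale (``"HU"`` or ``"detector_signal"``).
    ``provenance`` carries the generating protocol and seed.
    """

    pixels: np.ndarray
    spacing: tuple[float, float]
    units: str = "detector_signal"
    origin: tuple[float, float] = (0.0, 0.0)
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise DataError("Image2D requires a 2D array")
        if np.isscalar(self.spacing):
            self.spacing = (float(self.spacing), float(self.spacing))
        else:
            self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise DomainError("pixel spacing must be positive")
        if not np.all(np.isfinite(self.pixels)):
            raise DataError("Image2D pixels must be finite")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def extent_mm(self) -> tuple[float, float]:
        """Physical (height, width) spanned by pixel centers plus one pixel."""
        return tuple(n * s for n, s in zip(self.pixels.shape, self.spacing))

    def phys_to_index(self, y_mm: float, x_mm: float) -> tuple[float, float]:
        """Fractional (row, col) index of a physical (y, x) point."""
        return (
            (y_mm - self.origin[0]) / self.spacing[0],
            (x_mm - self.origin[1]) / self.spacing[1],
        )

    def index_to_phys(self, iy, ix) -> tuple[np.ndarray, np.ndarray]:
        return (
            self.origin[0] + np.asarray(iy) * self.spacing[0],
            self.origin[1] + np.asarray(ix) * self.spacing[1],
        )

    def contains_point(self, y_mm: float, x_mm: float) -> bool:
        r, c = self.phys_to_index(y_mm, x_mm)
        ny, nx = self.pixels.shape
        return 0 <= r <= ny - 1 and 0 <= c <= nx - 1

    def interp(self, y_mm, x_mm) -> np.ndarray:
        """Bilinear interpolation at physical points (arrays broadcast)."""
        from scipy import ndimage

        r = (np.asarray(y_mm, dtype=float) - self.origin[0]) / self.spacing[0]
        c = (np.asarray(x_mm, dtype=float) - self.origin[1]) / self.spacing[1]
        return ndimage.map_coordinates(self.pixels, [r, c], order=1, mode="nearest")
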