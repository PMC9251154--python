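"""Shared containers and coordinate conventions.

Pixel convention used throughout the package: 0-based ``(row, col)``
indices addressing pixel centers.  A circle center ``(a, b)`` therefore
means row ``a``, column ``b``; a point on its circumference at angle 0
along the column axis is ``(a, b + r)``.  Physical coordinates are
obtained by multiplying indices with per-axis spacing in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class ImageSlice:
    """A single 2-D intensity grid with in-plane spacing.

    Parameters
    ----------
    data : ndarray, shape (H, W)
        Intensity values (float).
    spacing_mm : tuple of float
        Physical size of one pixel along (row, col), in mm.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError(f"slice data must be 2-D, got {self.data.ndim}-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class ImageVolume:
    """A stack of slices: ``data[k]`` is slice ``k``.

    ``spacing_mm`` is (slice, row, col) in mm.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError(f"volume data must be 3-D, got {self.data.ndim}-D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def slice(self, k: int) -> ImageSlice:
        return ImageSlice(self.data[k], spacing_mm=self.spacing_mm[1:])


def as_array(image) -> np.ndarray:
    """Coerce an ImageSlice/ImageVolume or array-like to a float ndarray."""
    if isinstance(image, (ImageSlice, ImageVolume)):
        return image.data
    return np.asarray(image, dtype=float)
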