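"""The 2-D grayscale image container shared by all modules.

Images travel through the pipeline as float64 arrays on the [0, 1] intensity
scale; ``peak`` records the dynamic range the image is meant to be displayed
and evaluated at (255 for 8-bit material).  Quality metrics are computed on
the 0..peak scale, so ``scaled()`` is the bridge between the internal
representation and the metric conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import StructuralError

__all__ = ["ImageGrid", "aspixels", "to_uint8"]


@dataclass
class ImageGrid:
    pixels: np.ndarray
    peak: float = 1.0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise StructuralError("ImageGrid requires a 2-D array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def scaled(self, peak: float = 255.0) -> np.ndarray:
        """Pixels rescaled from [0, self.peak] to [0, peak]."""
        return self.pixels * (peak / self.peak)


def aspixels(image) -> np.ndarray:
    """Accept an ImageGrid or a bare 2-D array and return the array."""
    if isinstance(image, ImageGrid):
        return image.pixels
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise StructuralError("expected a 2-D image")
    return arr


def to_uint8(pixels: np.ndarray) -> np.ndarray:
    """[0,1] floats to 8-bit, rounding half away from zero."""
    x = np.clip(np.asarray(pixels, dtype=np.float64), 0.0, 1.0) * 255.0
    return np.floor(x + 0.5).astype(np.uint8)
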