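"""Reading and writing 8-bit grayscale images (PNG/PGM, optional DICOM)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

from .errors import FormatError
from .image import ImageGrid, to_uint8

__all__ = ["read_image", "write_image"]


def read_image(path) -> ImageGrid:
    """Load a grayscale image as [0,1] floats with peak 255.

    PNG/PGM go through Pillow (converted to 8-bit luminance); ``.dcm``
    files are read with pydicom, single frame, pixel data only, rescaled by
    the frame's maximum stored value.
    """
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        import pydicom

        ds = pydicom.dcmread(path)
        arr = np.asarray(ds.pixel_array, dtype=np.float64)
        if arr.ndim == 3:  # multi-frame: take the first
            arr = arr[0]
        peak = arr.max() if arr.max() > 0 else 1.0
        return ImageGrid(arr / peak, peak=1.0)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("L"), dtype=np.float64)
    except OSError as exc:
        raise FormatError(f"cannot read image {path}: {exc}") from None
    return ImageGrid(arr / 255.0, peak=1.0)


def write_image(path, image) -> None:
    """Write [0,1] pixels as 8-bit PNG or PGM (by extension), rounding half
    away from zero."""
    path = Path(path)
    px = image.pixels if isinstance(image, ImageGrid) else np.asarray(image)
    data = to_uint8(px)
    Image.fromarray(data, mode="L").save(path)
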