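"""Multi-level 2-D discrete wavelet analysis / synthesis.

A level-1 decomposition splits an image I into four subbands
{LL, LH, HL, HH}: the low-pass approximation plus three oriented detail
bands.  Orientation convention (fixed and relied on by the bitstream
format):

* ``LH`` — high-pass across rows (responds to horizontal edges; for Haar,
  the difference between row pairs),
* ``HL`` — high-pass across columns (vertical edges; column differences),
* ``HH`` — diagonal detail.

Level 1 is the finest scale; deeper levels re-decompose the approximation,
and only the coarsest level keeps its LL grid.  The default boundary mode
is ``periodization``: for orthonormal wavelets it makes the transform an
exact orthogonal map, so subband shapes are ⌈m/2^k⌉×⌈n/2^k⌉, total
coefficient energy equals image energy, and reconstruction is exact to
float64 round-off.  Other pywt modes (e.g. ``symmetric``) are accepted but
forfeit the exact-energy property.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .errors import DimensionError, StructuralError
from .image import ImageGrid, aspixels

__all__ = ["SubbandSet", "dwt2", "idwt2"]

DEFAULT_WAVELET = "haar"
DEFAULT_MODE = "periodization"


@dataclass
class SubbandSet:
    """Per-level subband grids. ``levels[0]`` is level 1 (finest); each dict
    has keys LH/HL/HH, and the last (coarsest) dict additionally LL."""

    levels: list[dict[str, np.ndarray]]
    wavelet_name: str = DEFAULT_WAVELET
    boundary_mode: str = DEFAULT_MODE
    original_shape: tuple[int, int] = (0, 0)

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def band(self, level: int, name: str) -> np.ndarray:
        """1-based level index, name in {LL, LH, HL, HH}."""
        return self.levels[level - 1][name]

    def energy(self) -> float:
        return float(sum(np.sum(g**2) for lv in self.levels for g in lv.values()))

    def validate(self) -> None:
        if not self.levels:
            raise StructuralError("empty SubbandSet")
        for k, lv in enumerate(self.levels, start=1):
            expected = {"LH", "HL", "HH"} | ({"LL"} if k == self.n_levels else set())
            if set(lv) != expected:
                raise StructuralError(f"level {k} has bands {sorted(lv)}")
            shapes = {g.shape for g in lv.values()}
            if len(shapes) != 1:
                raise StructuralError(f"level {k} bands have unequal shapes")


def dwt2(image, wavelet_name: str = DEFAULT_WAVELET, levels: int = 1,
         boundary_mode: str = DEFAULT_MODE) -> SubbandSet:
    """Decompose a 2-D image into a multi-level subband pyramid."""
    pixels = aspixels(image)
    if levels < 1:
        raise DimensionError("levels must be >= 1")
    m, n = pixels.shape
    if m < 2**levels or n < 2**levels:
        raise DimensionError(
            f"image {m}x{n} too small for {levels} decomposition level(s)"
        )
    coeffs = pywt.wavedec2(pixels, wavelet_name, mode=boundary_mode, level=levels)
    # pywt orders coarsest-first: [cA_L, (cH_L, cV_L, cD_L), ..., level 1]
    out: list[dict[str, np.ndarray]] = []
    for k, (ch, cv, cd) in enumerate(reversed(coeffs[1:]), start=1):
        out.append({"LH": np.asarray(ch), "HL": np.asarray(cv),
                    "HH": np.asarray(cd)})
    out[-1]["LL"] = np.asarray(coeffs[0])
    return SubbandSet(out, wavelet_name, boundary_mode, (m, n))


def idwt2(subbands: SubbandSet) -> ImageGrid:
    """Invert :func:`dwt2`; exact to numerical tolerance."""
    subbands.validate()
    coeffs = [subbands.levels[-1]["LL"]]
    for lv in reversed(subbands.levels):
        coeffs.append((lv["LH"], lv["HL"], lv["HH"]))
    try:
        rec = pywt.waverec2(coeffs, subbands.wavelet_name,
                            mode=subbands.boundary_mode)
    except ValueError as exc:
        raise StructuralError(f"inconsistent subband shapes: {exc}") from None
    m, n = subbands.original_shape
    if m and n:
        if rec.shape[0] < m or rec.shape[1] < n:
            raise StructuralError("reconstruction smaller than original_shape")
        rec = rec[:m, :n]
    return ImageGrid(rec, peak=1.0)
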