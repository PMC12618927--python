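"""Image quality metrics (MSE, PSNR, SSIM, NCC) and report aggregation.

All metrics operate on the 0..255 intensity scale: PSNR's peak is
hard-wired to 255 for 8-bit material and SSIM's stabilization constants
C1=(0.01*255)^2, C2=(0.03*255)^2 assume the same range, so internal [0,1]
images must be scaled (``ImageGrid.scaled()``) before evaluation.

SSIM uses the community-standard 11x11 Gaussian window (sigma 1.5) with
weighted (population-style) local moments, averaged over all positions
where the window fits entirely inside the image.

NCC here is the *uncentered* cosine similarity between the two pixel
vectors; it equals the Pearson correlation only when both images have zero
mean, and is scale-invariant (NCC(x, c*x) = 1 for c > 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
from scipy.ndimage import correlate

from .errors import DimensionError, StructuralError, UsageError, ZeroVarianceError
from .image import aspixels

__all__ = [
    "SSIMParams",
    "MetricRecord",
    "mse",
    "psnr",
    "ssim",
    "ncc",
    "aggregate",
]


@dataclass(frozen=True)
class SSIMParams:
    K1: float = 0.01
    K2: float = 0.03
    L: float = 255.0
    window_size: int = 11
    sigma: float = 1.5

    @property
    def C1(self) -> float:
        return (self.K1 * self.L) ** 2

    @property
    def C2(self) -> float:
        return (self.K2 * self.L) ** 2


@dataclass
class MetricRecord:
    """One evaluated image (or the aggregate row): the per-image columns of
    a rate-distortion report."""

    image_id: str = ""
    mse: float = math.nan
    psnr_db: float = math.nan
    ssim: float = math.nan
    ncc: float = math.nan
    bpp: float = math.nan
    time_ms: float = math.nan

    NUMERIC = ("mse", "psnr_db", "ssim", "ncc", "bpp", "time_ms")


def _pair(x, y):
    xa, ya = aspixels(x), aspixels(y)
    if xa.shape != ya.shape:
        raise StructuralError(f"shape mismatch {xa.shape} vs {ya.shape}")
    return xa, ya


def mse(x, y) -> float:
    """Mean squared pixel deviation (1/mn) * sum (I - Ihat)^2."""
    xa, ya = _pair(x, y)
    return float(np.mean((xa - ya) ** 2))


def psnr(x, y, peak: float = 255.0) -> float:
    """20*log10(peak / sqrt(MSE)) in dB; +inf for identical images."""
    e = mse(x, y)
    if e == 0.0:
        return math.inf
    return float(20.0 * np.log10(peak / np.sqrt(e)))


def _gaussian_window(size: int, sigma: float) -> np.ndarray:
    r = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(r**2) / (2 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def ssim(x, y, params: SSIMParams = SSIMParams()) -> float:
    """Mean structural similarity index over all fully-interior windows."""
    xa, ya = _pair(x, y)
    win = params.window_size
    if min(xa.shape) < win:
        raise DimensionError(f"image smaller than the {win}x{win} SSIM window")
    k = _gaussian_window(win, params.sigma)
    half = win // 2

    def filt(img):
        return correlate(img, k, mode="constant")[half:-half, half:-half]

    mu_x, mu_y = filt(xa), filt(ya)
    exx, eyy, exy = filt(xa * xa), filt(ya * ya), filt(xa * ya)
    var_x = exx - mu_x**2
    var_y = eyy - mu_y**2
    cov = exy - mu_x * mu_y
    c1, c2 = params.C1, params.C2
    s = ((2 * mu_x * mu_y + c1) * (2 * cov + c2)) / (
        (mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2)
    )
    return float(s.mean())


def ncc(x, y) -> float:
    """Uncentered normalized cross-correlation (cosine similarity)."""
    xa, ya = _pair(x, y)
    nx = np.sqrt(np.sum(xa**2))
    ny = np.sqrt(np.sum(ya**2))
    if nx == 0.0 or ny == 0.0:
        raise ZeroVarianceError("NCC undefined for an all-zero image")
    return float(np.sum(xa * ya) / (nx * ny))


def aggregate(records: list[MetricRecord]) -> MetricRecord:
    """Arithmetic mean of each numeric column (the report's average row).
    NaN fields are averaged over the records that define them; rounding is
    left to display code."""
    if not records:
        raise UsageError("cannot aggregate an empty record list")
    out = MetricRecord(image_id="average")
    for name in MetricRecord.NUMERIC:
        vals = [getattr(r, name) for r in records
                if not math.isnan(getattr(r, name))]
        if vals:
            setattr(out, name, float(np.mean(vals)))
    return out
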