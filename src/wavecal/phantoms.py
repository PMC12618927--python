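"""Seeded anatomy-like grayscale phantoms and dataset splits.

Real CT/MRI slices mix a smooth low-frequency background, sharp
high-contrast boundaries (skull or bone rims), small bright lesions or
nodules, and acquisition noise.  The generator emulates exactly those four
ingredients with a Shepp-Logan-flavoured construction: a constant
background, one dominant rim ellipse providing a clean intensity step of
magnitude ``edge_contrast``, a handful of rotated graded ellipses for
internal anatomy, Gaussian-profile bright nodules, and i.i.d. Gaussian
noise, all clipped to [0, 1].  Every pixel is a deterministic function of
the spec (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError
from .image import ImageGrid

__all__ = ["PhantomSpec", "DatasetSplit", "generate_phantom", "generate_dataset",
           "make_split"]

_BACKGROUND = 0.10
_LESION_AMPLITUDE = 0.30


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic phantom.

    height/width in pixels (>= 16 and even, so at least one dyadic wavelet
    level always applies); ``edge_contrast`` is the rim step height as a
    fraction of the [0, 1] dynamic range; ``noise_sigma`` the std dev of the
    additive Gaussian noise on the same scale.
    """

    height: int = 64
    width: int = 64
    n_ellipses: int = 6
    n_lesions: int = 3
    edge_contrast: float = 0.5
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self):
        for name, dim in (("height", self.height), ("width", self.width)):
            if dim < 16 or dim % 2:
                raise ConfigurationError(f"{name} must be >= 16 and even, got {dim}")
        if self.n_ellipses < 0 or self.n_lesions < 0:
            raise ConfigurationError("counts must be non-negative")
        if not 0.0 <= self.edge_contrast <= 1.0:
            raise ConfigurationError("edge_contrast must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class DatasetSplit:
    train_ids: tuple[int, ...]
    val_ids: tuple[int, ...]
    test_ids: tuple[int, ...]
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0


def _ellipse_mask(yy, xx, cy, cx, a, b, angle):
    ct, st = np.cos(angle), np.sin(angle)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> ImageGrid:
    """Render one phantom; identical specs give bitwise-identical pixels."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    img = np.full((h, w), _BACKGROUND)

    if spec.n_ellipses > 0:
        # dominant rim: a clean step edge of magnitude edge_contrast
        rim = _ellipse_mask(yy, xx, h / 2, w / 2,
                            0.42 * w + rng.uniform(-0.03, 0.03) * w,
                            0.42 * h + rng.uniform(-0.03, 0.03) * h,
                            rng.uniform(0, np.pi))
        img[rim] += spec.edge_contrast
        for _ in range(spec.n_ellipses - 1):
            cy = rng.uniform(0.3, 0.7) * h
            cx = rng.uniform(0.3, 0.7) * w
            a = rng.uniform(0.05, 0.22) * w
            b = rng.uniform(0.05, 0.22) * h
            mask = _ellipse_mask(yy, xx, cy, cx, a, b, rng.uniform(0, np.pi))
            img[mask] += rng.uniform(-0.5, 0.5) * spec.edge_contrast

    for _ in range(spec.n_lesions):
        cy = rng.uniform(0.25, 0.75) * h
        cx = rng.uniform(0.25, 0.75) * w
        sig = rng.uniform(0.8, 2.5)
        img += _LESION_AMPLITUDE * np.exp(
            -(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sig**2))
        )

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=(h, w))

    return ImageGrid(np.clip(img, 0.0, 1.0), peak=1.0)


def generate_dataset(n: int, base_spec: PhantomSpec | None = None,
                     seed: int = 0) -> list[ImageGrid]:
    """``n`` phantoms with per-image seeds derived from ``seed``."""
    base = base_spec if base_spec is not None else PhantomSpec()
    root = np.random.default_rng(seed)
    seeds = root.integers(0, 2**31 - 1, size=n)
    return [generate_phantom(replace(base, seed=int(s))) for s in seeds]


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def make_split(n_images: int,
               fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
               seed: int = 0) -> DatasetSplit:
    """Seeded disjoint 70/15/15-style split.

    Subset sizes come from rounding the cumulative boundaries
    ``round(n*f_train)`` and ``round(n*(f_train+f_val))`` half away from
    zero, so the rounding remainder lands in the training set and the three
    parts always cover 0..n-1 exactly once.
    """
    if n_images < 10:
        raise ConfigurationError("need at least 10 images to split")
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise ConfigurationError("fractions must be three non-negative values")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError("fractions must sum to 1")

    b1 = _round_half_away(n_images * fractions[0])
    b2 = _round_half_away(n_images * (fractions[0] + fractions[1]))
    perm = np.random.default_rng(seed).permutation(n_images)
    return DatasetSplit(
        train_ids=tuple(int(i) for i in perm[:b1]),
        val_ids=tuple(int(i) for i in perm[b1:b2]),
        test_ids=tuple(int(i) for i in perm[b2:]),
        fractions=fractions,
        seed=seed,
    )
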