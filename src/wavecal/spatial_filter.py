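"""Trainable 3x3 post-reconstruction refinement filter.

A single 3x3 cross-correlation kernel (plus bias) is applied to the
reconstructed image with reflect padding and the result clipped to [0, 1].
The kernel weights are learned by gradient descent (Adam) on a weighted
image-quality objective

    w_mse * MSE + w_ssim * (1 - SSIM)

evaluated on the 0..255 scale via the metrics module.  Initialization is
the identity kernel plus small seeded noise, and the best iterate seen is
returned, so the trained filter is never worse than its starting point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import correlate

from .errors import ConfigurationError, DimensionError, StructuralError
from .image import aspixels
from .metrics import mse as _mse
from .metrics import ssim as _ssim

__all__ = ["FilterKernel", "ObjectiveWeights", "apply_filter",
           "objective_value", "train_filter"]


@dataclass
class FilterKernel:
    weights: np.ndarray
    bias: float = 0.0

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.shape != (3, 3):
            raise StructuralError("filter kernel must be 3x3")
        if not (np.all(np.isfinite(self.weights)) and np.isfinite(self.bias)):
            raise ConfigurationError("kernel entries must be finite")

    @classmethod
    def identity(cls) -> "FilterKernel":
        w = np.zeros((3, 3))
        w[1, 1] = 1.0
        return cls(w, 0.0)


@dataclass(frozen=True)
class ObjectiveWeights:
    w_mse: float = 1.0
    w_ssim: float = 0.0

    def __post_init__(self):
        if self.w_mse < 0 or self.w_ssim < 0:
            raise ConfigurationError("objective weights must be non-negative")


@dataclass(frozen=True)
class FilterTrainConfig:
    iterations: int = 300
    learning_rate: float = 5e-3
    init_noise: float = 1e-3
    seed: int = 0


def _raw_response(image: np.ndarray, kernel: FilterKernel) -> np.ndarray:
    return correlate(image, kernel.weights, mode="reflect") + kernel.bias


def apply_filter(image, kernel: FilterKernel) -> np.ndarray:
    """Same-shape 3x3 cross-correlation with reflect padding, plus bias,
    clipped to [0, 1]."""
    px = aspixels(image)
    if px.shape[0] < 3 or px.shape[1] < 3:
        raise DimensionError("image must be at least 3x3")
    return np.clip(_raw_response(px, kernel), 0.0, 1.0)


def objective_value(filtered, original,
                    weights: ObjectiveWeights = ObjectiveWeights()) -> float:
    """w_mse * MSE + w_ssim * (1 - SSIM) on the 0..255 scale."""
    f = aspixels(filtered) * 255.0
    o = aspixels(original) * 255.0
    val = weights.w_mse * _mse(f, o)
    if weights.w_ssim > 0:
        val += weights.w_ssim * (1.0 - _ssim(f, o))
    return float(val)


def _dataset_objective(pairs, kernel, weights):
    vals = [objective_value(apply_filter(rec, kernel), orig, weights)
            for rec, orig in pairs]
    return float(np.mean(vals))


def _mse_gradient(pairs, kernel, weights):
    """Analytic gradient of the MSE term (clip treated as a hard gate)."""
    gw = np.zeros((3, 3))
    gb = 0.0
    for rec, orig in pairs:
        rec, orig = aspixels(rec), aspixels(orig)
        raw = _raw_response(rec, kernel)
        active = (raw > 0.0) & (raw < 1.0)
        resid = (np.clip(raw, 0.0, 1.0) - orig) * active
        scale = weights.w_mse * (255.0**2) * 2.0 / resid.size
        padded = np.pad(rec, 1, mode="reflect")
        m, n = rec.shape
        for u in range(3):
            for v in range(3):
                gw[u, v] += scale * np.sum(resid * padded[u : u + m, v : v + n])
        gb += scale * np.sum(resid)
    return gw / len(pairs), gb / len(pairs)


def _numeric_gradient(pairs, kernel, weights, eps=1e-4):
    gw = np.zeros((3, 3))
    base_w = kernel.weights
    for u in range(3):
        for v in range(3):
            wp = base_w.copy(); wp[u, v] += eps
            wm = base_w.copy(); wm[u, v] -= eps
            gw[u, v] = (
                _dataset_objective(pairs, FilterKernel(wp, kernel.bias), weights)
                - _dataset_objective(pairs, FilterKernel(wm, kernel.bias), weights)
            ) / (2 * eps)
    gb = (
        _dataset_objective(pairs, FilterKernel(base_w, kernel.bias + eps), weights)
        - _dataset_objective(pairs, FilterKernel(base_w, kernel.bias - eps), weights)
    ) / (2 * eps)
    return gw, gb


def train_filter(pairs, objective_weights: ObjectiveWeights = ObjectiveWeights(),
                 train_config: FilterTrainConfig = FilterTrainConfig()):
    """Adam refinement of the kernel on (reconstructed, original) pairs.

    Returns ``(kernel, history)`` where history is the per-iteration
    objective; the returned kernel is the best iterate, so its objective
    never exceeds the initial one.  The gradient of the MSE term is
    analytic; when ``w_ssim > 0`` a central-difference gradient of the full
    objective is used instead (10 parameters only).
    """
    pairs = [(aspixels(r), aspixels(o)) for r, o in pairs]
    if not pairs:
        raise ConfigurationError("need at least one training pair")

    ident = FilterKernel.identity()
    init_obj = _dataset_objective(pairs, ident, objective_weights)
    if init_obj == 0.0:
        return ident, [0.0]

    rng = np.random.default_rng(train_config.seed)
    w = ident.weights + rng.normal(0, train_config.init_noise, (3, 3))
    b = 0.0
    best = (_dataset_objective(pairs, FilterKernel(w, b), objective_weights),
            w.copy(), b)
    history = [best[0]]

    m_w = np.zeros((3, 3)); v_w = np.zeros((3, 3))
    m_b = 0.0; v_b = 0.0
    b1, b2, eps = 0.9, 0.999, 1e-8
    for t in range(1, train_config.iterations + 1):
        kern = FilterKernel(w, b)
        if objective_weights.w_ssim > 0:
            gw, gb = _numeric_gradient(pairs, kern, objective_weights)
        else:
            gw, gb = _mse_gradient(pairs, kern, objective_weights)
        m_w = b1 * m_w + (1 - b1) * gw
        v_w = b2 * v_w + (1 - b2) * gw * gw
        m_b = b1 * m_b + (1 - b1) * gb
        v_b = b2 * v_b + (1 - b2) * gb * gb
        w = w - train_config.learning_rate * (m_w / (1 - b1**t)) / (
            np.sqrt(v_w / (1 - b2**t)) + eps
        )
        b = b - train_config.learning_rate * (m_b / (1 - b1**t)) / (
            np.sqrt(v_b / (1 - b2**t)) + eps
        )
        obj = _dataset_objective(pairs, FilterKernel(w, b), objective_weights)
        history.append(obj)
        if obj < best[0]:
            best = (obj, w.copy(), b)

    # the returned kernel is the best iterate: objective <= initial
    return FilterKernel(best[1], best[2]), history
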