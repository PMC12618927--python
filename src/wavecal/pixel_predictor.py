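"""Neural pixel estimation from local causal context.

Two small feedforward regressors forecast pixel intensities from eight
neighbours:

* ``square3x3`` — the 8 pixels surrounding an interior pixel predict its
  centre; hidden stack 20 -> 18 -> 5, one output.
* ``linear1x8`` — within each row, 8 consecutive pixels predict the next
  two (trailing) pixels; hidden stack 20 -> 18 -> 5, two outputs.

Hidden activations are tanh, the output layer is linear, pixel values are
on the [0, 1] scale, and training quality is summarized by the Pearson
regression coefficient R between predictions and targets on a held-out 15%
of the samples.

This subsystem is deliberately not wired into the default compression
bitstream; it is exposed standalone (``wavecal predict-pixels``) and as an
optional residual-coding experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .errors import (ConfigurationError, DimensionError, StructuralError,
                     ZeroVarianceError)
from .image import aspixels
from .nn import Tensor

__all__ = [
    "PredictorSpec",
    "RegressionReport",
    "PixelPredictor",
    "extract_contexts",
    "train_predictor",
    "predict",
    "regression_r",
]

_HIDDEN = (20, 18, 5)
_OUT_WIDTH = {"square3x3": 1, "linear1x8": 2}


@dataclass(frozen=True)
class PredictorSpec:
    window: str = "square3x3"
    activation: str = "tanh"
    seed: int = 0

    def __post_init__(self):
        if self.window not in _OUT_WIDTH:
            raise ConfigurationError(f"unknown window {self.window!r}")
        if self.activation != "tanh":
            raise ConfigurationError("only tanh hidden activation is supported")

    @property
    def hidden_layers(self) -> tuple[int, ...]:
        return _HIDDEN

    @property
    def out_width(self) -> int:
        return _OUT_WIDTH[self.window]


@dataclass
class RegressionReport:
    R: float
    mse: float
    n_samples: int


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 800
    learning_rate: float = 0.01
    holdout_fraction: float = 0.15


def extract_contexts(image, spec: PredictorSpec):
    """Return (inputs n x 8, targets n x {1|2}) in row-major scan order."""
    px = aspixels(image)
    m, n = px.shape
    if spec.window == "square3x3":
        if m < 3 or n < 3:
            raise DimensionError("square3x3 needs at least a 3x3 image")
        centre = px[1:-1, 1:-1]
        neigh = [px[1 + di : m - 1 + di, 1 + dj : n - 1 + dj]
                 for di in (-1, 0, 1) for dj in (-1, 0, 1)
                 if not (di == 0 and dj == 0)]
        inputs = np.stack([g.ravel() for g in neigh], axis=1)
        targets = centre.reshape(-1, 1)
    else:  # linear1x8: runs of 10 pixels -> 8 inputs, next 2 targets
        if n < 10:
            raise DimensionError("linear1x8 needs rows of at least 10 pixels")
        windows = np.lib.stride_tricks.sliding_window_view(px, 10, axis=1)
        flat = windows.reshape(-1, 10)
        inputs, targets = flat[:, :8].copy(), flat[:, 8:].copy()
    return inputs, targets


class PixelPredictor(nn.Module):
    def __init__(self, spec: PredictorSpec):
        super().__init__()
        rng = np.random.default_rng(spec.seed)
        self.spec = spec
        widths = (8,) + spec.hidden_layers + (spec.out_width,)
        layers = []
        for i, (a, b) in enumerate(zip(widths[:-1], widths[1:])):
            layers.append(nn.Linear(a, b, rng))
            if i < len(widths) - 2:
                layers.append(nn.Tanh())
        self.net = nn.Sequential(*layers)

    def forward(self, x):
        return self.net(x)


def regression_r(predictions: np.ndarray, targets: np.ndarray) -> float:
    """Pearson correlation between predictions and targets, all output
    columns pooled.  Raises :class:`ZeroVarianceError` for degenerate data
    (never returns NaN)."""
    p = np.asarray(predictions, dtype=np.float64).ravel()
    t = np.asarray(targets, dtype=np.float64).ravel()
    if p.shape != t.shape:
        raise StructuralError("predictions/targets length mismatch")
    if p.size < 2:
        raise ZeroVarianceError("need at least 2 samples for R")
    if np.std(p) == 0.0 or np.std(t) == 0.0:
        raise ZeroVarianceError("R undefined: zero-variance data")
    return float(np.corrcoef(p, t)[0, 1])


def train_predictor(inputs: np.ndarray, targets: np.ndarray,
                    spec: PredictorSpec,
                    train_config: TrainConfig = TrainConfig()):
    """Full-batch Adam regression; returns (model, RegressionReport).

    The report's R is evaluated on a held-out 15% of the samples (seeded
    shuffle); mse is the final training MSE.
    """
    inputs = np.asarray(inputs, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    if inputs.ndim != 2 or inputs.shape[1] != 8:
        raise StructuralError("inputs must be n x 8")
    if targets.shape != (inputs.shape[0], spec.out_width):
        raise StructuralError("targets must be n x out_width")
    n = inputs.shape[0]
    if n < 10:
        raise ConfigurationError("need at least 10 samples")
    if np.std(targets) == 0.0:
        raise ZeroVarianceError("targets have zero variance")

    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    n_hold = max(1, int(round(train_config.holdout_fraction * n)))
    hold, tr = perm[:n_hold], perm[n_hold:]

    model = PixelPredictor(spec)
    opt = nn.Adam(model.parameters(), lr=train_config.learning_rate)
    x_t, y_t = Tensor(inputs[tr]), Tensor(targets[tr])
    last_mse = np.inf
    for _ in range(train_config.epochs):
        opt.zero_grad()
        loss = ((model(x_t) - y_t) ** 2).mean()
        loss.backward()
        opt.step()
        last_mse = float(loss.data)

    preds_hold = predict(model, inputs[hold], clip=False)
    r = regression_r(preds_hold, targets[hold])
    return model, RegressionReport(R=r, mse=last_mse, n_samples=n)


def predict(model: PixelPredictor, inputs: np.ndarray,
            clip: bool = True) -> np.ndarray:
    """Deterministic forward pass; outputs clipped to [0, 1] by default."""
    inputs = np.asarray(inputs, dtype=np.float64)
    if inputs.ndim != 2 or inputs.shape[1] != 8:
        raise StructuralError("inputs must be n x 8")
    model.eval()
    out = model(Tensor(inputs)).data
    return np.clip(out, 0.0, 1.0) if clip else out
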