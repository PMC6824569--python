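"""Training and working modes of the reconstruction framework.

Training: for each (incomplete, complete) sinogram pair, the incomplete data
is zero-filled, FBP-reconstructed and re-projected to a full-size "corrupted"
sinogram; the network learns to map the normalized corrupted sinogram to the
normalized complete one under an MSE loss, with Nadam updates and an
exponentially decayed learning rate.

Working mode: corrupted sinogram -> network -> de-normalization with the
corrupted input's statistics -> final FBP reconstruction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from sinoct.fbp import fbp_reconstruct
from sinoct.geometry import (
    CTImage,
    FanGeometry,
    Sinogram,
    embed_incomplete,
    forward_project,
)
from sinoct.network import SinoUNet, denormalize, normalize

__all__ = [
    "NadamOptimizer",
    "TrainConfig",
    "TrainState",
    "TrainingPair",
    "decayed_learning_rate",
    "dlfbp_infer",
    "initialize_parameters",
    "make_corrupted",
    "make_training_pair",
    "mse_loss",
    "mse_loss_grad",
    "train",
]


@dataclass
class TrainingPair:
    """An incomplete sinogram, its complete target, and the derived corrupted
    sinogram the network actually sees."""

    incomplete: Sinogram
    complete: Sinogram
    corrupted: Sinogram
    label: str = ""

    def __post_init__(self) -> None:
        if self.corrupted.values.shape != self.complete.values.shape:
            raise ValueError("corrupted and complete sinograms must share shape")


@dataclass
class TrainConfig:
    initial_learning_rate: float = 1e-4
    decay_rate: float = 0.1
    decay_steps: int = 20
    outer_iterations: int = 50
    batch_size: int = 1
    seed: int = 0
    # Nadam moment constants (canonical published defaults)
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8

    def __post_init__(self) -> None:
        if min(self.initial_learning_rate, self.decay_rate) <= 0:
            raise ValueError("learning rate and decay rate must be positive")
        if self.decay_steps < 1 or self.outer_iterations < 1 or self.batch_size < 1:
            raise ValueError("decay_steps, outer_iterations, batch_size must be >= 1")


@dataclass
class TrainState:
    epoch: int
    loss: float
    learning_rate: float


def make_corrupted(
    incomplete: Sinogram, geometry: FanGeometry, out_size: int = 512
) -> Sinogram:
    """Zero-fill, FBP-reconstruct and re-project to a full-size sinogram."""
    embedded = embed_incomplete(incomplete)
    initial = fbp_reconstruct(embedded, geometry, out_size)
    reproj = forward_project(initial, geometry)
    return Sinogram(
        reproj.values,
        geometry.view_angles,
        geometry,
        kind="corrupted",
        factor=incomplete.factor,
        max_angle=incomplete.max_angle,
    )


def make_training_pair(
    incomplete: Sinogram,
    complete: Sinogram,
    geometry: FanGeometry,
    out_size: int,
    label: str = "",
) -> TrainingPair:
    return TrainingPair(
        incomplete=incomplete,
        complete=complete,
        corrupted=make_corrupted(incomplete, geometry, out_size),
        label=label,
    )


def mse_loss(predicted: np.ndarray, target: np.ndarray, m: int = 1) -> float:
    """Half sum of squared deviations over the batch, divided by batch size:
    ``E = (1 / 2m) * sum((Y - Yhat)^2)``."""
    p = np.asarray(getattr(predicted, "values", predicted), dtype=np.float64)
    t = np.asarray(getattr(target, "values", target), dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    return float(((t - p) ** 2).sum() / (2.0 * m))


def mse_loss_grad(predicted: np.ndarray, target: np.ndarray, m: int = 1) -> np.ndarray:
    """Gradient of :func:`mse_loss` with respect to the prediction."""
    p = np.asarray(getattr(predicted, "values", predicted), dtype=np.float64)
    t = np.asarray(getattr(target, "values", target), dtype=np.float64)
    return (p - t) / m


def decayed_learning_rate(config: TrainConfig, global_step: int) -> float:
    """Staircase exponential decay:
    ``lr * decay_rate ** int(global_step / decay_steps)``."""
    if global_step < 0:
        raise ValueError(f"global_step must be >= 0, got {global_step}")
    exponent = global_step // config.decay_steps
    return config.initial_learning_rate * config.decay_rate**exponent


def initialize_parameters(net: SinoUNet, seed: int) -> SinoUNet:
    """Gaussian weight init with std ``sqrt(2 / (n_in + n_out))`` per layer;
    biases zero, feature-map norm scales at identity.  Deterministic in seed."""
    rng = np.random.default_rng(seed)
    for layer in net.trainable_layers():
        if hasattr(layer, "w"):
            std = math.sqrt(2.0 / (layer.fan_in + layer.fan_out))
            layer.w[...] = rng.normal(0.0, std, size=layer.w.shape)
            layer.b[...] = 0.0
        else:  # ChannelNorm
            layer.gamma[...] = 1.0
            layer.beta[...] = 0.0
    return net


class NadamOptimizer:
    """Nesterov-accelerated Adam (Dozat 2016, keras-style update)."""

    def __init__(self, params: Sequence[np.ndarray], config: TrainConfig):
        self.params = list(params)
        self.b1 = config.beta1
        self.b2 = config.beta2
        self.eps = config.epsilon
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads: Sequence[np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        c1 = 1.0 - b1**self.t
        c2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            m_hat = b1 * m / c1 + (1.0 - b1) * g / c1
            v_hat = v / c2
            p -= lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _train_step(
    net: SinoUNet,
    optimizer: NadamOptimizer,
    pair: TrainingPair,
    lr: float,
    batch_size: int,
) -> float:
    x = normalize(pair.corrupted.values)
    y = normalize(pair.complete.values)
    pred = net.forward(x.values)
    loss = mse_loss(pred, y.values, m=batch_size)
    net.backward(mse_loss_grad(pred, y.values, m=batch_size))
    optimizer.step(net.gradients(), lr)
    return loss


def train(
    pairs: Sequence[TrainingPair],
    net: SinoUNet,
    config: TrainConfig,
    start_epoch: int = 0,
) -> Tuple[SinoUNet, List[TrainState]]:
    """Run the outer-iteration training loop.

    Each outer iteration visits every pair once in a seeded shuffled order;
    the learning rate decays by outer-iteration index (so the default
    50-iteration schedule traverses 1e-4 -> 1e-5 -> 1e-6).  ``start_epoch``
    resumes the schedule at a recorded position.
    """
    if len(pairs) == 0:
        raise ValueError("need at least one training pair")
    rng = np.random.default_rng(config.seed + start_epoch)
    optimizer = NadamOptimizer(net.parameters(), config)
    history: List[TrainState] = []
    for epoch in range(start_epoch, config.outer_iterations):
        lr = decayed_learning_rate(config, epoch)
        order = rng.permutation(len(pairs))
        losses = []
        for idx in order:
            loss = _train_step(net, optimizer, pairs[idx], lr, config.batch_size)
            if not math.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, pair {idx}"
                )
            losses.append(loss)
        history.append(TrainState(epoch=epoch, loss=float(np.mean(losses)), learning_rate=lr))
    return net, history


def dlfbp_infer(
    incomplete: Sinogram,
    net: SinoUNet,
    geometry: FanGeometry,
    out_size: int = 512,
    rescale: str = "measured",
) -> Tuple[CTImage, Sinogram]:
    """Working mode: incomplete sinogram -> restored sinogram + CT image.

    The network output is first mapped back to physical units by inverting
    the normalization with the corrupted input sinogram's mean and std (the
    statistics available at inference time).  With ``rescale="measured"``
    (default) the restored sinogram is then affinely refitted against the
    measured rows of the input sinogram — the rows the restored sinogram must
    physically reproduce — which corrects the global amplitude bias the
    corrupted statistics carry in the limited-angle case.
    ``rescale="corrupted_stats"`` skips the refit.
    """
    if rescale not in ("measured", "corrupted_stats"):
        raise ValueError(f"unknown rescale mode {rescale!r}")
    corrupted = make_corrupted(incomplete, geometry, out_size)
    x = normalize(corrupted.values)
    y = net.predict(x)
    restored_values = denormalize(y)
    if rescale == "measured" and incomplete.values.size:
        if incomplete.measured_mask is not None:
            row_idx = np.flatnonzero(incomplete.measured_mask)
            measured = incomplete.values[row_idx].ravel()
        else:
            row_idx = incomplete.view_indices
            measured = incomplete.values.ravel()
        predicted = restored_values[row_idx].ravel()
        design = np.vstack([predicted, np.ones_like(predicted)]).T
        (a, b), *_ = np.linalg.lstsq(design, measured, rcond=None)
        if np.isfinite(a) and np.isfinite(b):
            restored_values = a * restored_values + b
    restored = Sinogram(
        restored_values,
        geometry.view_angles,
        geometry,
        kind="restored",
        factor=incomplete.factor,
        max_angle=incomplete.max_angle,
    )
    image = fbp_reconstruct(restored, geometry, out_size)
    return image, restored
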