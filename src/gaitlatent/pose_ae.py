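"""Feed-forward pose autoencoder with a 2-unit bottleneck.

A 14-dimensional standardized pose is compressed through a three-layer
encoder (dense + batch-norm + ReLU at widths 64, 32, 16) into a linear
latent layer, then reconstructed by a mirrored three-layer decoder.  The
loss is mean-squared reconstruction error; optimization is full-batch Adam
for a fixed number of iterations.  Batch normalization lives only in the
encoder, acting as the model's sole regularizer.

Training is fully deterministic given the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._nn import (
    Adam,
    BatchNorm,
    Dense,
    ReLU,
    TrainingDivergedError,
    collect_params,
    restore_params,
    zero_all,
)
from .preprocess import PoseSample, stack_poses


@dataclass
class PoseAEConfig:
    input_width: int = 14
    latent_width: int = 2
    hidden_widths: tuple[int, ...] = (64, 32, 16)  # encoder taper; decoder mirrors
    learning_rate: float = 1e-3
    iterations: int = 8000  # full-batch gradient steps
    seed: int = 0
    log_every: int = 100

    def __post_init__(self) -> None:
        if self.latent_width < 1:
            raise ValueError("latent width must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


class PoseAEModel:
    """Trained pose autoencoder (parameters, config, loss history)."""

    def __init__(self, config: PoseAEConfig) -> None:
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
        widths = config.hidden_widths
        self.encoder: list = []
        n_in = config.input_width
        for w in widths:
            self.encoder += [Dense(n_in, w, rng), BatchNorm(w), ReLU()]
            n_in = w
        self.encoder.append(Dense(n_in, config.latent_width, rng))
        self.decoder: list = []
        n_in = config.latent_width
        for w in reversed(widths):
            self.decoder += [Dense(n_in, w, rng), ReLU()]
            n_in = w
        self.decoder.append(Dense(n_in, config.input_width, rng))
        self.loss_history: list[float] = []
        self.final_loss: float = np.nan

    # -- forward passes ----------------------------------------------------
    def _encode(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.encoder:
            x = layer.forward(x, train)
        return x

    def _decode(self, z: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.decoder:
            z = layer.forward(z, train)
        return z

    @property
    def layers(self) -> list:
        return self.encoder + self.decoder

    # -- serialization -----------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        blob = collect_params(self.layers)
        blob["loss_history"] = np.asarray(self.loss_history)
        blob["final_loss"] = np.asarray(self.final_loss)
        np.savez(path, **blob)
        path.with_suffix(".config.json").write_text(json.dumps(asdict(self.config)))

    @classmethod
    def load(cls, path: str | Path) -> "PoseAEModel":
        path = Path(path)
        cfg_raw = json.loads(path.with_suffix(".config.json").read_text())
        cfg_raw["hidden_widths"] = tuple(cfg_raw["hidden_widths"])
        model = cls(PoseAEConfig(**cfg_raw))
        with np.load(path) as data:
            restore_params(model.layers, data)
            model.loss_history = list(data["loss_history"])
            model.final_loss = float(data["final_loss"])
        return model


def _as_matrix(poses, width: int) -> np.ndarray:
    if isinstance(poses, np.ndarray):
        x = poses
    elif poses and isinstance(poses[0], PoseSample):
        x = stack_poses(poses)
    else:
        x = np.asarray(poses, dtype=float)
    if x.ndim != 2 or x.shape[1] != width:
        raise ValueError(f"expected (n, {width}) poses, got {x.shape}")
    return x


def train_pose_ae(poses, config: PoseAEConfig | None = None) -> PoseAEModel:
    """Full-batch Adam on mean-squared reconstruction error."""
    config = config or PoseAEConfig()
    x = _as_matrix(poses, config.input_width)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 poses to train")
    model = PoseAEModel(config)
    layers = model.layers
    opt = Adam(layers, lr=config.learning_rate)
    n_total = x.size
    for it in range(config.iterations):
        zero_all(layers)
        z = model._encode(x, train=True)
        y = model._decode(z, train=True)
        resid = y - x
        loss = float(np.mean(resid**2))
        if not np.isfinite(loss):
            raise TrainingDivergedError(it)
        if it % config.log_every == 0:
            model.loss_history.append(loss)
        dy = 2.0 * resid / n_total
        for layer in reversed(model.decoder):
            dy = layer.backward(dy)
        for layer in reversed(model.encoder):
            dy = layer.backward(dy)
        opt.step()
    # final loss in inference mode (frozen batch-norm statistics)
    y = model._decode(model._encode(x, train=False), train=False)
    model.final_loss = float(np.mean((y - x) ** 2))
    model.loss_history.append(model.final_loss)
    return model


def encode_pose(model: PoseAEModel, poses) -> np.ndarray:
    """Latent coordinates (n, latent_width), inference mode."""
    x = _as_matrix(poses, model.config.input_width)
    return model._encode(x, train=False)


def decode_pose(model: PoseAEModel, latent: np.ndarray) -> np.ndarray:
    """Reconstructed poses (n, 14) from latent coordinates."""
    latent = np.asarray(latent, dtype=float)
    if latent.ndim != 2 or latent.shape[1] != model.config.latent_width:
        raise ValueError(
            f"expected (n, {model.config.latent_width}) latent, got {latent.shape}"
        )
    return model._decode(latent, train=False)


def reconstruct(model: PoseAEModel, poses) -> np.ndarray:
    return decode_pose(model, encode_pose(model, poses))
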