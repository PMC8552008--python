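"""Recurrent movement autoencoder: one-second windows to a 2-D latent.

The encoder passes each 60 x 14 standardized window through a
time-distributed dense layer of width 64, two stacked bidirectional LSTM
layers, and an intermediate dense layer before the 2-unit linear latent.
The decoder repeats the latent vector across all 60 timesteps, runs two
bidirectional LSTM layers, and maps each timestep back to 14 channels
through time-distributed dense layers.  The loss is mean-squared
reconstruction error over all 840 entries of the window; optimization is
mini-batch Adam (batch size 32), one iteration = one mini-batch step.

Because each latent point summarizes a full second of movement, the model
can represent temporal structure — e.g. whether a gait cycle runs forward
or backward — that no pose-level reducer can see.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from ._nn import (
    Adam,
    BiLSTM,
    Dense,
    ReLU,
    TrainingDivergedError,
    clip_gradients,
    collect_params,
    restore_params,
    zero_all,
)
from .preprocess import MovementWindow, stack_windows


@dataclass
class MoveAEConfig:
    window: int = 60
    channels: int = 14
    latent_width: int = 2
    td_width: int = 64  # time-distributed dense width
    hidden_size: int = 32  # LSTM units per direction
    intermediate_width: int = 16
    learning_rate: float = 1e-3
    iterations: int = 8000  # mini-batch gradient steps
    batch_size: int = 32
    seed: int = 0
    grad_clip: float | None = None
    log_every: int = 50

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")


class MoveAEModel:
    """Trained movement autoencoder."""

    def __init__(self, config: MoveAEConfig) -> None:
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
        c = config
        self.td_in = Dense(c.channels, c.td_width, rng)
        self.td_in_act = ReLU()
        self.enc_rnn1 = BiLSTM(c.td_width, c.hidden_size, rng)
        self.enc_rnn2 = BiLSTM(2 * c.hidden_size, c.hidden_size, rng)
        self.inter = Dense(2 * c.hidden_size, c.intermediate_width, rng)
        self.inter_act = ReLU()
        self.to_latent = Dense(c.intermediate_width, c.latent_width, rng)
        self.dec_rnn1 = BiLSTM(c.latent_width, c.hidden_size, rng)
        self.dec_rnn2 = BiLSTM(2 * c.hidden_size, c.hidden_size, rng)
        self.td_out1 = Dense(2 * c.hidden_size, c.td_width, rng)
        self.td_out1_act = ReLU()
        self.td_out2 = Dense(c.td_width, c.channels, rng)
        self.loss_history: list[float] = []
        self.final_loss: float = np.nan

    @property
    def layers(self) -> list:
        return [
            self.td_in,
            self.enc_rnn1,
            self.enc_rnn2,
            self.inter,
            self.to_latent,
            self.dec_rnn1,
            self.dec_rnn2,
            self.td_out1,
            self.td_out2,
        ]

    # -- forward/backward --------------------------------------------------
    def _encode(self, w: np.ndarray, train: bool) -> np.ndarray:
        x = self.td_in_act.forward(self.td_in.forward(w, train), train)
        x = self.enc_rnn1.forward(x, train)
        x = self.enc_rnn2.forward(x, train)
        self._enc_out_shape = x.shape
        final = self.enc_rnn2.final_state(x)
        z = self.inter_act.forward(self.inter.forward(final, train), train)
        return self.to_latent.forward(z, train)

    def _encode_backward(self, dz: np.ndarray) -> None:
        d = self.to_latent.backward(dz)
        d = self.inter.backward(self.inter_act.backward(d))
        d = self.enc_rnn2.final_state_grad(d, self._enc_out_shape)
        d = self.enc_rnn2.backward(d)
        d = self.enc_rnn1.backward(d)
        self.td_in.backward(self.td_in_act.backward(d))

    def _decode(self, z: np.ndarray, train: bool) -> np.ndarray:
        seq = np.repeat(z[:, None, :], self.config.window, axis=1)
        x = self.dec_rnn1.forward(seq, train)
        x = self.dec_rnn2.forward(x, train)
        x = self.td_out1_act.forward(self.td_out1.forward(x, train), train)
        return self.td_out2.forward(x, train)

    def _decode_backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.td_out1.backward(self.td_out1_act.backward(self.td_out2.backward(dy)))
        d = self.dec_rnn2.backward(d)
        d = self.dec_rnn1.backward(d)
        return d.sum(axis=1)  # gradient through the latent repeat

    # -- serialization -----------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        blob = collect_params(self.layers)
        blob["loss_history"] = np.asarray(self.loss_history)
        blob["final_loss"] = np.asarray(self.final_loss)
        np.savez(path, **blob)
        path.with_suffix(".config.json").write_text(json.dumps(asdict(self.config)))

    @classmethod
    def load(cls, path: str | Path) -> "MoveAEModel":
        path = Path(path)
        cfg = MoveAEConfig(**json.loads(path.with_suffix(".config.json").read_text()))
        model = cls(cfg)
        with np.load(path) as data:
            restore_params(model.layers, data)
            model.loss_history = list(data["loss_history"])
            model.final_loss = float(data["final_loss"])
        return model


def _as_tensor(windows, config: MoveAEConfig) -> np.ndarray:
    if isinstance(windows, np.ndarray):
        w = windows
    elif windows and isinstance(windows[0], MovementWindow):
        w = stack_windows(windows)
    else:
        w = np.asarray(windows, dtype=float)
    if w.ndim != 3 or w.shape[1:] != (config.window, config.channels):
        raise ValueError(
            f"expected (n, {config.window}, {config.channels}) windows, got {w.shape}"
        )
    return w


def train_move_ae(windows, config: MoveAEConfig | None = None) -> MoveAEModel:
    """Mini-batch Adam on mean-squared window reconstruction error."""
    config = config or MoveAEConfig()
    w = _as_tensor(windows, config)
    n = w.shape[0]
    if n < config.batch_size:
        raise ValueError(
            f"need at least batch_size={config.batch_size} windows, got {n}"
        )
    model = MoveAEModel(config)
    layers = model.layers
    opt = Adam(layers, lr=config.learning_rate)
    batch_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    order = batch_rng.permutation(n)
    cursor = 0
    for it in range(config.iterations):
        if cursor + config.batch_size > n:
            order = batch_rng.permutation(n)
            cursor = 0
        batch = w[order[cursor : cursor + config.batch_size]]
        cursor += config.batch_size
        zero_all(layers)
        z = model._encode(batch, train=True)
        y = model._decode(z, train=True)
        resid = y - batch
        loss = float(np.mean(resid**2))
        if not np.isfinite(loss):
            raise TrainingDivergedError(it)
        if it % config.log_every == 0:
            model.loss_history.append(loss)
        dy = 2.0 * resid / batch.size
        dz = model._decode_backward(dy)
        model._encode_backward(dz)
        if config.grad_clip is not None:
            clip_gradients(layers, config.grad_clip)
        opt.step()
    # final loss over the full training set
    recon = decode_move(model, encode_move(model, w))
    model.final_loss = float(np.mean((recon - w) ** 2))
    model.loss_history.append(model.final_loss)
    return model


def encode_move(
    model: MoveAEModel, windows, chunk: int = 512
) -> np.ndarray:
    """Latent coordinates (n, 2); processed in chunks to bound memory."""
    w = _as_tensor(windows, model.config)
    outs = [
        model._encode(w[i : i + chunk], train=False)
        for i in range(0, w.shape[0], chunk)
    ]
    return np.concatenate(outs, axis=0)


def decode_move(
    model: MoveAEModel, latent: np.ndarray, chunk: int = 512
) -> np.ndarray:
    """Reconstructed windows (n, 60, 14) from latent coordinates."""
    latent = np.asarray(latent, dtype=float)
    if latent.ndim != 2 or latent.shape[1] != model.config.latent_width:
        raise ValueError(
            f"expected (n, {model.config.latent_width}) latent, got {latent.shape}"
        )
    outs = [
        model._decode(latent[i : i + chunk], train=False)
        for i in range(0, latent.shape[0], chunk)
    ]
    return np.concatenate(outs, axis=0)


def reconstruct(model: MoveAEModel, windows) -> np.ndarray:
    return decode_move(model, encode_move(model, windows))


def compression_ratio(config: MoveAEConfig) -> float:
    """Input elements per latent unit (420 for the default 60x14 -> 2)."""
    return config.window * config.channels / config.latent_width
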