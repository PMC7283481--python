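"""Tile classifier, data augmentation and optimizer-schedule primitives.

The default backbone is a small convolutional network (4 conv blocks with
2x2 mean pooling, global average pooling, a single-logit sigmoid head)
implemented directly on NumPy with hand-written backpropagation and an
Adam optimizer (beta1 = 0.9, beta2 = 0.999).  It is sized for desk-scale
tiles (64 px default); the backbone is pluggable by name so larger
architectures can be swapped in where a deep-learning runtime is present.

The loss is binary cross-entropy on the carcinoma probability, computed in
logit space for numerical stability.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

BACKBONE_SMALL_CNN = "small_cnn"


@dataclass(frozen=True)
class OptimizerConfig:
    """Adam hyperparameters shared by both training regimes."""

    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 64
    epsilon: float = 1e-8

    def __post_init__(self) -> None:
        if not (0.0 < self.beta1 < 1.0 and 0.0 < self.beta2 < 1.0):
            raise ValueError("Adam betas must lie in (0, 1)")
        if self.batch_size <= 0:
            raise ValueError("batch_size must be positive")


@dataclass(frozen=True)
class AugmentationConfig:
    """Tile flips, translations and per-channel additive colour shifts."""

    flip_horizontal: bool = True
    flip_vertical: bool = True
    max_translation: int = 4
    colour_shift_range: float = 0.04  # fraction of dynamic range, per channel


def augment(tile: np.ndarray, cfg: AugmentationConfig, rng: np.random.Generator) -> np.ndarray:
    """Randomly flip, translate and colour-shift one float tile in [0, 1]."""
    if tile.shape[0] != tile.shape[1]:
        raise ValueError("tile must be square")
    if cfg.max_translation >= tile.shape[0]:
        raise ValueError("max_translation must be smaller than the tile size")
    out = tile
    if cfg.flip_horizontal and rng.uniform() < 0.5:
        out = out[:, ::-1]
    if cfg.flip_vertical and rng.uniform() < 0.5:
        out = out[::-1, :]
    if cfg.max_translation > 0:
        dy, dx = rng.integers(-cfg.max_translation, cfg.max_translation + 1, size=2)
        if dy or dx:
            pad = cfg.max_translation
            padded = np.pad(out, ((pad, pad), (pad, pad), (0, 0)), mode="reflect")
            s = tile.shape[0]
            out = padded[pad + dy : pad + dy + s, pad + dx : pad + dx + s]
    if cfg.colour_shift_range > 0:
        shift = rng.uniform(-cfg.colour_shift_range, cfg.colour_shift_range, size=3)
        out = out + shift
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def fs_lr_schedule(epoch: int, iteration_in_epoch: int, iterations_per_epoch: int) -> float:
    """Warm start 0.001 -> 0.05 across epoch 1, then 0.05 * 0.9**(epoch-1).

    The first 0.9 decay applies when epoch 1 ends, so epoch 2 runs at 0.045.
    """
    if epoch < 1:
        raise ValueError("epoch index starts at 1")
    if epoch == 1:
        denom = max(iterations_per_epoch - 1, 1)
        frac = min(iteration_in_epoch, denom) / denom
        return 0.001 + (0.05 - 0.001) * frac
    return 0.05 * 0.9 ** (epoch - 1)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


class SmallCNN:
    """Desk-scale convolutional tile classifier on NumPy.

    Blocks: [conv 3x3, stride 2, same padding -> ReLU] x len(channels),
    global average pooling, then a single linear logit.  ``predict_proba``
    is deterministic for fixed parameters; ``train_step`` performs one Adam
    update on a labelled batch and returns its BCE loss.
    """

    def __init__(
        self,
        input_size: int = 64,
        channels: tuple[int, ...] = (8, 16, 32, 32),
        seed: int = 0,
        optimizer: OptimizerConfig | None = None,
    ) -> None:
        if input_size % (2 ** len(channels)) != 0:
            raise ValueError("input_size must be divisible by 2**n_blocks")
        self.input_size = int(input_size)
        self.channels = tuple(int(c) for c in channels)
        self.optimizer = optimizer or OptimizerConfig()
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        c_in = 3
        for i, c_out in enumerate(self.channels):
            fan_in = 9 * c_in
            self.params[f"W{i}"] = (
                rng.standard_normal((3, 3, c_in, c_out)) * np.sqrt(2.0 / fan_in)
            ).astype(np.float32)
            self.params[f"b{i}"] = np.zeros(c_out, dtype=np.float32)
            c_in = c_out
        self.params["w_head"] = (rng.standard_normal(c_in) * np.sqrt(1.0 / c_in)).astype(np.float32)
        self.params["b_head"] = np.zeros(1, dtype=np.float32)
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # ---- plumbing ---------------------------------------------------------

    @staticmethod
    def _prep(tiles: np.ndarray) -> np.ndarray:
        x = np.asarray(tiles)
        if x.dtype == np.uint8:
            x = x.astype(np.float32) / 255.0
        x = x.astype(np.float32, copy=False)
        return x - 0.5

    @staticmethod
    def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
        """3x3 convolution, stride 2, same padding; per-offset matmuls."""
        n, h, w, _ = x.shape
        c_out = W.shape[3]
        ho, wo = h // 2, w // 2
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        out = np.tile(b, (n, ho, wo, 1)).astype(np.float32)
        for di in range(3):
            for dj in range(3):
                sl = xp[:, di : di + h : 2, dj : dj + w : 2, :]
                out += sl.reshape(-1, sl.shape[-1]).dot(W[di, dj]).reshape(n, ho, wo, c_out)
        return out

    @staticmethod
    def _conv_backward(
        x: np.ndarray, W: np.ndarray, dout: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        n, h, w, c_in = x.shape
        c_out = W.shape[3]
        ho, wo = h // 2, w // 2
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        dxp = np.zeros_like(xp)
        dW = np.zeros_like(W)
        dflat = dout.reshape(-1, c_out)
        for di in range(3):
            for dj in range(3):
                sl = xp[:, di : di + h : 2, dj : dj + w : 2, :].reshape(-1, c_in)
                dW[di, dj] = sl.T.dot(dflat)
                dxp[:, di : di + h : 2, dj : dj + w : 2, :] += dflat.dot(W[di, dj].T).reshape(
                    n, ho, wo, c_in
                )
        db = dflat.sum(axis=0)
        return dxp[:, 1:-1, 1:-1, :], dW, db

    def _forward(self, x: np.ndarray, want_cache: bool) -> tuple[np.ndarray, list]:
        cache = []
        for i in range(len(self.channels)):
            pre = self._conv_forward(x, self.params[f"W{i}"], self.params[f"b{i}"])
            act = np.maximum(pre, 0.0)
            if want_cache:
                cache.append((x, pre))
            x = act
        feat = x.mean(axis=(1, 2))
        logit = feat.dot(self.params["w_head"]) + self.params["b_head"][0]
        if want_cache:
            cache.append((x.shape, feat))
        return logit, cache

    # ---- public contract --------------------------------------------------

    def predict_proba(self, tiles: np.ndarray, chunk: int = 256) -> np.ndarray:
        """Carcinoma probability per tile, order-preserving; empty in -> empty out."""
        tiles = np.asarray(tiles)
        if tiles.size == 0:
            return np.zeros(0, dtype=np.float32)
        probs = []
        for start in range(0, tiles.shape[0], chunk):
            x = self._prep(tiles[start : start + chunk])
            logit, _ = self._forward(x, want_cache=False)
            probs.append(_sigmoid(logit))
        return np.concatenate(probs).astype(np.float32)

    def _loss_and_grads(self, x: np.ndarray, y: np.ndarray) -> tuple[float, dict[str, np.ndarray]]:
        n = x.shape[0]
        logit, cache = self._forward(x, want_cache=True)
        loss = float(np.mean(np.logaddexp(0.0, logit) - y * logit))

        grads: dict[str, np.ndarray] = {}
        dlogit = (_sigmoid(logit) - y) / n
        pool_shape, feat = cache[-1]
        grads["w_head"] = feat.T.dot(dlogit)
        grads["b_head"] = np.array([dlogit.sum()], dtype=np.float32)
        dfeat = np.outer(dlogit, self.params["w_head"])
        _, ph, pw, _ = pool_shape
        dx = np.broadcast_to(dfeat[:, None, None, :], pool_shape).astype(np.float32) / (ph * pw)
        for i in reversed(range(len(self.channels))):
            x_in, pre = cache[i]
            dpre = dx * (pre > 0)
            dx, dW, db = self._conv_backward(x_in, self.params[f"W{i}"], dpre)
            grads[f"W{i}"] = dW
            grads[f"b{i}"] = db
        return loss, grads

    def train_step(self, tiles: np.ndarray, labels: np.ndarray, lr: float) -> float:
        """One Adam update on a labelled batch; returns the batch BCE loss."""
        x = self._prep(tiles)
        y = np.asarray(labels, dtype=np.float32)
        loss, grads = self._loss_and_grads(x, y)
        self._adam_t += 1
        opt = self.optimizer
        bc1 = 1.0 - opt.beta1 ** self._adam_t
        bc2 = 1.0 - opt.beta2 ** self._adam_t
        for k, g in grads.items():
            g = g.astype(np.float32)
            m = self._adam_m[k]
            v = self._adam_v[k]
            m *= opt.beta1
            m += (1 - opt.beta1) * g
            v *= opt.beta2
            v += (1 - opt.beta2) * g * g
            self.params[k] -= lr * (m / bc1) / (np.sqrt(v / bc2) + opt.epsilon)
        return loss

    # ---- state ------------------------------------------------------------

    def get_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = state[k].copy()

    def save(self, path: str | Path) -> None:
        meta = dict(
            backbone=BACKBONE_SMALL_CNN,
            input_size=self.input_size,
            channels=np.asarray(self.channels),
        )
        np.savez(path, **meta, **{f"param_{k}": v for k, v in self.params.items()})

    @classmethod
    def load(cls, path: str | Path) -> "SmallCNN":
        with np.load(path, allow_pickle=False) as data:
            backbone = str(data["backbone"])
            if backbone != BACKBONE_SMALL_CNN:
                raise ValueError(f"checkpoint backbone {backbone!r} is not loadable here")
            model = cls(
                input_size=int(data["input_size"]),
                channels=tuple(int(c) for c in data["channels"]),
            )
            for k in model.params:
                model.params[k] = data[f"param_{k}"].astype(np.float32)
        return model


def build_backbone(name: str, input_size: int, seed: int, channels: tuple[int, ...] | None = None) -> SmallCNN:
    """Instantiate a tile classifier by backbone name."""
    if name == BACKBONE_SMALL_CNN:
        kwargs = {"channels": channels} if channels else {}
        return SmallCNN(input_size=input_size, seed=seed, **kwargs)
    raise NotImplementedError(
        f"backbone {name!r} requires a deep-learning runtime; available: {BACKBONE_SMALL_CNN!r}"
    )


def predict_tiles(model, tiles: np.ndarray) -> np.ndarray:
    """One probability per tile in input order (thin contract wrapper)."""
    return model.predict_proba(np.asarray(tiles))
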