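"""A compact U-net: encoder/decoder with skip concatenation, in numpy.

Architecture per stage i (i = 0..n_stages-1): two 3x3 'same' convolutions
with ReLU at ``base_features * 2**i`` channels, then 2x2 max pooling.  The
bridge doubles the features once more and applies dropout.  Each decoder
stage upsamples with a learned 2x2 stride-2 transposed convolution,
concatenates the matching encoder feature map and applies two 3x3
conv+ReLU blocks.  A final 1x1 convolution maps to class scores.

Pooling requires even edge lengths at every stage, so inference
reflect-pads any input to the next multiple of ``2**n_stages`` and crops
the output back (the pad/crop round trip is lossless).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import Adam, Conv, Dropout, MaxPool2, ReLU, UpConv2
from .loss import TverskyConfig, softmax, tversky_loss_and_grad

__all__ = ["UNetConfig", "TrainConfig", "UNet", "pad_to_multiple"]


@dataclass
class UNetConfig:
    n_stages: int = 3
    base_features: int = 32
    n_classes: int = 3
    dropout_rate: float = 0.5

    def validate(self) -> None:
        if self.n_stages < 1:
            raise ValueError("n_stages must be >= 1")
        if self.base_features < 1 or self.n_classes < 2:
            raise ValueError("base_features >= 1 and n_classes >= 2 required")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")


@dataclass
class TrainConfig:
    lr: float = 0.001
    lr_decay_per_epoch: float = 0.9
    batch_size: int = 30
    epochs: int = 10
    augmentations_per_image: int = 0
    shuffle_each_epoch: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative")
        if not 0 <= self.augmentations_per_image <= 100:
            raise ValueError("augmentations_per_image must lie in [0, 100]")


def pad_to_multiple(frame: np.ndarray, multiple: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Reflect-pad a 2-D frame so both dimensions divide ``multiple``."""
    h, w = frame.shape
    ph = (-h) % multiple
    pw = (-w) % multiple
    if ph or pw:
        frame = np.pad(frame, ((0, ph), (0, pw)), mode="reflect")
    return frame, (ph, pw)


class _ConvBlock:
    def __init__(self, c_in, c_out, rng):
        self.layers = [Conv(c_in, c_out, 3, rng), ReLU(), Conv(c_out, c_out, 3, rng), ReLU()]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g


class UNet:
    """The network itself; estimator-level concerns live elsewhere."""

    def __init__(self, cfg: UNetConfig, seed: int = 0):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(rng.integers(2**31))
        f = cfg.base_features
        self.enc = []
        c_in = 1
        for i in range(cfg.n_stages):
            c_out = f * 2**i
            self.enc.append((_ConvBlock(c_in, c_out, rng), MaxPool2()))
            c_in = c_out
        c_bridge = f * 2**cfg.n_stages
        self.bridge = _ConvBlock(c_in, c_bridge, rng)
        self.dropout = Dropout(cfg.dropout_rate, self._dropout_rng)
        self.dec = []
        c_in = c_bridge
        for i in reversed(range(cfg.n_stages)):
            c_skip = f * 2**i
            self.dec.append((UpConv2(c_in, c_skip, rng), _ConvBlock(2 * c_skip, c_skip, rng)))
            c_in = c_skip
        self.head = Conv(c_in, cfg.n_classes, 1, rng)

    # -- parameter plumbing ------------------------------------------------
    def _modules(self):
        for block, _pool in self.enc:
            yield from block.layers
        yield from self.bridge.layers
        for up, block in self.dec:
            yield up
            yield from block.layers
        yield self.head

    def parameters(self) -> list[np.ndarray]:
        return [p for m in self._modules() for p in m.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for m in self._modules() for g in m.grads]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(weights):
            raise ValueError("weight list does not match the architecture")
        for p, w in zip(params, weights):
            if p.shape != np.asarray(w).shape:
                raise ValueError("weight shapes do not match the architecture")
            p[...] = w

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch (N, H, W, 1); H and W must divide 2**n_stages."""
        self._skips = []
        for block, pool in self.enc:
            x = block.forward(x, train)
            self._skips.append(x)
            x = pool.forward(x, train)
        x = self.bridge.forward(x, train)
        x = self.dropout.forward(x, train)
        self._concat_channels = []
        for (up, block), skip in zip(self.dec, reversed(self._skips)):
            x = up.forward(x, train)
            self._concat_channels.append(skip.shape[-1])
            x = np.concatenate([skip, x], axis=-1)
            x = block.forward(x, train)
        return self.head.forward(x, train)

    def backward(self, glogits: np.ndarray) -> None:
        g = self.head.backward(glogits)
        # decoder, shallowest level first; collect the skip gradients, which
        # re-enter the encoder at the matching depth
        skip_grads = []  # collected shallowest-first: skip_grads[i] <-> enc[i]
        for (up, block), c_skip in zip(reversed(self.dec), reversed(self._concat_channels)):
            g = block.backward(g)
            skip_grads.append(g[..., :c_skip])
            g = up.backward(g[..., c_skip:])
        g = self.dropout.backward(g)
        g = self.bridge.backward(g)
        for (block, pool), g_skip in zip(reversed(self.enc), reversed(skip_grads)):
            g = pool.backward(g)
            g = g + g_skip
            g = block.backward(g)

    def train_step(self, images: np.ndarray, targets: np.ndarray, tversky: TverskyConfig, opt: Adam, lr: float) -> float:
        """One Adam step on an NHWC batch with NHWC one-hot targets."""
        logits = self.forward(images, train=True)
        probs = softmax(logits, axis=-1)
        loss, gprob = tversky_loss_and_grad(probs, targets, tversky, class_axis=-1)
        # softmax backward: dL/dz = p * (g - sum_c g_c p_c)
        gz = probs * (gprob - (gprob * probs).sum(axis=-1, keepdims=True))
        self.backward(gz.astype(np.float32))
        opt.step(self.gradients(), lr)
        return loss

    def predict_proba(self, frame: np.ndarray) -> np.ndarray:
        """Class probabilities (C, H, W) for an arbitrary-size frame."""
        frame = np.asarray(frame, dtype=np.float32)
        if frame.ndim != 2:
            raise ValueError("frame must be 2-D")
        padded, (ph, pw) = pad_to_multiple(frame, 2**self.cfg.n_stages)
        logits = self.forward(padded[None, :, :, None], train=False)
        probs = softmax(logits, axis=-1)[0].transpose(2, 0, 1)
        h, w = frame.shape
        return probs[:, :h, :w]

    def fit(
        self,
        images: np.ndarray,
        targets: np.ndarray,
        tversky: TverskyConfig,
        train_cfg: TrainConfig,
    ) -> list[float]:
        """Mini-batch Adam training; returns the per-epoch mean loss.

        The learning rate decays by ``lr_decay_per_epoch`` each epoch
        (lr_e = lr * decay**e) and data are shuffled before each epoch.
        """
        train_cfg.validate()
        tversky.validate()
        images = np.asarray(images, dtype=np.float32)
        targets = np.asarray(targets, dtype=np.float32)
        if images.ndim == 4 and images.shape[1] == 1:  # NCHW -> NHWC
            images = images.transpose(0, 2, 3, 1)
        if targets.shape[1] == self.cfg.n_classes and targets.shape[-1] != self.cfg.n_classes:
            targets = targets.transpose(0, 2, 3, 1)
        n = images.shape[0]
        if n == 0:
            raise ValueError("empty training set")
        rng = np.random.default_rng(train_cfg.seed)
        opt = Adam(self.parameters())
        history: list[float] = []
        for epoch in range(train_cfg.epochs):
            lr = train_cfg.lr * train_cfg.lr_decay_per_epoch**epoch
            order = rng.permutation(n) if train_cfg.shuffle_each_epoch else np.arange(n)
            losses = []
            for start in range(0, n, train_cfg.batch_size):
                idx = order[start : start + train_cfg.batch_size]
                losses.append(self.train_step(images[idx], targets[idx], tversky, opt, lr))
            history.append(float(np.mean(losses)))
        return history
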