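"""Residual dual-frame U-Net assembled from the NumPy layers.

The network maps a normalized sparse-view image to its pure-artifact
residual (same shape). Decoder widths mirror the encoder: each decoder
block's second convolution halves the channel count, which makes every
dual-frame bridge (pooled encoder output added to the decoder input
before upsampling) channel-matched and parameter-free.
"""

from __future__ import annotations

import copy

import numpy as np

from sparsect.model.config import UNetConfig
from sparsect.model.layers import (
    DTYPE,
    BatchNorm2d,
    Conv2d,
    Layer,
    MaxPool2x2,
    ReLU,
    UpsampleNearest2x2,
)


class _ConvBNRelu:
    def __init__(self, cin: int, cout: int, k: int, cfg: UNetConfig, rng: np.random.Generator) -> None:
        self.conv = Conv2d(cin, cout, k, bias=cfg.conv_bias, rng=rng)
        self.bn = BatchNorm2d(cout, affine=cfg.bn_affine)
        self.relu = ReLU()

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        return self.relu.forward(self.bn.forward(self.conv.forward(x, training), training), training)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.conv.backward(self.bn.backward(self.relu.backward(dy)))

    @property
    def layers(self) -> list[Layer]:
        return [self.conv, self.bn, self.relu]


class ResidualModel:
    """Dual-frame U-Net with manual forward/backward graph traversal."""

    def __init__(self, config: UNetConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        enc = config.encoder_channels
        bott = config.bottleneck_channels
        k = config.kernel_size

        self.enc_blocks: list[tuple[_ConvBNRelu, _ConvBNRelu]] = []
        cin = config.in_channels
        for c in enc:
            self.enc_blocks.append(
                (_ConvBNRelu(cin, c, k, config, rng), _ConvBNRelu(c, c, k, config, rng))
            )
            cin = c
        self.pools = [MaxPool2x2() for _ in enc]

        self.bott1 = _ConvBNRelu(enc[-1], bott, k, config, rng)
        self.bott2 = _ConvBNRelu(bott, enc[-1], k, config, rng)

        # decoder from deepest to shallowest; block i consumes concat(up, skip_i)
        self.upsamples = [UpsampleNearest2x2() for _ in enc]
        self.dec_blocks: list[tuple[_ConvBNRelu, _ConvBNRelu]] = []
        for i in reversed(range(config.depth)):
            c = enc[i]
            c_out = enc[i - 1] if i > 0 else enc[0]
            self.dec_blocks.append(
                (_ConvBNRelu(2 * c, c, k, config, rng), _ConvBNRelu(c, c_out, k, config, rng))
            )
        # near-zero head: a fresh model predicts ~no artifact, which keeps the
        # residual regression well-scaled from the first step
        self.final = Conv2d(enc[0], 1, 1, bias=config.conv_bias, rng=rng, init_scale=0.01)

    # -- plumbing -----------------------------------------------------------

    @property
    def layers(self) -> list[Layer]:
        out: list[Layer] = []
        for b1, b2 in self.enc_blocks:
            out.extend(b1.layers)
            out.extend(b2.layers)
        out.extend(self.pools)
        out.extend(self.bott1.layers)
        out.extend(self.bott2.layers)
        out.extend(self.upsamples)
        for b1, b2 in self.dec_blocks:
            out.extend(b1.layers)
            out.extend(b2.layers)
        out.append(self.final)
        return out

    @property
    def n_skip_pathways(self) -> int:
        """Concatenating skips plus (when dual-frame) additive bridges."""
        return self.config.depth * (2 if self.config.dual_frame else 1)

    def state_dict(self) -> dict:
        state = {}
        for i, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                state[f"{i}.{name}"] = p.copy()
            if isinstance(layer, BatchNorm2d):
                state[f"{i}.running_mean"] = layer.running_mean.copy()
                state[f"{i}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name] = state[f"{i}.{name}"].copy()
            if isinstance(layer, BatchNorm2d):
                layer.running_mean = state[f"{i}.running_mean"].copy()
                layer.running_var = state[f"{i}.running_var"].copy()

    # -- forward / backward -------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError("expected input of shape (N, H, W) or (N, C, H, W)")
        if x.shape[2] % (2**self.config.depth) or x.shape[3] % (2**self.config.depth):
            raise ValueError(
                f"spatial size {x.shape[2:]} must be divisible by 2^depth = {2 ** self.config.depth}"
            )
        return x

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = self._check_input(x)
        skips: list[np.ndarray] = []
        pooled: list[np.ndarray] = []
        for (b1, b2), pool in zip(self.enc_blocks, self.pools):
            x = b2.forward(b1.forward(x, training), training)
            skips.append(x)
            x = pool.forward(x, training)
            pooled.append(x)

        x = self.bott2.forward(self.bott1.forward(x, training), training)

        for j, i in enumerate(reversed(range(self.config.depth))):
            if self.config.dual_frame:
                x = x + pooled[i]
            x = self.upsamples[j].forward(x, training)
            x = np.concatenate([x, skips[i]], axis=1)
            b1, b2 = self.dec_blocks[j]
            x = b2.forward(b1.forward(x, training), training)
        return self.final.forward(x, training)

    def backward(self, dy: np.ndarray) -> None:
        """Backpropagate the loss gradient; gradients land in layer.grads."""
        d = self.final.backward(dy)
        dskips: dict[int, np.ndarray] = {}
        dpooled: dict[int, np.ndarray] = {}
        for j in reversed(range(self.config.depth)):
            i = self.config.depth - 1 - j
            b1, b2 = self.dec_blocks[j]
            d = b1.backward(b2.backward(d))
            c = self.config.encoder_channels[i]
            d, dskip = d[:, :c], d[:, c:]
            dskips[i] = dskip
            d = self.upsamples[j].backward(d)
            if self.config.dual_frame:
                dpooled[i] = d  # additive bridge: gradient passes through unchanged
        d = self.bott1.backward(self.bott2.backward(d))
        for i in reversed(range(self.config.depth)):
            if self.config.dual_frame:
                d = d + dpooled[i]  # gradient of the additive bridge, at the pool output
            d = self.pools[i].backward(d)
            d = d + dskips[i]
            b1, b2 = self.enc_blocks[i]
            d = b1.backward(b2.backward(d))


def build_model(config: UNetConfig) -> ResidualModel:
    """Instantiate the network with seeded random initialization."""
    return ResidualModel(config)


def count_parameters(model: ResidualModel) -> int:
    """Total trainable parameters (kernel weights, biases, BN affine terms).

    Under the paper configuration (bias-free convs, non-affine batch norm)
    this reproduces the published total of 21,971,584 exactly; batch-norm
    running statistics are non-trainable state and are not counted.
    """
    return int(sum(layer.parameter_count() for layer in model.layers))


def predict_residual(model: ResidualModel, sparse_batch: np.ndarray) -> np.ndarray:
    """Inference-mode residual prediction (batch norm uses running stats)."""
    x = np.asarray(sparse_batch)
    squeeze = x.ndim == 2
    out = model.forward(x, training=False)
    out = out[:, 0]
    return out[0] if squeeze else out


def clone_model(model: ResidualModel) -> ResidualModel:
    """Deep copy with identical weights and running statistics."""
    m = ResidualModel(model.config)
    m.load_state_dict(model.state_dict())
    return m


__all__ = [
    "ResidualModel",
    "build_model",
    "count_parameters",
    "predict_residual",
    "clone_model",
]
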